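"""EEG session data model, CSV I/O, channel blocks and segmentation.

An :class:`EEGSession` is a sampled multichannel recording (samples ×
channels), its channel names (10–20 montage labels), the sampling rate and a
cue-event track labelling every sample as waiting (0), left (1) or right (2).

On disk a session is two plain CSV files:

* ``<name>.csv`` — one line ``# sample_rate=<Hz>`` followed by a header of
  channel names and one row of floats per sample (C locale).
* ``<name>.events.csv`` — columns ``label,onset_sample,duration_samples``.

The channel *blocks* are the ordered 4-tuples of channels fed to the
quaternion constructor: the first channel becomes the scalar component and
the remaining three the vector part.  :func:`standard_blocks` returns the ten
published block definitions verbatim (note blocks 5 and 6 are printed
identically; they are reproduced as-is rather than silently "fixed").

All sample coordinates are 0-based and half-open: a segment covers
``[start_sample, start_sample + length)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd


class SessionFormatError(ValueError):
    """A session or events file violates the on-disk contract."""


class ConfigError(ValueError):
    """An invalid configuration value was supplied."""


#: Electrode labels of the extended international 10–20 placement system
#: (10-10 superset) accepted for channel names.
TEN_TWENTY_LABELS = frozenset(
    """
    Fp1 Fpz Fp2 AF7 AF3 AFz AF4 AF8
    F7 F5 F3 F1 Fz F2 F4 F6 F8
    FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8
    T7 C5 C3 C1 Cz C2 C4 C6 T8
    TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8
    P7 P5 P3 P1 Pz P2 P4 P6 P8
    PO7 PO3 POz PO4 PO8 O1 Oz O2
    """.split()
)

VALID_LABELS = (0, 1, 2)


class Event(NamedTuple):
    """One cue or rest interval of the recording."""

    label: int
    onset_sample: int
    duration_samples: int


@dataclass(frozen=True)
class ChannelBlock:
    """Ordered 4-tuple of channel names; the first is the scalar channel."""

    block_id: int
    names: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.names) != 4:
            raise ConfigError(
                f"block {self.block_id}: expected exactly 4 channel names, "
                f"got {len(self.names)}"
            )


@dataclass(frozen=True)
class Segment:
    """A maximal run of constant class label; half-open sample range."""

    label: int
    start_sample: int
    length: int

    @property
    def stop_sample(self) -> int:
        return self.start_sample + self.length


@dataclass
class EEGSession:
    """A multichannel EEG recording with a tiling cue-event track."""

    sample_rate: float
    channel_names: list[str]
    data: np.ndarray
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise SessionFormatError(
                f"session data must be samples × channels, got shape "
                f"{self.data.shape}"
            )
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise SessionFormatError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} data columns"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise SessionFormatError("duplicate channel name in header")
        if not self.sample_rate > 0:
            raise ConfigError(f"sample_rate must be positive, got {self.sample_rate}")
        self.events = [Event(*ev) for ev in self.events]
        self._validate_events()

    def _validate_events(self) -> None:
        # Events must tile [0, n_samples) exactly: every sample gets one label.
        expected_onset = 0
        for i, ev in enumerate(self.events):
            if ev.label not in VALID_LABELS:
                raise SessionFormatError(
                    f"event row {i}: label {ev.label} not in {VALID_LABELS}"
                )
            if ev.duration_samples <= 0:
                raise SessionFormatError(
                    f"event row {i}: non-positive duration {ev.duration_samples}"
                )
            if ev.onset_sample != expected_onset:
                raise SessionFormatError(
                    f"event row {i}: onset {ev.onset_sample} does not meet the "
                    f"previous event's end {expected_onset}; events must tile "
                    f"the recording without gap or overlap"
                )
            expected_onset += ev.duration_samples
        if expected_onset != self.n_samples:
            raise SessionFormatError(
                f"events cover {expected_onset} samples but the recording has "
                f"{self.n_samples}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 1-D view, by 10–20 label."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in session (has {self.channel_names})"
            ) from None
        return self.data[:, idx]

    def label_track(self) -> np.ndarray:
        """Per-sample class labels, expanded from the event track."""
        if not self.events:
            return np.zeros(0, dtype=int)
        labels = [ev.label for ev in self.events]
        lengths = [ev.duration_samples for ev in self.events]
        return np.repeat(np.asarray(labels, dtype=int), lengths)


# ---------------------------------------------------------------------------
# Published channel blocks
# ---------------------------------------------------------------------------

_BLOCK_TABLE: tuple[tuple[str, str, str, str], ...] = (
    ("FC5", "FC6", "P7", "P8"),
    ("FC5", "FC6", "T7", "T8"),
    ("FC6", "FC5", "P7", "P8"),
    ("FC6", "FC5", "T7", "T8"),
    ("F3", "F4", "FC5", "FC6"),
    ("F3", "F4", "FC5", "FC6"),  # printed identical to block 5; kept verbatim
    ("F4", "F3", "FC5", "FC6"),
    ("F4", "F3", "T7", "T8"),
    ("T7", "T8", "FC5", "FC6"),
    ("T7", "T8", "P7", "P8"),
)


def standard_blocks() -> list[ChannelBlock]:
    """The ten published channel blocks, in order, ids 1..10."""
    return [ChannelBlock(i + 1, names) for i, names in enumerate(_BLOCK_TABLE)]


def get_block(block_id: int) -> ChannelBlock:
    """Look up one standard block by its 1-based id."""
    if not 1 <= block_id <= len(_BLOCK_TABLE):
        raise ConfigError(
            f"block id must be in 1..{len(_BLOCK_TABLE)}, got {block_id}"
        )
    return ChannelBlock(block_id, _BLOCK_TABLE[block_id - 1])


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_session(session: EEGSession) -> list[Segment]:
    """Split the session at class changes.

    Returns one :class:`Segment` per maximal run of constant label, in
    temporal order; consecutive events carrying the same label are merged.
    """
    if session.n_samples == 0 or not session.events:
        raise SessionFormatError("cannot segment an empty session")
    segments: list[Segment] = []
    for ev in session.events:
        if segments and segments[-1].label == ev.label:
            prev = segments.pop()
            segments.append(
                Segment(prev.label, prev.start_sample, prev.length + ev.duration_samples)
            )
        else:
            segments.append(Segment(ev.label, ev.onset_sample, ev.duration_samples))
    return segments


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def default_events_path(path: str | Path) -> Path:
    """``s.csv`` → ``s.events.csv`` (the canonical sidecar name)."""
    path = Path(path)
    return path.with_name(path.stem + ".events" + path.suffix)


def write_session(
    session: EEGSession, path: str | Path, events_path: str | Path | None = None
) -> None:
    """Write the session CSV and its events sidecar.

    The float formatting is the shortest round-tripping repr, so
    write → read reproduces the matrix bit-exactly for finite values.
    """
    path = Path(path)
    events_path = Path(events_path) if events_path else default_events_path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# sample_rate={session.sample_rate!r}\n")
        frame = pd.DataFrame(session.data, columns=session.channel_names)
        # repr is the shortest representation that round-trips a float64
        frame.to_csv(
            fh, index=False, lineterminator="\n",
            float_format=lambda v: repr(float(v)),
        )
    events = pd.DataFrame(session.events, columns=Event._fields)
    events.to_csv(events_path, index=False, lineterminator="\n")


def read_session(
    path: str | Path, events_path: str | Path | None = None
) -> EEGSession:
    """Read a session CSV plus events sidecar back into an :class:`EEGSession`."""
    path = Path(path)
    events_path = Path(events_path) if events_path else default_events_path(path)
    with open(path) as fh:
        meta = fh.readline().strip()
        if not meta.startswith("# sample_rate="):
            raise SessionFormatError(
                f"{path}: first line must be '# sample_rate=<Hz>', got {meta!r}"
            )
        try:
            sample_rate = float(meta.split("=", 1)[1])
        except ValueError as exc:
            raise SessionFormatError(f"{path}: unreadable sample rate: {exc}") from exc
        header = fh.readline().strip()
        names = header.split(",") if header else []
        if len(set(names)) != len(names):
            raise SessionFormatError(f"{path}: duplicate channel name in header")
        try:
            frame = pd.read_csv(
                fh, header=None, names=names, dtype=float,
                float_precision="round_trip",
            )
        except (pd.errors.ParserError, ValueError) as exc:
            raise SessionFormatError(f"{path}: malformed data row: {exc}") from exc
    if frame.isna().any().any():
        bad = int(frame.index[frame.isna().any(axis=1)][0])
        raise SessionFormatError(f"{path}: ragged or non-numeric data row {bad}")

    try:
        ev_frame = pd.read_csv(events_path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise SessionFormatError(f"{events_path}: malformed events file: {exc}") from exc
    missing = set(Event._fields) - set(ev_frame.columns)
    if missing:
        raise SessionFormatError(
            f"{events_path}: missing column(s) {sorted(missing)}"
        )
    events = [
        Event(int(row.label), int(row.onset_sample), int(row.duration_samples))
        for row in ev_frame.itertuples(index=False)
    ]
    return EEGSession(
        sample_rate=sample_rate,
        channel_names=names,
        data=frame.to_numpy(dtype=float),
        events=events,
    )


def require_channels(session: EEGSession, names: Sequence[str]) -> np.ndarray:
    """Column indices of ``names`` in the session; error names the culprit."""
    idx = []
    for name in names:
        if name not in session.channel_names:
            raise SessionFormatError(
                f"channel {name!r} not present in session "
                f"(has {session.channel_names})"
            )
        idx.append(session.channel_names.index(name))
    return np.asarray(idx, dtype=int)
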