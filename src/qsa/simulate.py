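"""Seeded synthetic EEG sessions following the visual-cue BCI protocol.

The generator emulates a standard motor-imagery acquisition session: the
subject watches 40 directional arrows (left/right strictly alternating,
starting left), each shown for 10 s and followed by a 5 s rest cross, at a
device rate of 128 Hz over eight motor/frontal channels — 600 s and 76,800
samples per channel in total.

The signal model is deliberately minimal: every channel carries i.i.d.
Gaussian baseline noise plus a mu-band (10 Hz by default) sinusoid with a
per-channel random phase.  Class information enters through event-related
desynchronisation (ERD): during a cue, the oscillation amplitude on the
hemisphere contralateral to the imagined movement is attenuated by
``1 − erd_factor``.  Imagining *left* attenuates the right-hemisphere
channels (FC6, P8, T8, F4) and vice versa; rest attenuates nothing.  This is
the textbook mu-rhythm signature reduced to its separable essence — no 1/f
background, no artifacts, no inter-subject variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .sessions import (
    TEN_TWENTY_LABELS,
    ConfigError,
    EEGSession,
    Event,
)

#: The eight recorded channels, in acquisition order.
DEFAULT_CHANNELS: tuple[str, ...] = ("FC5", "FC6", "P7", "P8", "T7", "T8", "F3", "F4")

#: Contralateral ERD: class 1 (left) attenuates right-hemisphere channels,
#: class 2 (right) attenuates left-hemisphere channels.
DEFAULT_LATERAL_MAP: dict[int, tuple[str, ...]] = {
    1: ("FC6", "P8", "T8", "F4"),
    2: ("FC5", "P7", "T7", "F3"),
}


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and montage of one cue-protocol session.

    Defaults reproduce the acquisition protocol: 40 cues × (10 s cue + 5 s
    rest) at 128 Hz = 600 s = 76,800 samples per channel.  Every cue,
    including the last, is followed by its rest period.
    """

    cue_duration: float = 10.0
    rest_duration: float = 5.0
    n_cues: int = 40
    sample_rate: float = 128.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if self.cue_duration <= 0 or self.rest_duration <= 0:
            raise ConfigError("cue and rest durations must be positive")
        if self.n_cues < 1:
            raise ConfigError(f"n_cues must be >= 1, got {self.n_cues}")
        if self.sample_rate <= 0:
            raise ConfigError(f"sample_rate must be positive, got {self.sample_rate}")
        if len(set(self.channels)) != len(self.channels):
            raise ConfigError("channel names must be unique")
        unknown = [c for c in self.channels if c not in TEN_TWENTY_LABELS]
        if unknown:
            raise ConfigError(
                f"channel(s) {unknown} are not 10-20 montage labels"
            )

    @property
    def cue_samples(self) -> int:
        return int(round(self.cue_duration * self.sample_rate))

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_duration * self.sample_rate))

    @property
    def n_samples(self) -> int:
        """Total samples per channel for the whole session."""
        return self.n_cues * (self.cue_samples + self.rest_samples)

    def events(self) -> list[Event]:
        """The cue/rest event track: left and right alternate, starting left."""
        out: list[Event] = []
        onset = 0
        for k in range(self.n_cues):
            label = 1 if k % 2 == 0 else 2
            out.append(Event(label, onset, self.cue_samples))
            onset += self.cue_samples
            out.append(Event(0, onset, self.rest_samples))
            onset += self.rest_samples
        return out


@dataclass(frozen=True)
class SignalModelParams:
    """Parameters of the lateralised oscillatory signal model.

    ``baseline_sigma`` is the standard deviation of the Gaussian noise floor,
    ``osc_freq``/``osc_amp`` describe the mu-band oscillation, and
    ``erd_factor`` ∈ [0, 1) is the fractional amplitude attenuation applied
    to ``lateral_map[class]`` channels while that class's cue is on screen.
    ``erd_factor=0`` produces a session with no class information at all —
    the negative control used in testing.
    """

    baseline_sigma: float = 0.1
    osc_freq: float = 10.0
    osc_amp: float = 1.0
    erd_factor: float = 0.8
    lateral_map: Mapping[int, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_LATERAL_MAP)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_sigma < 0:
            raise ConfigError("baseline_sigma must be >= 0")
        if self.osc_amp < 0:
            raise ConfigError("osc_amp must be >= 0")
        if not 0 <= self.erd_factor < 1:
            raise ConfigError(
                f"erd_factor must be in [0, 1), got {self.erd_factor}"
            )


def label_track(protocol: ProtocolSpec) -> np.ndarray:
    """Per-sample class labels in {0, 1, 2} for the protocol.

    Deterministic: cues alternate 1, 2, 1, 2, ... each followed by a rest
    block of zeros; length is ``protocol.n_samples``.
    """
    labels = [ev.label for ev in protocol.events()]
    lengths = [ev.duration_samples for ev in protocol.events()]
    return np.repeat(np.asarray(labels, dtype=int), lengths)


def generate_session(
    protocol: ProtocolSpec, model: SignalModelParams | None = None
) -> EEGSession:
    """Generate one seeded synthetic session under the signal model.

    Each channel c is ``gain(t) · osc_amp · sin(2π f t + φ_c) + ε(t)`` with
    ``ε ~ N(0, baseline_sigma²)`` i.i.d., φ_c drawn uniformly per channel per
    session, and ``gain(t) = 1 − erd_factor`` while a cue of a class that
    attenuates c is active, 1 otherwise.  The same seed always reproduces the
    identical session.
    """
    model = model if model is not None else SignalModelParams()
    for cls, chans in model.lateral_map.items():
        if cls not in (0, 1, 2):
            raise ConfigError(f"lateral_map class {cls} not in (0, 1, 2)")
        for name in chans:
            if name not in protocol.channels:
                raise ConfigError(
                    f"lateral_map channel {name!r} is not in the protocol "
                    f"channels {list(protocol.channels)}"
                )

    rng = np.random.default_rng(model.seed)
    n = protocol.n_samples
    n_ch = len(protocol.channels)
    labels = label_track(protocol)
    t = np.arange(n) / protocol.sample_rate

    phases = rng.uniform(0.0, 2.0 * math.pi, size=n_ch)
    noise = rng.normal(0.0, model.baseline_sigma, size=(n, n_ch))

    data = np.empty((n, n_ch))
    for c, name in enumerate(protocol.channels):
        gain = np.ones(n)
        for cls, chans in model.lateral_map.items():
            if name in chans:
                gain[labels == cls] = 1.0 - model.erd_factor
        data[:, c] = (
            gain * model.osc_amp * np.sin(2.0 * math.pi * model.osc_freq * t + phases[c])
            + noise[:, c]
        )

    return EEGSession(
        sample_rate=protocol.sample_rate,
        channel_names=list(protocol.channels),
        data=data,
        events=protocol.events(),
    )
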