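"""Independent reference implementations used as oracles by the tests.

Everything here is deliberately scalar and loop-based, sharing no code path
with the vectorised pipeline it checks (the rotation-matrix oracle does not
use quaternion multiplication at all).
"""

from __future__ import annotations

import numpy as np

from qsa.quaternion import PureQuaternion, Quaternion, q_inv, q_mul
from qsa.sessions import ChannelBlock, EEGSession


def rotation_matrix_from_quaternion(w: float, x: float, y: float, z: float) -> np.ndarray:
    """The 3×3 rotation matrix of the normalised quaternion (w, x, y, z)."""
    n = np.sqrt(w * w + x * x + y * y + z * z)
    w, x, y, z = w / n, x / n, y / n, z / n
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def naive_qsa_features(
    session: EEGSession,
    block: ChannelBlock,
    dt: int,
    feature_names: tuple[str, ...] = ("mean", "variance", "contrast", "homogeneity"),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample scalar re-implementation of the QSA transform.

    Builds one Quaternion per sample, rotates the lagged pure quaternion with
    the scalar algebra (q ⊗ r ⊗ q⁻¹), takes moduli, then computes the
    statistics with plain Python loops per maximal constant-label run,
    dropping the t < dt prefix.  Returns (M, labels).
    """
    cols = [session.channel_names.index(n) for n in block.names]
    n = session.n_samples
    q_mod = np.empty(n)
    q_mod[:dt] = np.nan
    for t in range(dt, n):
        qt = Quaternion(*(session.data[t, c] for c in cols))
        rt = PureQuaternion(*(session.data[t - dt, c] for c in cols[1:]))
        rot = q_mul(q_mul(qt, rt.as_quaternion()), q_inv(qt))
        q_mod[t] = np.sqrt(rot.w**2 + rot.x**2 + rot.y**2 + rot.z**2)

    track = session.label_track()
    bounds = [0] + [t for t in range(1, n) if track[t] != track[t - 1]] + [n]
    rows, labels = [], []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        window = [q_mod[t] for t in range(max(lo, dt), hi)]
        m = len(window)
        mu = sum(window) / m
        row = []
        for name in feature_names:
            if name == "mean":
                row.append(mu)
            elif name == "variance":
                row.append(sum((v - mu) ** 2 for v in window) / (m - 1))
            elif name == "contrast":
                row.append(sum(v * v for v in window) / m**2)
            elif name == "homogeneity":
                row.append(sum(1.0 / (1.0 + v * v) for v in window))
            elif name == "cluster_shade":
                row.append(sum((v - mu) ** 3 for v in window))
            elif name == "cluster_prominence":
                row.append(sum((v - mu) ** 4 for v in window))
            else:
                raise ValueError(name)
        rows.append(row)
        labels.append(int(track[lo]))
    return np.array(rows), np.array(labels)


def recount_metrics(cm: np.ndarray, d: int) -> dict[str, float | None]:
    """Brute-force per-class metrics by expanding the matrix into label pairs."""
    pairs = [
        (true, pred)
        for true in range(3)
        for pred in range(3)
        for _ in range(int(cm[true, pred]))
    ]
    n_d = sum(1 for t, _ in pairs if t == d)
    not_d = [p for p in pairs if p[0] != d]
    pred_d = sum(1 for _, p in pairs if p == d)
    s = sum(1 for t, p in pairs if t == d and t == p) / n_d if n_d else None
    sp = sum(1 for t, p in not_d if t == p) / len(not_d) if not_d else None
    a = sum(1 for t, p in pairs if t == d and t == p) / pred_d if pred_d else None
    return {"S": s, "Sp": sp, "A": a}
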