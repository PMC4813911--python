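"""Quaternion algebra and 3-D rotation operators.

A quaternion q = w + ix + jy + kz has one real (scalar) component ``w`` and a
three-component vector part ``(x, y, z)`` attached to the imaginary units
i, j, k, which satisfy i² = j² = k² = ijk = −1.  The analysis pipeline in
:mod:`qsa.features` treats each four-channel EEG sample as one quaternion and
uses the rotation operator q ⊗ r ⊗ q⁻¹ to fold the four channels into a
single scalar series, so this module is the algebraic foundation of
everything downstream.

Two representations are provided:

* :class:`Quaternion` / :class:`PureQuaternion` — immutable scalar objects
  with the textbook operations (``q_add``, ``q_mul``, ``rotate`` ...), used
  for clarity and as the reference semantics.
* array helpers (:func:`hamilton_product`, :func:`conjugate_array`,
  :func:`norm_array`) operating on ``(..., 4)`` float arrays in
  ``(w, x, y, z)`` order, used to process whole EEG streams at once.

Component storage order is ``(w, x, y, z)`` everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Absolute tolerance used for floating-point comparisons throughout the
#: package (double precision with O(10) flops per operation).
ATOL = 1e-9

#: Maximum deviation from unit norm tolerated by :func:`from_axis_angle`;
#: axes within this band are renormalised, anything further off is an error.
AXIS_UNIT_TOL = 1e-6


class NonInvertibleError(ZeroDivisionError):
    """The zero quaternion has no inverse and defines no rotation."""


@dataclass(frozen=True)
class Quaternion:
    """A quaternion w + ix + jy + kz with real components."""

    w: float
    x: float
    y: float
    z: float

    @property
    def vector(self) -> tuple[float, float, float]:
        """The vector part (x, y, z)."""
        return (self.x, self.y, self.z)

    def __add__(self, other: "Quaternion") -> "Quaternion":
        return q_add(self, other)

    def __mul__(self, other: "Quaternion") -> "Quaternion":
        return q_mul(self, other)

    def __neg__(self) -> "Quaternion":
        return Quaternion(-self.w, -self.x, -self.y, -self.z)


@dataclass(frozen=True)
class PureQuaternion:
    """A quaternion with zero scalar part; represents a 3-vector."""

    x: float
    y: float
    z: float

    def as_quaternion(self) -> Quaternion:
        return Quaternion(0.0, self.x, self.y, self.z)

    def norm(self) -> float:
        return math.sqrt(self.x * self.x + self.y * self.y + self.z * self.z)


IDENTITY = Quaternion(1.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Scalar operations
# ---------------------------------------------------------------------------

def q_add(q: Quaternion, p: Quaternion) -> Quaternion:
    """Componentwise sum (s_q + s_p, v_q + v_p)."""
    return Quaternion(q.w + p.w, q.x + p.x, q.y + p.y, q.z + p.z)


def q_mul(q: Quaternion, p: Quaternion) -> Quaternion:
    """Hamilton product q ⊗ p.

    Scalar part is s_q s_p − v_q·v_p; vector part is
    s_p v_q + s_q v_p + v_q×v_p.  Non-commutative: ij = k but ji = −k.
    """
    return Quaternion(
        q.w * p.w - q.x * p.x - q.y * p.y - q.z * p.z,
        q.w * p.x + q.x * p.w + q.y * p.z - q.z * p.y,
        q.w * p.y - q.x * p.z + q.y * p.w + q.z * p.x,
        q.w * p.z + q.x * p.y - q.y * p.x + q.z * p.w,
    )


def q_dot(q: Quaternion, p: Quaternion) -> float:
    """Real inner product of the two 4-vectors: s_q s_p + v_q·v_p."""
    return q.w * p.w + q.x * p.x + q.y * p.y + q.z * p.z


def q_conj(q: Quaternion) -> Quaternion:
    """Conjugate q̄ = (s_q, −v_q)."""
    return Quaternion(q.w, -q.x, -q.y, -q.z)


def q_norm(q: Quaternion) -> float:
    """Euclidean norm of the 4-vector; multiplicative over ⊗."""
    return math.sqrt(q.w * q.w + q.x * q.x + q.y * q.y + q.z * q.z)


def q_inv(q: Quaternion) -> Quaternion:
    """Inverse q⁻¹ = q̄ / ‖q‖², so that q ⊗ q⁻¹ = (1, 0, 0, 0).

    Raises :class:`NonInvertibleError` for the zero quaternion.
    """
    n2 = q.w * q.w + q.x * q.x + q.y * q.y + q.z * q.z
    if n2 == 0.0:
        raise NonInvertibleError("the zero quaternion is not invertible")
    return Quaternion(q.w / n2, -q.x / n2, -q.y / n2, -q.z / n2)


def from_axis_angle(axis: PureQuaternion, theta: float) -> Quaternion:
    """Unit quaternion for a rotation of ``theta`` radians about ``axis``.

    q = cos(θ/2) + a·sin(θ/2) with ``a`` the unit rotation axis.  The axis
    must be unit length; deviations up to ``AXIS_UNIT_TOL`` are renormalised
    (float drift), larger deviations raise ``ValueError`` (misuse).
    """
    n = axis.norm()
    if abs(n - 1.0) > AXIS_UNIT_TOL:
        raise ValueError(f"rotation axis must be unit length, got norm {n!r}")
    half = 0.5 * theta
    s = math.sin(half) / n
    return Quaternion(math.cos(half), axis.x * s, axis.y * s, axis.z * s)


def rotate(q: Quaternion, r: PureQuaternion) -> PureQuaternion:
    """Rotate the vector r by q: r′ = q ⊗ r ⊗ q⁻¹.

    Uses the true inverse q̄/‖q‖², so any nonzero q (not only unit
    quaternions) acts as the rotation of its normalised self: the result is
    pure and ‖r′‖ = ‖r‖.  Raises :class:`NonInvertibleError` for zero q.
    """
    res = q_mul(q_mul(q, r.as_quaternion()), q_inv(q))
    return PureQuaternion(res.x, res.y, res.z)


# ---------------------------------------------------------------------------
# Array operations on (..., 4) streams in (w, x, y, z) order
# ---------------------------------------------------------------------------

def hamilton_product(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise Hamilton product of two ``(..., 4)`` arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    bw, bx, by, bz = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def conjugate_array(a: np.ndarray) -> np.ndarray:
    """Elementwise conjugate of a ``(..., 4)`` array."""
    out = np.array(a, dtype=float, copy=True)
    out[..., 1:] *= -1.0
    return out


def norm_array(a: np.ndarray) -> np.ndarray:
    """Elementwise quaternion norm of a ``(..., 4)`` array."""
    return np.linalg.norm(np.asarray(a, dtype=float), axis=-1)
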