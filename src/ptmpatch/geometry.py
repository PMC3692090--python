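"""Internal-coordinate atom placement.

A new atom D is located relative to three reference atoms: the bond anchor
``c``, the angle reference ``b`` and the dihedral reference ``a``.  The
local frame has its origin at ``c``, its first axis along the b->c bond and
its second axis in the a-b-c plane.

Sign convention: the dihedral a-b-c-d is positive when, sighting along
b->c, d is rotated counter-clockwise from the perpendicular component of
a (right-hand rule about the b->c axis).  ``place_atom`` and
``measure_internal`` are exact inverses under this convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFrameError

_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class InternalCoordinate:
    """Bond length / bond angle / dihedral against three named references."""

    ref_bond: str      # c: atom the new atom bonds to
    ref_angle: str     # b
    ref_dihedral: str  # a
    r: float           # nm
    theta: float       # degrees, angle b-c-D
    phi: float         # degrees, dihedral a-b-c-D

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"bond length must be positive, got {self.r}")
        if not 0 < self.theta < 180:
            raise ValueError(f"bond angle must be in (0, 180), got {self.theta}")
        if not -180 < self.phi <= 180:
            raise ValueError(f"dihedral must be in (-180, 180], got {self.phi}")


@dataclass(frozen=True)
class Frame:
    origin: np.ndarray
    axes: np.ndarray  # rows ex, ey, ez; orthonormal, right-handed


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _COLLINEAR_TOL:
        raise DegenerateFrameError(f"degenerate {what}: zero length")
    return v / n


def build_frame(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> Frame:
    """Right-handed orthonormal frame at ``c`` from three reference points.

    Raises :class:`DegenerateFrameError` when the points are coincident or
    collinear (sine of the a-b-c angle below 1e-8).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    ex = _unit(c - b, "bond b->c")
    v = a - b
    v_perp = v - np.dot(v, ex) * ex
    n = np.linalg.norm(v_perp)
    if n < _COLLINEAR_TOL * max(1.0, np.linalg.norm(v)):
        raise DegenerateFrameError("reference points are collinear or coincident")
    ey = v_perp / n
    ez = np.cross(ex, ey)
    return Frame(origin=c, axes=np.array([ex, ey, ez]))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    r: float,
    theta: float,
    phi: float,
) -> np.ndarray:
    """Cartesian position of atom D with |D-c| = r, angle(b,c,D) = theta
    and dihedral(a,b,c,D) = phi (degrees)."""
    frame = build_frame(a, b, c)
    ex, ey, ez = frame.axes
    th = np.deg2rad(theta)
    ph = np.deg2rad(phi)
    direction = (
        -np.cos(th) * ex
        + np.sin(th) * (np.cos(ph) * ey + np.sin(ph) * ez)
    )
    return frame.origin + r * direction


def place_from_ic(a, b, c, ic: InternalCoordinate) -> np.ndarray:
    return place_atom(a, b, c, ic.r, ic.theta, ic.phi)


def measure_internal(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> tuple[float, float, float]:
    """Inverse of :func:`place_atom`: (r, theta, phi) of d against (a, b, c)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)

    cd = d - c
    r = float(np.linalg.norm(cd))
    if r < _COLLINEAR_TOL:
        raise DegenerateFrameError("coincident atoms c and d")
    cb = _unit(b - c, "bond c->b")
    cos_t = float(np.clip(np.dot(cd / r, cb), -1.0, 1.0))
    theta = float(np.degrees(np.arccos(cos_t)))

    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise DegenerateFrameError("dihedral undefined: collinear references")
    u2 = _unit(b2, "bond b->c")
    phi = float(np.degrees(np.arctan2(np.dot(np.cross(n1, n2), u2), np.dot(n1, n2))))
    return r, theta, phi


def dihedral(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d in degrees (same convention as above)."""
    return measure_internal(a, b, c, d)[2]
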