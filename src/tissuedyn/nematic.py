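"""Symmetric traceless 2x2 tensors (nematics).

A nematic encodes an axis (not a direction) and a magnitude.  It is used
throughout the package for cell elongation, division orientation, T1
orientation and pure shear.  Only two independent components exist::

    n = | xx   xy |
        | xy  -xx |

The polar form is ``xx = norm * cos(2*angle)``, ``xy = norm * sin(2*angle)``
with the angle defined modulo pi (an axis at angle phi and phi + pi is the
same axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Nematic", "nematic_polar", "from_axis_angle", "EPS_GENERATOR"]

#: antisymmetric generator of in-plane rotations, e = [[0, -1], [1, 0]]
EPS_GENERATOR = np.array([[0.0, -1.0], [1.0, 0.0]])


@dataclass(frozen=True)
class Nematic:
    """A symmetric traceless 2x2 tensor with components ``xx`` and ``xy``."""

    xx: float = 0.0
    xy: float = 0.0

    @property
    def norm(self) -> float:
        return math.hypot(self.xx, self.xy)

    @property
    def angle(self) -> float:
        """Axis angle in [0, pi); 0 for the zero tensor."""
        if self.norm == 0.0:
            return 0.0
        a = 0.5 * math.atan2(self.xy, self.xx)
        return a % math.pi

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.xx, self.xy], [self.xy, -self.xx]])

    def rotated(self, theta: float) -> "Nematic":
        """Return the tensor after rotating the underlying axes by ``theta``."""
        c, s = math.cos(2.0 * theta), math.sin(2.0 * theta)
        return Nematic(c * self.xx - s * self.xy, s * self.xx + c * self.xy)

    def __add__(self, other: "Nematic") -> "Nematic":
        return Nematic(self.xx + other.xx, self.xy + other.xy)

    def __sub__(self, other: "Nematic") -> "Nematic":
        return Nematic(self.xx - other.xx, self.xy - other.xy)

    def __neg__(self) -> "Nematic":
        return Nematic(-self.xx, -self.xy)

    def __mul__(self, k: float) -> "Nematic":
        return Nematic(self.xx * k, self.xy * k)

    __rmul__ = __mul__

    def __truediv__(self, k: float) -> "Nematic":
        return Nematic(self.xx / k, self.xy / k)

    @staticmethod
    def from_matrix(m: np.ndarray) -> "Nematic":
        """Project a 2x2 matrix onto its symmetric traceless part."""
        return Nematic(0.5 * (m[0, 0] - m[1, 1]), 0.5 * (m[0, 1] + m[1, 0]))


def from_axis_angle(norm: float, angle: float) -> Nematic:
    """Build a nematic from magnitude and axis angle."""
    return Nematic(norm * math.cos(2.0 * angle), norm * math.sin(2.0 * angle))


def nematic_polar(n: Nematic) -> tuple[float, float]:
    """Return ``(norm, angle)`` with the angle in [0, pi).

    The zero tensor has an undefined axis; it is reported as angle 0.
    """
    return n.norm, n.angle
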