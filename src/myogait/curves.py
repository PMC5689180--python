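"""Normalized Hill-model constitutive curves.

All curves are dimensionless: forces are normalized by the maximum
isometric force F_o, fiber lengths by the optimal fiber length L_o, fiber
velocities by V_max, and tendon deformation is expressed as engineering
strain relative to the slack length.

The shapes are the standard smooth parameterizations of the generic
Hill-type curve family:

* active force-length: Gaussian bump centered at the optimal length,
  ``f_L(l) = exp(-(l - 1)^2 / w)`` with width ``w = 0.45``;
* passive force-length: zero at or below the optimal length, exponential
  rise reaching 1 at a normalized length of 1.7;
* force-velocity: Hill hyperbola on the shortening side (zero force at
  maximal shortening, 1 at zero velocity) and a saturating eccentric
  branch with plateau 1.4 whose slope at zero velocity is twice the
  concentric slope, the standard stiff eccentric response of this model
  family;
* tendon force-strain: quadratic toe region up to one third of the
  reference strain, then linear, calibrated so the normalized force is
  exactly 1 at the reference strain ``eps_o`` (default 4.9 %, plausible
  range 2-9 %).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CurveSet", "default_curves"]

_ECC_PLATEAU = 1.4  # eccentric force-velocity asymptote
_HILL_A = 0.25      # Hill shortening curvature constant
_FL_WIDTH = 0.45    # Gaussian active force-length width
_FP_MAX_LEN = 1.7   # normalized length at which passive force reaches 1
_FP_SHAPE = 4.0     # passive exponential shape constant


@dataclass(frozen=True)
class CurveSet:
    """The four normalized constitutive curves of a Hill-type muscle model.

    Parameters
    ----------
    eps_o:
        Tendon strain at which the normalized tendon force equals 1, i.e.
        the strain when the fiber develops maximum isometric force.
        Default 0.049; admissible range [0.02, 0.09].
    """

    eps_o: float = 0.049

    def __post_init__(self):
        if not (0.0 < self.eps_o <= 0.2):
            raise ValueError(f"eps_o={self.eps_o} outside sensible range (0, 0.2]")

    # -- fiber force-length ------------------------------------------------

    def active_fl(self, l_norm):
        """Active force-length multiplier f_L at normalized fiber length."""
        l = np.asarray(l_norm, dtype=float)
        return np.exp(-((l - 1.0) ** 2) / _FL_WIDTH)

    def passive_fl(self, l_norm):
        """Passive fiber force f_P; zero at or below optimal length."""
        l = np.asarray(l_norm, dtype=float)
        scale = math.expm1(_FP_SHAPE * (_FP_MAX_LEN - 1.0))
        out = np.expm1(_FP_SHAPE * np.maximum(l - 1.0, 0.0)) / scale
        return out

    # -- fiber force-velocity ----------------------------------------------

    def force_velocity(self, v_norm):
        """Force-velocity multiplier f_V; v < 0 is shortening, v > 0 lengthening."""
        v = np.asarray(v_norm, dtype=float)
        v = np.clip(v, -1.0, None)
        # shortening: Hill hyperbola, f(−1)=0, f(0)=1, slope 1/a+1 at 0
        short = (1.0 + v) / (1.0 - v / _HILL_A)
        # eccentric: saturating branch, slope 2*(1 + 1/a) at v=0 (stiff
        # eccentric response, as in the standard curve family)
        slope0 = 2.0 * (1.0 + 1.0 / _HILL_A)
        b = (_ECC_PLATEAU - 1.0) / slope0
        ecc = 1.0 + (_ECC_PLATEAU - 1.0) * v / (v + b)
        return np.where(v < 0.0, short, ecc)

    def force_velocity_inverse(self, f):
        """Normalized fiber velocity at force multiplier f (clamped to range)."""
        f = np.asarray(f, dtype=float)
        fc = np.clip(f, 0.0, _ECC_PLATEAU * (1.0 - 1e-9))
        # shortening branch: f = (1+v)/(1 - v/a)  =>  v = (f-1)/(1 + f/a)
        v_short = (fc - 1.0) / (1.0 + fc / _HILL_A)
        # eccentric branch: f = 1 + df*v/(v+b)  =>  v = b*(f-1)/(df - (f-1))
        slope0 = 2.0 * (1.0 + 1.0 / _HILL_A)
        b = (_ECC_PLATEAU - 1.0) / slope0
        df = _ECC_PLATEAU - 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            v_ecc = b * (fc - 1.0) / (df - (fc - 1.0))
        return np.where(fc <= 1.0, v_short, v_ecc)

    # -- tendon force-strain -----------------------------------------------

    @property
    def _toe_strain(self) -> float:
        return self.eps_o / 3.0

    @property
    def _toe_quad(self) -> float:
        # c such that quadratic toe + continuous linear limb give f(eps_o)=1
        return 9.0 / (5.0 * self.eps_o**2)

    def tendon(self, strain):
        """Normalized tendon force at engineering strain (0 for slack tendon)."""
        e = np.asarray(strain, dtype=float)
        c = self._toe_quad
        et = self._toe_strain
        k = 2.0 * c * et  # linear-limb slope (slope continuity at toe end)
        toe = c * np.square(np.maximum(e, 0.0))
        lin = 1.0 + k * (e - self.eps_o)  # anchored: f(eps_o) = 1 exactly
        return np.where(e <= 0.0, 0.0, np.where(e <= et, toe, lin))

    @property
    def max_tendon_slope(self) -> float:
        """Slope of the tendon linear limb (its maximum stiffness), 1/strain."""
        return 2.0 * self._toe_quad * self._toe_strain

    def tendon_inverse(self, f):
        """Strain at which the normalized tendon force equals f (f >= 0)."""
        f = np.asarray(f, dtype=float)
        c = self._toe_quad
        et = self._toe_strain
        k = 2.0 * c * et
        f_toe = c * et**2
        with np.errstate(invalid="ignore"):
            quad = np.sqrt(np.maximum(f, 0.0) / c)
        lin = self.eps_o + (f - 1.0) / k
        return np.where(f <= 0.0, 0.0, np.where(f <= f_toe, quad, lin))


    # -- scalar fast paths ---------------------------------------------------
    # Used by the inner integration loops; same formulas and constants as
    # the array versions (a test asserts agreement to floating-point rounding).

    def active_fl_scalar(self, l: float) -> float:
        return math.exp(-((l - 1.0) ** 2) / _FL_WIDTH)

    def passive_fl_scalar(self, l: float) -> float:
        if l <= 1.0:
            return 0.0
        return math.expm1(_FP_SHAPE * (l - 1.0)) / math.expm1(
            _FP_SHAPE * (_FP_MAX_LEN - 1.0)
        )

    def tendon_scalar(self, e: float) -> float:
        if e <= 0.0:
            return 0.0
        c = self._toe_quad
        et = self._toe_strain
        if e <= et:
            return c * e * e
        return 1.0 + 2.0 * c * et * (e - self.eps_o)

    def force_velocity_scalar(self, v: float) -> float:
        v = max(v, -1.0)
        if v < 0.0:
            return (1.0 + v) / (1.0 - v / _HILL_A)
        slope0 = 2.0 * (1.0 + 1.0 / _HILL_A)
        b = (_ECC_PLATEAU - 1.0) / slope0
        return 1.0 + (_ECC_PLATEAU - 1.0) * v / (v + b)

    def force_velocity_inverse_scalar(self, f: float) -> float:
        fc = min(max(f, 0.0), _ECC_PLATEAU * (1.0 - 1e-9))
        if fc <= 1.0:
            return (fc - 1.0) / (1.0 + fc / _HILL_A)
        slope0 = 2.0 * (1.0 + 1.0 / _HILL_A)
        b = (_ECC_PLATEAU - 1.0) / slope0
        df = _ECC_PLATEAU - 1.0
        return b * (fc - 1.0) / (df - (fc - 1.0))


def default_curves(eps_o: float = 0.049) -> CurveSet:
    """The default generic curve set (tendon reference strain 4.9 %)."""
    return CurveSet(eps_o=eps_o)
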