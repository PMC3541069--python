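"""Static physiologic models for oscillometric blood-pressure simulation.

This module holds the three building blocks of the cuff–arm–artery system:

* a bi-exponential artery pressure–volume law (`ArteryModel`,
  :func:`artery_volume`, :func:`artery_compliance`) with one exponential
  branch for collapse (negative transmural pressure) and one decelerating
  branch for distension,
* the dynamic compliance of the sealed air cuff from Boyle's law
  (`CuffModel`, :func:`cuff_compliance`), and
* a three-harmonic Fourier arterial pressure waveform
  (`PressureWaveform`, :func:`waveform_pressure`, :func:`waveform_derivative`).

All pressures are gauge mmHg unless noted, volumes are ml, time is seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ATM_MMHG",
    "ArteryModel",
    "CuffModel",
    "PressureWaveform",
    "derive_a",
    "derive_b",
    "artery_volume",
    "artery_compliance",
    "cuff_compliance",
    "waveform_pressure",
    "waveform_derivative",
    "cylinder_volume",
    "pulse_volume_from_strain",
]

#: Atmospheric pressure offset used to convert gauge cuff pressure to absolute.
ATM_MMHG = 760.0

#: ln(0.1), kept at full precision; display rounding happens only in reports.
_LN_TENTH = math.log(0.1)


def derive_a(Pc: float) -> float:
    """Collapse-branch stiffness exponent from the collapse pressure.

    The collapse pressure ``Pc`` (negative, mmHg) is the transmural pressure
    at which the artery segment volume has fallen to 10 % of its
    zero-pressure volume, so ``exp(a*Pc) = 0.1`` and ``a = ln(0.1)/Pc``.

    Parameters
    ----------
    Pc : float
        Collapse pressure in mmHg; must be strictly negative.

    Returns
    -------
    float
        Stiffness exponent ``a`` in 1/mmHg (strictly positive).

    Examples
    --------
    >>> round(derive_a(-20.0), 2)
    0.12
    """
    if not Pc < 0:
        raise ValueError(f"collapse pressure must be negative, got Pc={Pc}")
    return _LN_TENTH / Pc


def derive_b(Cn: float, a: float, Va0: float, Pmid: float) -> float:
    """Distension-branch stiffness exponent from a measured compliance.

    Given the dynamic compliance ``Cn`` measured at mid-level arterial
    pressure ``Pmid`` (distension branch, ``Cn = a*Va0*exp(-b*Pmid)``),
    solve for ``b = -ln(Cn/(a*Va0))/Pmid``.

    Parameters
    ----------
    Cn : float
        Compliance at ``Pmid`` in ml/mmHg; ``0 < Cn < a*Va0``.
    a : float
        Collapse-branch exponent in 1/mmHg.
    Va0 : float
        Zero-pressure segment volume in ml.
    Pmid : float
        Mid-level arterial pressure in mmHg, positive.

    Returns
    -------
    float
        Stiffness exponent ``b`` in 1/mmHg (strictly positive).
    """
    if Cn <= 0 or a <= 0 or Va0 <= 0 or Pmid <= 0:
        raise ValueError("Cn, a, Va0 and Pmid must all be positive")
    if Cn >= a * Va0:
        raise ValueError(
            f"Cn={Cn} must be below the zero-pressure compliance a*Va0={a * Va0}; "
            "otherwise b would be non-positive"
        )
    return -math.log(Cn / (a * Va0)) / Pmid


@dataclass(frozen=True)
class ArteryModel:
    """Bi-exponential pressure–volume model of a compressed artery segment.

    Attributes
    ----------
    a : float
        Stiffness exponent of the collapse branch (transmural pressure < 0),
        1/mmHg.
    b : float
        Stiffness exponent of the distension branch (transmural pressure
        >= 0), 1/mmHg.  Typically ``b < a``.
    Va0 : float
        Segment volume at zero transmural pressure, ml.  ``Va0 = 0`` is
        allowed and disables the artery (used for cuff-only checks).
    Pc, Cn, Pmid : float or None
        Optional provenance: the collapse pressure, mid-pressure compliance
        and mid-level pressure the exponents were derived from.
    """

    a: float = 0.11
    b: float = 0.03
    Va0: float = 0.3
    Pc: float | None = None
    Cn: float | None = None
    Pmid: float | None = None

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"stiffness exponents must be positive: a={self.a}, b={self.b}")
        if self.Va0 < 0:
            raise ValueError(f"zero-pressure volume must be non-negative: Va0={self.Va0}")

    @classmethod
    def from_physiology(
        cls,
        Pc: float = -20.0,
        Cn: float = 0.0016,
        Va0: float = 0.3,
        Pmid: float = 100.0,
    ) -> "ArteryModel":
        """Build the model from collapse pressure and mid-pressure compliance."""
        a = derive_a(Pc)
        b = derive_b(Cn, a, Va0, Pmid)
        return cls(a=a, b=b, Va0=Va0, Pc=Pc, Cn=Cn, Pmid=Pmid)

    def scaled(self, factor: float) -> "ArteryModel":
        """Scale both exponents by ``factor``.

        Larger ``factor`` means larger volume change for a given pressure
        change, i.e. a *more compliant* (less stiff) artery; the ratio a/b —
        and with it the maximal distension — is unchanged.
        """
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return replace(self, a=self.a * factor, b=self.b * factor, Pc=None, Cn=None, Pmid=None)

    @property
    def max_volume(self) -> float:
        """Asymptotic volume at large distension, ``Va0 * (1 + a/b)`` (ml)."""
        return self.Va0 * (1.0 + self.a / self.b)


@dataclass(frozen=True)
class CuffModel:
    """Sealed air cuff during one deflation run.

    Attributes
    ----------
    V0 : float
        Cuff air volume between heartbeats, ml.  Default 300 ml from nominal
        30 cm x 10 cm x 1 cm cuff dimensions; only the oscillation amplitude
        scale depends on it, not the extracted pressures.
    P0 : float
        Cuff pressure at onset of deflation, mmHg gauge.
    r : float
        Deflation (bleed) rate, mmHg/s.
    """

    V0: float = 300.0
    P0: float = 150.0
    r: float = 3.0

    def __post_init__(self) -> None:
        if self.V0 <= 0 or self.P0 <= 0 or self.r <= 0:
            raise ValueError(f"V0, P0 and r must be positive: {self}")


@dataclass(frozen=True)
class PressureWaveform:
    """Three-harmonic Fourier arterial pressure waveform.

    ``Pa(t) = DBP + 0.5*PP + 0.36*PP*(sin wt + 1/2 sin 2wt + 1/4 sin 3wt)``
    with ``PP = SBP - DBP`` and ``w = 2*pi*f``.  The nominal SBP/DBP label
    the waveform; its actual extremes are ``mean +/- 0.36*max|g|*PP`` with
    ``max|g| ~ 1.3876``, i.e. within 0.05 mmHg of the labels for 120/80.
    """

    SBP: float = 120.0
    DBP: float = 80.0
    f: float = 80.0 / 60.0

    def __post_init__(self) -> None:
        if not self.SBP > self.DBP:
            raise ValueError(f"SBP={self.SBP} must exceed DBP={self.DBP}")
        if self.f <= 0:
            raise ValueError(f"cardiac frequency must be positive: f={self.f}")

    @property
    def PP(self) -> float:
        """Pulse pressure, SBP - DBP (mmHg)."""
        return self.SBP - self.DBP

    @property
    def omega(self) -> float:
        """Angular cardiac frequency, 2*pi*f (rad/s)."""
        return 2.0 * math.pi * self.f

    @property
    def mean(self) -> float:
        """Time-averaged arterial pressure, DBP + PP/2 (mmHg)."""
        return self.DBP + 0.5 * self.PP

    @property
    def period(self) -> float:
        """Beat period 1/f (s)."""
        return 1.0 / self.f


def waveform_pressure(t, w: PressureWaveform):
    """Arterial pressure (mmHg) at time(s) ``t`` for waveform ``w``."""
    t = np.asarray(t, dtype=float)
    th = w.omega * t
    g = np.sin(th) + 0.5 * np.sin(2.0 * th) + 0.25 * np.sin(3.0 * th)
    out = w.mean + 0.36 * w.PP * g
    return out if out.ndim else float(out)


def waveform_derivative(t, w: PressureWaveform):
    """Time derivative dPa/dt (mmHg/s) of :func:`waveform_pressure`.

    Includes the pulse-pressure factor so that it is the exact derivative
    of the pressure waveform (required for the chain rule coupling the
    artery volume to the cuff).
    """
    t = np.asarray(t, dtype=float)
    th = w.omega * t
    dg = np.cos(th) + np.cos(2.0 * th) + 0.75 * np.cos(3.0 * th)
    out = 0.36 * w.PP * w.omega * dg
    return out if out.ndim else float(out)


def artery_volume(Pt, model: ArteryModel):
    """Artery segment volume (ml) at transmural pressure ``Pt`` (mmHg).

    ``Va0 * exp(a*Pt)`` for ``Pt < 0`` and
    ``Va0 * (1 + a/b * (1 - exp(-b*Pt)))`` for ``Pt >= 0``; continuous at
    zero with value ``Va0``, strictly increasing, bounded by
    ``Va0 * (1 + a/b)``.
    """
    Pt = np.asarray(Pt, dtype=float)
    a, b, Va0 = model.a, model.b, model.Va0
    collapsed = Va0 * np.exp(a * np.minimum(Pt, 0.0))
    distended = Va0 * (1.0 + (a / b) * (1.0 - np.exp(-b * np.maximum(Pt, 0.0))))
    out = np.where(Pt < 0.0, collapsed, distended)
    return out if out.ndim else float(out)


def artery_compliance(Pt, model: ArteryModel):
    """Dynamic artery compliance dVa/dPt (ml/mmHg) at transmural pressure Pt.

    ``a*Va0*exp(a*Pt)`` for ``Pt < 0`` and ``a*Va0*exp(-b*Pt)`` for
    ``Pt >= 0``; both branches meet at ``a*Va0`` so the compliance is
    continuous through the zero-transmural-pressure point.
    """
    Pt = np.asarray(Pt, dtype=float)
    a, b, Va0 = model.a, model.b, model.Va0
    collapsed = a * Va0 * np.exp(a * np.minimum(Pt, 0.0))
    distended = a * Va0 * np.exp(-b * np.maximum(Pt, 0.0))
    out = np.where(Pt < 0.0, collapsed, distended)
    return out if out.ndim else float(out)


def cuff_compliance(P, cuff: CuffModel):
    """Dynamic cuff compliance ``V0 / (P + 760)`` in ml/mmHg.

    ``P`` is gauge cuff pressure (mmHg).  The compliance rises as the cuff
    deflates: the same arterial volume pulse produces larger cuff-pressure
    oscillations late in the run.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P <= -ATM_MMHG):
        raise ValueError("gauge pressure at or below vacuum (-760 mmHg)")
    out = cuff.V0 / (P + ATM_MMHG)
    return out if out.ndim else float(out)


def cylinder_volume(radius_cm: float, length_cm: float) -> float:
    """Volume (ml) of a cylindrical artery segment, ``pi * r^2 * L``."""
    return math.pi * radius_cm**2 * length_cm


def pulse_volume_from_strain(radius_cm: float, strain: float, length_cm: float) -> float:
    """Pulse volume increment (ml) of a segment from a radial strain.

    A radial strain ``dr/r`` during one pulse expands the segment by
    ``2*pi*r*dr*L = 2*pi*r^2*strain*L`` to first order; dividing by the
    pulse pressure yields the mid-pressure compliance used by
    :func:`derive_b`.
    """
    return 2.0 * math.pi * radius_cm * (strain * radius_cm) * length_cm
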