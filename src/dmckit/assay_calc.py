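"""Quantitative formulas for the tension-probe fluorescence assays.

Covers the surface-assay arithmetic around the mechanocapsule experiments:

- quenching efficiency of a fluorophore-quencher pair,
  Q.E. = (1 − I_quenched/I_unquenched) × 100, and the fold fluorescence
  enhancement on rupture it implies, 1/(1 − Q.E./100);
- the F-factor, the molecular-brightness ratio between a labelled
  oligonucleotide and a reference lipid dye (ratio of titration slopes);
- supported-lipid-bilayer density calibration: fluorophore mole fractions
  convert to surface densities through the lipid footprint (0.72 nm² per
  lipid, both leaflets by default), and intensity is regressed on density;
- conversion of a probe intensity to probes/µm² through that calibration and
  the F-factor, and the mean inter-probe spacing under a square-lattice
  convention, ρ^(−1/2);
- exponential decay fitting, I(t) = A·exp(−λt) (+ c), reporting the
  half-life t½ = ln 2/λ of surface-probe degradation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CalibrationCurve",
    "DecayFit",
    "quenching_efficiency",
    "fold_enhancement",
    "f_factor",
    "mole_fraction_to_density",
    "fit_density_calibration",
    "intensity_to_density",
    "mean_spacing",
    "decay_halflife",
]

LIPID_FOOTPRINT_NM2 = 0.72
NM2_PER_UM2 = 1e6


def quenching_efficiency(i_quenched: float, i_unquenched: float) -> float:
    """Quenching efficiency in percent: (1 − I_q/I_uq) × 100.

    Values outside [0, 100] (negative intensities bar, super-quenching noise)
    are clipped with a warning.
    """
    if i_unquenched <= 0:
        raise ValueError("unquenched intensity must be positive")
    if i_quenched < 0:
        raise ValueError("quenched intensity must be non-negative")
    qe = (1.0 - i_quenched / i_unquenched) * 100.0
    if not 0.0 <= qe <= 100.0:
        warnings.warn(f"quenching efficiency {qe:.3g}% outside [0, 100]; "
                      "clipped", stacklevel=2)
        qe = float(np.clip(qe, 0.0, 100.0))
    return qe


def fold_enhancement(qe: float) -> float:
    """Fold fluorescence increase on rupture implied by a quenching
    efficiency ``qe`` in percent: 1/(1 − qe/100)."""
    if not 0 <= qe < 100:
        raise ValueError("quenching efficiency must be in [0, 100)")
    return 1.0 / (1.0 - qe / 100.0)


def f_factor(i_dna: float, i_lipid: float) -> float:
    """Brightness ratio of labelled DNA to reference lipid dye (slope ratio)."""
    if i_dna <= 0 or i_lipid <= 0:
        raise ValueError("titration slopes must be positive")
    return i_dna / i_lipid


def mole_fraction_to_density(fraction: float,
                             footprint: float = LIPID_FOOTPRINT_NM2,
                             leaflet_factor: float = 2.0) -> float:
    """Fluorophores per µm² for a lipid mole fraction in a bilayer.

    density = fraction × leaflet_factor × 10⁶ nm²/µm² / footprint.  The
    leaflet factor counts how many leaflets carry the dye (default both).
    """
    if footprint <= 0 or leaflet_factor <= 0:
        raise ValueError("footprint and leaflet factor must be positive")
    return fraction * leaflet_factor * NM2_PER_UM2 / footprint


@dataclass
class CalibrationCurve:
    """Linear intensity-vs-density calibration from bilayer standards.

    ``slope`` is intensity per (fluorophore/µm²); a curve is ``usable`` only
    with a positive, finite slope.
    """

    slope: float
    intercept: float
    r_squared: float
    footprint: float = LIPID_FOOTPRINT_NM2
    leaflet_factor: float = 2.0

    @property
    def usable(self) -> bool:
        return np.isfinite(self.slope) and self.slope > 0


def fit_density_calibration(points: Sequence[tuple[float, float]],
                            footprint: float = LIPID_FOOTPRINT_NM2,
                            leaflet_factor: float = 2.0) -> CalibrationCurve:
    """OLS fit of intensity on fluorophore density for (mole fraction,
    intensity) standards; at least 3 points required."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (mole_fraction, intensity) points")
    density = np.array([mole_fraction_to_density(f, footprint, leaflet_factor)
                        for f in pts[:, 0]])
    if np.ptp(density) == 0:
        raise ValueError("zero variance in density; cannot calibrate")
    res = stats.linregress(density, pts[:, 1])
    curve = CalibrationCurve(slope=float(res.slope),
                             intercept=float(res.intercept),
                             r_squared=float(res.rvalue ** 2),
                             footprint=footprint,
                             leaflet_factor=leaflet_factor)
    if not curve.usable:
        warnings.warn("calibration slope is not positive; curve flagged "
                      "unusable", stacklevel=2)
    return curve


def intensity_to_density(i_probe: float, curve: CalibrationCurve,
                         f: float) -> float:
    """Probes per µm² from a surface intensity, via the bilayer calibration
    corrected by the F-factor."""
    if not curve.usable:
        raise ValueError("calibration curve is unusable (non-positive slope)")
    if f <= 0:
        raise ValueError("F-factor must be positive")
    if i_probe < curve.intercept:
        warnings.warn("probe intensity below calibration intercept; "
                      "density reported as 0", stacklevel=2)
        return 0.0
    return ((i_probe - curve.intercept) / curve.slope) / f


def mean_spacing(density: float) -> float:
    """Mean inter-probe spacing (nm) at ``density`` probes/µm²,
    square-lattice convention: (10⁶/ρ)^½."""
    if density <= 0:
        raise ValueError("density must be positive")
    return float(np.sqrt(NM2_PER_UM2 / density))


@dataclass
class DecayFit:
    """Exponential decay fit I(t) = A·exp(−λt) + c.

    ``rate`` is λ per minute when times are in minutes; ``half_life`` is
    ln 2/λ.  ``valid`` is False for non-decaying data (λ ≤ 0 or failed fit).
    """

    amplitude: float
    rate: float
    offset: float
    valid: bool

    @property
    def half_life(self) -> float:
        return np.log(2.0) / self.rate if self.valid else float("nan")


def decay_halflife(times: Sequence[float], intensities: Sequence[float],
                   fit_offset: bool = False) -> DecayFit:
    """Least-squares exponential decay fit and half-life.

    ``times`` must be strictly increasing with at least 4 points.  The offset
    term c is fixed at 0 unless ``fit_offset``.  Non-decaying data return an
    invalid fit rather than raising.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size < 4 or t.size != y.size:
        raise ValueError("need at least 4 matching (time, intensity) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    span = y[0] - y[-1]
    if span <= 0:
        return DecayFit(float(y[0]), 0.0, 0.0, valid=False)
    # log-linear seed for the rate, robust amplitude seed
    scale = max(np.max(np.abs(y)), 1e-30)
    lam0 = max(np.log(max(y[0], 1e-12 * scale)
                      / max(y[-1], 1e-12 * scale)) / (t[-1] - t[0]), 1e-12)
    if fit_offset:
        model = lambda tt, a, lam, c: a * np.exp(-lam * tt) + c  # noqa: E731
        p0 = [span, lam0, y[-1]]
    else:
        model = lambda tt, a, lam: a * np.exp(-lam * tt)  # noqa: E731
        p0 = [y[0], lam0]
    try:
        popt, _ = optimize.curve_fit(model, t, y, p0=p0, maxfev=10_000)
    except RuntimeError:
        return DecayFit(float(y[0]), 0.0, 0.0, valid=False)
    amp, lam = float(popt[0]), float(popt[1])
    offset = float(popt[2]) if fit_offset else 0.0
    return DecayFit(amp, lam, offset, valid=lam > 0)
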