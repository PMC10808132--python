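"""Force reconstruction from dual harmonic-trap pulling trajectories.

A pulling protocol tethers two nucleotides to virtual springs: one trap is
fixed in space (the anchor side), the other is translated at constant velocity
along a pulling axis.  The two traps act in series, so the force transmitted
through the structure is the effective series stiffness times the summed
stretch of both springs projected on the pulling axis:

    1/k_eff = 1/k1 + 1/k2
    F(t) = k_eff * [ (x_a(t) - a) + (b(t) - x_b(t)) ] . axis

where ``a`` is the fixed trap position, ``b(t)`` the moving trap position and
``x_a``, ``x_b`` the attachment-nucleotide positions.  Each spring's stretch
is counted positively in the pulling direction, so for springs in mechanical
series the expression reduces to the common tension.  The raw force series is
smoothed with an exponential moving average (EMA) before rupture detection;
the rupture force is the global maximum of the smoothed force, accepted only
if the force subsequently collapses (a configurable fractional drop within a
configurable window), which distinguishes a genuine rupture from a
still-loading ramp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .oxdna_io import DEFAULT_UNITS, TrajectoryFrame, UnitSystem

__all__ = [
    "Trap",
    "TrapProtocol",
    "ForceExtensionCurve",
    "RuptureResult",
    "effective_stiffness",
    "loading_rate_si",
    "ema",
    "default_ema_alpha",
    "force_extension_curve",
    "detect_rupture",
]


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------

@dataclass
class Trap:
    """A harmonic trap tethered to one nucleotide.

    ``position`` (nm) is the anchor point at t = 0; ``velocity`` (nm/s) is the
    translation velocity (zero for the fixed trap).  ``stiffness`` is in pN/nm.
    """

    nucleotide: int
    stiffness: float
    position: np.ndarray
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.stiffness <= 0:
            raise ValueError("trap stiffness must be positive")

    def position_at(self, t: float) -> np.ndarray:
        return self.position + self.velocity * t


@dataclass
class TrapProtocol:
    """Dual-trap pulling protocol: ``trap_a`` fixed, ``trap_b`` moving.

    ``axis`` is the unit pulling direction (the direction of trap_b motion);
    forces and extensions are projected onto it.
    """

    trap_a: Trap
    trap_b: Trap
    axis: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if not np.isclose(norm, 1.0, atol=1e-6):
            if norm == 0:
                raise ValueError("pulling axis must be non-zero")
            self.axis = self.axis / norm
        if self.trap_a.nucleotide == self.trap_b.nucleotide:
            raise ValueError("trap attachment nucleotides must be distinct")

    @property
    def k_eff(self) -> float:
        return effective_stiffness([self.trap_a.stiffness,
                                    self.trap_b.stiffness])

    @property
    def loading_rate(self) -> float:
        """Speed of the moving trap, nm/s."""
        return float(np.linalg.norm(self.trap_b.velocity))


# ---------------------------------------------------------------------------
# Elementary quantities
# ---------------------------------------------------------------------------

def effective_stiffness(stiffnesses: Sequence[float]) -> float:
    """Series stiffness: reciprocal of the sum of reciprocals (pN/nm)."""
    ks = np.asarray(stiffnesses, dtype=float)
    if ks.size == 0:
        raise ValueError("at least one stiffness required")
    if np.any(ks <= 0):
        raise ValueError("stiffnesses must be positive")
    return float(1.0 / np.sum(1.0 / ks))


def loading_rate_si(rate_sim: float,
                    units: UnitSystem = DEFAULT_UNITS) -> float:
    """Convert a trap speed from simulation (length/time) units to nm/s."""
    if rate_sim < 0:
        raise ValueError("loading rate must be non-negative")
    return rate_sim * units.rate_nm_s


def ema(series: Sequence[float], alpha: float) -> np.ndarray:
    """Exponential moving average: y0 = x0, y_i = a·x_i + (1−a)·y_{i−1}.

    ``alpha`` in (0, 1]; alpha = 1 returns the input unchanged.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    if alpha == 1.0:
        return x.copy()
    y = np.empty_like(x)
    y[0] = x[0]
    one_minus = 1.0 - alpha
    for i in range(1, x.size):
        y[i] = alpha * x[i] + one_minus * y[i - 1]
    return y


def default_ema_alpha(n_frames: int) -> float:
    """Scale-free default smoothing factor: 2/(W+1) with W = 1% of frames."""
    window = max(1, round(0.01 * n_frames))
    return 2.0 / (window + 1)


# ---------------------------------------------------------------------------
# Force-extension reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ForceExtensionCurve:
    """Per-frame pulling record in SI-friendly units (s, nm, pN)."""

    time: np.ndarray
    extension: np.ndarray
    force_raw: np.ndarray
    force_ema: np.ndarray
    k_eff: float
    loading_rate: float
    extension_convention: str = "nucleotide"

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("extension", "force_raw", "force_ema"):
            if len(getattr(self, name)) != n:
                raise ValueError("curve series must have equal length")

    def __len__(self) -> int:
        return len(self.time)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.time, "extension": self.extension,
            "force_raw": self.force_raw, "force_ema": self.force_ema})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, k_eff: float = float("nan"),
                 loading_rate: float = float("nan")) -> "ForceExtensionCurve":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["extension"].to_numpy(),
                   df["force_raw"].to_numpy(), df["force_ema"].to_numpy(),
                   k_eff=k_eff, loading_rate=loading_rate)


def force_extension_curve(frames: Sequence[TrajectoryFrame],
                          protocol: TrapProtocol,
                          units: UnitSystem = DEFAULT_UNITS,
                          alpha: float | None = None,
                          extension_convention: str = "nucleotide",
                          ) -> ForceExtensionCurve:
    """Reconstruct the force-extension curve of a dual-trap pull.

    Per frame, the moving trap is advanced to ``start + velocity * t`` and the
    net force is ``k_eff`` times the summed projected stretch of both trap
    springs (see module docstring).  Extension follows
    ``extension_convention``:

    - ``"nucleotide"`` (default): projected separation of the two attachment
      nucleotides minus its value in the first frame — this convention shows
      the rupture jump.
    - ``"trap"``: projected trap separation minus its initial value.

    ``alpha`` defaults to :func:`default_ema_alpha` of the frame count.
    """
    if len(frames) == 0:
        raise ValueError("trajectory is empty")
    n_nt = frames[0].n_nucleotides
    ia, ib = protocol.trap_a.nucleotide, protocol.trap_b.nucleotide
    for idx in (ia, ib):
        if not 0 <= idx < n_nt:
            raise IndexError(f"trap nucleotide index {idx} out of range "
                             f"(trajectory has {n_nt} nucleotides)")
    if extension_convention not in ("nucleotide", "trap"):
        raise ValueError(f"unknown extension convention "
                         f"{extension_convention!r}")

    axis = protocol.axis
    k_eff = protocol.k_eff
    times = np.array([f.time * units.s_per_time_unit for f in frames])
    pos_a = np.array([f.positions[ia] for f in frames]) * units.nm_per_length_unit
    pos_b = np.array([f.positions[ib] for f in frames]) * units.nm_per_length_unit
    trap_a_pos = protocol.trap_a.position_at(0.0)
    trap_b_pos = (protocol.trap_b.position[None, :]
                  + protocol.trap_b.velocity[None, :] * times[:, None])

    # both spring stretches counted positively along the pulling direction
    stretch = ((pos_a - trap_a_pos) @ axis) + ((trap_b_pos - pos_b) @ axis)
    force_raw = k_eff * stretch

    if extension_convention == "nucleotide":
        sep = (pos_b - pos_a) @ axis
    else:
        sep = (trap_b_pos - trap_a_pos) @ axis
    extension = sep - sep[0]

    if alpha is None:
        alpha = default_ema_alpha(len(frames))
    force_ema = ema(force_raw, alpha)

    return ForceExtensionCurve(
        time=times, extension=extension, force_raw=force_raw,
        force_ema=force_ema, k_eff=k_eff,
        loading_rate=protocol.loading_rate,
        extension_convention=extension_convention)


# ---------------------------------------------------------------------------
# Rupture detection
# ---------------------------------------------------------------------------

@dataclass
class RuptureResult:
    """Outcome of rupture detection on a smoothed force curve.

    ``rupture_force`` (pN) is the global EMA maximum, reported only when the
    force subsequently dropped by at least the requested fraction within the
    look-ahead window (``valid``).  ``drop_observed`` is the largest
    fractional drop seen inside the window.
    """

    rupture_force: float | None
    rupture_frame: int
    valid: bool
    drop_observed: float


def detect_rupture(curve: ForceExtensionCurve,
                   drop_fraction: float = 0.5,
                   window_fraction: float = 0.1) -> RuptureResult:
    """Locate the rupture event on a force-extension curve.

    The candidate rupture is the global maximum of the EMA force.  It is
    accepted when the EMA falls below ``(1 − drop_fraction) × peak`` within
    the subsequent ``window_fraction`` of the trajectory; a curve still
    loading at its end yields ``valid = False`` and no force.
    """
    n = len(curve)
    if n == 0:
        raise ValueError("curve is empty")
    f = np.asarray(curve.force_ema, dtype=float)
    i_peak = int(np.argmax(f))
    peak = f[i_peak]
    window = max(1, int(np.ceil(window_fraction * n)))
    after = f[i_peak + 1: i_peak + 1 + window]
    if after.size == 0 or peak <= 0:
        return RuptureResult(None, i_peak, False, 0.0)
    drop_observed = float(1.0 - np.min(after) / peak)
    valid = drop_observed >= drop_fraction
    return RuptureResult(float(peak) if valid else None, i_peak, valid,
                         drop_observed)
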