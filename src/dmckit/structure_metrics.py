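"""Structural rupture metrics: base-pair state, denaturation, distances, pores.

Base pairing is judged geometrically: each nucleotide carries a hydrogen-
bonding site displaced 0.4 simulation length units along its base vector, and
a designed pair counts as bound while the two sites sit within a cutoff
(default 0.4 simulation units ≈ 0.34 nm) and, optionally, the base vectors are
anti-aligned.  The denatured fraction of a frame is one minus the bound share
of the designed (reference) pairs.

Pore geometry treats each of a tetrahedron's four faces as the triangle of its
three hinge nucleotides.  The incircle radius r = 2·area/perimeter of the
largest circle inscribed in that triangle bounds the spherical cargo that can
escape through the face; a structure is leaky at a frame when the largest of
the four radii strictly exceeds the cargo radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .oxdna_io import (COMPLEMENT, DEFAULT_UNITS, Topology, TrajectoryFrame,
                       UnitSystem, ValidationError)

__all__ = [
    "HBOND_SITE_OFFSET",
    "BasePairSet",
    "PoreSpec",
    "PoreSeries",
    "reference_pairs_from_topology",
    "detect_base_pairs",
    "bound_mask_series",
    "denatured_fraction",
    "site_distance_series",
    "incircle_radius",
    "pore_series",
    "leakage_frames",
]

HBOND_SITE_OFFSET = 0.4     # sim length units along the base vector
DEFAULT_HBOND_CUTOFF = 0.4  # sim length units between hydrogen-bonding sites
DEGENERATE_AREA = 1e-9      # nm^2; triangles flatter than this have radius 0


# ---------------------------------------------------------------------------
# Base pairs
# ---------------------------------------------------------------------------

def _validate_pairs(pairs: np.ndarray, topology: Topology) -> np.ndarray:
    pairs = np.asarray(pairs, dtype=int)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValidationError("pairs must be an (n, 2) index array")
    n = topology.n_nucleotides
    if np.any(pairs < 0) or np.any(pairs >= n):
        raise ValidationError("pair index out of range")
    if np.any(pairs[:, 0] >= pairs[:, 1]):
        raise ValidationError("pairs must satisfy i < j")
    flat = pairs.ravel()
    if len(set(flat.tolist())) != flat.size:
        raise ValidationError("a nucleotide appears in more than one pair")
    seq = topology.sequence
    for i, j in pairs:
        if COMPLEMENT[seq[i]] != seq[j]:
            raise ValidationError(
                f"pair ({i}, {j}) is not complementary: "
                f"{seq[i]}-{seq[j]}")
    return pairs


@dataclass
class BasePairSet:
    """Designed base pairs plus their per-frame bound mask.

    ``reference_pairs`` is (P, 2) with i < j and complementary bases;
    ``bound`` is (n_frames, P) boolean.
    """

    reference_pairs: np.ndarray
    bound: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.reference_pairs.shape[0])

    def fraction_bound(self) -> np.ndarray:
        return self.bound.mean(axis=1)


def reference_pairs_from_topology(topology: Topology,
                                  pairs: Sequence[tuple[int, int]] | None
                                  = None) -> np.ndarray:
    """Validate an explicit pair list against ``topology``.

    The designed pairing of a structure is not derivable from connectivity
    alone, so an explicit list (e.g. from the structure builder) is required;
    this normalises it to i < j order and checks complementarity.
    """
    if pairs is None or len(pairs) == 0:
        raise ValidationError("reference pair list must be non-empty")
    arr = np.asarray(pairs, dtype=int)
    arr = np.sort(arr, axis=1)
    return _validate_pairs(arr, topology)


def detect_base_pairs(frame: TrajectoryFrame, topology: Topology,
                      reference_pairs: Sequence[tuple[int, int]],
                      distance_cutoff: float = DEFAULT_HBOND_CUTOFF,
                      require_antiparallel: bool = True) -> np.ndarray:
    """Boolean bound mask over ``reference_pairs`` for one frame.

    A pair is bound iff its hydrogen-bonding sites (position + 0.4 × base
    vector, simulation units) are closer than ``distance_cutoff`` and, when
    ``require_antiparallel``, the base vectors point toward each other
    (dot product < 0).
    """
    pairs = _validate_pairs(np.sort(np.asarray(reference_pairs, dtype=int),
                                    axis=1), topology)
    sites = frame.positions + HBOND_SITE_OFFSET * frame.base_vectors
    d = np.linalg.norm(sites[pairs[:, 0]] - sites[pairs[:, 1]], axis=1)
    bound = d < distance_cutoff
    if require_antiparallel:
        dots = np.einsum("ij,ij->i", frame.base_vectors[pairs[:, 0]],
                         frame.base_vectors[pairs[:, 1]])
        bound &= dots < 0
    return bound


def bound_mask_series(frames: Sequence[TrajectoryFrame], topology: Topology,
                      reference_pairs: Sequence[tuple[int, int]],
                      **criterion) -> BasePairSet:
    """Apply :func:`detect_base_pairs` to every frame."""
    pairs = reference_pairs_from_topology(topology, reference_pairs)
    masks = np.array([detect_base_pairs(f, topology, pairs, **criterion)
                      for f in frames])
    return BasePairSet(pairs, masks)


def denatured_fraction(frames: Sequence[TrajectoryFrame], topology: Topology,
                       reference_pairs: Sequence[tuple[int, int]],
                       **criterion) -> tuple[np.ndarray, float]:
    """Per-frame denatured fraction and its end-of-run value.

    fraction = 1 − bound/reference, in [0, 1]; the end value is taken from
    the final frame (the convention used when a single percentage summarises
    a pulling run).
    """
    if len(frames) == 0:
        raise ValueError("trajectory is empty")
    pair_set = bound_mask_series(frames, topology, reference_pairs,
                                 **criterion)
    series = 1.0 - pair_set.fraction_bound()
    return series, float(series[-1])


def site_distance_series(frames: Sequence[TrajectoryFrame], i: int, j: int,
                         units: UnitSystem = DEFAULT_UNITS) -> np.ndarray:
    """Euclidean distance (nm) between nucleotides ``i`` and ``j`` per frame.

    Serves both fluorophore-quencher separations and strand-separation
    distances during rupture.
    """
    if len(frames) == 0:
        raise ValueError("trajectory is empty")
    n = frames[0].n_nucleotides
    for idx in (i, j):
        if not 0 <= idx < n:
            raise IndexError(f"nucleotide index {idx} out of range")
    d = np.array([np.linalg.norm(f.positions[i] - f.positions[j])
                  for f in frames])
    return d * units.nm_per_length_unit


# ---------------------------------------------------------------------------
# Pore geometry
# ---------------------------------------------------------------------------

def incircle_radius(p1, p2, p3) -> float:
    """Incircle radius 2·area/perimeter of the triangle (p1, p2, p3), nm.

    Degenerate triangles (area < 1e-9 nm²) return 0.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = np.linalg.norm(p2 - p3)
    b = np.linalg.norm(p1 - p3)
    c = np.linalg.norm(p1 - p2)
    perimeter = a + b + c
    area = 0.5 * np.linalg.norm(np.cross(p2 - p1, p3 - p1))
    if area < DEGENERATE_AREA or perimeter == 0:
        return 0.0
    return float(2.0 * area / perimeter)


@dataclass
class PoreSpec:
    """The four faces of a tetrahedral structure, each a triple of hinge
    nucleotide indices."""

    faces: np.ndarray

    def __post_init__(self) -> None:
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.shape != (4, 3):
            raise ValidationError("PoreSpec requires exactly 4 faces of "
                                  "3 hinge indices")
        for face in self.faces:
            if len(set(face.tolist())) != 3:
                raise ValidationError(
                    f"face {face.tolist()} repeats a hinge index")

    def validate_against(self, n_nucleotides: int) -> None:
        if np.any(self.faces < 0) or np.any(self.faces >= n_nucleotides):
            raise ValidationError("hinge index out of range")


@dataclass
class PoreSeries:
    """Per-frame incircle radii (nm) of the four faces with aggregates.

    The plotting convention for these series is: draw ``max_radius`` as the
    solid line and shade between ``max_radius`` and ``mean_radius``.
    """

    radii: np.ndarray  # (n_frames, 4)
    times: np.ndarray  # simulation time units

    @property
    def max_radius(self) -> np.ndarray:
        return self.radii.max(axis=1)

    @property
    def mean_radius(self) -> np.ndarray:
        return self.radii.mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.radii, columns=["r1", "r2", "r3", "r4"])
        df.insert(0, "frame", np.arange(len(df)))
        df["max"] = self.max_radius
        df["mean"] = self.mean_radius
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def pore_series(frames: Sequence[TrajectoryFrame], spec: PoreSpec,
                units: UnitSystem = DEFAULT_UNITS) -> PoreSeries:
    """Incircle radii of the four hinge-vertex faces for every frame (nm)."""
    if len(frames) == 0:
        raise ValueError("trajectory is empty")
    spec.validate_against(frames[0].n_nucleotides)
    radii = np.empty((len(frames), 4))
    for fi, frame in enumerate(frames):
        pos = frame.positions * units.nm_per_length_unit
        for k, face in enumerate(spec.faces):
            radii[fi, k] = incircle_radius(pos[face[0]], pos[face[1]],
                                           pos[face[2]])
    times = np.array([f.time for f in frames])
    return PoreSeries(radii=radii, times=times)


def leakage_frames(series: PoreSeries, cargo_radius: float) -> np.ndarray:
    """Frame indices at which the structure is leaky for a spherical cargo.

    Leaky means the per-frame maximum incircle radius *strictly* exceeds
    ``cargo_radius`` (nm): a pore exactly the cargo size does not leak.
    """
    if cargo_radius <= 0:
        raise ValueError("cargo radius must be positive")
    return np.flatnonzero(series.max_radius > cargo_radius)
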