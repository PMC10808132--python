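"""Simplified bead-per-nucleotide Langevin simulator of a pulled DNA tetrahedron.

This module generates synthetic pulling trajectories in oxDNA classic format
so that the analysis modules can be exercised end to end without an external
coarse-grained engine.  It is deliberately minimal and makes no claim of
quantitative agreement with nucleotide-level DNA models:

- one bead per nucleotide, placed on straight duplex edge axes (no helix);
- harmonic backbone springs between strand neighbours, rest lengths taken
  from the built geometry (≈ the 0.34 nm helical rise within an edge);
- harmonic base-pair springs between designed complementary beads that break
  *irreversibly* the first time their extension exceeds a threshold x*
  (optionally a Bell-model stochastic off-rate instead);
- two harmonic traps, one fixed at the anchor nucleotide and one translated
  at constant speed, exactly the dual-trap protocol the analysis modules
  reconstruct forces from;
- first-order (overdamped) Langevin integration with thermal noise at a
  configurable temperature — there is no inertia, only quasi-static pulling
  behaviour matters here.

The tetrahedron is wireframe: four faces, six duplex edges.  Four "face"
strands each run around the perimeter of one face, so every edge carries two
antiparallel strands; one face strand is truncated and the final stretch of
its last edge is supplied by a separate short force-bearing (FB) strand whose
outer terminus is the ligand/pull point.  Releasing the FB strand is what
constitutes rupture.  Base vectors of paired beads point at each other so the
geometric hydrogen-bond criterion in :mod:`dmckit.structure_metrics` applies
unchanged.

Determinism: the integer seed fixes the entire random stream; two runs with
identical parameters and seed produce bit-identical trajectories and bond
event logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .oxdna_io import (DEFAULT_UNITS, Topology, TrajectoryFrame, UnitSystem,
                       complement)
from .structure_metrics import PoreSpec
from .trap_mechanics import Trap, TrapProtocol, effective_stiffness

__all__ = [
    "BOLTZMANN_PN_NM",
    "PAIR_REST_SIM",
    "SimParams",
    "TetraDesign",
    "BuildResult",
    "SimResult",
    "SimulationInstability",
    "build_tetrahedron",
    "make_pull_protocol",
    "rigid_pull_indices",
    "run_pulling",
]

logger = logging.getLogger(__name__)

BOLTZMANN_PN_NM = 0.0138064852  # pN nm / K

# Paired beads rest at 0.8 sim length units so that the two hydrogen-bonding
# sites (offset 0.4 units along each base vector) coincide at rest: the
# geometric bound criterion then has its full cutoff as noise margin.
PAIR_REST_SIM = 0.8

_SEQ_PATTERN = "ACGT"


class SimulationInstability(RuntimeError):
    """Timestep instability: a bead moved more than one rest length in one
    integration step."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Physical and numerical parameters of a pulling run.

    Units are SI-friendly: pN/nm, nm, K, s.  ``backbone_rest = None`` takes
    every backbone rest length from the built geometry (making the initial
    frame force-free); a number overrides all of them.  A base-pair bond
    breaks irreversibly once its extension beyond rest first exceeds
    ``rupture_extension`` — unless ``bell_k0`` is set, in which case breaking
    is stochastic with rate k0·exp(f·x_b/kT) (Bell model).

    The defaults put the bond-breaking threshold ~7 thermal standard
    deviations of the pair extension (≈0.11 nm at 310 K, including the soft
    shear modes of the bead-ladder duplex) above rest, so bonds do not break
    spontaneously on desk-scale runs.
    """

    seed: int
    backbone_stiffness: float = 400.0   # pN/nm
    backbone_rest: float | None = None  # nm; None -> from geometry
    pair_stiffness: float = 300.0       # pN/nm
    rupture_extension: float = 0.8      # nm beyond rest (x*)
    temperature: float = 310.0          # K
    friction: float = 1e-6              # pN s / nm
    dt: float = 1e-10                   # s
    n_steps: int = 400_000
    stride: int = 2_000                 # steps between emitted frames
    excluded_volume: bool = False
    ev_radius: float = 0.3              # nm (soft repulsion range = 2r)
    ev_stiffness: float = 100.0         # pN/nm
    bell_k0: float | None = None        # 1/s; None -> threshold breaking
    bell_xb: float = 0.3                # nm

    def __post_init__(self) -> None:
        for name in ("backbone_stiffness", "pair_stiffness",
                     "rupture_extension", "friction", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.bell_k0 is not None and self.temperature <= 0:
            raise ValueError("the Bell off-rate model needs temperature > 0")
        if self.n_steps < 1 or self.stride < 1:
            raise ValueError("n_steps and stride must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @property
    def kT(self) -> float:
        return BOLTZMANN_PN_NM * self.temperature


@dataclass
class TetraDesign:
    """Geometry and strand layout of the tetrahedron analog.

    ``edge_bp`` base pairs per edge at ``rise`` nm per pair; ``fb_bp`` of the
    pairs on one edge are carried by the separate force-bearing strand
    (1 ≤ fb_bp < edge_bp), giving 5 strands in total.
    """

    edge_bp: int = 20
    rise: float = 0.34   # nm
    fb_bp: int = 7

    def __post_init__(self) -> None:
        if self.edge_bp < 4:
            raise ValueError("edge_bp must be at least 4")
        if not 1 <= self.fb_bp < self.edge_bp:
            raise ValueError("fb_bp must satisfy 1 <= fb_bp < edge_bp")
        if self.rise <= 0:
            raise ValueError("rise must be positive")

    @property
    def edge_length(self) -> float:
        return self.edge_bp * self.rise

    @property
    def n_strands(self) -> int:
        return 5


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

# faces oriented so every undirected edge is traversed once in each direction
_FACES = ((0, 1, 2), (0, 2, 3), (0, 3, 1), (1, 3, 2))
_CANONICAL_EDGES = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class BuildResult:
    """A built structure ready for simulation and analysis.

    Positions are stored twice: ``frame0`` in oxDNA simulation units (what
    the I/O layer writes) and ``positions_nm`` in nm (what the simulator
    integrates).  ``reference_pairs`` lists every designed base pair;
    ``fb_pairs`` is the subset carried by the force-bearing strand.  The
    labelled indices mark the surface anchor, the ligand/pull point and the
    fluorophore/quencher reporter beads; ``pore_spec`` holds the four
    hinge-vertex faces and ``vertex_beads`` one representative bead per
    tetrahedron vertex.
    """

    design: TetraDesign
    topology: Topology
    frame0: TrajectoryFrame
    positions_nm: np.ndarray
    bonds: np.ndarray          # (M, 2) backbone springs
    bond_rests: np.ndarray     # (M,) nm
    reference_pairs: np.ndarray  # (P, 2)
    fb_pairs: np.ndarray       # (Q, 2)
    partner: np.ndarray        # (N,) paired bead, -1 if unpaired
    anchor: int
    pull: int
    fluorophore: int
    quencher: int
    pore_spec: PoreSpec
    vertex_beads: np.ndarray   # (4,)
    vertices: np.ndarray | None = None  # (4, 3) geometric vertices, nm

    @property
    def n_beads(self) -> int:
        return int(self.positions_nm.shape[0])


def build_tetrahedron(design: TetraDesign,
                      units: UnitSystem = DEFAULT_UNITS) -> BuildResult:
    """Construct topology and an equilibrium initial frame for ``design``."""
    E = design.edge_bp
    L = design.edge_length
    w = PAIR_REST_SIM * units.nm_per_length_unit  # pair rest separation, nm

    s = L / (2.0 * np.sqrt(2.0))
    vertices = s * np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1),
                             (-1, -1, 1)], dtype=float)

    edge_index = {e: k for k, e in enumerate(_CANONICAL_EDGES)}

    def edge_normal(a: int, b: int) -> np.ndarray:
        mid = 0.5 * (vertices[a] + vertices[b])  # centroid is the origin
        u = vertices[b] - vertices[a]
        u = u / np.linalg.norm(u)
        n = mid - (mid @ u) * u
        return n / np.linalg.norm(n)

    # beads in face-strand order; strand 3 is split later into strand 3 + FB
    positions: list[np.ndarray] = []
    bases: list[str] = []
    tangents: list[np.ndarray] = []
    slot_of: dict[tuple[int, bool, int], int] = {}  # (edge, canonical?, slot)
    for face in _FACES:
        cycle = [(face[0], face[1]), (face[1], face[2]), (face[2], face[0])]
        for a, b in cycle:
            canonical = a < b
            e = edge_index[(a, b) if canonical else (b, a)]
            u = vertices[b] - vertices[a]
            u = u / np.linalg.norm(u)
            n_hat = edge_normal(*((a, b) if canonical else (b, a)))
            side = 0.5 * w * (1.0 if canonical else -1.0) * n_hat
            for k in range(E):
                frac = (k + 0.5) / E
                positions.append(vertices[a] + frac * (vertices[b]
                                                       - vertices[a]) + side)
                tangents.append(u)
                if canonical:
                    bases.append(_SEQ_PATTERN[(k + e) % 4])
                else:
                    # slot k runs b->a; it pairs with canonical slot E-1-k
                    bases.append(complement(_SEQ_PATTERN[(E - 1 - k + e) % 4]))
                slot_of[(e, canonical, k)] = len(positions) - 1

    positions_nm = np.asarray(positions)
    n = positions_nm.shape[0]  # 12 * E

    # pairs: canonical slot k with reverse slot E-1-k on the same edge
    pairs = []
    for e in range(6):
        for k in range(E):
            i = slot_of[(e, True, k)]
            j = slot_of[(e, False, E - 1 - k)]
            pairs.append((min(i, j), max(i, j)))
    reference_pairs = np.asarray(pairs, dtype=int)
    partner = np.full(n, -1, dtype=int)
    partner[reference_pairs[:, 0]] = reference_pairs[:, 1]
    partner[reference_pairs[:, 1]] = reference_pairs[:, 0]

    # strand boundaries: faces 0-2 are full strands of 3E; face 3 is split
    # into a truncated strand (3E - fb) and the FB strand (fb) whose outer
    # terminus sits at a vertex and carries the ligand
    fb = design.fb_bp
    starts = [0, 3 * E, 6 * E, 9 * E, 12 * E - fb]
    lengths = [3 * E, 3 * E, 3 * E, 3 * E - fb, fb]
    strands = []
    n3 = np.full(n, -1, dtype=int)
    n5 = np.full(n, -1, dtype=int)
    for sid, (st, ln) in enumerate(zip(starts, lengths), start=1):
        strands.append((sid, "".join(bases[st:st + ln])))
        for i in range(st, st + ln - 1):
            n5[i] = i + 1
            n3[i + 1] = i
    topology = Topology(strands, n3, n5)

    bonds = np.array([(i, n5[i]) for i in range(n) if n5[i] != -1], dtype=int)
    bond_rests = np.linalg.norm(positions_nm[bonds[:, 1]]
                                - positions_nm[bonds[:, 0]], axis=1)

    fb_mask = reference_pairs[:, 1] >= starts[4]
    fb_pairs = reference_pairs[fb_mask]
    if fb_pairs.shape[0] != fb:
        raise ValueError("inconsistent strand layout: FB pairing is broken")

    # labelled sites
    pull = n - 1                        # outer FB terminus, at a vertex
    anchor = starts[1] + E              # strand 2's bead at vertex 2
    quencher = starts[4]                # inner FB terminus
    fluorophore = int(partner[quencher])

    # hinge beads: each face strand starts one of its edges at each face
    # vertex; local offsets 0, E and 2E are those starting beads
    face_hinges = np.array([[starts[f], starts[f] + E, starts[f] + 2 * E]
                            for f in range(4)], dtype=int)
    pore_spec = PoreSpec(face_hinges)
    vertex_beads = np.array([int(np.argmin(np.linalg.norm(
        positions_nm - vertices[v], axis=1))) for v in range(4)])

    base_vectors = np.zeros((n, 3))
    has = partner >= 0
    d = positions_nm[partner[has]] - positions_nm[has]
    base_vectors[has] = d / np.linalg.norm(d, axis=1, keepdims=True)
    normal_vectors = np.asarray(tangents)

    box = 4.0 * L / units.nm_per_length_unit
    frame0 = TrajectoryFrame(
        time=0.0, box=np.full(3, box),
        positions=positions_nm / units.nm_per_length_unit,
        base_vectors=base_vectors, normal_vectors=normal_vectors,
        energies=np.zeros(3))

    return BuildResult(
        design=design, topology=topology, frame0=frame0,
        positions_nm=positions_nm, bonds=bonds, bond_rests=bond_rests,
        reference_pairs=reference_pairs, fb_pairs=fb_pairs, partner=partner,
        anchor=anchor, pull=pull, fluorophore=fluorophore, quencher=quencher,
        pore_spec=pore_spec, vertex_beads=vertex_beads, vertices=vertices)


def rigid_pull_indices(build: BuildResult, n_points: int = 5,
                       spacing: int | None = None) -> list[int]:
    """Pull points 1..n along the anchoring strand, at increasing contour
    separation from the anchor bead (the rigid-analog designs: ligand and
    anchor on the same strand, so pulling cannot release the FB strand)."""
    E = build.design.edge_bp
    strand_start = build.anchor - E  # anchor strand begins at its face start
    strand_len = 3 * E
    if spacing is None:
        spacing = max(1, (2 * E - 1) // n_points)
    out = []
    local_anchor = build.anchor - strand_start
    for i in range(1, n_points + 1):
        local = local_anchor + i * spacing
        if local >= strand_len:
            raise ValueError("pull positions run off the anchoring strand; "
                             "reduce spacing or n_points")
        out.append(strand_start + local)
    return out


# ---------------------------------------------------------------------------
# Protocol helper
# ---------------------------------------------------------------------------

DEFAULT_LOADING_RATE = 1.4e4  # nm/s, the converted reference pulling rate
DEFAULT_TRAP_STIFFNESS = 11.42  # pN/nm per trap


def make_pull_protocol(build: BuildResult, params: SimParams,
                       pull_distance: float | None = None,
                       rate: float = DEFAULT_LOADING_RATE,
                       stiffness: float = DEFAULT_TRAP_STIFFNESS,
                       pull_index: int | None = None,
                       anchor_index: int | None = None,
                       axis: np.ndarray | None = None) -> TrapProtocol:
    """Build the dual-trap protocol for a structure.

    Traps start exactly on their attachment beads (zero initial force); the
    pulling axis defaults to the anchor→pull direction.  When
    ``pull_distance`` (nm) is given and cannot be covered within
    ``params.n_steps × params.dt`` at the requested rate, the rate is raised
    to fit the step budget and the rescaling is logged — equivalently, the
    pull is scaled down in duration rather than truncated.
    """
    ia = build.anchor if anchor_index is None else anchor_index
    ib = build.pull if pull_index is None else pull_index
    pa = build.positions_nm[ia]
    pb = build.positions_nm[ib]
    if axis is None:
        axis = pb - pa
        axis = axis / np.linalg.norm(axis)
    else:
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
    if pull_distance is not None:
        horizon = params.n_steps * params.dt
        reachable = rate * horizon
        if reachable < pull_distance:
            new_rate = pull_distance / horizon
            logger.warning(
                "loading rate rescaled from %.4g to %.4g nm/s to cover "
                "%.3g nm within the %d-step budget", rate, new_rate,
                pull_distance, params.n_steps)
            rate = new_rate
    return TrapProtocol(
        trap_a=Trap(ia, stiffness, pa.copy()),
        trap_b=Trap(ib, stiffness, pb.copy(), rate * axis),
        axis=axis)


# ---------------------------------------------------------------------------
# Integrator
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Trajectory (oxDNA simulation units), bond-event log and run status."""

    frames: list[TrajectoryFrame]
    events: list[tuple[int, int, int]]  # (step, i, j)
    stopped_early: bool
    final_step: int
    params: SimParams
    protocol: TrapProtocol | None

    def events_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["step", "i", "j"])

    def write_event_log(self, path) -> None:
        self.events_dataframe().to_csv(path, index=False)


@njit(cache=False)
def _advance_block(pos, bi, bj, brest, kbb, pi, pj, prest, kpair, intact,
                   xstar, use_bell, bell_k0, bell_xb, kT, uniforms,
                   has_traps, ia, ib, k1, k2, a_pos, b0, vel, dt, step0,
                   mobility, noise, noise_scale, max_rest,
                   ev_on, ev_cut, ev_k,
                   ev_steps, ev_i, ev_j, n_ev):  # pragma: no cover - numba
    """Advance ``noise.shape[0]`` Langevin steps in place.

    Returns (event count, instability step or -1).  Compiled with numba: the
    per-step work is simple loops over a few hundred springs, which would be
    dominated by array-creation overhead in pure numpy.
    """
    n = pos.shape[0]
    nsteps = noise.shape[0]
    force = np.zeros((n, 3))
    for s in range(nsteps):
        step = step0 + s + 1
        for i in range(n):
            force[i, 0] = 0.0
            force[i, 1] = 0.0
            force[i, 2] = 0.0
        for m in range(bi.shape[0]):
            i = bi[m]
            j = bj[m]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            length = np.sqrt(dx * dx + dy * dy + dz * dz)
            if length < 1e-12:
                length = 1e-12
            c = kbb * (length - brest[m]) / length
            force[i, 0] += c * dx
            force[i, 1] += c * dy
            force[i, 2] += c * dz
            force[j, 0] -= c * dx
            force[j, 1] -= c * dy
            force[j, 2] -= c * dz
        for m in range(pi.shape[0]):
            if not intact[m]:
                continue
            i = pi[m]
            j = pj[m]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            length = np.sqrt(dx * dx + dy * dy + dz * dz)
            if length < 1e-12:
                length = 1e-12
            ext = length - prest[m]
            broke = False
            if use_bell:
                f_pair = kpair * abs(ext)
                p_break = bell_k0 * np.exp(f_pair * bell_xb / kT) * dt
                broke = uniforms[s, m] < p_break
            elif ext > xstar:
                broke = True
            if broke:
                intact[m] = False
                ev_steps[n_ev] = step
                ev_i[n_ev] = i
                ev_j[n_ev] = j
                n_ev += 1
                continue
            c = kpair * ext / length
            force[i, 0] += c * dx
            force[i, 1] += c * dy
            force[i, 2] += c * dz
            force[j, 0] -= c * dx
            force[j, 1] -= c * dy
            force[j, 2] -= c * dz
        if ev_on:
            cutoff = 2.0 * ev_cut
            for i in range(n):
                for j in range(i + 1, n):
                    dx = pos[j, 0] - pos[i, 0]
                    dy = pos[j, 1] - pos[i, 1]
                    dz = pos[j, 2] - pos[i, 2]
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 < cutoff * cutoff and d2 > 1e-24:
                        length = np.sqrt(d2)
                        c = -ev_k * (cutoff - length) / length
                        force[i, 0] += c * dx
                        force[i, 1] += c * dy
                        force[i, 2] += c * dz
                        force[j, 0] -= c * dx
                        force[j, 1] -= c * dy
                        force[j, 2] -= c * dz
        if has_traps:
            t = step * dt
            force[ia, 0] += k1 * (a_pos[0] - pos[ia, 0])
            force[ia, 1] += k1 * (a_pos[1] - pos[ia, 1])
            force[ia, 2] += k1 * (a_pos[2] - pos[ia, 2])
            force[ib, 0] += k2 * (b0[0] + vel[0] * t - pos[ib, 0])
            force[ib, 1] += k2 * (b0[1] + vel[1] * t - pos[ib, 1])
            force[ib, 2] += k2 * (b0[2] + vel[2] * t - pos[ib, 2])
        max_disp = 0.0
        for i in range(n):
            for c_ax in range(3):
                d = mobility * force[i, c_ax]
                if abs(d) > max_disp:
                    max_disp = abs(d)
                pos[i, c_ax] += d + noise_scale * noise[s, i, c_ax]
        if max_disp > max_rest:
            return n_ev, step
    return n_ev, -1


def run_pulling(build: BuildResult, params: SimParams,
                protocol: TrapProtocol | None,
                stop_force: float | None = None,
                units: UnitSystem = DEFAULT_UNITS) -> SimResult:
    """Integrate the overdamped Langevin dynamics of a dual-trap pull.

    Emits a frame every ``params.stride`` steps (the initial configuration is
    frame 0) plus the final configuration.  A base-pair spring breaks
    irreversibly the first time its extension exceeds
    ``params.rupture_extension``; every break is recorded as
    ``(step, i, j)``.  When ``stop_force`` (pN) is given, the run ends at the
    first emitted frame whose projected trap force reaches it — this is how
    sub-rupture pulls are kept below a planted threshold.

    Raises :class:`SimulationInstability` if any bead moves farther than the
    largest rest length in a single step.
    """
    pos = build.positions_nm.copy()
    n = pos.shape[0]
    rng = np.random.default_rng(params.seed)

    bonds = build.bonds
    has_bonds = bonds.shape[0] > 0
    if has_bonds:
        bi, bj = bonds[:, 0], bonds[:, 1]
        bond_rests = (build.bond_rests if params.backbone_rest is None
                      else np.full(bonds.shape[0], params.backbone_rest))
    pairs = build.reference_pairs
    has_pairs = pairs.shape[0] > 0
    if has_pairs:
        pi, pj = pairs[:, 0].copy(), pairs[:, 1].copy()
        pair_rests = np.linalg.norm(build.positions_nm[pj]
                                    - build.positions_nm[pi], axis=1)
        intact = np.ones(pairs.shape[0], dtype=bool)

    if protocol is not None:
        ia, ib = protocol.trap_a.nucleotide, protocol.trap_b.nucleotide
        for idx in (ia, ib):
            if not 0 <= idx < n:
                raise IndexError(f"trap index {idx} out of range")
        k1, k2 = protocol.trap_a.stiffness, protocol.trap_b.stiffness
        k_eff = effective_stiffness([k1, k2])
        a_pos = protocol.trap_a.position_at(0.0)
        axis = protocol.axis

    mobility = params.dt / params.friction
    noise_scale = np.sqrt(2.0 * params.kT * params.dt / params.friction)
    max_rest = 1.0
    if has_bonds:
        max_rest = max(max_rest, float(np.max(bond_rests)))
    kT = params.kT

    def emit(step: int) -> TrajectoryFrame:
        bv = build.frame0.base_vectors.copy()
        has = build.partner >= 0
        d = pos[build.partner[has]] - pos[has]
        norms = np.linalg.norm(d, axis=1, keepdims=True)
        ok = norms[:, 0] > 1e-9
        bv_has = bv[has]
        bv_has[ok] = d[ok] / norms[ok]
        bv[has] = bv_has
        return TrajectoryFrame(
            time=step * params.dt / units.s_per_time_unit,
            box=build.frame0.box,
            positions=pos / units.nm_per_length_unit,
            base_vectors=bv,
            normal_vectors=build.frame0.normal_vectors,
            energies=np.zeros(3))

    def trap_force(t: float) -> float:
        b_pos = protocol.trap_b.position_at(t)
        return float(k_eff * (((pos[ia] - a_pos) @ axis)
                              + ((b_pos - pos[ib]) @ axis)))

    frames = [emit(0)]
    events: list[tuple[int, int, int]] = []
    stopped_early = False
    final_step = params.n_steps

    n_pairs = pairs.shape[0]
    if not has_bonds:
        bi = bj = np.empty(0, dtype=np.int64)
        bond_rests = np.empty(0)
    if not has_pairs:
        pi = pj = np.empty(0, dtype=np.int64)
        pair_rests = np.empty(0)
        intact = np.empty(0, dtype=np.bool_)
    use_bell = params.bell_k0 is not None
    if protocol is None:
        ia_k = ib_k = 0
        k1_k = k2_k = 0.0
        a_pos_k = b0_k = vel_k = np.zeros(3)
    else:
        ia_k, ib_k, k1_k, k2_k = ia, ib, k1, k2
        a_pos_k = np.asarray(a_pos, dtype=float)
        b0_k = np.asarray(protocol.trap_b.position, dtype=float)
        vel_k = np.asarray(protocol.trap_b.velocity, dtype=float)

    ev_steps = np.zeros(max(1, n_pairs), dtype=np.int64)
    ev_i = np.zeros(max(1, n_pairs), dtype=np.int64)
    ev_j = np.zeros(max(1, n_pairs), dtype=np.int64)
    n_ev = 0

    step0 = 0
    while step0 < params.n_steps:
        block = min(params.stride, params.n_steps - step0)
        noise = rng.standard_normal((block, n, 3))
        uniforms = (rng.random((block, n_pairs)) if use_bell
                    else np.zeros((1, 1)))
        n_ev, instab = _advance_block(
            pos, np.asarray(bi, dtype=np.int64),
            np.asarray(bj, dtype=np.int64), bond_rests,
            params.backbone_stiffness, np.asarray(pi, dtype=np.int64),
            np.asarray(pj, dtype=np.int64), pair_rests,
            params.pair_stiffness, intact, params.rupture_extension,
            use_bell, params.bell_k0 or 0.0, params.bell_xb, kT, uniforms,
            protocol is not None, ia_k, ib_k, k1_k, k2_k, a_pos_k, b0_k,
            vel_k, params.dt, step0, mobility, noise, noise_scale, max_rest,
            params.excluded_volume, params.ev_radius, params.ev_stiffness,
            ev_steps, ev_i, ev_j, n_ev)
        if instab >= 0:
            raise SimulationInstability(
                f"step {instab}: a bead displacement exceeded the largest "
                f"rest length {max_rest:.3g} nm in one step; reduce dt or "
                "stiffnesses")
        step0 += block
        frames.append(emit(step0))
        if (stop_force is not None and protocol is not None
                and trap_force(step0 * params.dt) >= stop_force):
            stopped_early = True
            final_step = step0
            break

    events = [(int(ev_steps[k]), int(ev_i[k]), int(ev_j[k]))
              for k in range(n_ev)]
    return SimResult(frames=frames, events=events,
                     stopped_early=stopped_early, final_step=final_step,
                     params=params, protocol=protocol)
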