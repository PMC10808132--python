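"""Reading, writing and validation of oxDNA classic files, plus unit conversion.

The classic oxDNA interchange consists of a *topology* file (``.top``) giving
strand membership, bases and 3'/5' backbone connectivity, and a
*configuration/trajectory* file (``.dat``/``.conf``) holding one or more frames
of per-nucleotide rigid-body coordinates.  Only the classic dialect is
supported: a topology header ``N_nucleotides N_strands`` followed by one
``strand base 3'-neighbour 5'-neighbour`` row per nucleotide, and frames headed
by ``t = ...``, ``b = ...``, ``E = ...`` lines followed by per-nucleotide rows
of 9 columns (position, base vector, normal vector) or 15 columns (additionally
velocity and angular velocity).

Nucleotides are indexed 0-based in file order throughout the package.
Coordinates are treated as unwrapped; the structures of interest (~10 nm) are
small compared to typical simulation boxes.

Simulation units map to SI via :class:`UnitSystem`: one oxDNA length unit is
0.8518 nm and one time unit is 3.03e-12 s.  The force unit (48.63 pN) follows
from the standard oxDNA energy/length convention and is consistent with a
printed trap stiffness of 11.42 pN/nm for 0.2 simulation stiffness units.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ParseError",
    "ValidationError",
    "UnitSystem",
    "DEFAULT_UNITS",
    "Topology",
    "NucleotideRecord",
    "TrajectoryFrame",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "convert_units",
    "complement",
    "COMPLEMENT",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_UNIT_TOL = 1e-3  # allowed deviation of base/normal vectors from unit norm


class ParseError(ValueError):
    """Malformed oxDNA file; message names the offending line or frame."""


class ValidationError(ValueError):
    """In-memory object violates a structural invariant."""


def complement(seq: str) -> str:
    """Watson-Crick complement of ``seq`` (no reversal)."""
    try:
        return "".join(COMPLEMENT[b] for b in seq)
    except KeyError as exc:  # pragma: no cover - guarded by parser
        raise ValidationError(f"non-ACGT base {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# Units
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitSystem:
    """Conversion constants between oxDNA simulation units and SI units.

    Attributes
    ----------
    nm_per_length_unit : float
        Nanometres per simulation length unit (0.8518).
    s_per_time_unit : float
        Seconds per simulation time unit (3.03e-12).
    pN_per_force_unit : float
        Piconewtons per simulation force unit.  Default 48.63, the standard
        oxDNA energy/length convention (energy unit / length unit).
    """

    nm_per_length_unit: float = 0.8518
    s_per_time_unit: float = 3.03e-12
    pN_per_force_unit: float = 48.63

    def __post_init__(self) -> None:
        if min(self.nm_per_length_unit, self.s_per_time_unit,
               self.pN_per_force_unit) <= 0:
            raise ValidationError("unit conversion constants must be positive")

    @property
    def rate_nm_s(self) -> float:
        """nm/s per simulation (length/time) rate unit."""
        return self.nm_per_length_unit / self.s_per_time_unit

    @property
    def stiffness_pN_nm(self) -> float:
        """pN/nm per simulation (force/length) stiffness unit."""
        return self.pN_per_force_unit / self.nm_per_length_unit


DEFAULT_UNITS = UnitSystem()

_KIND_FACTORS = {
    "length": lambda u: u.nm_per_length_unit,
    "time": lambda u: u.s_per_time_unit,
    "force": lambda u: u.pN_per_force_unit,
    "rate": lambda u: u.rate_nm_s,
    "stiffness": lambda u: u.stiffness_pN_nm,
}


def convert_units(value: float, kind: str, direction: str = "sim_to_si",
                  units: UnitSystem = DEFAULT_UNITS) -> float:
    """Convert ``value`` between simulation and SI units.

    Parameters
    ----------
    kind : {"length", "time", "force", "rate", "stiffness"}
        Physical dimension.  Lengths convert to nm, times to s, forces to pN,
        rates to nm/s and stiffnesses to pN/nm.
    direction : {"sim_to_si", "si_to_sim"}

    The two directions are exact inverses.
    """
    try:
        factor = _KIND_FACTORS[kind](units)
    except KeyError:
        raise ValueError(f"unknown unit kind {kind!r}; expected one of "
                         f"{sorted(_KIND_FACTORS)}") from None
    if direction == "sim_to_si":
        return value * factor
    if direction == "si_to_sim":
        return value / factor
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Strand layout and backbone connectivity of a structure.

    ``strands`` is an ordered list of ``(strand_id, sequence)`` with contiguous
    1-based strand ids; ``neighbors3``/``neighbors5`` give, per nucleotide (in
    file order), the index of its 3'/5' backbone neighbour, −1 at chain ends.
    Sequences are listed in file order, which for the classic format runs
    3' → 5' along each strand.
    """

    strands: list[tuple[int, str]]
    neighbors3: np.ndarray
    neighbors5: np.ndarray

    def __post_init__(self) -> None:
        self.neighbors3 = np.asarray(self.neighbors3, dtype=int)
        self.neighbors5 = np.asarray(self.neighbors5, dtype=int)
        self.validate()

    @property
    def n_nucleotides(self) -> int:
        return int(self.neighbors3.shape[0])

    @property
    def n_strands(self) -> int:
        return len(self.strands)

    @property
    def sequence(self) -> str:
        """Concatenated bases in file order."""
        return "".join(seq for _, seq in self.strands)

    @property
    def strand_ids(self) -> np.ndarray:
        """Per-nucleotide strand id (1-based), in file order."""
        out = np.empty(self.n_nucleotides, dtype=int)
        pos = 0
        for sid, seq in self.strands:
            out[pos:pos + len(seq)] = sid
            pos += len(seq)
        return out

    def validate(self) -> None:
        ids = [sid for sid, _ in self.strands]
        if ids != list(range(1, len(ids) + 1)):
            raise ValidationError(
                f"strand ids must be contiguous starting at 1, got {ids}")
        n = sum(len(seq) for _, seq in self.strands)
        for sid, seq in self.strands:
            bad = set(seq) - set("ACGT")
            if bad:
                raise ValidationError(
                    f"strand {sid}: non-ACGT bases {sorted(bad)}")
        if self.neighbors3.shape != (n,) or self.neighbors5.shape != (n,):
            raise ValidationError(
                "neighbor arrays must have one entry per nucleotide")
        sid_of = self.strand_ids
        for i in range(n):
            for nb, other in ((self.neighbors3[i], self.neighbors5),
                              (self.neighbors5[i], self.neighbors3)):
                if nb == -1:
                    continue
                if not 0 <= nb < n:
                    raise ValidationError(
                        f"nucleotide {i}: neighbor index {nb} out of range")
                if other[nb] != i:
                    raise ValidationError(
                        f"nucleotide {i}: asymmetric neighbor link to {nb}")
                if sid_of[nb] != sid_of[i]:
                    raise ValidationError(
                        f"nucleotide {i}: neighbor {nb} crosses a strand "
                        "boundary")


def read_topology(path: str | Path) -> Topology:
    """Parse a classic oxDNA topology file."""
    path = Path(path)
    lines = path.read_text().splitlines()
    stripped = [ln.strip() for ln in lines]
    if not stripped or not stripped[0]:
        raise ParseError(f"{path}: line 1: empty file or missing header")
    head = stripped[0].split()
    if len(head) != 2:
        raise ParseError(
            f"{path}: line 1: header must be 'N_nucleotides N_strands', "
            f"got {stripped[0]!r}")
    try:
        n_nt, n_strands = int(head[0]), int(head[1])
    except ValueError:
        raise ParseError(f"{path}: line 1: non-integer header field") from None

    rows = [(num, ln) for num, ln in enumerate(stripped[1:], start=2) if ln]
    if len(rows) != n_nt:
        raise ParseError(
            f"{path}: header declares {n_nt} nucleotides but file has "
            f"{len(rows)} rows")

    strand_of = np.empty(n_nt, dtype=int)
    bases: list[str] = []
    n3 = np.empty(n_nt, dtype=int)
    n5 = np.empty(n_nt, dtype=int)
    for i, (lineno, ln) in enumerate(rows):
        parts = ln.split()
        if len(parts) != 4:
            raise ParseError(
                f"{path}: line {lineno}: expected 4 fields, got {len(parts)}")
        try:
            strand_of[i] = int(parts[0])
            n3[i] = int(parts[2])
            n5[i] = int(parts[3])
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-integer field") from None
        base = parts[1].upper()
        if base not in COMPLEMENT:
            raise ParseError(
                f"{path}: line {lineno}: non-ACGT base {parts[1]!r}")
        bases.append(base)

    # group into strands by contiguous runs of strand id
    strands: list[tuple[int, str]] = []
    start = 0
    for i in range(1, n_nt + 1):
        if i == n_nt or strand_of[i] != strand_of[start]:
            strands.append((int(strand_of[start]), "".join(bases[start:i])))
            start = i
    if len(strands) != n_strands:
        raise ParseError(
            f"{path}: header declares {n_strands} strands but rows describe "
            f"{len(strands)} contiguous runs")
    try:
        return Topology(strands, n3, n5)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_topology(topology: Topology, path: str | Path) -> None:
    """Write ``topology`` in canonical classic format (deterministic bytes)."""
    path = Path(path)
    sid_of = topology.strand_ids
    seq = topology.sequence
    with path.open("w") as fh:
        fh.write(f"{topology.n_nucleotides} {topology.n_strands}\n")
        for i in range(topology.n_nucleotides):
            fh.write(f"{sid_of[i]} {seq[i]} {topology.neighbors3[i]} "
                     f"{topology.neighbors5[i]}\n")


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

@dataclass
class NucleotideRecord:
    """Rigid-body state of a single nucleotide (simulation units)."""

    position: np.ndarray
    base_vector: np.ndarray
    normal_vector: np.ndarray
    velocity: np.ndarray | None = None
    angular_velocity: np.ndarray | None = None


@dataclass
class TrajectoryFrame:
    """One configuration: per-nucleotide arrays plus frame metadata.

    All quantities are in oxDNA simulation units.  ``positions``,
    ``base_vectors`` and ``normal_vectors`` are (N, 3); velocities are
    optional and either both present or both absent.
    """

    time: float
    box: np.ndarray
    positions: np.ndarray
    base_vectors: np.ndarray
    normal_vectors: np.ndarray
    energies: np.ndarray | None = None
    velocities: np.ndarray | None = None
    angular_velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        for name in ("positions", "base_vectors", "normal_vectors"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    @property
    def n_nucleotides(self) -> int:
        return int(self.positions.shape[0])

    def nucleotide(self, i: int) -> NucleotideRecord:
        return NucleotideRecord(
            self.positions[i], self.base_vectors[i], self.normal_vectors[i],
            None if self.velocities is None else self.velocities[i],
            None if self.angular_velocities is None
            else self.angular_velocities[i])

    def validate(self) -> None:
        n = self.positions.shape[0]
        for name in ("positions", "base_vectors", "normal_vectors"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValidationError(f"{name} must be (N, 3)")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
        for name in ("base_vectors", "normal_vectors"):
            norms = np.linalg.norm(getattr(self, name), axis=1)
            if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
                raise ValidationError(
                    f"{name} must be unit vectors within {_UNIT_TOL}")
        if self.box.shape != (3,):
            raise ValidationError("box must have 3 components")


def _parse_header_line(line: str, prefix: str, path: Path,
                       lineno: int) -> np.ndarray:
    if not line.startswith(prefix):
        raise ParseError(
            f"{path}: line {lineno}: expected header {prefix!r}, got "
            f"{line[:30]!r}")
    try:
        return np.array([float(x) for x in line.split("=", 1)[1].split()])
    except ValueError:
        raise ParseError(
            f"{path}: line {lineno}: non-numeric value in {prefix!r} header"
        ) from None


def read_trajectory(path: str | Path,
                    topology: Topology) -> list[TrajectoryFrame]:
    """Parse a classic configuration/trajectory file.

    Accepts 9-column rows (positions and orientations) and 15-column rows
    (with velocities); the two yield identical positions.  Frames must match
    ``topology`` in nucleotide count and carry non-decreasing times.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    n = topology.n_nucleotides
    frames: list[TrajectoryFrame] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines and not lines[i].strip():
        i += 1
    while i < n_lines:
        frame_index = len(frames)
        t_arr = _parse_header_line(lines[i].strip(), "t", path, i + 1)
        if t_arr.size != 1:
            raise ParseError(f"{path}: line {i + 1}: malformed time header")
        if i + 2 >= n_lines:
            raise ParseError(
                f"{path}: frame {frame_index}: truncated header")
        box = _parse_header_line(lines[i + 1].strip(), "b", path, i + 2)
        energies = _parse_header_line(lines[i + 2].strip(), "E", path, i + 3)
        if box.size != 3:
            raise ParseError(
                f"{path}: frame {frame_index}: box must have 3 components")
        i += 3
        if i + n > n_lines:
            raise ParseError(
                f"{path}: frame {frame_index}: truncated (expected {n} "
                f"nucleotide rows)")
        try:
            data = np.loadtxt(io.StringIO("\n".join(lines[i:i + n])),
                              ndmin=2)
        except ValueError:
            raise ParseError(
                f"{path}: frame {frame_index}: non-numeric field in "
                "nucleotide rows") from None
        if data.shape[0] != n:
            raise ParseError(
                f"{path}: frame {frame_index}: row count {data.shape[0]} "
                f"does not match topology ({n})")
        if data.shape[1] not in (9, 15):
            raise ParseError(
                f"{path}: frame {frame_index}: rows must have 9 or 15 "
                f"columns, got {data.shape[1]}")
        kwargs = {}
        if data.shape[1] == 15:
            kwargs = {"velocities": data[:, 9:12],
                      "angular_velocities": data[:, 12:15]}
        try:
            frame = TrajectoryFrame(
                time=float(t_arr[0]), box=box,
                positions=data[:, 0:3], base_vectors=data[:, 3:6],
                normal_vectors=data[:, 6:9],
                energies=energies if energies.size else None, **kwargs)
        except ValidationError as exc:
            raise ParseError(f"{path}: frame {frame_index}: {exc}") from exc
        if frames and frame.time < frames[-1].time:
            raise ParseError(
                f"{path}: frame {frame_index}: time {frame.time} decreases "
                f"below previous {frames[-1].time}")
        frames.append(frame)
        i += n
        while i < n_lines and not lines[i].strip():
            i += 1
    return frames


def _fmt(values: Iterable[float]) -> str:
    return " ".join(f"{v:.12g}" for v in values)


def write_trajectory(frames: Sequence[TrajectoryFrame],
                     path: str | Path) -> None:
    """Write frames in classic format; ``read_trajectory`` round-trips it.

    Frames carrying velocities are written as 15-column rows, others as
    9-column rows.  Invalid frames are refused.
    """
    path = Path(path)
    with path.open("w") as fh:
        for frame in frames:
            frame.validate()
            fh.write(f"t = {frame.time:.12g}\n")
            fh.write(f"b = {_fmt(frame.box)}\n")
            e = frame.energies if frame.energies is not None else np.zeros(3)
            fh.write(f"E = {_fmt(e)}\n")
            has_vel = frame.velocities is not None
            for i in range(frame.n_nucleotides):
                row = [*frame.positions[i], *frame.base_vectors[i],
                       *frame.normal_vectors[i]]
                if has_vel:
                    row += [*frame.velocities[i],
                            *frame.angular_velocities[i]]
                fh.write(_fmt(row) + "\n")


def minimum_image_unwrap(frames: Sequence[TrajectoryFrame],
                         reference: int = 0) -> list[TrajectoryFrame]:
    """Optional utility: re-image each frame so every nucleotide sits in the
    periodic image nearest nucleotide ``reference``.  Off by default in all
    pipelines — structures here are small relative to their boxes."""
    out = []
    for frame in frames:
        pos = frame.positions.copy()
        delta = pos - pos[reference]
        pos -= np.round(delta / frame.box) * frame.box
        out.append(TrajectoryFrame(
            time=frame.time, box=frame.box, positions=pos,
            base_vectors=frame.base_vectors,
            normal_vectors=frame.normal_vectors, energies=frame.energies,
            velocities=frame.velocities,
            angular_velocities=frame.angular_velocities))
    return out
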