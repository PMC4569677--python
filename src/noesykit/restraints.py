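"""Ambiguous distance restraints, calibration, and ensemble-averaged distances.

An NOE cross-peak gives rise to one distance restraint that may have several
*contributions* (candidate atom pairs).  Against a single conformer the
contributions combine through an r^-6 sum,

    d = ( sum_a d_a^-6 )^(-1/6),

which is always at most the shortest contributing distance.  Against an
ensemble of S conformers the *effective distance* is the arithmetic mean of
the per-conformer r^-6-summed distances, and its difference from the target
distance (``ec = d_eff - d_target``) feeds the adaptive violation tolerance.

Targets are calibrated from peak intensities via ``d = c * |I|**(-1/6)``,
with the scale ``c`` fixed by pinning a chosen quantile of the calibrated
distances to a reference distance (median to 3.0 A by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .peaks import PeakList

__all__ = [
    "Contribution",
    "DistanceRestraint",
    "CoordinateEnsemble",
    "RestraintFit",
    "per_structure_distance",
    "effective_distance",
    "calibrate_targets",
    "bounds_from_target",
    "read_restraints",
    "write_restraints",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
]

AtomId = tuple[int, str]  # (residue number, atom name)


@dataclass(frozen=True)
class Contribution:
    """One assignment possibility of an ambiguous restraint."""

    atom_a: AtomId
    atom_b: AtomId

    def __post_init__(self) -> None:
        if self.atom_a == self.atom_b:
            raise ValueError(f"contribution pairs an atom with itself: {self.atom_a}")


@dataclass
class DistanceRestraint:
    """A distance restraint with target, bounds and ambiguous contributions.

    ``active`` and ``weight`` track the restraint's state across iterations;
    rejected restraints are deactivated, never deleted, so the audit trail of
    the original list is preserved.
    """

    id: int
    d_target: float
    lower: float
    upper: float
    contributions: list[Contribution]
    active: bool = True
    weight: float = 1.0
    origin_peak: int | None = None

    def __post_init__(self) -> None:
        if not self.contributions:
            raise ValueError(f"restraint {self.id} has no contributions")
        if not 0.0 < self.lower <= self.d_target <= self.upper:
            raise ValueError(
                f"restraint {self.id}: need 0 < lower <= target <= upper, got "
                f"({self.lower}, {self.d_target}, {self.upper})"
            )
        if self.weight < 0:
            raise ValueError(f"restraint {self.id}: negative weight")


class AtomLookupError(KeyError):
    """An atom referenced by a restraint is absent from a conformer."""


@dataclass
class CoordinateEnsemble:
    """S conformers over a shared atom table, coordinates in Angstrom."""

    atoms: list[AtomId]
    coords: np.ndarray  # shape (S, n_atoms, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must have shape (S, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one conformer")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("conformers do not index the atom table")
        self._index = {atom: i for i, atom in enumerate(self.atoms)}

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    def atom_index(self, atom: AtomId, conformer: int | None = None) -> int:
        try:
            return self._index[atom]
        except KeyError:
            where = f" in conformer {conformer}" if conformer is not None else ""
            raise AtomLookupError(f"atom {atom} not found{where}") from None

    def conformer(self, j: int) -> np.ndarray:
        return self.coords[j]


@dataclass
class RestraintFit:
    """How one restraint fits an ensemble: per-conformer and mean distances."""

    restraint_id: int
    d_target: float
    per_structure: list[float]
    d_eff: float = field(init=False)
    ec: float = field(init=False)

    def __post_init__(self) -> None:
        self.d_eff = float(np.mean(self.per_structure))
        self.ec = self.d_eff - self.d_target


def per_structure_distance(
    r: DistanceRestraint,
    conformer: np.ndarray,
    atoms: list[AtomId] | CoordinateEnsemble,
    conformer_index: int | None = None,
) -> float:
    """r^-6-summed distance of restraint ``r`` in a single conformer.

    Equals the plain distance for a single contribution and is bounded above
    by the shortest contributing distance in general.
    """
    if isinstance(atoms, CoordinateEnsemble):
        ens = atoms
    else:
        ens = CoordinateEnsemble(atoms=list(atoms), coords=np.asarray(conformer)[None])
    total = 0.0
    for c in r.contributions:
        ia = ens.atom_index(c.atom_a, conformer_index)
        ib = ens.atom_index(c.atom_b, conformer_index)
        d = float(np.linalg.norm(np.asarray(conformer)[ia] - np.asarray(conformer)[ib]))
        total += d ** -6
    return total ** (-1.0 / 6.0)


def effective_distance(r: DistanceRestraint, ens: CoordinateEnsemble) -> RestraintFit:
    """Effective distance of ``r`` against an ensemble.

    The per-conformer r^-6-summed distances are averaged arithmetically over
    conformers; ``ec`` is their mean minus the target.
    """
    per = [
        per_structure_distance(r, ens.conformer(j), ens, conformer_index=j)
        for j in range(ens.n_conformers)
    ]
    return RestraintFit(restraint_id=r.id, d_target=r.d_target, per_structure=per)


def calibrate_targets(
    peaks: PeakList, d_ref: float = 3.0, quantile: float = 0.5
) -> dict[int, float]:
    """Per-peak target distances from intensities, ``d_p = c * |I_p|**(-1/6)``.

    The scale ``c`` is chosen so the given quantile of the calibrated
    distances equals ``d_ref`` (the median by default; an even-count median is
    the mean of the two middle values).  Returns a mapping peak id -> A.
    """
    if not peaks.peaks:
        raise ValueError("cannot calibrate an empty peak list")
    mags = []
    for p in peaks.peaks:
        if p.intensity == 0.0:
            raise ValueError(f"peak {p.id} has zero intensity; cannot calibrate")
        mags.append(abs(p.intensity))
    raw = np.asarray(mags) ** (-1.0 / 6.0)
    pivot = float(np.quantile(raw, quantile))
    c = d_ref / pivot
    return {p.id: float(c * r) for p, r in zip(peaks.peaks, raw)}


def bounds_from_target(d_target: float, frac: float = 0.25) -> tuple[float, float]:
    """Symmetric fractional bounds ``((1-frac)*d, (1+frac)*d)`` around a target."""
    if d_target <= 0:
        raise ValueError(f"target distance must be positive, got {d_target}")
    if not 0.0 <= frac < 1.0:
        raise ValueError(f"bounds fraction must be in [0, 1), got {frac}")
    return ((1.0 - frac) * d_target, (1.0 + frac) * d_target)


# ---------------------------------------------------------------------------
# restraint table I/O

_RESTRAINT_HEADER = "#id\tres_a\tatom_a\tres_b\tatom_b\td_target\tlower\tupper\tweight\tactive"


def write_restraints(
    restraints: Sequence[DistanceRestraint], path: str | Path, dialect: str = "tsv"
) -> None:
    """Write restraints as TSV (round-trippable) or CNS ASSIGN statements.

    TSV repeats the id row once per contribution of an ambiguous restraint.
    The CNS dialect emits ``assign (resid R and name A)(resid R' and name A')
    d dminus dplus`` with ``or`` continuation lines, and is write-only.
    """
    path = Path(path)
    if dialect == "tsv":
        lines = [_RESTRAINT_HEADER]
        for r in restraints:
            for c in r.contributions:
                lines.append(
                    f"{r.id}\t{c.atom_a[0]}\t{c.atom_a[1]}\t{c.atom_b[0]}\t{c.atom_b[1]}"
                    f"\t{r.d_target!r}\t{r.lower!r}\t{r.upper!r}\t{r.weight!r}"
                    f"\t{int(r.active)}"
                )
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "cns_assign":
        lines = []
        for r in restraints:
            dminus = r.d_target - r.lower
            dplus = r.upper - r.d_target
            first = r.contributions[0]
            lines.append(
                f"assign (resid {first.atom_a[0]:d} and name {first.atom_a[1]})"
                f"(resid {first.atom_b[0]:d} and name {first.atom_b[1]}) "
                f"{r.d_target:.3f} {dminus:.3f} {dplus:.3f}"
            )
            for c in r.contributions[1:]:
                lines.append(
                    f"    or (resid {c.atom_a[0]:d} and name {c.atom_a[1]})"
                    f"(resid {c.atom_b[0]:d} and name {c.atom_b[1]})"
                )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown restraint dialect {dialect!r}")


def read_restraints(path: str | Path, dialect: str = "tsv") -> list[DistanceRestraint]:
    """Read a TSV restraint table (consecutive rows with equal id merge into
    one ambiguous restraint)."""
    if dialect != "tsv":
        raise ValueError(f"unsupported read dialect {dialect!r} (cns_assign is write-only)")
    path = Path(path)
    rows: list[tuple[int, Contribution, float, float, float, float, bool]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ValueError(f"{path}:{lineno}: expected 10 columns, got {len(fields)}")
            try:
                rid = int(fields[0])
                contrib = Contribution(
                    atom_a=(int(fields[1]), fields[2]), atom_b=(int(fields[3]), fields[4])
                )
                d, lo, up, w = (float(f) for f in fields[5:9])
                active = bool(int(fields[9]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            rows.append((rid, contrib, d, lo, up, w, active))
    restraints: list[DistanceRestraint] = []
    for rid, contrib, d, lo, up, w, active in rows:
        if restraints and restraints[-1].id == rid:
            restraints[-1].contributions.append(contrib)
        else:
            restraints.append(
                DistanceRestraint(
                    id=rid, d_target=d, lower=lo, upper=up,
                    contributions=[contrib], active=active, weight=w,
                )
            )
    return restraints


# ---------------------------------------------------------------------------
# PDB ensemble I/O (multi-model, first chain, altloc 'A')

def read_pdb_ensemble(path: str | Path) -> CoordinateEnsemble:
    """Read a multi-model PDB file into a coordinate ensemble.

    Every MODEL becomes one conformer; only the first chain is used and
    alternate locations take conformation 'A'.  Atom identity is
    (residue serial, atom name).
    """
    import gemmi

    structure = gemmi.read_pdb(str(path))
    structure.setup_entities()
    atoms: list[AtomId] | None = None
    conformers: list[np.ndarray] = []
    for model in structure:
        chain = model[0]
        ids: list[AtomId] = []
        xyz: list[tuple[float, float, float]] = []
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("", "A", "\x00"):
                    continue
                ids.append((residue.seqid.num, atom.name))
                xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
        if atoms is None:
            atoms = ids
        elif ids != atoms:
            raise ValueError(f"{path}: models do not share one atom table")
        conformers.append(np.asarray(xyz))
    if atoms is None:
        raise ValueError(f"{path}: no models found")
    return CoordinateEnsemble(atoms=atoms, coords=np.stack(conformers))


def write_pdb_ensemble(ens: CoordinateEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (single chain A).

    Toy point-atoms are emitted as CA pseudo-atoms of ALA residues so any
    standard PDB reader accepts the file.
    """
    lines: list[str] = []
    for j in range(ens.n_conformers):
        lines.append(f"MODEL     {j + 1:>4d}")
        for serial, ((resnum, name), (x, y, z)) in enumerate(
            zip(ens.atoms, ens.coords[j]), start=1
        ):
            atom_name = name if len(name) >= 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:>5d} {atom_name:<4s} ALA A{resnum:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
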