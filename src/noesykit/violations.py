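"""Consistent-violation detection and the adaptive violation tolerance.

Iterative NOE assignment rejects restraints that are *consistently* violated
across the low-energy conformers of an iteration.  A conformer violates a
restraint when its r^-6-summed distance lies outside the bounds by more than
the violation tolerance ``t``; the violated fraction over the S analysed
conformers is

    f_i = S^-1 * sum_j max(theta(L_i - d_ij - t), theta(d_ij - U_i - t)),

with theta the Heaviside step (theta(0) = 0: strict exceedance).  A restraint
is rejected when f_i strictly exceeds the violation threshold (0.5 by
default).

The tolerance itself comes from a nine-iteration schedule.  In *fixed* mode
the schedule holds t directly in Angstrom, with the legacy defaults
1000.0, 5.0, 3.0, 1.0, 1.0, 1.0, 0.1, 0.1, 0.1 A.  In *adaptive* mode the
schedule holds a scaling factor T per iteration (defaults 200, 6.0, 3.0,
2.0, 1.0, 1.0, 0.5, 0.5, 0.5) and the tolerance is t = D*T, where D is the
population standard deviation of the effective-minus-target distance
differences ``ec_i`` over the active restraints: the worse the current
ensemble fits the data, the more tolerant the rejection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .restraints import CoordinateEnsemble, DistanceRestraint, RestraintFit, effective_distance

__all__ = [
    "FIXED_TOLERANCE_DEFAULTS",
    "ADAPTIVE_T_DEFAULTS",
    "DEFAULT_VIOLATION_THRESHOLD",
    "ToleranceSchedule",
    "ViolationReport",
    "violation_fraction",
    "adaptive_tolerance",
    "analyse_violations",
    "reject_violated",
]

logger = logging.getLogger(__name__)

#: Legacy per-iteration violation tolerances t (Angstrom), iterations 0..8.
FIXED_TOLERANCE_DEFAULTS: tuple[float, ...] = (
    1000.0, 5.0, 3.0, 1.0, 1.0, 1.0, 0.1, 0.1, 0.1,
)

#: Adaptive-mode scaling factors T per iteration (t = D*T), iterations 0..8.
ADAPTIVE_T_DEFAULTS: tuple[float, ...] = (200.0, 6.0, 3.0, 2.0, 1.0, 1.0, 0.5, 0.5, 0.5)

DEFAULT_VIOLATION_THRESHOLD: float = 0.5


@dataclass(frozen=True)
class ToleranceSchedule:
    """Nine per-iteration values: tolerances t (fixed) or scalings T (adaptive)."""

    mode: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "adaptive"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if len(self.values) != 9:
            raise ValueError(f"schedule needs exactly 9 values, got {len(self.values)}")
        if any(v < 0 for v in self.values):
            raise ValueError("schedule values must be >= 0")

    @classmethod
    def default_fixed(cls) -> "ToleranceSchedule":
        return cls(mode="fixed", values=FIXED_TOLERANCE_DEFAULTS)

    @classmethod
    def default_adaptive(cls) -> "ToleranceSchedule":
        return cls(mode="adaptive", values=ADAPTIVE_T_DEFAULTS)


@dataclass
class ViolationReport:
    """Outcome of one violation-analysis pass over the active restraints."""

    t_used: float
    threshold: float
    fractions: dict[int, float] = field(default_factory=dict)
    violated: dict[int, bool] = field(default_factory=dict)
    D: float | None = None  # adaptive mode only

    @property
    def n_violated(self) -> int:
        return sum(self.violated.values())


def violation_fraction(r: DistanceRestraint, ens: CoordinateEnsemble, t: float) -> float:
    """Fraction of conformers violating restraint ``r`` at tolerance ``t``.

    A conformer counts iff its r^-6 distance is strictly below ``lower - t``
    or strictly above ``upper + t`` (a distance exactly on the tolerated
    bound does not violate).
    """
    if t < 0:
        raise ValueError(f"tolerance must be >= 0, got {t}")
    fit = effective_distance(r, ens)
    n_viol = sum(
        1 for d in fit.per_structure if (r.lower - d - t) > 0 or (d - r.upper - t) > 0
    )
    return n_viol / ens.n_conformers


def adaptive_tolerance(fits: Sequence[RestraintFit], T: float) -> tuple[float, float]:
    """Tolerance t = D*T from the spread of effective-vs-target differences.

    D is the population standard deviation of ``{ec_i}`` over ``fits``; at
    least two fits are required for a meaningful spread.  Returns ``(t, D)``.
    """
    if len(fits) < 2:
        raise ValueError(f"adaptive tolerance needs >= 2 restraint fits, got {len(fits)}")
    if T < 0:
        raise ValueError(f"T must be >= 0, got {T}")
    ec = np.asarray([f.ec for f in fits])
    D = float(np.sqrt(np.mean(ec**2) - np.mean(ec) ** 2))
    if not D > 0:
        D = 0.0
        logger.warning("all effective-target differences identical; tolerance collapses to 0")
    return D * T, D


def analyse_violations(
    restraints: Sequence[DistanceRestraint],
    ens: CoordinateEnsemble,
    schedule: ToleranceSchedule,
    iteration: int,
    threshold: float = DEFAULT_VIOLATION_THRESHOLD,
) -> ViolationReport:
    """Violation analysis of the active restraints at one iteration.

    Fixed mode applies the scheduled tolerance directly; adaptive mode first
    computes D over the active restraints' fits and applies t = D*T.  Every
    active restraint receives a violated fraction and a flag (violated iff
    the fraction strictly exceeds ``threshold``).
    """
    if not 0 <= iteration < len(schedule.values):
        raise ValueError(f"iteration {iteration} outside schedule 0..{len(schedule.values) - 1}")
    active = [r for r in restraints if r.active]
    if not active:
        raise ValueError("no active restraints to analyse")
    D: float | None = None
    if schedule.mode == "fixed":
        t = schedule.values[iteration]
    else:
        fits = [effective_distance(r, ens) for r in active]
        t, D = adaptive_tolerance(fits, schedule.values[iteration])
    report = ViolationReport(t_used=t, threshold=threshold, D=D)
    for r in active:
        f = violation_fraction(r, ens, t)
        report.fractions[r.id] = f
        report.violated[r.id] = f > threshold
    return report


def reject_violated(
    restraints: Sequence[DistanceRestraint], report: ViolationReport
) -> list[DistanceRestraint]:
    """Deactivate every restraint the report flags as violated.

    Nothing is deleted: rejected restraints stay in the list with
    ``active=False`` so the decision history remains auditable.
    """
    for r in restraints:
        if report.violated.get(r.id, False):
            r.active = False
    return list(restraints)
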