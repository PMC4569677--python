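"""Distance-restraint energy potentials and the softened geometric force field.

Two restraint potentials are provided, as energy/gradient pairs in the
restraint distance ``d``:

* Flat-bottom harmonic wall (FBHW): zero inside the bounds ``[L, U]``,
  harmonic ``k (d-U)^2`` just above the upper bound, switching to a linear
  asymptote with matched slope ``2 k s`` beyond ``U + s``, and plain
  harmonic below ``L``.  Energy and first derivative are continuous at L, U
  and U+s.
* Log-harmonic: ``E = k ln^2(d / d_target)``.  There are no bounds — the
  target is a single value; the energy rises sharply below the target
  (infinitely repulsive as d -> 0) and its slope decays to zero at long
  range, so a badly violated restraint cannot dominate the force field.

The log-harmonic weight ``k`` can be set automatically from how well the
current ensemble satisfies the restraints, ``k = N / sum_i ln^2(d_eff,i /
d_target,i)`` capped at ``k_max``: the worse the fit, the lower the weight,
so convergence is never forced by wrong restraints.  This estimator is an
approximation to the full Bayesian treatment of the restraint-error scale.

The force-field side of the same philosophy softens the covalent geometry
and restores realistic hydrogen sizes: bond-angle and improper force
constants drop by a factor 10 (500 -> 50 kcal/mol, units as conventionally
printed per radian) and the pairwise hydrogen-hydrogen van der Waals radii
are raised to aliphatic 1.2 A, amide 1.0 A, charged 1.0 A, emitted as
NBFIX-style pairwise overrides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

from .restraints import DistanceRestraint, RestraintFit

__all__ = [
    "PotentialSpec",
    "ForceFieldParams",
    "MODIFIED_HH_RADII",
    "fbhw_energy",
    "log_harmonic_energy",
    "restraint_energy",
    "auto_weight",
    "apply_forcefield_modifications",
    "emit_nbfix",
]

#: Pairwise H-H van der Waals radii (Angstrom) of the modified force field.
MODIFIED_HH_RADII: dict[str, float] = {"HA": 1.2, "H": 1.0, "HC": 1.0}

#: Radii of the unmodified PROLSQ-style parameter set.
LEGACY_HH_RADII: dict[str, float] = {"HA": 1.0, "H": 0.8, "HC": 0.8}


@dataclass(frozen=True)
class PotentialSpec:
    """Choice and parameters of the restraint potential.

    ``s`` is the FBHW harmonic-to-linear switch offset in Angstrom (ignored
    by the log-harmonic potential); ``weight_mode`` selects whether ``k`` is
    held fixed or re-estimated from the restraint fit each iteration.
    """

    kind: str = "log_harmonic"
    k: float = 1.0
    s: float = 1.0
    weight_mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.kind not in ("fbhw", "log_harmonic"):
            raise ValueError(f"unknown potential kind {self.kind!r}")
        if self.k < 0:
            raise ValueError("force constant k must be >= 0")
        if self.s < 0:
            raise ValueError("FBHW switch offset s must be >= 0")
        if self.weight_mode not in ("fixed", "auto"):
            raise ValueError(f"unknown weight mode {self.weight_mode!r}")


def fbhw_energy(
    d: float, r: DistanceRestraint, spec: PotentialSpec
) -> tuple[float, float]:
    """Flat-bottom harmonic-wall energy and gradient dE/dd at distance ``d``.

    Zero on ``[L, U]``; ``k (d-U)^2`` on ``(U, U+s]``; linear with the
    matched slope ``2 k s`` beyond; ``k (L-d)^2`` below ``L`` (no linear
    switch on the short side).
    """
    if d <= 0:
        raise ValueError(f"distance must be positive, got {d}")
    k, s = spec.k, spec.s
    L, U = r.lower, r.upper
    if d < L:
        delta = L - d
        return k * delta * delta, -2.0 * k * delta
    if d <= U:
        return 0.0, 0.0
    delta = d - U
    if delta <= s:
        return k * delta * delta, 2.0 * k * delta
    return k * s * s + 2.0 * k * s * (delta - s), 2.0 * k * s


def log_harmonic_energy(
    d: float, r: DistanceRestraint, spec: PotentialSpec
) -> tuple[float, float]:
    """Log-harmonic energy ``k ln^2(d/d_target)`` and gradient at ``d``.

    Zero at the target, divergent as d -> 0+, asymptotically flat as
    d -> infinity.
    """
    if d <= 0:
        raise ValueError(f"distance must be positive, got {d}")
    k = spec.k
    ratio = math.log(d / r.d_target)
    return k * ratio * ratio, 2.0 * k * ratio / d


def restraint_energy(
    d: float, r: DistanceRestraint, spec: PotentialSpec
) -> tuple[float, float]:
    """Dispatch to the spec'd potential; energy is scaled by the restraint weight."""
    fn = fbhw_energy if spec.kind == "fbhw" else log_harmonic_energy
    e, g = fn(d, r, spec)
    return r.weight * e, r.weight * g


def auto_weight(fits: Sequence[RestraintFit], k_max: float = 1e4) -> float:
    """Restraint force constant from the quality of the current fit.

    ``k = N / sum_i ln^2(d_eff,i / d_target,i)``, capped at ``k_max``; a
    perfect fit returns the cap.  The weight shrinks quadratically as the
    log-misfit grows, down-weighting data the structures cannot satisfy.
    """
    if not fits:
        raise ValueError("auto_weight needs at least one restraint fit")
    total = 0.0
    for f in fits:
        if f.d_eff <= 0 or f.d_target <= 0:
            raise ValueError(f"restraint {f.restraint_id}: non-positive distance")
        total += math.log(f.d_eff / f.d_target) ** 2
    if total == 0.0:
        return k_max
    return min(len(fits) / total, k_max)


@dataclass
class ForceFieldParams:
    """Bond-angle/improper force constants and pairwise H-H radii.

    Units: kcal mol^-1 per squared radian for the force constants (stored
    under the conventional per-radian label), Angstrom for radii.  The
    ``hh_radii`` keys are the three CNS hydrogen types: HA (aliphatic),
    H (amide), HC (charged).
    """

    angle_k: float = 500.0
    improper_k: float = 500.0
    hh_radii: dict[str, float] = field(default_factory=lambda: dict(LEGACY_HH_RADII))
    scale_applied: bool = False

    def __post_init__(self) -> None:
        if self.angle_k <= 0 or self.improper_k <= 0:
            raise ValueError("force constants must be positive")
        if set(self.hh_radii) != {"HA", "H", "HC"}:
            raise ValueError(f"hh_radii keys must be exactly HA/H/HC, got {set(self.hh_radii)}")
        if any(v <= 0 for v in self.hh_radii.values()):
            raise ValueError("radii must be positive")


def apply_forcefield_modifications(base: ForceFieldParams) -> ForceFieldParams:
    """Soften the geometric force field and enlarge the hydrogens.

    Angle and improper force constants are divided by 10 (500 -> 50) and the
    pairwise H-H radii replaced by the enlarged set {HA: 1.2, H: 1.0,
    HC: 1.0} A.  Refuses to run twice on the same parameter set.
    """
    if base.scale_applied:
        raise ValueError("force-field modifications already applied")
    return replace(
        base,
        angle_k=base.angle_k / 10.0,
        improper_k=base.improper_k / 10.0,
        hh_radii=dict(MODIFIED_HH_RADII),
        scale_applied=True,
    )


_HH_TYPE_ORDER = ("HA", "H", "HC")


def emit_nbfix(ff: ForceFieldParams) -> str:
    """NBFIX-style pairwise overrides for all H-H type pairs.

    One line per unordered pair with repetition (6 lines), combined radius =
    sum of the two per-type radii, in the fixed order HA, H, HC.
    """
    if not ff.scale_applied:
        raise ValueError("emit_nbfix expects the modified parameter set (scale_applied=True)")
    lines = []
    for i, a in enumerate(_HH_TYPE_ORDER):
        for b in _HH_TYPE_ORDER[i:]:
            combined = ff.hh_radii[a] + ff.hh_radii[b]
            lines.append(f"NBFIX {a:<3s} {b:<3s} {combined:6.3f}")
    return "\n".join(lines) + "\n"
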