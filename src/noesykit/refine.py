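"""Desk-scale iterative refinement: calibrate -> fit -> analyse -> reject.

This module exercises the restraint machinery end-to-end without a molecular
dynamics engine.  Conformers are point-atom chains minimized by steepest
descent with backtracking line search under a toy energy

    E = sum_restraints w_i * E_pot(d_eff_i)  +  k_rep * sum_pairs max(0, r_min - d)^2,

where ``E_pot`` is either restraint potential, ``d_eff`` the r^-6-summed
contribution distance, and the soft-sphere repulsion radius comes from the
force-field H-H radii.  Each protocol iteration regenerates an ensemble from
Gaussian-perturbed extended chains, analyses restraint violations on the
lowest-energy conformers, deactivates the consistently violated restraints,
and (optionally) re-estimates the restraint weight — the same
analyse/reject/re-weight loop a full structure-calculation run performs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .potentials import ForceFieldParams, PotentialSpec, auto_weight
from .restraints import CoordinateEnsemble, DistanceRestraint, effective_distance
from .synth import LabelledFixture, make_ensemble
from .violations import ToleranceSchedule, ViolationReport, analyse_violations, reject_violated

__all__ = [
    "IterationState",
    "ToyEnergy",
    "minimize",
    "run_iteration",
    "run_protocol",
    "kabsch_rmsd",
    "ensemble_precision",
]


class ToyEnergy:
    """Vectorized energy/gradient of a point-atom conformer.

    Restraint energies act on the r^-6-summed distance of each restraint's
    contributions; a soft-sphere repulsion ``k_rep * max(0, r_min - d)^2``
    acts on every atom pair, with ``r_min`` twice the aliphatic H radius of
    the force field.
    """

    def __init__(
        self,
        restraints: Sequence[DistanceRestraint],
        atoms: Sequence[tuple[int, str]],
        spec: PotentialSpec,
        ff: ForceFieldParams | None = None,
        k_rep: float = 10.0,
    ) -> None:
        self.spec = spec
        self.k_rep = k_rep
        radii = (ff or ForceFieldParams()).hh_radii
        self.r_min = 2.0 * radii["HA"]
        index = {atom: i for i, atom in enumerate(atoms)}
        ia, ib, group = [], [], []
        dt, lo, up, w = [], [], [], []
        for g, r in enumerate(restraints):
            dt.append(r.d_target)
            lo.append(r.lower)
            up.append(r.upper)
            w.append(r.weight)
            for c in r.contributions:
                ia.append(index[c.atom_a])
                ib.append(index[c.atom_b])
                group.append(g)
        self.ia = np.asarray(ia, dtype=int)
        self.ib = np.asarray(ib, dtype=int)
        self.group = np.asarray(group, dtype=int)
        self.dt = np.asarray(dt)
        self.lo = np.asarray(lo)
        self.up = np.asarray(up)
        self.w = np.asarray(w)
        n = len(atoms)
        self.pi, self.pj = np.triu_indices(n, k=1)

    def _restraint_terms(self, d_eff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-restraint energy and dE/dd at the effective distances."""
        k, s = self.spec.k, self.spec.s
        if self.spec.kind == "log_harmonic":
            lr = np.log(d_eff / self.dt)
            return k * lr * lr, 2.0 * k * lr / d_eff
        e = np.zeros_like(d_eff)
        g = np.zeros_like(d_eff)
        below = d_eff < self.lo
        e[below] = k * (self.lo[below] - d_eff[below]) ** 2
        g[below] = -2.0 * k * (self.lo[below] - d_eff[below])
        harm = (d_eff > self.up) & (d_eff <= self.up + s)
        e[harm] = k * (d_eff[harm] - self.up[harm]) ** 2
        g[harm] = 2.0 * k * (d_eff[harm] - self.up[harm])
        lin = d_eff > self.up + s
        e[lin] = k * s * s + 2.0 * k * s * (d_eff[lin] - self.up[lin] - s)
        g[lin] = 2.0 * k * s
        return e, g

    def __call__(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = np.asarray(coords, dtype=float)
        grad = np.zeros_like(coords)
        energy = 0.0
        if self.ia.size:
            diff = coords[self.ia] - coords[self.ib]
            d_a = np.linalg.norm(diff, axis=1)
            inv6 = d_a ** -6.0
            sums = np.zeros(self.dt.size)
            np.add.at(sums, self.group, inv6)
            d_eff = sums ** (-1.0 / 6.0)
            e_r, g_r = self._restraint_terms(d_eff)
            energy += float(np.sum(self.w * e_r))
            # chain rule: d(d_eff)/d(d_a) = (d_eff / d_a)^7
            c_a = (self.w * g_r)[self.group] * (d_eff[self.group] / d_a) ** 7
            f_a = (c_a / d_a)[:, None] * diff
            np.add.at(grad, self.ia, f_a)
            np.add.at(grad, self.ib, -f_a)
        # soft-sphere repulsion over all pairs
        pdiff = coords[self.pi] - coords[self.pj]
        pd = np.linalg.norm(pdiff, axis=1)
        overlap = self.r_min - pd
        hit = overlap > 0
        if np.any(hit):
            energy += float(self.k_rep * np.sum(overlap[hit] ** 2))
            c_p = -2.0 * self.k_rep * overlap[hit] / pd[hit]
            f_p = c_p[:, None] * pdiff[hit]
            np.add.at(grad, self.pi[hit], f_p)
            np.add.at(grad, self.pj[hit], -f_p)
        return energy, grad


def minimize(
    coords: np.ndarray,
    restraints: Sequence[DistanceRestraint],
    spec: PotentialSpec,
    ff: ForceFieldParams | None = None,
    max_steps: int = 400,
    initial_step: float = 0.02,
    grad_tol: float = 1e-6,
    min_step: float = 1e-10,
) -> tuple[np.ndarray, list[float]]:
    """Steepest descent with backtracking step halving.

    Only active restraints contribute.  The returned energy trace holds the
    initial energy followed by one entry per accepted step and is
    monotonically non-increasing by construction; a vanishing gradient (or
    an exhausted line search) stops the run.
    """
    coords = np.array(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite input coordinates")
    atoms = [(i + 1, "CA") for i in range(coords.shape[0])]
    energy = ToyEnergy([r for r in restraints if r.active], atoms, spec, ff)
    e, g = energy(coords)
    if not math.isfinite(e):
        raise FloatingPointError(f"non-finite initial energy {e}")
    trace = [e]
    step = initial_step
    for _ in range(max_steps):
        gnorm = float(np.linalg.norm(g))
        if gnorm < grad_tol:
            break
        accepted = False
        while step > min_step:
            cand = coords - step * g
            e_new, g_new = energy(cand)
            if math.isfinite(e_new) and e_new < e:
                coords, e, g = cand, e_new, g_new
                trace.append(e)
                step *= 1.5
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    return coords, trace


@dataclass
class IterationState:
    """Mutable state of the iterative protocol plus its decision history."""

    restraints: list[DistanceRestraint]
    ensemble: CoordinateEnsemble | None = None
    iteration: int = 0
    weight: float = 1.0
    report: ViolationReport | None = None
    history: list[dict] = field(default_factory=list)

    @property
    def n_active(self) -> int:
        return sum(r.active for r in self.restraints)


def run_iteration(
    state: IterationState,
    schedule: ToleranceSchedule,
    spec: PotentialSpec,
    ff: ForceFieldParams | None = None,
    S_analyse: int = 15,
    threshold: float = 0.5,
) -> IterationState:
    """One analyse/reject/re-weight pass over the current ensemble.

    The ``S_analyse`` lowest-energy conformers (at most the ensemble size)
    are selected by total toy energy, restraint violations are analysed at
    the scheduled tolerance of ``state.iteration``, the consistently
    violated restraints are deactivated, and the restraint weight is
    re-estimated when ``spec.weight_mode == "auto"``.
    """
    if state.ensemble is None:
        raise ValueError("state has no ensemble to analyse")
    active = [r for r in state.restraints if r.active]
    if not active:
        raise RuntimeError("no active restraints")
    ens = state.ensemble
    energy = ToyEnergy(active, ens.atoms, replace(spec, k=state.weight), ff)
    conf_e = np.asarray([energy(ens.conformer(j))[0] for j in range(ens.n_conformers)])
    s_best = min(S_analyse, ens.n_conformers)
    best = np.argsort(conf_e, kind="stable")[:s_best]
    sub = CoordinateEnsemble(atoms=ens.atoms, coords=ens.coords[best])
    report = analyse_violations(active, sub, schedule, state.iteration, threshold=threshold)
    reject_violated(state.restraints, report)
    weight = state.weight
    if spec.weight_mode == "auto":
        still_active = [r for r in state.restraints if r.active]
        if still_active:
            fits = [effective_distance(r, sub) for r in still_active]
            weight = auto_weight(fits)
    state.report = report
    state.weight = weight
    state.history.append(
        {
            "iteration": state.iteration,
            "t_used": report.t_used,
            "D": report.D,
            "n_active": state.n_active,
            "n_violated": report.n_violated,
            "weight": weight,
            "energy_best_mean": float(np.mean(conf_e[best])),
        }
    )
    state.iteration += 1
    if state.n_active == 0:
        raise RuntimeError("no active restraints remain after rejection")
    return state


def _extended_chain(n_atoms: int, spacing: float = 3.8) -> np.ndarray:
    coords = np.zeros((n_atoms, 3))
    coords[:, 0] = spacing * np.arange(n_atoms)
    return coords


def run_protocol(
    fixture: LabelledFixture,
    schedule: ToleranceSchedule | None = None,
    spec: PotentialSpec | None = None,
    ff: ForceFieldParams | None = None,
    iterations: int = 9,
    conformers_per_iter: int = 20,
    S_analyse: int = 15,
    start_sigma: float = 2.0,
    max_steps: int = 800,
    threshold: float = 0.5,
) -> tuple[IterationState, dict]:
    """Run the full iterative protocol on a labelled fixture.

    Each iteration minimizes ``conformers_per_iter`` Gaussian-perturbed
    extended chains under the currently active restraints, then analyses and
    rejects violated restraints on the lowest-energy conformers.  Returns
    the final state and a summary with ensemble precision (mean RMSD of the
    conformers to their mean after superposition) and accuracy (RMSD of the
    mean structure to the fixture reference).
    """
    schedule = schedule or ToleranceSchedule.default_adaptive()
    spec = spec or PotentialSpec(kind="log_harmonic", k=1.0, weight_mode="auto")
    rng = np.random.default_rng(fixture.seed + 101)
    n_atoms = fixture.reference.shape[0]
    template = _extended_chain(n_atoms)
    state = IterationState(restraints=fixture.restraints)
    ensemble = None
    for it in range(iterations):
        active = [r for r in state.restraints if r.active]
        run_spec = replace(spec, k=state.weight)
        confs = []
        for _ in range(conformers_per_iter):
            start = template + rng.normal(scale=start_sigma, size=template.shape)
            final, _trace = minimize(start, active, run_spec, ff, max_steps=max_steps)
            confs.append(final)
        atoms = [(i + 1, "CA") for i in range(n_atoms)]
        ensemble = CoordinateEnsemble(atoms=atoms, coords=np.stack(confs))
        state.ensemble = ensemble
        state = run_iteration(
            state, schedule, spec, ff, S_analyse=S_analyse, threshold=threshold
        )
    assert ensemble is not None
    precision, mean_structure = ensemble_precision(ensemble.coords)
    accuracy = kabsch_rmsd(mean_structure, fixture.reference)
    labels = fixture.restraint_labels
    active_ids = {r.id for r in state.restraints if r.active}
    n_true = sum(1 for i, lab in labels.items() if lab == "true")
    n_noise = sum(1 for i, lab in labels.items() if lab == "noise")
    true_kept = sum(1 for i in active_ids if labels.get(i) == "true")
    noise_rejected = sum(
        1 for i, lab in labels.items() if lab == "noise" and i not in active_ids
    )
    summary = {
        "precision": precision,
        "accuracy": accuracy,
        "n_true": n_true,
        "n_noise": n_noise,
        "true_retention": true_kept / n_true if n_true else float("nan"),
        "noise_rejection_recall": noise_rejected / n_noise if n_noise else float("nan"),
        "n_active_final": len(active_ids),
    }
    return state, summary


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two conformations after least-squares superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(ac, bc)
    resid = ac - rot.apply(bc)
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def ensemble_precision(coords: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean RMSD of conformers to their superposed mean structure.

    Conformers are superposed onto the first one, averaged, and the mean of
    the per-conformer RMSDs to that average is returned along with the mean
    structure itself.
    """
    coords = np.asarray(coords, dtype=float)
    ref = coords[0] - coords[0].mean(axis=0)
    aligned = []
    for conf in coords:
        c = conf - conf.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref, c)
        aligned.append(rot.apply(c))
    aligned = np.stack(aligned)
    mean_structure = aligned.mean(axis=0)
    rmsds = [kabsch_rmsd(conf, mean_structure) for conf in aligned]
    return float(np.mean(rmsds)), mean_structure
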