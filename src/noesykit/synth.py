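"""Seeded generators for labelled toy inputs: reference chains, perturbed
ensembles, true/noise restraint sets and labelled NOESY peak lists.

Every generator is a pure function of its parameters and an integer seed; a
composite :class:`LabelledFixture` derives per-generator substreams from one
master seed by fixed offsets, so regeneration is bit-identical.

The peak-list generator emulates the three populations an automatically
picked ("unrefined") 3D NOESY list contains: *real* cross-peaks whose
intensities follow the r^-6 distance dependence, *weak* peaks whose
calibrated distance would be uninformative, and *solvent* artifacts piled up
on the water frequency in both proton dimensions, forming a high-density
line across the heteronuclear plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .peaks import Peak, PeakList
from .restraints import (
    Contribution,
    CoordinateEnsemble,
    DistanceRestraint,
    bounds_from_target,
)

__all__ = [
    "LabelledFixture",
    "make_reference",
    "make_ensemble",
    "make_restraints",
    "make_peaklist",
    "make_fixture",
]

# substream offsets from the master seed
_OFF_REFERENCE = 11
_OFF_ENSEMBLE = 23
_OFF_RESTRAINTS = 37
_OFF_PEAKS = 53


def make_reference(n_atoms: int, seed: int, step: float = 3.8, min_sep: float = 3.0) -> np.ndarray:
    """Self-avoiding 3D random walk standing in for a folded chain.

    Consecutive points are exactly ``step`` (3.8 A, the CA-CA virtual bond)
    apart; every non-consecutive pair is at least ``min_sep`` (3.0 A) apart.
    Directions are drawn uniformly on the sphere with rejection of
    self-clashing steps.
    """
    if n_atoms < 2:
        raise ValueError(f"need at least 2 atoms, got {n_atoms}")
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_atoms, 3))
    # mild persistence toward the previous direction keeps the walk compact
    # but escapable; pure uniform steps also work, just slower to accept.
    i = 1
    attempts = 0
    while i < n_atoms:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        cand = coords[i - 1] + step * v
        prior = coords[: max(i - 1, 0)]
        if prior.size == 0 or np.min(np.linalg.norm(prior - cand, axis=1)) >= min_sep:
            coords[i] = cand
            i += 1
            attempts = 0
        else:
            attempts += 1
            if attempts > 10_000:
                # back up one step to escape a dead end
                i = max(1, i - 1)
                attempts = 0
    return coords


def make_ensemble(
    reference: np.ndarray, S: int, sigma: float, seed: int
) -> CoordinateEnsemble:
    """``S`` conformers = reference + i.i.d. Gaussian noise (per coordinate SD
    ``sigma`` A)."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if S < 1:
        raise ValueError(f"need at least one conformer, got {S}")
    reference = np.asarray(reference, dtype=float)
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=sigma, size=(S, *reference.shape)) if sigma > 0 else 0.0
    coords = np.broadcast_to(reference, (S, *reference.shape)) + noise
    atoms = [(i + 1, "CA") for i in range(reference.shape[0])]
    return CoordinateEnsemble(atoms=atoms, coords=np.array(coords, dtype=float))


def make_restraints(
    reference: np.ndarray,
    cutoff: float = 5.5,
    noise_frac: float = 0.1,
    seed: int = 0,
    bounds_frac: float = 0.25,
) -> tuple[list[DistanceRestraint], dict[int, str]]:
    """Contact restraints from a reference chain plus planted noise restraints.

    True restraints: every pair ``|i-j| >= 2`` within ``cutoff`` A, target =
    the actual distance, symmetric fractional bounds.  Noise restraints:
    random non-contact pairs (actual distance beyond ``cutoff``) given a
    plausible-looking target uniform in [2.5, 5.0] A; their count is
    ``round(noise_frac/(1-noise_frac) * n_true)``.  Returns the restraint
    list and a mapping id -> "true"/"noise".
    """
    if not 0.0 <= noise_frac < 1.0:
        raise ValueError(f"noise_frac must be in [0, 1), got {noise_frac}")
    reference = np.asarray(reference, dtype=float)
    n = reference.shape[0]
    rng = np.random.default_rng(seed)
    restraints: list[DistanceRestraint] = []
    labels: dict[int, str] = {}
    rid = 1
    noncontact: list[tuple[int, int, float]] = []
    for i in range(n):
        for j in range(i + 2, n):
            d = float(np.linalg.norm(reference[i] - reference[j]))
            if d <= cutoff:
                lo, up = bounds_from_target(d, bounds_frac)
                restraints.append(
                    DistanceRestraint(
                        id=rid, d_target=d, lower=lo, upper=up,
                        contributions=[Contribution((i + 1, "CA"), (j + 1, "CA"))],
                    )
                )
                labels[rid] = "true"
                rid += 1
            else:
                noncontact.append((i, j, d))
    n_noise = round(noise_frac / (1.0 - noise_frac) * len(restraints))
    if n_noise > len(noncontact):
        raise ValueError("not enough non-contact pairs for the requested noise fraction")
    picks = rng.choice(len(noncontact), size=n_noise, replace=False)
    for p in sorted(picks):
        i, j, _ = noncontact[p]
        d_target = float(rng.uniform(2.5, 5.0))
        lo, up = bounds_from_target(d_target, bounds_frac)
        restraints.append(
            DistanceRestraint(
                id=rid, d_target=d_target, lower=lo, upper=up,
                contributions=[Contribution((i + 1, "CA"), (j + 1, "CA"))],
            )
        )
        labels[rid] = "noise"
        rid += 1
    return restraints, labels


# Shift ranges of the emulated 13C NOESY: aliphatic carbons and protons.
_HEAVY_RANGE = (10.0, 75.0)
_PROTON_RANGE = (0.0, 10.0)

#: Peak-list assignment tolerances used by the generator (ppm).  Coarser
#: than a real spectrometer's so that a desk-scale list (hundreds of peaks)
#: reproduces the per-cell occupancy a 13-19k-peak list has on the
#: conventional 2 x (0.2, 0.02) ppm grid; see the methods note.
FIXTURE_TOLERANCES: dict[str, float] = {"C": 1.0, "H": 0.25, "N": 1.0}


def make_peaklist(
    n_real: int = 600,
    n_weak: int = 60,
    n_solvent: int = 100,
    solvent_h_ppm: float = 4.7,
    seed: int = 0,
    weak_fraction: float = 0.9,
) -> tuple[PeakList, dict[int, str]]:
    """A labelled 3D NOESY peak list with real, weak and solvent populations.

    Real peaks are uniform over the aliphatic 13C/1H shift ranges with
    intensities ``I = A d^-6`` for d uniform in [2.2, 5.0] A, scaled so every
    real peak clears the weak-filter threshold implied by the planted weak
    peaks (when ``n_weak == 0`` the longest-distance real peak is stretched
    so it alone is classified weak, as the filter criterion forces).  Weak
    peaks share the real shift distribution but carry intensities strictly
    inside the weak regime.  Solvent peaks sit on the water frequency in
    both proton dimensions (NOE proton at ``solvent_h_ppm`` +- 0.01 ppm)
    with heavy shifts spread along a narrow band, forming one high-density
    column of the projected grid.  Returns the list and id -> label map.
    """
    if min(n_real, n_weak, n_solvent) < 0:
        raise ValueError("peak counts must be >= 0")
    if n_real == 0 and n_weak == 0 and n_solvent == 0:
        raise ValueError("at least one peak is required")
    rng = np.random.default_rng(seed)
    peaks: list[Peak] = []
    labels: dict[int, str] = {}
    pid = 1

    # distances behind the real intensities
    d_real = rng.uniform(2.2, 5.0, size=n_real)
    if n_weak == 0 and n_real > 1:
        # stretch the largest distance so only it falls in the weak regime
        # (d > weak_fraction * d_max for no other peak)
        order = np.argsort(d_real)
        second = d_real[order[-2]]
        d_real[order[-1]] = max(d_real[order[-1]], second / weak_fraction * 1.01)
    intensities_real = d_real ** -6.0

    # weak-regime floor: weak peaks define I_min of the list; real peaks are
    # scaled to clear the resulting threshold fraction**-6 * I_min.
    if n_weak > 0:
        i_floor = 1.0
        ratio = weak_fraction ** -6.0  # approx 1.88 for 0.9
        intensities_weak = i_floor * rng.uniform(1.0, 0.95 * ratio, size=n_weak)
        scale = 2.5 * ratio * i_floor / intensities_real.min() if n_real else 1.0
        intensities_real = intensities_real * scale
    else:
        intensities_weak = np.empty(0)

    for k in range(n_real):
        peaks.append(
            Peak(
                pid,
                float(rng.uniform(*_HEAVY_RANGE)),
                float(rng.uniform(*_PROTON_RANGE)),
                float(rng.uniform(*_PROTON_RANGE)),
                float(intensities_real[k]),
            )
        )
        labels[pid] = "real"
        pid += 1
    for k in range(n_weak):
        peaks.append(
            Peak(
                pid,
                float(rng.uniform(*_HEAVY_RANGE)),
                float(rng.uniform(*_PROTON_RANGE)),
                float(rng.uniform(*_PROTON_RANGE)),
                float(intensities_weak[k]),
            )
        )
        labels[pid] = "weak"
        pid += 1
    # solvent line: attached proton pinned to the water frequency (one
    # projected-grid column), heavy shifts in a narrow band so the column
    # cells carry extreme density.
    solvent_heavy_band = (30.0, 36.0)
    med = float(np.median(intensities_real)) if n_real else 1.0
    for _ in range(n_solvent):
        peaks.append(
            Peak(
                pid,
                float(rng.uniform(*solvent_heavy_band)),
                float(solvent_h_ppm + rng.uniform(-0.01, 0.01)),
                float(solvent_h_ppm + rng.uniform(-0.01, 0.01)),
                float(med * rng.uniform(0.5, 2.0)),
            )
        )
        labels[pid] = "solvent"
        pid += 1
    pl = PeakList(
        peaks=peaks,
        nucleus_types=("C", "H", "H"),
        tolerances=dict(FIXTURE_TOLERANCES),
        source=f"synthetic(seed={seed})",
    )
    return pl, labels


@dataclass
class LabelledFixture:
    """A complete labelled toy data set built from one master seed."""

    reference: np.ndarray
    ensemble: CoordinateEnsemble
    restraints: list[DistanceRestraint]
    restraint_labels: dict[int, str]
    peaklist: PeakList
    peak_labels: dict[int, str]
    seed: int
    params: dict = field(default_factory=dict)


def make_fixture(
    seed: int,
    n_atoms: int = 40,
    S: int = 15,
    sigma: float = 0.5,
    cutoff: float = 5.5,
    noise_frac: float = 0.1,
    n_real: int = 600,
    n_weak: int = 60,
    n_solvent: int = 100,
) -> LabelledFixture:
    """Build the composite fixture; substreams are fixed offsets of ``seed``."""
    reference = make_reference(n_atoms, seed + _OFF_REFERENCE)
    ensemble = make_ensemble(reference, S, sigma, seed + _OFF_ENSEMBLE)
    restraints, rlabels = make_restraints(
        reference, cutoff=cutoff, noise_frac=noise_frac, seed=seed + _OFF_RESTRAINTS
    )
    peaklist, plabels = make_peaklist(
        n_real=n_real, n_weak=n_weak, n_solvent=n_solvent, seed=seed + _OFF_PEAKS
    )
    return LabelledFixture(
        reference=reference,
        ensemble=ensemble,
        restraints=restraints,
        restraint_labels=rlabels,
        peaklist=peaklist,
        peak_labels=plabels,
        seed=seed,
        params={
            "n_atoms": n_atoms, "S": S, "sigma": sigma, "cutoff": cutoff,
            "noise_frac": noise_frac, "n_real": n_real, "n_weak": n_weak,
            "n_solvent": n_solvent,
        },
    )
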