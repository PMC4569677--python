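import numpy as np
import pytest

from noesykit.peaks import Peak, PeakList
from noesykit.restraints import Contribution, CoordinateEnsemble, DistanceRestraint


@pytest.fixture
def simple_peaklist() -> PeakList:
    """Four peaks with intensities {1.0, 1.5, 2.0, 100.0}."""
    peaks = [
        Peak(1, 120.5, 8.21, 1.05, 1.0),
        Peak(2, 55.0, 4.10, 2.00, 1.5),
        Peak(3, 30.2, 1.90, 3.10, 2.0),
        Peak(4, 42.0, 2.50, 0.80, 100.0),
    ]
    return PeakList(peaks=peaks, nucleus_types=("C", "H", "H"))


@pytest.fixture
def two_atom_restraint() -> DistanceRestraint:
    return DistanceRestraint(
        id=1,
        d_target=3.0,
        lower=2.25,
        upper=3.75,
        contributions=[Contribution((1, "CA"), (2, "CA"))],
    )


def ensemble_from_separations(seps) -> CoordinateEnsemble:
    """Two-atom ensemble with one conformer per requested separation."""
    coords = np.array([[[0.0, 0.0, 0.0], [s, 0.0, 0.0]] for s in seps])
    return CoordinateEnsemble(atoms=[(1, "CA"), (2, "CA")], coords=coords)


@pytest.fixture
def random_peaklist_factory():
    """Seeded factory for random peak lists used by oracle-equivalence tests."""

    def make(seed: int, n: int = 30) -> PeakList:
        rng = np.random.default_rng(seed)
        peaks = [
            Peak(
                i + 1,
                float(rng.uniform(10, 75)),
                float(rng.uniform(0, 10)),
                float(rng.uniform(0, 10)),
                float(rng.uniform(0.05, 50.0) * rng.choice([-1.0, 1.0])),
            )
            for i in range(n)
        ]
        tol = {"C": float(rng.uniform(0.5, 2.0)), "H": float(rng.uniform(0.1, 0.5)), "N": 1.0}
        return PeakList(peaks=peaks, nucleus_types=("C", "H", "H"), tolerances=tol)

    return make
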