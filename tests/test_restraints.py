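import numpy as np
import pytest

from noesykit.peaks import Peak, PeakList
from noesykit.restraints import (
    AtomLookupError,
    Contribution,
    CoordinateEnsemble,
    DistanceRestraint,
    bounds_from_target,
    calibrate_targets,
    effective_distance,
    per_structure_distance,
    read_pdb_ensemble,
    read_restraints,
    write_pdb_ensemble,
    write_restraints,
)
from .conftest import ensemble_from_separations


def naive_effective_distance(r, ens):
    """Independent double-loop oracle for the r^-6 ensemble average."""
    per = []
    for j in range(ens.n_conformers):
        total = 0.0
        for c in r.contributions:
            pa = ens.coords[j][ens.atom_index(c.atom_a)]
            pb = ens.coords[j][ens.atom_index(c.atom_b)]
            total += sum((x - y) ** 2 for x, y in zip(pa, pb)) ** -3
        per.append(total ** (-1 / 6))
    return sum(per) / len(per)


class TestPerStructureDistance:
    def test_single_contribution_equals_plain_distance(self, two_atom_restraint):
        ens = ensemble_from_separations([4.0])
        assert per_structure_distance(
            two_atom_restraint, ens.conformer(0), ens
        ) == pytest.approx(4.0)

    def test_two_contributions_r6_sum(self):
        # (3^-6 + 5^-6)^(-1/6) ~ 2.9773
        coords = np.array([[[0, 0, 0], [3, 0, 0], [0, 5, 0]]], dtype=float)
        ens = CoordinateEnsemble(
            atoms=[(1, "HA"), (2, "HA"), (3, "HA")], coords=coords
        )
        r = DistanceRestraint(
            id=1, d_target=3.0, lower=2.0, upper=4.0,
            contributions=[
                Contribution((1, "HA"), (2, "HA")),
                Contribution((1, "HA"), (3, "HA")),
            ],
        )
        expected = (3.0**-6 + 5.0**-6) ** (-1 / 6)
        got = per_structure_distance(r, ens.conformer(0), ens)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(2.9773, abs=1e-4)

    def test_k_identical_contributions_closed_form(self):
        # k copies at distance d give d * k^(-1/6)
        d, k = 4.0, 5
        atoms = [(i, "HA") for i in range(k + 1)]
        coords = np.zeros((1, k + 1, 3))
        for i in range(1, k + 1):
            coords[0, i] = [d, 0, 0]
        # place each partner at the same distance in different directions
        rng = np.random.default_rng(0)
        for i in range(1, k + 1):
            v = rng.normal(size=3)
            coords[0, i] = d * v / np.linalg.norm(v)
        ens = CoordinateEnsemble(atoms=atoms, coords=coords)
        r = DistanceRestraint(
            id=1, d_target=3.0, lower=2.0, upper=4.0,
            contributions=[Contribution((0, "HA"), (i, "HA")) for i in range(1, k + 1)],
        )
        assert per_structure_distance(r, ens.conformer(0), ens) == pytest.approx(
            d * k ** (-1 / 6), abs=1e-10
        )

    def test_bounded_by_shortest_contribution(self):
        coords = np.array([[[0, 0, 0], [3, 0, 0], [0, 7, 0]]], dtype=float)
        ens = CoordinateEnsemble(atoms=[(1, "H"), (2, "H"), (3, "H")], coords=coords)
        r = DistanceRestraint(
            id=1, d_target=3.0, lower=2.0, upper=4.0,
            contributions=[Contribution((1, "H"), (2, "H")), Contribution((1, "H"), (3, "H"))],
        )
        assert per_structure_distance(r, ens.conformer(0), ens) <= 3.0

    def test_missing_atom_names_atom_and_conformer(self, two_atom_restraint):
        ens = ensemble_from_separations([4.0])
        bad = DistanceRestraint(
            id=2, d_target=3.0, lower=2.0, upper=4.0,
            contributions=[Contribution((1, "CA"), (9, "CB"))],
        )
        with pytest.raises(AtomLookupError, match="CB"):
            per_structure_distance(bad, ens.conformer(0), ens, conformer_index=0)


class TestEffectiveDistance:
    def test_single_conformer_equals_per_structure(self, two_atom_restraint):
        ens = ensemble_from_separations([3.3])
        fit = effective_distance(two_atom_restraint, ens)
        assert fit.d_eff == pytest.approx(3.3)

    def test_arithmetic_mean_over_conformers(self, two_atom_restraint):
        ens = ensemble_from_separations([3.0, 5.0])
        assert effective_distance(two_atom_restraint, ens).d_eff == pytest.approx(4.0)

    def test_ec_is_mean_minus_target(self, two_atom_restraint):
        ens = ensemble_from_separations([2.0, 3.0, 4.0])
        fit = effective_distance(two_atom_restraint, ens)
        assert fit.d_eff == pytest.approx(3.0)
        assert fit.ec == pytest.approx(3.0 - two_atom_restraint.d_target)

    def test_invariant_under_conformer_reordering(self, two_atom_restraint):
        a = ensemble_from_separations([2.5, 3.5, 4.5])
        b = ensemble_from_separations([4.5, 2.5, 3.5])
        assert effective_distance(two_atom_restraint, a).d_eff == pytest.approx(
            effective_distance(two_atom_restraint, b).d_eff
        )

    def test_agrees_with_naive_double_loop_oracle(self):
        rng = np.random.default_rng(42)
        atoms = [(i, "HA") for i in range(8)]
        for _ in range(100):
            coords = rng.uniform(-10, 10, size=(4, 8, 3))
            ens = CoordinateEnsemble(atoms=atoms, coords=coords)
            n_contrib = rng.integers(1, 4)
            pairs = set()
            while len(pairs) < n_contrib:
                i, j = sorted(rng.choice(8, size=2, replace=False))
                pairs.add((int(i), int(j)))
            r = DistanceRestraint(
                id=1, d_target=3.0, lower=2.0, upper=4.0,
                contributions=[Contribution((i, "HA"), (j, "HA")) for i, j in pairs],
            )
            assert effective_distance(r, ens).d_eff == pytest.approx(
                naive_effective_distance(r, ens), abs=1e-10
            )


class TestCalibration:
    def test_single_peak_gets_reference_distance(self):
        pl = PeakList(peaks=[Peak(1, 50, 4, 2, 7.0)])
        assert calibrate_targets(pl) == {1: pytest.approx(3.0)}

    def test_two_peak_median_solved_by_hand(self):
        # |I|^(-1/6) = {1, 0.5}; median 0.75c = 3 => targets {4, 2}
        pl = PeakList(peaks=[Peak(1, 50, 4, 2, 1.0), Peak(2, 51, 5, 3, 64.0)])
        targets = calibrate_targets(pl, d_ref=3.0)
        assert targets[1] == pytest.approx(4.0)
        assert targets[2] == pytest.approx(2.0)

    def test_equal_intensities_all_at_reference(self):
        pl = PeakList(peaks=[Peak(i, 50, 4, 2, 5.5) for i in range(1, 5)])
        assert all(v == pytest.approx(3.0) for v in calibrate_targets(pl).values())

    def test_zero_intensity_rejected(self):
        pl = PeakList(peaks=[Peak(1, 50, 4, 2, 0.0)])
        with pytest.raises(ValueError, match="zero intensity"):
            calibrate_targets(pl)


class TestBounds:
    @pytest.mark.parametrize(
        "d, frac, expected",
        [(4.0, 0.25, (3.0, 5.0)), (3.0, 0.25, (2.25, 3.75)), (2.0, 0.0, (2.0, 2.0))],
    )
    def test_symmetric_fractional_bounds(self, d, frac, expected):
        lo, up = bounds_from_target(d, frac)
        assert (lo, up) == pytest.approx(expected)

    def test_fraction_at_least_one_rejected(self):
        with pytest.raises(ValueError):
            bounds_from_target(3.0, frac=1.0)


class TestRestraintIO:
    def _random_restraints(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(1, n + 1):
            d = float(rng.uniform(2.5, 5.5))
            lo, up = bounds_from_target(d, 0.25)
            n_c = int(rng.integers(1, 4))
            contribs = [
                Contribution((int(rng.integers(1, 40)), "HA"), (int(rng.integers(41, 80)), "HB"))
                for _ in range(n_c)
            ]
            out.append(
                DistanceRestraint(
                    id=i, d_target=d, lower=lo, upper=up, contributions=contribs,
                    active=bool(rng.integers(0, 2)), weight=float(rng.uniform(0, 2)),
                )
            )
        return out

    def test_tsv_round_trip_identity(self, tmp_path):
        rl = self._random_restraints()
        path = tmp_path / "r.tsv"
        write_restraints(rl, path, dialect="tsv")
        back = read_restraints(path)
        assert len(back) == len(rl)
        for a, b in zip(rl, back):
            assert (a.id, a.d_target, a.lower, a.upper, a.weight, a.active) == (
                b.id, b.d_target, b.lower, b.upper, b.weight, b.active
            )
            assert a.contributions == b.contributions

    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_restraints([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#id")

    def test_cns_assign_line_format(self, tmp_path, two_atom_restraint):
        path = tmp_path / "r.tbl"
        write_restraints([two_atom_restraint], path, dialect="cns_assign")
        line = path.read_text().splitlines()[0]
        assert line == (
            "assign (resid 1 and name CA)(resid 2 and name CA) 3.000 0.750 0.750"
        )

    def test_cns_assign_or_lines_for_ambiguity(self, tmp_path):
        r = DistanceRestraint(
            id=1, d_target=3.0, lower=2.25, upper=3.75,
            contributions=[
                Contribution((1, "HA"), (5, "HB")),
                Contribution((1, "HA"), (9, "HG")),
            ],
        )
        path = tmp_path / "amb.tbl"
        write_restraints([r], path, dialect="cns_assign")
        lines = path.read_text().splitlines()
        assert lines[1].strip().startswith("or (resid 1 and name HA)")


class TestPdbEnsembleIO:
    def test_multi_model_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        atoms = [(i + 1, "CA") for i in range(10)]
        coords = rng.uniform(-20, 20, size=(3, 10, 3)).round(3)
        ens = CoordinateEnsemble(atoms=atoms, coords=coords)
        path = tmp_path / "ens.pdb"
        write_pdb_ensemble(ens, path)
        back = read_pdb_ensemble(path)
        assert back.n_conformers == 3
        assert back.atoms == atoms
        np.testing.assert_allclose(back.coords, coords, atol=1e-3)
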