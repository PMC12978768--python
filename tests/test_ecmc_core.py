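"""Tests for ECMC construction, Boltzmann weights and submatrix matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ecga
from ecga import ECMC, ToleranceMatrix
from ecga.ecmc_core import R_KCAL

from conftest import make_simple_ensemble


def random_candidate(rng, n, elements=("C", "N", "O")):
    """Random symmetric candidate 'matrix of contiguity' with a C-H mask."""
    els = [str(rng.choice(elements)) for _ in range(n)]
    m = rng.uniform(-0.5, 6.0, (n, n))
    m = (m + m.T) / 2.0
    mask = np.zeros((n, n), dtype=bool)
    return ECMC(compound_id="rand", conformer_id="c1",
                atom_indices=list(range(1, n + 1)), elements=els,
                labels=[None] * n, matrix=m, mask=mask)


class TestBoltzmann:
    def test_two_equal_energies_split_evenly(self):
        assert np.allclose(ecga.boltzmann_weights([0.0, 0.0], T=500.0),
                           [0.5, 0.5])

    def test_single_conformer(self):
        assert ecga.boltzmann_weights([0.0]).tolist() == [1.0]

    def test_one_kcal_gap_at_room_temperature(self):
        w = ecga.boltzmann_weights([0.0, 1.0], T=298.15)
        expected = 1.0 / (1.0 + np.exp(-1.0 / (R_KCAL * 298.15)))
        assert w[0] == pytest.approx(expected, abs=1e-12)
        assert w[0] == pytest.approx(0.844, abs=5e-4)

    @given(st.lists(st.floats(min_value=0, max_value=20), min_size=1,
                    max_size=8),
           st.floats(min_value=-5, max_value=5))
    @settings(max_examples=50, derandomize=True)
    def test_shift_invariance_and_normalization(self, energies, shift):
        w = ecga.boltzmann_weights(energies)
        w_shift = ecga.boltzmann_weights([e + shift for e in energies])
        assert np.allclose(w, w_shift, atol=1e-12)
        assert abs(w.sum() - 1.0) < 1e-12
        order = np.argsort(energies)
        assert np.all(np.diff(w[order]) <= 1e-12)  # monotone in energy

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecga.boltzmann_weights([])


class TestFilterConformers:
    def test_energy_window(self):
        ens = make_simple_ensemble(energies=(0.0, 1.0, 2.0))
        kept = ecga.filter_conformers(ens, energy_window=1.5)
        assert kept.n_conformers == 2

    def test_cap_keeps_lowest(self):
        ens = make_simple_ensemble(energies=tuple(np.linspace(0, 1.4, 120)))
        kept = ecga.filter_conformers(ens, energy_window=1.5, max_conformers=100)
        assert kept.n_conformers == 100
        assert kept.rel_energies().max() < 1.2

    def test_imaginary_frequency_removed_before_windowing(self):
        ens = make_simple_ensemble(energies=(0.0, 0.2))
        ens.conformers[0].has_imaginary_freq = True
        kept = ecga.filter_conformers(ens)
        assert [c.conformer_id for c in kept.conformers] == ["conf2"]
        assert kept.rel_energies().tolist() == [0.0]  # re-referenced

    def test_empty_result_errors(self):
        ens = make_simple_ensemble(energies=(0.0,))
        ens.conformers[0].has_imaginary_freq = True
        with pytest.raises(ValueError, match="no conformers survive"):
            ecga.filter_conformers(ens)


class TestBuildECMC:
    def test_single_atom_matrix_is_charge(self):
        ens = make_simple_ensemble(energies=(0.0,), charges=(-0.136,))
        mat = ecga.build_ecmc(ens, "conf1")
        assert mat.matrix.tolist() == [[-0.136]]

    def test_nonbonded_distance_345_triangle(self):
        ens = make_simple_ensemble(energies=(0.0,))
        ens.conformers[0].coords = np.array(
            [[0.0, 0.0, 0.0], [3.0, 4.0, 0.0], [0.0, 1.1, 0.0]])
        mat = ecga.build_ecmc(ens, "conf1")
        assert mat.matrix[0, 1] == pytest.approx(5.0)

    def test_ch_bond_masked(self):
        ens = make_simple_ensemble()  # bond (1,3) is C-H
        mat = ecga.build_ecmc(ens, "conf1")
        assert mat.mask[0, 2] and mat.mask[2, 0]
        assert not mat.mask[0, 1]
        off = ecga.build_ecmc(ens, "conf1", mask_ch=False)
        assert not off.mask.any()

    def test_symmetry_and_rotation_invariance(self):
        rng = np.random.default_rng(7)
        ens = make_simple_ensemble(energies=(0.0,))
        base = ecga.build_ecmc(ens, "conf1")
        assert np.allclose(base.matrix, base.matrix.T)
        for _ in range(5):
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r))
            ens.conformers[0].coords = ens.conformers[0].coords @ q.T + rng.normal(size=3)
            rotated = ecga.build_ecmc(ens, "conf1")
            assert np.allclose(rotated.matrix, base.matrix, atol=1e-9)

    def test_missing_charges_named(self):
        ens = make_simple_ensemble(energies=(0.0,))
        ens.conformers[0].atomic_charge = None
        with pytest.raises(ValueError, match="charges absent"):
            ecga.build_ecmc(ens, "conf1")


class TestMatching:
    def test_self_match_of_reference_fixture(self):
        """The packaged reference submatrix matches itself under its own
        high-activity tolerances with zero deviation everywhere."""
        labels, values = ecga.load_fixture("table2a")
        _, tol = ecga.load_fixture("table2b")
        cand = ECMC(compound_id="ref", conformer_id="c1",
                    atom_indices=list(range(1, 7)),
                    elements=[lbl[0] for lbl in labels], labels=labels,
                    matrix=values, mask=np.zeros((6, 6), dtype=bool))
        result = ecga.match_submatrix(values, tol, cand,
                                      reference_elements=cand.elements)
        assert result.matched
        assert result.max_abs_deviation == 0.0

    def test_boundary_inclusive_and_double_violation(self):
        rng = np.random.default_rng(0)
        cand = random_candidate(rng, 4)
        # Dyadic values keep the +tolerance boundary float-exact.
        cand.matrix[1, 2] = cand.matrix[2, 1] = 1.0
        ref = cand.matrix.copy()
        tol = ToleranceMatrix.uniform(4, 0.125, 0.125)
        bumped = cand.matrix.copy()
        bumped[1, 2] = bumped[2, 1] = 1.125  # exactly +tolerance
        cand_eq = ECMC(**{**cand.__dict__, "matrix": bumped})
        assert ecga.match_submatrix(ref, tol, cand_eq,
                                    fixed_assignment={i: i for i in range(4)}
                                    ).matched
        bumped2 = cand.matrix.copy()
        bumped2[1, 2] = bumped2[2, 1] = 1.25  # 2x tolerance
        cand_bad = ECMC(**{**cand.__dict__, "matrix": bumped2})
        result = ecga.match_submatrix(ref, tol, cand_bad,
                                      fixed_assignment={i: i for i in range(4)})
        assert not result.matched
        assert any(e[:2] == (1, 2) for e in result.failing_elements)

    def test_zero_tolerance_matches_only_exact_copies(self):
        rng = np.random.default_rng(1)
        cand = random_candidate(rng, 5)
        sub = cand.submatrix([0, 2, 4])
        tol = ToleranceMatrix(np.zeros((3, 3)))
        assert ecga.match_submatrix(sub.matrix, tol, cand,
                                    reference_elements=sub.elements).matched
        perturbed = sub.matrix.copy()
        perturbed[0, 1] = perturbed[1, 0] = perturbed[0, 1] + 1e-6
        assert not ecga.match_submatrix(perturbed, tol, cand,
                                        reference_elements=sub.elements).matched

    def test_tolerance_monotonicity(self):
        """Enlarging any tolerance never turns a match into a non-match."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            cand = random_candidate(rng, 6)
            k = 3
            pos = rng.choice(6, size=k, replace=False).tolist()
            ref = cand.submatrix(pos).matrix + rng.normal(0, 0.5, (k, k))
            ref = (ref + ref.T) / 2.0
            base = rng.uniform(0.0, 1.0, (k, k))
            base = (base + base.T) / 2.0
            small = ecga.match_submatrix(ref, ToleranceMatrix(base), cand)
            large = ecga.match_submatrix(ref, ToleranceMatrix(base + 0.5), cand)
            if small.matched:
                assert large.matched

    def test_no_compatible_elements_unmatched(self):
        rng = np.random.default_rng(3)
        cand = random_candidate(rng, 4, elements=("C",))
        ref = cand.submatrix([0, 1]).matrix
        result = ecga.match_submatrix(ref, ToleranceMatrix.uniform(2, 10, 10),
                                      cand, reference_elements=["N", "N"])
        assert not result.matched

    def test_brute_force_guard(self):
        rng = np.random.default_rng(4)
        cand = random_candidate(rng, 11)
        ref = cand.submatrix([0, 1]).matrix
        with pytest.raises(ValueError, match="guard"):
            ecga.brute_force_match(ref, ToleranceMatrix.uniform(2, 1, 1), cand)

    def test_backtracking_agrees_with_brute_force(self):
        """Seeded equivalence of the search and the exhaustive oracle on
        random <= 8-atom instances, including the chosen assignment."""
        rng = np.random.default_rng(5)
        matched = 0
        for _ in range(200):
            n = int(rng.integers(3, 9))
            k = int(rng.integers(2, min(n, 5) + 1))
            cand = random_candidate(rng, n)
            pos = rng.choice(n, size=k, replace=False).tolist()
            ref = cand.submatrix(pos).matrix + rng.normal(0, 0.3, (k, k))
            ref = (ref + ref.T) / 2.0
            elements = [cand.elements[p] for p in pos]
            tol = ToleranceMatrix.uniform(k, float(rng.uniform(0, 0.6)),
                                          float(rng.uniform(0, 0.6)))
            fast = ecga.match_submatrix(ref, tol, cand,
                                        reference_elements=elements)
            slow = ecga.brute_force_match(ref, tol, cand,
                                          reference_elements=elements)
            assert fast.matched == slow.matched
            if fast.matched:
                matched += 1
                assert fast.assignment == slow.assignment
        assert 20 < matched < 200  # both verdicts exercised
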