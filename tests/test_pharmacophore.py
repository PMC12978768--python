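"""Tests for ECSA discovery, screening, tolerances and quality statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ecga
from ecga import QualityStats
from ecga.pharmacophore import DegenerateMarginalError, \
    NoDiscriminatingSubmatrixError

from conftest import table2_scenario


class TestQualityStats:
    def test_perfect_separation_counts(self):
        qs = QualityStats(h1=28, h2=0, h3=0, h4=26)
        assert qs.p_a == pytest.approx(29 / 30)
        assert qs.alpha_a == pytest.approx(1.0)

    def test_mixed_table_arithmetic(self):
        qs = QualityStats(h1=25, h2=3, h3=5, h4=21)
        assert qs.p_a == pytest.approx(26 / 30)
        assert qs.alpha_a == pytest.approx(
            510 / np.sqrt(28 * 26 * 30 * 24), abs=1e-12)
        assert qs.alpha_a == pytest.approx(0.704, abs=5e-4)

    def test_independence_gives_zero(self):
        qs = QualityStats(h1=4, h2=2, h3=6, h4=3)  # h1*h4 == h2*h3
        assert qs.alpha_a == 0.0

    def test_degenerate_marginal_raises(self):
        with pytest.raises(DegenerateMarginalError):
            QualityStats(h1=0, h2=0, h3=3, h4=3).alpha_a

    @given(st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=200, derandomize=True)
    def test_alpha_is_bounded_phi(self, h1, h2, h3, h4):
        qs = QualityStats(h1=h1, h2=h2, h3=h3, h4=h4)
        try:
            alpha = qs.alpha_a
        except DegenerateMarginalError:
            return
        assert -1.0 - 1e-12 <= alpha <= 1.0 + 1e-12

    @given(st.integers(0, 20), st.integers(0, 20))
    @settings(max_examples=100, derandomize=True)
    def test_p_a_monotone(self, h1, h2):
        qs = QualityStats(h1=h1, h2=h2, h3=1, h4=1)
        up = QualityStats(h1=h1 + 1, h2=h2, h3=1, h4=1)
        down = QualityStats(h1=h1, h2=h2 + 1, h3=1, h4=1)
        assert up.p_a > qs.p_a > down.p_a


class TestScreenAndTolerances:
    def test_reference_matches_itself(self, planted_set):
        _, ensembles, activities = planted_set
        ecsa = ecga.find_ecsa(ensembles, activities, "act01", size_range=(3, 3))
        table = ecga.screen(ecsa, [ensembles[0]])
        ref_row = table.frame[
            table.frame["conformer_id"] == ecsa.reference_conformer_id]
        assert (ref_row["delta"] == 1).all()

    def test_compound_presence_is_or_over_conformers(self, planted_set):
        _, ensembles, activities = planted_set
        ecsa = ecga.find_ecsa(ensembles, activities, "act01", size_range=(3, 3))
        table = ecga.screen(ecsa, ensembles)
        presence = table.compound_presence()
        for cid, cls in activities.classes().items():
            assert presence[cid] == (1 if cls == "high" else 0)
        # actives match in every conformer; inactives in none
        grouped = table.frame.groupby("compound_id")["delta"]
        assert (grouped.min()[lambda s: s.index.str.startswith("act")] == 1).all()

    def test_derived_tolerances_from_reference_only_are_zero(self, planted_set):
        _, ensembles, activities = planted_set
        ecsa = ecga.find_ecsa(ensembles, activities, "act01", size_range=(3, 3))
        ref = ensembles[0]
        tol = ecga.derive_tolerances(ecsa, [(ref, ecsa.reference_conformer_id)])
        assert np.all(tol.values == 0.0)

    def test_derived_tolerances_are_maxima_and_monotone(self, planted_set):
        _, ensembles, activities = planted_set
        ecsa = ecga.find_ecsa(ensembles, activities, "act01", size_range=(3, 3))
        actives = [e for e in ensembles if e.compound_id.startswith("act")]
        subset = [(e, c.conformer_id) for e in actives for c in e.conformers]
        running = np.zeros_like(ecsa.reference_values)
        for upto in range(1, len(subset) + 1):
            tol = ecga.derive_tolerances(ecsa, subset[:upto])
            assert np.all(tol.values >= running - 1e-15)  # never decreases
            running = tol.values
        batch = ecga.derive_tolerances(ecsa, subset)
        assert np.allclose(batch.values, running)

    def test_derived_tolerances_readmit_their_subset(self, planted_set):
        """Self-consistency: screening the derivation subset under the
        derived tolerances flags every conformer as a match."""
        _, ensembles, activities = planted_set
        ecsa = ecga.find_ecsa(ensembles, activities, "act01", size_range=(3, 3))
        actives = [e for e in ensembles if e.compound_id.startswith("act")]
        subset = [(e, c.conformer_id) for e in actives for c in e.conformers]
        tol = ecga.derive_tolerances(ecsa, subset)
        rescreen = ecga.screen(ecsa, actives, tolerances=tol)
        assert (rescreen.frame["delta"] == 1).all()

    def test_unmatched_conformer_in_subset_errors(self, planted_set):
        _, ensembles, activities = planted_set
        ecsa = ecga.find_ecsa(ensembles, activities, "act01", size_range=(3, 3))
        inactive = next(e for e in ensembles
                        if e.compound_id.startswith("inact"))
        with pytest.raises(ValueError, match="does not match"):
            ecga.derive_tolerances(
                ecsa, [(inactive, inactive.conformers[0].conformer_id)])


class TestFindECSA:
    def test_recovers_planted_atoms_with_perfect_alpha(self, planted_set):
        _, ensembles, activities = planted_set
        ecsa = ecga.find_ecsa(ensembles, activities, "act01", size_range=(3, 4))
        assert ecsa.atom_labels == ["C1", "N1", "O1"]
        presence = ecga.screen(ecsa, ensembles).compound_presence()
        assert ecga.quality_stats(presence,
                                  activities.classes()).alpha_a == 1.0

    def test_identical_compounds_have_no_discriminator(self, planted_set):
        spec, _, _ = planted_set
        ensembles, activities = ecga.gen_pharmacophore_set(
            ecga.SyntheticSpec(seed=9, n_active=3, n_inactive=3,
                               pharmacophore_size=3, max_atoms=9))
        # Make every compound an exact copy of the first active.
        clones = []
        for ens in ensembles:
            clone = ecga.ConformerEnsemble(
                compound_id=ens.compound_id, atoms=ensembles[0].atoms,
                bonds=ensembles[0].bonds, conformers=ensembles[0].conformers)
            clones.append(clone)
        with pytest.raises(NoDiscriminatingSubmatrixError):
            ecga.find_ecsa(clones, activities, "act01", size_range=(3, 3))

    def test_reference_must_be_high_activity(self, planted_set):
        _, ensembles, activities = planted_set
        with pytest.raises(ValueError, match="not a high-activity"):
            ecga.find_ecsa(ensembles, activities, "inact01")

    def test_reference_table_scenario_recovers_six_skeleton_atoms(self):
        """A compound set embedding the packaged 6-atom reference submatrix
        (within the high-activity tolerances) yields an ECSA over exactly
        the atoms C1, C7, C9, H9, N1, N2."""
        ensembles, activities, labels = table2_scenario(seed=0)
        ecsa = ecga.find_ecsa(ensembles, activities, "act01",
                              init_tol=(0.12, 0.10), size_range=(3, 6))
        assert sorted(ecsa.atom_labels) == sorted(labels)
        assert sorted(ecsa.atom_labels) == ["C1", "C7", "C9", "H9", "N1", "N2"]
        presence = ecga.screen(ecsa, ensembles).compound_presence()
        assert ecga.quality_stats(presence,
                                  activities.classes()).alpha_a == 1.0

    def test_class_tolerances_nest_inside_screening_tolerances(self):
        ensembles, activities, _ = table2_scenario(seed=1)
        ecsa = ecga.find_ecsa(ensembles, activities, "act01",
                              init_tol=(0.12, 0.10), size_range=(3, 6))
        groups = ecga.class_tolerances(ecsa, ensembles, activities)
        assert set(groups) == {"high", "all"}  # no inactive ever matches
        assert np.all(groups["high"].values <= 0.10 + 1e-12)
        assert np.allclose(groups["all"].values, groups["high"].values)
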