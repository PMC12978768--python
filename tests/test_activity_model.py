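"""Tests for the Boltzmann-weighted activity model and kappa fitting."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import ecga
from ecga import ActivityDataset, CompoundData, KappaModel


class TestShielding:
    def test_zero_kappa_gives_zero(self):
        a = np.arange(6, dtype=float)
        assert ecga.shielding(a, np.zeros(2), [1, 4]) == 0.0

    def test_hand_arithmetic(self):
        s = ecga.shielding(np.array([0.5, 0.1]), np.array([1.0, -2.0]), [1, 2])
        assert s == pytest.approx(0.3)

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=8)
        kappa = rng.normal(size=3)
        idx = [2, 5, 7]
        assert ecga.shielding(2 * a, kappa, idx) == pytest.approx(
            2 * ecga.shielding(a, kappa, idx))

    def test_missing_descriptor_rejected(self):
        with pytest.raises(ValueError, match="1..3"):
            ecga.shielding(np.zeros(3), np.zeros(1), [4])


class TestPredictOne:
    def test_all_match_zero_shielding_returns_a0(self):
        """Every conformer carries the pharmacophore with S=0: the
        Boltzmann ratio collapses and the prediction equals the reference
        activity exactly (the reference compound's own 9.301)."""
        e = np.array([0.0, 0.3, 0.7])
        a = ecga.predict_one(np.ones(3), e, np.zeros(3), a0=9.301)
        assert a == pytest.approx(9.301, abs=1e-12)

    def test_no_matching_conformer_predicts_zero(self):
        a = ecga.predict_one(np.zeros(2), np.array([0.0, 0.5]), np.zeros(2),
                             a0=9.0)
        assert a == 0.0

    def test_half_weight_single_match(self):
        a = ecga.predict_one(np.array([1.0, 0.0]), np.zeros(2), np.zeros(2),
                             a0=8.0)
        assert a == pytest.approx(4.0)

    def test_energy_shift_invariance_and_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = int(rng.integers(1, 6))
            delta = (rng.random(m) < 0.7).astype(float)
            e = rng.uniform(0, 3, m)
            s = rng.uniform(0, 2, m)  # non-negative shielding
            a = ecga.predict_one(delta, e, s, a0=9.0)
            shifted = ecga.predict_one(delta, e + 5.0, s, a0=9.0)
            assert a == pytest.approx(shifted, rel=1e-12)
            assert 0.0 <= a <= 9.0 + 1e-12

    def test_high_energy_nonmatching_conformer_is_negligible(self):
        delta = np.array([1.0, 0.0])
        base = ecga.predict_one(np.array([1.0]), np.array([0.0]),
                                np.array([0.0]), a0=9.0)
        extended = ecga.predict_one(delta, np.array([0.0, 25.0]),
                                    np.zeros(2), a0=9.0)
        assert extended == pytest.approx(base, abs=1e-9)


class TestFitKappa:
    def test_noiseless_recovery(self, activity_data):
        spec, dataset, kappa_true = activity_data
        sig = spec.resolved_signal_indices()
        model = ecga.fit_kappa(dataset, list(sig))
        expected = kappa_true[[i - 1 for i in sig]]
        assert np.abs(model.kappa - expected).max() <= 1e-3

    def test_never_worse_than_zero_init(self, activity_data):
        _, dataset, _ = activity_data
        model = ecga.fit_kappa(dataset, [1, 2])
        zero = KappaModel(a0=dataset.a0, temperature=dataset.temperature,
                          descriptor_indices=[1, 2], kappa=np.zeros(2))
        obj_fit = sum((c.a_exp - model.predict(c)) ** 2
                      for c in dataset.training())
        obj_zero = sum((c.a_exp - zero.predict(c)) ** 2
                       for c in dataset.training())
        assert obj_fit <= obj_zero + 1e-12

    def test_single_descriptor_matches_scalar_oracle(self):
        """One compound, one conformer, one descriptor: the fit agrees with
        a direct scalar minimization of the same objective."""
        compound = CompoundData(compound_id="c1", a_exp=5.0,
                                rel_energies=[0.0], delta=[1.0],
                                descriptors=[[0.7]])
        dataset = ActivityDataset(compounds=[compound],
                                  descriptor_names=["d1"], a0=9.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ecga.fit_kappa(dataset, [1])
        oracle = minimize_scalar(
            lambda k: (5.0 - 9.0 * np.exp(-k * 0.7)) ** 2,
            bounds=(-10, 10), method="bounded")
        assert model.kappa[0] == pytest.approx(oracle.x, abs=1e-5)

    def test_all_unmatched_errors(self, activity_data):
        _, dataset, _ = activity_data
        broken = dataset.subset([
            CompoundData(c.compound_id, c.a_exp, c.rel_energies,
                         np.zeros_like(c.delta), c.descriptors)
            for c in dataset.compounds])
        with pytest.raises(ValueError, match="lacks a matching conformer"):
            ecga.fit_kappa(broken, [1])


class TestLOO:
    def test_noiseless_press_is_zero(self, activity_data):
        spec, dataset, _ = activity_data
        table = ecga.loo_predictions(dataset,
                                     list(spec.resolved_signal_indices()))
        assert ecga.press(table["a_exp"], table["a_calc"]) <= 1e-6
        assert ecga.q2_loo(table["a_exp"], table["a_calc"]) >= 1.0 - 1e-6

    def test_equals_naive_refits(self):
        spec = ecga.SyntheticSpec(seed=8, n_active=3, n_inactive=3,
                                  noise_sd=0.05, p_descriptors=3,
                                  n_conformers=3)
        ens, mt, panel, acts, _ = ecga.gen_activity_data(spec)
        dataset = ActivityDataset.assemble(ens, mt, panel, acts, a0=spec.a0)
        table = ecga.loo_predictions(dataset, [1, 2])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for held in range(dataset.n):
                rest = [c for i, c in enumerate(dataset.compounds) if i != held]
                model = ecga.fit_kappa(dataset.subset(rest), [1, 2])
                naive = model.predict(dataset.compounds[held])
                assert table["a_calc"].iloc[held] == pytest.approx(naive,
                                                                   rel=1e-9)

    def test_too_few_compounds_rejected(self, activity_data):
        _, dataset, _ = activity_data
        tiny = dataset.subset(dataset.compounds[:2])
        with pytest.raises(ValueError, match="at least 3"):
            ecga.loo_predictions(tiny, [1])


@pytest.fixture(scope="module")
def planted_signal():
    spec = ecga.SyntheticSpec(seed=21, n_active=10, n_inactive=10,
                              noise_sd=0.05, p_descriptors=3,
                              signal_indices=(1,), n_conformers=3)
    ens, mt, panel, acts, _ = ecga.gen_activity_data(spec)
    dataset = ActivityDataset.assemble(ens, mt, panel, acts, a0=spec.a0)
    model = ecga.fit_kappa(dataset, [1, 2, 3])
    return ecga.e_statistics(dataset, model)


class TestEStatistics:
    def test_noise_descriptor_has_unit_e(self, planted_signal):
        noise_e = planted_signal.set_index("descriptor_index").loc[[2, 3], "E"]
        assert ((noise_e >= 0.8) & (noise_e <= 1.2)).all()

    def test_signal_descriptor_is_most_influential(self, planted_signal):
        table = planted_signal.set_index("descriptor_index")
        assert table.loc[1, "E"] < table.loc[[2, 3], "E"].min()

    def test_reference_table_ranking(self):
        """In the packaged per-descriptor E table the minimum (0.624) sits
        at parameter 121, the H9-N1-N2 angle."""
        table = ecga.load_fixture("table4_E")
        best = table.loc[table["E"].idxmin()]
        assert int(best["parameter_number"]) == 121
        assert best["E"] == pytest.approx(0.624)

    def test_needs_two_descriptors(self, activity_data):
        _, dataset, _ = activity_data
        model = ecga.fit_kappa(dataset, [1])
        with pytest.raises(ValueError, match="at least 2"):
            ecga.e_statistics(dataset, model)
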