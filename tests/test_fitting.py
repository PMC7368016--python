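import numpy as np
import pytest
from scipy import optimize, stats

from chemobarcode import (
    Catalog,
    MutationRecord,
    SignatureModel,
    bootstrap_ci,
    fit_exposures,
    nonsyn_chemo_fraction,
    strand_bias_test,
)
from chemobarcode.catalogs import CHANNELS_96
from chemobarcode.fitting import strand_bias_for_signature
from tests.conftest import mixture_catalog


def slsqp_oracle(counts: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Brute-force constrained multinomial ML on the simplex."""
    J = P.shape[1]

    def nll(w):
        r = np.maximum(P @ w, 1e-300)
        return -(counts @ np.log(r))

    res = optimize.minimize(
        nll,
        np.full(J, 1.0 / J),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * J,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    return res.x


class TestFitExposures:
    def test_pure_signature_dominates(self, reference):
        rng = np.random.default_rng(0)
        cat = mixture_catalog(reference, {"SBS2": 1.0}, 10_000, rng)
        fit = fit_exposures(cat, reference)
        assert fit.proportion("SBS2") >= 0.98
        assert fit.retained == ("SBS2",)

    def test_noiseless_two_signature_mixture(self, reference):
        cat = mixture_catalog(reference, {"SBS2": 0.6, "SBS35": 0.4}, 10_000)
        fit = fit_exposures(cat, reference)
        assert abs(fit.proportion("SBS2") - 0.6) < 0.01
        assert abs(fit.proportion("SBS35") - 0.4) < 0.01
        # independent constrained-optimisation oracle agrees
        oracle = slsqp_oracle(np.asarray(cat.counts, float), reference.matrix)
        full = SignatureModel(cat, reference).fit(elimination_threshold=None)
        np.testing.assert_allclose(full.proportions, oracle, atol=1e-3)

    def test_proportions_sum_to_one(self, reference):
        rng = np.random.default_rng(1)
        cat = mixture_catalog(
            reference, {"SBS1": 0.3, "SBS5": 0.4, "SBS9": 0.3}, 3000, rng
        )
        fit = fit_exposures(cat, reference)
        assert abs(fit.proportions.sum() - 1.0) < 1e-6
        np.testing.assert_allclose(fit.counts, fit.proportions * 3000)

    def test_empty_catalog_rejected(self, reference):
        with pytest.raises(ValueError, match="empty"):
            fit_exposures(Catalog(CHANNELS_96, np.zeros(96)), reference)

    def test_absent_signature_elimination_is_consistent(self, reference):
        """Dropping a truly absent signature changes the reconstruction
        cosine by less than the elimination threshold."""
        from chemobarcode.fitting import _cosine

        rng = np.random.default_rng(2)
        cat = mixture_catalog(reference, {"SBS1": 0.5, "SBS35": 0.5}, 5000, rng)
        freq = np.asarray(cat.counts, float) / cat.n_total
        full = SignatureModel(cat, reference).fit(elimination_threshold=None)
        cos_full = _cosine(reference.matrix @ full.proportions, freq)
        reduced_ref = reference.subset(["SBS1", "SBS35"])
        reduced = SignatureModel(cat, reduced_ref).fit(elimination_threshold=None)
        cos_red = _cosine(reduced_ref.matrix @ reduced.proportions, freq)
        assert cos_full - cos_red < 0.01


class TestBootstrap:
    def test_pure_signature_narrow_ci(self, reference):
        rng = np.random.default_rng(3)
        cat = mixture_catalog(reference, {"SBS13": 1.0}, 10_000, rng)
        fit = bootstrap_ci(cat, reference, n_boot=1000, seed=4)
        j = fit.signatures.index("SBS13")
        assert fit.ci_high[j] - fit.ci_low[j] < 0.02
        assert fit.ci_low[j] <= fit.proportion("SBS13") <= fit.ci_high[j]

    def test_seeded_bootstrap_reproducible(self, reference):
        rng = np.random.default_rng(5)
        cat = mixture_catalog(reference, {"SBS1": 0.5, "SBS2": 0.5}, 2000, rng)
        a = bootstrap_ci(cat, reference, n_boot=200, seed=9)
        b = bootstrap_ci(cat, reference, n_boot=200, seed=9)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)
        np.testing.assert_array_equal(a.ci_high, b.ci_high)

    def test_single_draw_rejected(self, reference):
        rng = np.random.default_rng(6)
        cat = mixture_catalog(reference, {"SBS1": 1.0}, 100, rng)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ci(cat, reference, n_boot=1)


class TestStrandBias:
    def test_balanced_counts_not_significant(self):
        res = strand_bias_test(50, 50)
        assert res.ratio == 1.0
        assert res.p_value > 0.99
        assert not res.significant

    def test_strong_bias_significant(self):
        res = strand_bias_test(150, 50)
        # closed-form two-sided exact binomial tail
        expected = 2 * stats.binom.sf(149, 200, 0.5)
        assert res.p_value == pytest.approx(expected, rel=1e-9)
        assert res.p_value < 0.001
        assert res.significant

    def test_underpowered_counts(self):
        res = strand_bias_test(3, 1)
        assert res.p_value == pytest.approx(0.625)
        assert not res.significant

    def test_no_stranded_mutations_rejected(self):
        with pytest.raises(ValueError):
            strand_bias_test(0, 0)

    def test_signature_attribution_recovers_planted_bias(self, reference):
        from chemobarcode import simulate_patient
        from chemobarcode.catalogs import build_catalog
        from tests.test_simulate import single_cluster_config

        cfg = single_cluster_config(
            n=4000, signature="SBS-MM1", intergenic_fraction=0.3,
            strand_bias_ratio=2.0, rng_seed=8,
        )
        muts, _ = simulate_patient(cfg, reference)
        fit = fit_exposures(build_catalog(muts), reference)
        res = strand_bias_for_signature(muts, fit, "SBS-MM1")
        assert res.significant
        assert res.ratio > 1.5


class TestNonsynChemoFraction:
    def _patient_catalogs(self, reference, chemo_weight, n_patients=10, n=400, seed=0):
        rng = np.random.default_rng(seed)
        base = {"SBS1": 0.3, "SBS5": 0.4, "SBS2": 0.3}
        cats = []
        for _ in range(n_patients):
            weights = {k: v * (1 - chemo_weight) for k, v in base.items()}
            if chemo_weight > 0:
                weights["SBS-MM1"] = 0.6 * chemo_weight
                weights["SBS35"] = 0.4 * chemo_weight
            cats.append(mixture_catalog(reference, weights, n, rng))
        return cats

    def test_planted_quarter_recovered(self, reference):
        cats = self._patient_catalogs(reference, 0.25, seed=10)
        est, (lo, hi), table = nonsyn_chemo_fraction(cats, reference, seed=11)
        assert abs(est - 0.25) < 0.03
        assert lo <= est <= hi
        assert len(table) == 10

    def test_zero_planted_near_zero(self, reference):
        cats = self._patient_catalogs(reference, 0.0, seed=12)
        est, (lo, hi), _ = nonsyn_chemo_fraction(cats, reference, seed=13)
        assert est < 0.02
        assert lo < 1e-3  # CI reaches zero up to EM boundary resolution

    def test_all_chemo_near_one(self, reference):
        cats = self._patient_catalogs(reference, 1.0, seed=14)
        est, _, _ = nonsyn_chemo_fraction(cats, reference, seed=15)
        assert est >= 0.97

    def test_empty_input_rejected(self, reference):
        with pytest.raises(ValueError, match="catalog"):
            nonsyn_chemo_fraction([], reference)
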