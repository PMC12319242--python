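"""Generator: Hardy-Weinberg sampling, LD, clearance model, TDM controller."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tacfis.io import pk_frame
from tacfis.screen import dosage_vector, hwe_test
from tacfis.synthetic import (
    EffectSpec,
    GeneratorConfig,
    LocusSpec,
    sample_genotypes,
    simulate_clearance,
    simulate_cohort,
    simulate_outcomes,
    simulate_tdm_course,
    trend,
)
from tacfis.types import ValidationError


def _single_locus_config(maf, **kwargs):
    return GeneratorConfig(
        loci=(LocusSpec("rs776746", maf, "A", "G"),), effects=(), ld_pairs=(), **kwargs
    )


class TestSampleGenotypes:
    def test_minor_homozygote_frequency_matches_hwe(self, rng):
        n = 100_000
        pairs = sample_genotypes(_single_locus_config(0.28), n, rng)
        freq = np.mean([p.recipient_genotypes["rs776746"] == "AA" for p in pairs])
        expected = 0.28**2
        se = np.sqrt(expected * (1 - expected) / n)
        assert freq == pytest.approx(expected, abs=3 * se)

    def test_monomorphic_panel(self, rng):
        pairs = sample_genotypes(_single_locus_config(0.0), 200, rng)
        assert all(p.donor_genotypes["rs776746"] == "GG" for p in pairs)

    def test_perfect_ld_duplicates_dosage(self, rng):
        cfg = GeneratorConfig(
            loci=(LocusSpec("rs1", 0.3, "A", "G"), LocusSpec("rs2", 0.3, "C", "T")),
            effects=(),
            ld_pairs=(("rs1", "rs2", 1.0),),
        )
        pairs = sample_genotypes(cfg, 2000, rng)
        d1 = dosage_vector([p.recipient_genotypes["rs1"] for p in pairs])
        d2 = dosage_vector([p.recipient_genotypes["rs2"] for p in pairs])
        assert np.corrcoef(d1, d2)[0, 1] ** 2 > 0.999

    def test_target_ld_recovered(self, rng):
        cfg = GeneratorConfig(
            loci=(LocusSpec("rs776746", 0.28, "A", "G"), LocusSpec("rs2242480", 0.25, "A", "G")),
            effects=(),
            ld_pairs=(("rs776746", "rs2242480", 0.52),),
        )
        n = 20_000
        pairs = sample_genotypes(cfg, n, rng)
        d1 = dosage_vector([p.donor_genotypes["rs776746"] for p in pairs])
        d2 = dosage_vector([p.donor_genotypes["rs2242480"] for p in pairs])
        r2 = np.corrcoef(d1, d2)[0, 1] ** 2
        assert r2 == pytest.approx(0.52, abs=0.03)

    def test_infeasible_ld_reports_bound(self):
        cfg = GeneratorConfig(
            loci=(LocusSpec("rs1", 0.05, "A", "G"), LocusSpec("rs2", 0.45, "C", "T")),
            effects=(),
            ld_pairs=(("rs1", "rs2", 0.9),),
        )
        with pytest.raises(ValidationError, match="feasible bound"):
            sample_genotypes(cfg, 10, np.random.default_rng(0))

    def test_hwe_holds_in_generated_genotypes(self, rng):
        pairs = sample_genotypes(_single_locus_config(0.28), 5000, rng)
        calls = [p.donor_genotypes["rs776746"] for p in pairs]
        counts = (calls.count("GG"), calls.count("AG"), calls.count("AA"))
        _, p = hwe_test(*counts)
        assert p > 0.001  # no systematic HWE violation


class TestSimulateClearance:
    def test_no_effects_no_noise_all_equal_mu(self, rng):
        cfg = _single_locus_config(0.3, mu=4.5, sd_patient=0.0)
        pairs = sample_genotypes(cfg, 50, rng)
        out = simulate_clearance(pairs, cfg, rng)
        assert np.allclose(out["baseline_logcdr"], 4.5)

    def test_single_locus_effect_separates_two_values(self, rng):
        cfg = GeneratorConfig(
            loci=(LocusSpec("rs776746", 0.3, "A", "G"),),
            effects=(EffectSpec("rs776746", "recipient", "noncarrier", 0.7),),
            ld_pairs=(),
            mu=4.0,
            sd_patient=0.0,
        )
        pairs = sample_genotypes(cfg, 300, rng)
        out = simulate_clearance(pairs, cfg, rng)
        values = sorted(out["baseline_logcdr"].unique())
        assert values == pytest.approx([4.0, 4.7])

    def test_ols_refit_recovers_betas(self, rng):
        """Parameter recovery: regressing baselines on the true dominant
        codes returns each generating beta within 3 standard errors."""
        import statsmodels.api as sm

        cfg = GeneratorConfig()
        pairs = sample_genotypes(cfg, 2000, rng)
        out = simulate_clearance(pairs, cfg, rng)
        X = pd.DataFrame(
            {
                "D.rs776746": [p.donor_genotypes["rs776746"] == "GG" for p in pairs],
                "R.rs776746": [p.recipient_genotypes["rs776746"] == "GG" for p in pairs],
                "R.rs3775770": ["A" in p.recipient_genotypes["rs3775770"] for p in pairs],
                "D.rs7141505": [p.donor_genotypes["rs7141505"] == "TT" for p in pairs],
            },
            dtype=float,
        )
        fit = sm.OLS(out["baseline_logcdr"], sm.add_constant(X)).fit()
        expected = {"D.rs776746": 0.35, "R.rs776746": 0.35, "R.rs3775770": 0.30, "D.rs7141505": -0.70}
        for name, beta in expected.items():
            assert abs(fit.params[name] - beta) < 3 * fit.bse[name]

    def test_missing_panel_genotype_fatal(self):
        from tacfis.types import GenotypePair

        cfg = GeneratorConfig()
        pair = GenotypePair("P1", donor_genotypes={}, recipient_genotypes={})
        with pytest.raises(ValidationError, match="missing"):
            simulate_clearance([pair], cfg, np.random.default_rng(0))


class TestTDMCourse:
    @staticmethod
    def _flat_config(**kwargs):
        defaults = dict(
            sd_day=0.0, trend_day1=0.0, trend_peak=0.0, max_step=0.0,
        )
        defaults.update(kwargs)
        return GeneratorConfig(**defaults)

    def test_flat_course_has_constant_cdr(self, rng):
        cfg = self._flat_config()
        records = simulate_tdm_course(4.6, cfg, rng, weight=70.0)
        cdrs = [r.trough / (r.daily_dose / r.weight) for r in records]
        assert np.allclose(cdrs, np.exp(4.6))
        assert len(records) == 28

    def test_slow_eliminator_gets_lower_plateau_dose(self):
        cfg = GeneratorConfig()
        fast = simulate_tdm_course(4.0, cfg, np.random.default_rng(7), weight=70.0)
        slow = simulate_tdm_course(5.5, cfg, np.random.default_rng(7), weight=70.0)
        dose_fast = np.mean([r.daily_dose for r in fast[14:]])
        dose_slow = np.mean([r.daily_dose for r in slow[14:]])
        assert dose_slow < dose_fast

    def test_population_median_plateau_trough_in_window(self):
        cohort = simulate_cohort(GeneratorConfig().scaled(1000), seed=3)
        pk = pk_frame(cohort.pk)
        plateau = pk[pk["day"] >= 15]
        med = plateau["trough"].median()
        assert GeneratorConfig().trough_low <= med <= GeneratorConfig().trough_high

    def test_trend_shape(self):
        cfg = GeneratorConfig()
        assert trend(2, cfg) == trend(3, cfg) == cfg.trend_peak
        assert trend(1, cfg) < trend(2, cfg)
        decline = [trend(d, cfg) for d in range(3, 12)]
        assert all(a >= b for a, b in zip(decline, decline[1:]))
        assert trend(11, cfg) == trend(28, cfg) == 0.0


class TestOutcomes:
    def test_zero_slope_rate_matches_intercept(self, rng):
        cfg = GeneratorConfig(leuk_slope=0.0, leuk_intercept=0.0)  # expit(0) = 0.5
        df = pd.DataFrame({"patient_id": [f"P{i}" for i in range(4000)],
                           "week1_mean_trough": rng.uniform(3, 15, 4000)})
        out = simulate_outcomes(df, cfg, rng)
        rate = np.mean([o.leukocyte_elevated for o in out])
        assert rate == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 4000))

    def test_positive_infection_slope_orders_tertiles(self, rng):
        cfg = GeneratorConfig(infection_slope=1.0)
        trough = rng.uniform(3, 15, 2000)
        df = pd.DataFrame({"patient_id": [f"P{i}" for i in range(2000)],
                           "week1_mean_trough": trough})
        out = simulate_outcomes(df, cfg, rng)
        inf = np.array([o.infection for o in out])
        order = np.argsort(trough)
        low, high = inf[order[:666]], inf[order[-666:]]
        assert high.mean() > low.mean()


class TestDeterminism:
    def test_fixed_seed_bit_identical(self):
        cfg = GeneratorConfig().scaled(60)
        a = simulate_cohort(cfg, seed=11)
        b = simulate_cohort(cfg, seed=11)
        assert pk_frame(a.pk).equals(pk_frame(b.pk))
        assert a.genotypes == b.genotypes
        assert a.outcomes == b.outcomes

    def test_different_seed_differs(self):
        cfg = GeneratorConfig().scaled(60)
        a = simulate_cohort(cfg, seed=11)
        b = simulate_cohort(cfg, seed=12)
        assert not pk_frame(a.pk).equals(pk_frame(b.pk))
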