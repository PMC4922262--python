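import math

import numpy as np
import pandas as pd
import pytest

from respirotools import (
    ComparisonSpec,
    STUDY_DESIGN,
    fit_comparison,
    fit_ucrit_lm,
    percent_difference,
    simulate_method_effect_cohort,
)


def _balanced_frame(n_fish=8, methods=("swim", "chase", "circle"),
                    species=("A", "B"), method_effect=None, noise_sd=0.0,
                    seed=0):
    rng = np.random.default_rng(seed)
    method_effect = method_effect or {m: 0.0 for m in methods}
    rows = []
    for i in range(n_fish):
        sp = species[i % len(species)]
        base = 1000.0 + 80.0 * i
        for m in methods:
            rows.append(dict(fish_id=f"f{i}", species=sp, method=m,
                             mmr=base + method_effect[m] +
                             rng.normal(0, noise_sd)))
    return pd.DataFrame(rows)


class TestFitComparison:
    def test_zero_effect_zero_noise_contrasts_are_zero(self):
        df = _balanced_frame()
        res = fit_comparison(df, ComparisonSpec(response="mmr"))
        for c in res.contrasts:
            assert c["estimate"] == pytest.approx(0.0, abs=1e-6)

    def test_method_ratio_recovery_within_mc_interval(self):
        """Generative swim:chase:circle ratios 1.0 : 0.8 : 0.75 are
        recovered by the log-scale contrasts within their CIs (checked
        across seeds to allow normal sampling variation)."""
        ratios = {"swim": 1.0, "chase": 0.8, "circle": 0.75}
        true_lr = math.log(ratios["chase"] / ratios["swim"])
        hits = 0
        for seed in range(10):
            df = simulate_method_effect_cohort(
                n_per_species=20, ratios=ratios, seed=seed)
            df = df.rename(columns={"value": "mmr"})
            res = fit_comparison(df, ComparisonSpec(response="mmr",
                                                    log_transform=True))
            c = res.contrast("chase", "swim")
            hits += c["ci_low"] <= true_lr <= c["ci_high"]
            pct, _ = percent_difference(res, ("swim", "chase"))
            assert pct == pytest.approx(25.0, abs=8.0)  # 1/0.8 - 1 = 25%
        assert hits >= 8

    def test_dropping_one_trial_still_fits_with_fewer_df(self):
        df = _balanced_frame(noise_sd=20.0, seed=1)
        full = fit_comparison(df, ComparisonSpec(response="mmr"))
        dropped = fit_comparison(df.iloc[:-1], ComparisonSpec(response="mmr"))
        assert dropped.n_obs == full.n_obs - 1
        f_full = next(t for t in full.fixed_effect_tests if t["term"] == "method")
        f_drop = next(t for t in dropped.fixed_effect_tests if t["term"] == "method")
        assert f_drop["df_den"] < f_full["df_den"]

    def test_interaction_removed_when_absent(self):
        df = _balanced_frame(noise_sd=30.0,
                             method_effect={"swim": 200.0, "chase": 0.0,
                                            "circle": -50.0}, seed=2)
        res = fit_comparison(df, ComparisonSpec(response="mmr"))
        assert res.interaction_test is not None
        if res.interaction_test["p"] >= 0.05:
            assert res.interaction_removed

    def test_single_fish_repeated_falls_back_to_ols(self):
        rows = [dict(fish_id="f0", species="A", method=m, mmr=v)
                for m, v in [("swim", 1200.0), ("chase", 1000.0)]]
        rows += [dict(fish_id=f"g{i}", species="A", method="swim",
                      mmr=1100.0 + i) for i in range(4)]
        res = fit_comparison(pd.DataFrame(rows), ComparisonSpec(response="mmr"))
        assert res.engine == "ols"
        assert any("fixed-effects" in n for n in res.notes)

    def test_interaction_removal_rate_near_one_minus_alpha(self):
        """Under a zero-interaction generative model, the simplification
        rule drops the interaction with frequency ~ 1 - alpha."""
        removed = 0
        n_sims = 500
        rng = np.random.default_rng(99)
        for _ in range(n_sims):
            rows = []
            for i in range(8):
                sp = "A" if i < 4 else "B"
                base = rng.normal(1000.0, 150.0)
                for m, eff in (("swim", 100.0), ("chase", 0.0)):
                    rows.append(dict(fish_id=f"f{i}", species=sp, method=m,
                                     mmr=base + eff + rng.normal(0, 50.0)))
            res = fit_comparison(pd.DataFrame(rows),
                                 ComparisonSpec(response="mmr"))
            removed += res.interaction_removed
        assert 0.90 <= removed / n_sims <= 0.99


class TestPercentDifference:
    def test_arithmetic(self):
        df = _balanced_frame(method_effect={"swim": 200.0, "chase": 0.0,
                                            "circle": 0.0})
        res = fit_comparison(df, ComparisonSpec(response="mmr"))
        preds = res.predictions.set_index("method")["pred"]
        expected = 100.0 * (preds["swim"] - preds["chase"]) / preds["chase"]
        pct, (lo, hi) = percent_difference(res, ("swim", "chase"))
        assert pct == pytest.approx(expected, rel=1e-9)
        assert lo <= pct <= hi

    def test_identical_predictions_zero(self):
        df = _balanced_frame()
        res = fit_comparison(df, ComparisonSpec(response="mmr"))
        pct, (lo, hi) = percent_difference(res, ("swim", "chase"))
        assert pct == pytest.approx(0.0, abs=1e-6)
        assert lo == pytest.approx(0.0, abs=1e-6)

    def test_antisymmetry_identity(self):
        df = _balanced_frame(method_effect={"swim": 150.0, "chase": 0.0,
                                            "circle": -100.0}, noise_sd=10.0,
                             seed=3)
        res = fit_comparison(df, ComparisonSpec(response="mmr"))
        ab, _ = percent_difference(res, ("swim", "chase"))
        ba, _ = percent_difference(res, ("chase", "swim"))
        assert ab == pytest.approx(-ba / (1 + ba / 100.0), rel=1e-9)

    def test_species_range_is_min_max(self):
        df = _balanced_frame(method_effect={"swim": 150.0, "chase": 0.0,
                                            "circle": 0.0}, noise_sd=25.0,
                             species=("A", "B", "C"), n_fish=9, seed=4)
        res = fit_comparison(df, ComparisonSpec(response="mmr"))
        _, (lo, hi) = percent_difference(res, ("swim", "chase"))
        sp = res.species_predictions.pivot(index="species", columns="method",
                                           values="pred")
        per = 100.0 * (sp["swim"] - sp["chase"]) / sp["chase"]
        assert lo == pytest.approx(per.min())
        assert hi == pytest.approx(per.max())


class TestUcritLm:
    def test_separated_modes_significant_with_distinct_letters(self):
        rng = np.random.default_rng(0)
        rows = []
        for sp, mode, mu in [("A", "BCF", 90.0), ("B", "MPF", 40.0)]:
            for i in range(8):
                rows.append(dict(fish_id=f"{sp}{i}", species=sp, swim_mode=mode,
                                 ucrit_abs=mu + rng.normal(0, 1.0)))
        res = fit_ucrit_lm(pd.DataFrame(rows))
        mode_test = next(t for t in res.fixed_effect_tests
                         if t["term"] == "swim_mode")
        assert mode_test["p"] < 0.05
        assert res.letters["A"] != res.letters["B"]

    def test_identical_values_share_a_letter(self):
        rows = [dict(fish_id=f"{sp}{i}", species=sp, swim_mode=mode,
                     ucrit_abs=70.0)
                for sp, mode in [("A", "BCF"), ("B", "MPF")] for i in range(5)]
        res = fit_ucrit_lm(pd.DataFrame(rows))
        assert res.letters["A"] == res.letters["B"]
        assert all(t["p"] >= 0.05 for t in res.fixed_effect_tests)

    def test_bcf_exceeds_mpf_in_expectation(self):
        """Cohorts drawn from the four-species design show higher absolute
        Ucrit for body-caudal-fin than median-paired-fin swimmers."""
        wins = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            rows = []
            for sp in STUDY_DESIGN:
                sd = sp.ucrit_rel_mean_bl_s * sp.ucrit_cv
                for i in range(sp.n):
                    rel = rng.normal(sp.ucrit_rel_mean_bl_s, sd)
                    length = rng.normal(sp.length_mean_m,
                                        sp.length_mean_m * sp.length_cv)
                    rows.append(dict(fish_id=f"{sp.species}_{i}",
                                     species=sp.species, swim_mode=sp.swim_mode,
                                     ucrit_abs=rel * length * 100.0))
            df = pd.DataFrame(rows)
            means = df.groupby("swim_mode")["ucrit_abs"].mean()
            wins += means["BCF"] > means["MPF"]
        assert wins >= 5

    def test_single_group_rejected(self):
        rows = [dict(fish_id=f"f{i}", species="A", swim_mode="BCF",
                     ucrit_abs=70.0 + i) for i in range(5)]
        with pytest.raises(ValueError, match="2 groups"):
            fit_ucrit_lm(pd.DataFrame(rows))

    def test_one_value_per_fish_enforced(self):
        rows = [dict(fish_id="f0", species="A", swim_mode="BCF", ucrit_abs=70.0),
                dict(fish_id="f0", species="A", swim_mode="BCF", ucrit_abs=71.0),
                dict(fish_id="f1", species="B", swim_mode="MPF", ucrit_abs=50.0)]
        with pytest.raises(ValueError, match="one Ucrit"):
            fit_ucrit_lm(pd.DataFrame(rows))
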