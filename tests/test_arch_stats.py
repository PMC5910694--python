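import numpy as np
import pandas as pd
import pytest

from myoarch.arch_stats import (METRICS, WHOLE, compartment_table, holm_adjust,
                                lmm_compartment, lmm_lengthening, per_cm_change,
                                posterior_fraction, round_half_up)

COMPS = ["MA", "LA", "MP", "LP"]


def records_from_values(values_by_subject):
    """values_by_subject: {subject: {(comp, cond): {metric: value}}}"""
    rows = []
    for subject, cells in values_by_subject.items():
        for (comp, cond), metrics in cells.items():
            rows.append({"subject_id": subject, "compartment": comp, "condition": cond, **metrics})
    return pd.DataFrame(rows)


def constant_metrics(**overrides):
    base = dict(volume_cm3=100.0, pcsa_cm2=25.0, fascicle_length_mm=40.0,
                pennation_deg=30.0, curvature_per_m=15.0)
    base.update(overrides)
    return base


def simulate_cohort(rng, comp_means, n_subjects=6, subject_sd=1.0, resid_sd=0.5,
                    metric="pennation_deg", cond_effect=None):
    rows = []
    for s in range(n_subjects):
        intercept = rng.normal(0, subject_sd)
        for comp in comp_means:
            for cond in ("short", "long"):
                value = comp_means[comp] + intercept + rng.normal(0, resid_sd)
                if cond == "long" and cond_effect is not None:
                    value += cond_effect.get(comp, 0.0)
                rows.append({"subject_id": f"s{s}", "compartment": comp, "condition": cond,
                             metric: value})
    return pd.DataFrame(rows)


class TestRounding:
    @pytest.mark.parametrize("x,decimals,expected", [
        (21.15, 1, 21.2), (9.45, 1, 9.5), (-9.45, 1, -9.5),
        (17.425, 1, 17.4), (355.65, 0, 356.0), (12.05, 0, 12.0),
        (2.5, 0, 3.0), (-2.5, 0, -3.0),
    ])
    def test_half_up(self, x, decimals, expected):
        assert round_half_up(x, decimals) == expected


class TestCompartmentTable:
    def test_single_subject_single_compartment_whole_equals_compartment(self):
        recs = records_from_values({"s1": {
            ("MA", "short"): constant_metrics(),
            ("MA", "long"): constant_metrics(fascicle_length_mm=50.0),
        }})
        table = compartment_table(recs)
        for m in METRICS:
            assert table.loc[(WHOLE, "short"), f"{m}_mean"] == pytest.approx(
                table.loc[("MA", "short"), f"{m}_mean"])
        assert table.loc[(WHOLE, "change"), "fascicle_length_mm_mean"] == pytest.approx(10.0)

    def test_whole_muscle_sums_and_means(self):
        cells = {}
        for comp, vol in zip(COMPS, [33.5, 40.4, 146.6, 141.7]):
            cells[(comp, "short")] = constant_metrics(volume_cm3=vol, pcsa_cm2=vol / 4)
            cells[(comp, "long")] = constant_metrics(volume_cm3=vol, pcsa_cm2=vol / 4)
        table = compartment_table(records_from_values({"s1": cells}))
        assert table.loc[(WHOLE, "short"), "volume_cm3_mean"] == pytest.approx(362.2)
        assert table.loc[(WHOLE, "short"), "pcsa_cm2_mean"] == pytest.approx(362.2 / 4)
        assert table.loc[(WHOLE, "short"), "fascicle_length_mm_mean"] == pytest.approx(40.0)

    def test_change_within_subject_before_averaging(self):
        # two subjects with opposite-sign changes averaging to zero, but
        # different baselines: change row must use within-subject differences
        recs = records_from_values({
            "s1": {("MA", "short"): constant_metrics(pennation_deg=20.0),
                   ("MA", "long"): constant_metrics(pennation_deg=30.0)},
            "s2": {("MA", "short"): constant_metrics(pennation_deg=40.0),
                   ("MA", "long"): constant_metrics(pennation_deg=30.0)},
        })
        table = compartment_table(recs)
        assert table.loc[("MA", "change"), "pennation_deg_mean"] == pytest.approx(0.0)
        assert table.loc[("MA", "change"), "pennation_deg_sd"] == pytest.approx(
            np.std([10.0, -10.0], ddof=1))

    def test_missing_condition_excluded_with_warning(self):
        recs = records_from_values({
            "s1": {("MA", "short"): constant_metrics(),
                   ("MA", "long"): constant_metrics()},
            "s2": {("MA", "short"): constant_metrics(volume_cm3=999.0)},
        })
        with pytest.warns(UserWarning, match="missing a condition"):
            table = compartment_table(recs)
        assert table.loc[("MA", "short"), "volume_cm3_mean"] == pytest.approx(100.0)

    def test_sd_across_subjects(self):
        recs = records_from_values({
            "s1": {("MA", "short"): constant_metrics(volume_cm3=90.0),
                   ("MA", "long"): constant_metrics(volume_cm3=90.0)},
            "s2": {("MA", "short"): constant_metrics(volume_cm3=110.0),
                   ("MA", "long"): constant_metrics(volume_cm3=110.0)},
        })
        table = compartment_table(recs)
        assert table.loc[("MA", "short"), "volume_cm3_sd"] == pytest.approx(
            np.std([90.0, 110.0], ddof=1))


class TestPosteriorFraction:
    def make(self, vols):
        cells = {}
        for comp, v in zip(COMPS, vols):
            cells[(comp, "short")] = constant_metrics(volume_cm3=v)
            cells[(comp, "long")] = constant_metrics(volume_cm3=v)
        return records_from_values({"s1": cells})

    def test_equal_volumes(self):
        _, mean, _ = posterior_fraction(self.make([10, 10, 10, 10]))
        assert mean == pytest.approx(50.0)

    def test_zero_anterior(self):
        _, mean, _ = posterior_fraction(self.make([0.0, 0.0, 10.0, 10.0]))
        assert mean == pytest.approx(100.0)

    def test_short_long_averaged_per_compartment(self):
        cells = {}
        for comp, (vs, vl) in zip(COMPS, [(10, 20), (10, 20), (40, 20), (40, 20)]):
            cells[(comp, "short")] = constant_metrics(volume_cm3=vs)
            cells[(comp, "long")] = constant_metrics(volume_cm3=vl)
        _, mean, _ = posterior_fraction(records_from_values({"s1": cells}))
        assert mean == pytest.approx(100.0 * 60.0 / 90.0)

    def test_missing_compartment_errors(self):
        recs = records_from_values({"s1": {("MA", "short"): constant_metrics()}})
        with pytest.raises(ValueError, match="missing"):
            posterior_fraction(recs)


class TestPerCmChange:
    def test_hand_computed_slope(self):
        recs = records_from_values({"s1": {
            ("MA", "short"): constant_metrics(fascicle_length_mm=40.0),
            ("MA", "long"): constant_metrics(fascicle_length_mm=50.0),
        }})
        out = per_cm_change(recs, {"s1": 20.0})
        assert out.loc["MA", "fascicle_length_mm_per_cm_mean"] == pytest.approx(5.0)

    def test_identical_conditions_zero(self):
        recs = records_from_values({"s1": {
            ("MA", "short"): constant_metrics(),
            ("MA", "long"): constant_metrics(),
        }})
        out = per_cm_change(recs, {"s1": 30.0})
        assert out.loc["MA", "fascicle_length_mm_per_cm_mean"] == pytest.approx(0.0)

    def test_scale_consistency(self, rng):
        recs = simulate_cohort(rng, {"MA": 30.0, "LA": 32.0}, cond_effect={"MA": 5.0, "LA": 7.0},
                               metric="fascicle_length_mm")
        mtu = {f"s{i}": 25.0 for i in range(6)}
        base = per_cm_change(recs, mtu, metrics=["fascicle_length_mm"])
        doubled = recs.copy()
        doubled.loc[doubled["condition"] == "long", "fascicle_length_mm"] *= 1.0
        # double the within-subject change by doubling long-short difference
        short = doubled["condition"] == "short"
        pivot_change = doubled.loc[~short].set_index(["subject_id", "compartment"])["fascicle_length_mm"]
        base_short = doubled.loc[short].set_index(["subject_id", "compartment"])["fascicle_length_mm"]
        doubled.loc[~short, "fascicle_length_mm"] = (
            base_short + 2 * (pivot_change - base_short)).reindex(
            pd.MultiIndex.from_frame(doubled.loc[~short, ["subject_id", "compartment"]])).to_numpy()
        out2 = per_cm_change(doubled, mtu, metrics=["fascicle_length_mm"])
        assert out2.loc["MA", "fascicle_length_mm_per_cm_mean"] == pytest.approx(
            2 * base.loc["MA", "fascicle_length_mm_per_cm_mean"])

    def test_zero_mtu_excluded_with_warning(self):
        recs = records_from_values({
            "s1": {("MA", "short"): constant_metrics(fascicle_length_mm=40.0),
                   ("MA", "long"): constant_metrics(fascicle_length_mm=50.0)},
            "s2": {("MA", "short"): constant_metrics(fascicle_length_mm=40.0),
                   ("MA", "long"): constant_metrics(fascicle_length_mm=60.0)},
        })
        with pytest.warns(UserWarning, match="zero MTU"):
            out = per_cm_change(recs, {"s1": 0.0, "s2": 20.0})
        assert out.loc["MA", "fascicle_length_mm_per_cm_mean"] == pytest.approx(10.0)

    def test_simulated_cohort_recovers_slope(self, rng):
        # known 3.7 mm/cm slope with noise
        mtu = 30.0
        rows = []
        for s in range(6):
            base = rng.normal(40.0, 5.0)
            for comp in COMPS:
                rows.append({"subject_id": f"s{s}", "compartment": comp, "condition": "short",
                             "fascicle_length_mm": base})
                rows.append({"subject_id": f"s{s}", "compartment": comp, "condition": "long",
                             "fascicle_length_mm": base + 3.7 * mtu / 10 + rng.normal(0, 1.0)})
        out = per_cm_change(pd.DataFrame(rows), {f"s{i}": mtu for i in range(6)},
                            metrics=["fascicle_length_mm"])
        se = out.loc[WHOLE, "fascicle_length_mm_per_cm_sd"] / np.sqrt(6)
        assert out.loc[WHOLE, "fascicle_length_mm_per_cm_mean"] == pytest.approx(3.7, abs=3 * se)


class TestHolm:
    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 0.2, 8)
        _, expected, _, _ = multipletests(p, method="holm")
        assert np.allclose(holm_adjust(p), expected)


class TestLmm:
    def test_zero_variance_fixed_effects_equal_group_means(self):
        means = {"MA": 22.0, "LA": 27.0, "MP": 38.0, "LP": 35.0}
        rows = [{"subject_id": f"s{s}", "compartment": c, "condition": "short",
                 "pennation_deg": m} for s in range(4) for c, m in means.items()]
        result = lmm_compartment(pd.DataFrame(rows), "pennation_deg")
        assert result.singular
        for comp, mean in means.items():
            assert result.group_means[comp] == pytest.approx(mean, abs=1e-9)

    def test_balanced_design_matches_ols(self, rng):
        import statsmodels.formula.api as smf

        df = simulate_cohort(rng, {"MA": 22.0, "LA": 27.0, "MP": 38.0, "LP": 35.0})
        df = df[df["condition"] == "short"]
        result = lmm_compartment(df, "pennation_deg")
        ols = smf.ols("pennation_deg ~ C(compartment)", data=df).fit()
        assert np.allclose(np.asarray(result.params), np.asarray(ols.params), atol=1e-6)

    def test_simulation_recovery_small(self, rng):
        means = {"MA": 22.0, "LA": 27.0, "MP": 38.0, "LP": 35.0}
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            df = simulate_cohort(rng, means, subject_sd=1.0, resid_sd=0.5)
            df = df[df["condition"] == "short"]
            result = lmm_compartment(df, "pennation_deg")
            est = result.group_means
            # posterior - anterior contrast, truth 12.25
            diff = (est["MP"] + est["LP"]) / 2 - (est["MA"] + est["LA"]) / 2
            truth = (means["MP"] + means["LP"]) / 2 - (means["MA"] + means["LA"]) / 2
            if abs(diff - truth) < 1.0:
                hits += 1
        assert hits >= int(0.8 * n_rep)

    def test_pairwise_contrasts_present_with_holm(self, rng):
        df = simulate_cohort(rng, {"MA": 22.0, "LA": 27.0, "MP": 38.0, "LP": 35.0})
        result = lmm_compartment(df[df["condition"] == "short"], "pennation_deg")
        assert len(result.contrasts) == 6
        assert "p_holm" in result.contrasts.columns
        assert (result.contrasts["p_holm"] >= result.contrasts["p"] - 1e-12).all()

    def test_requires_two_subjects_and_compartments(self):
        rows = [{"subject_id": "s1", "compartment": c, "condition": "short",
                 "pennation_deg": 30.0} for c in COMPS]
        with pytest.raises(ValueError, match="2 subjects"):
            lmm_compartment(pd.DataFrame(rows), "pennation_deg")

    def test_lengthening_null_interaction(self, rng):
        df = simulate_cohort(rng, {"MA": 30.0, "MP": 40.0}, cond_effect={"MA": -5.0, "MP": -5.0})
        result = lmm_lengthening(df, "pennation_deg")
        # both compartments change by -5; their change contrast is ~0
        assert result.contrasts["estimate"].iloc[0] == pytest.approx(
            0.0, abs=3 * result.contrasts["se"].iloc[0] + 1e-9)

    def test_lengthening_recovers_compartment_changes(self, rng):
        df = simulate_cohort(rng, {"MA": 30.0, "MP": 40.0},
                             cond_effect={"MA": -2.0, "MP": -8.0}, resid_sd=0.3)
        result = lmm_lengthening(df, "pennation_deg")
        assert result.group_means["MA"] == pytest.approx(-2.0, abs=1.0)
        assert result.group_means["MP"] == pytest.approx(-8.0, abs=1.0)

    def test_single_compartment_reduces_to_paired_model(self, rng):
        df = simulate_cohort(rng, {"MA": 30.0}, cond_effect={"MA": -4.0}, resid_sd=0.2)
        result = lmm_lengthening(df, "pennation_deg")
        changes = df.pivot_table(index="subject_id", columns="condition",
                                 values="pennation_deg")
        paired = (changes["long"] - changes["short"]).mean()
        assert result.group_means["MA"] == pytest.approx(paired, abs=1e-6)
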