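"""Study analyses: morphospace summaries, regressions, mediation, ROPEs."""

import numpy as np
import pandas as pd
import pytest

from dicascade import analyses, synthetic
from dicascade.analyses import (
    mediation_from_draws,
    run_agenesis_anthropoid,
    run_agenesis_human,
    run_area_correction_check,
    run_cv_comparison,
    run_diet_logistic,
    run_mass_deviation,
    run_mediation,
    run_proportion_regression,
    summarize_morphospace,
)
from dicascade.pglmm import MCMCSchedule


def _summary_frame(triples):
    return pd.DataFrame(
        [
            {
                "species": f"s{i}",
                "mean_area_1": a,
                "mean_area_2": b,
                "mean_area_3": c,
                "m2m1": b / a,
                "m3m1": c / a if np.isfinite(c) else np.nan,
                "m3_agenesis": not np.isfinite(c),
            }
            for i, (a, b, c) in enumerate(triples)
        ]
    )


class TestMorphospaceSummary:
    def test_all_on_line(self):
        frame = _summary_frame([(1, 1.2, 1.4), (1, 0.8, 0.6), (1, 1, 1)])
        out = summarize_morphospace(frame)
        assert out.percent_consistent == 100.0

    def test_mixed_counts(self):
        frame = _summary_frame(
            [(1, 1.2, 1.5), (1, 1.3, 1.6), (1, 1.4, 1.7), (1, 1.1, 1.0)]
        )
        out = summarize_morphospace(frame)
        assert out.percent_consistent == pytest.approx(75.0)
        assert out.region_counts["INCREASING"] == 3
        assert out.region_counts["M2_PEAK"] == 1

    def test_all_inconsistent(self):
        frame = _summary_frame([(1, 1.2, 1.0), (1, 1.3, 0.9)])
        out = summarize_morphospace(frame)
        assert out.percent_consistent == 0.0

    def test_agenesis_excluded_from_denominator(self):
        frame = _summary_frame([(1, 1.2, 1.4), (1, 0.4, np.nan)])
        out = summarize_morphospace(frame)
        assert out.n_species == 1
        assert out.n_excluded_agenesis == 1

    def test_line_tolerance_rescues_near_line_points(self):
        # an M2-peak point a perpendicular distance ~0.0067 off the line
        frame = _summary_frame([(1, 1.01, 1.005)])
        assert summarize_morphospace(frame).percent_consistent == 0.0
        assert (
            summarize_morphospace(frame, line_tol=0.01).percent_consistent
            == 100.0
        )


class TestMediationAlgebra:
    def test_no_direct_path_gives_unity(self):
        draws, point = mediation_from_draws(
            beta_1b=[0.0, 0.0], beta_2b=[1.5, 1.4], beta_1b_prime=[1.1, 1.2]
        )
        assert np.allclose(draws.pr_m, 1.0)
        assert point["pr_m_hat"] == pytest.approx(1.0)

    def test_no_indirect_path_gives_zero(self):
        draws, point = mediation_from_draws(
            beta_1b=[1.0, 1.0], beta_2b=[0.0, 0.0], beta_1b_prime=[1.0, 1.0]
        )
        assert np.allclose(draws.pr_m, 0.0)
        assert point["pr_m_hat"] == pytest.approx(0.0)

    def test_unit_draws_split_evenly(self):
        draws, point = mediation_from_draws([1.0] * 3, [1.0] * 3, [1.0] * 3)
        assert np.allclose(draws.ab, 1.0)
        assert np.allclose(draws.c_prime_abs, 1.0)
        assert np.allclose(draws.pr_m, 0.5)
        assert point["pr_m_hat"] == pytest.approx(0.5)

    def test_draw_count_mismatch(self):
        with pytest.raises(ValueError, match="draw"):
            mediation_from_draws([1.0, 2.0], [1.0], [1.0])


class TestRegressionRecovery:
    def test_low_noise_recovers_the_line(self, tiny_schedule):
        config = synthetic.SimulationConfig(
            n_species=25,
            n_specimens_per_species=8,
            specimen_cv=0.005,
            wear_rate=0.0,
            indeterminate_sex_rate=0.0,
            zoo_rate=0.0,
            seed=21,
        )
        sim = synthetic.simulate_dataset(config)
        specimens, _, _ = analyses.prepare_specimens(sim.specimens)
        res = run_proportion_regression(
            specimens, sim.tree, schedule=tiny_schedule, seed=21
        )
        assert res.slope_between.posterior_mean == pytest.approx(2.0, abs=0.05)
        assert res.intercept.posterior_mean == pytest.approx(-1.0, abs=0.05)

    def test_clade_subset_matches_isolated_run(self, small_study, tiny_schedule):
        """No cross-clade leakage: a clade fit ignores other species."""
        sim, specimens, summaries, _ = small_study
        clade = sorted(summaries.species.unique())[:12]
        full = run_proportion_regression(
            specimens, sim.tree, clade=clade, schedule=tiny_schedule, seed=22
        )
        isolated = run_proportion_regression(
            specimens[specimens.species.isin(clade)],
            sim.tree,
            clade=clade,
            schedule=tiny_schedule,
            seed=22,
        )
        pd.testing.assert_frame_equal(full.fit.draws, isolated.fit.draws)

    def test_tiny_clade_refused(self, small_study, tiny_schedule):
        sim, specimens, summaries, _ = small_study
        with pytest.raises(ValueError, match="at least"):
            run_proportion_regression(
                specimens,
                sim.tree,
                clade=sorted(summaries.species.unique())[:3],
                schedule=tiny_schedule,
                seed=23,
            )


class TestMediationRecovery:
    def test_strict_mediation_recovers_high_pr_m(self, tiny_schedule):
        sim = synthetic.simulate_strict_mediation(40, seed=24, n_specimens=6)
        specimens, _, _ = analyses.prepare_specimens(sim.specimens)
        res = run_mediation(specimens, sim.tree, schedule=tiny_schedule, seed=24)
        assert res.pr_m.posterior_mean >= 0.85
        assert res.ab.mean > 1.0

    def test_direct_only_variant_recovers_low_pr_m(self, tiny_schedule):
        sim = synthetic.simulate_strict_mediation(
            40, seed=25, n_specimens=6, b_coef=0.0, direct_coef=1.2
        )
        specimens, _, _ = analyses.prepare_specimens(sim.specimens)
        res = run_mediation(specimens, sim.tree, schedule=tiny_schedule, seed=25)
        assert res.pr_m.posterior_mean <= 0.3

    def test_scale_invariance_of_pr_m(self, tiny_schedule):
        """Rescaling every molar area leaves the proportion mediated alone."""
        sim = synthetic.simulate_strict_mediation(30, seed=26, n_specimens=5)
        specimens, _, _ = analyses.prepare_specimens(sim.specimens)
        base = run_mediation(specimens, sim.tree, schedule=tiny_schedule, seed=26)
        scaled = specimens.copy()
        for col in scaled.columns:
            if col.endswith(("_length", "_breadth_trigonid", "_breadth_talonid")):
                scaled[col] = scaled[col] * np.sqrt(7.0)  # areas scale by 7
        rescaled = run_mediation(scaled, sim.tree, schedule=tiny_schedule, seed=26)
        assert rescaled.pr_m.posterior_mean == pytest.approx(
            base.pr_m.posterior_mean, abs=0.05
        )


class TestMassDeviation:
    def test_null_slope_covers_zero(self, small_study, tiny_schedule):
        sim, specimens, _, _ = small_study
        res = run_mass_deviation(specimens, sim.tree, schedule=tiny_schedule, seed=27)
        lo, hi = res.slope_between.hdi95
        assert lo <= 0.0 <= hi

    def test_negative_association_recovered(self, tiny_schedule):
        """Species that sit further off the line are simulated smaller."""
        config = synthetic.SimulationConfig(
            n_species=30, n_specimens_per_species=8, seed=28,
            wear_rate=0.0, indeterminate_sex_rate=0.0,
        )
        sim = synthetic.simulate_dataset(config)
        specimens, _, _ = analyses.prepare_specimens(sim.specimens)
        rng = np.random.default_rng(28)
        # heterogeneous per-species violations of the line: scale M3 lengths
        offsets = pd.Series(
            np.exp(0.25 * rng.standard_normal(specimens.species.nunique())),
            index=sorted(specimens.species.unique()),
        )
        specimens = specimens.assign(
            m3_length=specimens.m3_length * specimens.species.map(offsets)
        )
        specimens = analyses.prepare_specimens(specimens)[0]
        dist = np.abs(
            2.0 * specimens.m2_area / specimens.m1_area
            - specimens.m3_area / specimens.m1_area
            - 1.0
        ) / np.sqrt(5.0)
        per_species = dist.groupby(specimens.species).mean()
        mass = np.exp(
            2.0
            - 3.0 * per_species
            + 0.02 * rng.standard_normal(len(per_species))
        )
        specimens = specimens.assign(
            body_mass_kg=specimens.species.map(mass).astype(float)
        )
        res = run_mass_deviation(specimens, sim.tree, schedule=tiny_schedule, seed=28)
        assert res.slope_between.mean < 0.0
        lo, hi = res.slope_between.hdi95
        assert hi < 0.0

    def test_exclusion_refuses_empty(self, small_study, tiny_schedule):
        sim, specimens, summaries, _ = small_study
        with pytest.raises(ValueError):
            run_mass_deviation(
                specimens,
                sim.tree,
                exclude=list(summaries.species),
                schedule=tiny_schedule,
                seed=29,
            )


class TestCvComparison:
    def test_equal_cvs_cover_zero(self, small_study, tiny_schedule):
        sim, _, summaries, _ = small_study
        flat = summaries.copy()
        for k in (1, 2, 3):
            flat[f"cv_{k}"] = 0.07
        res = run_cv_comparison(flat, sim.tree, schedule=tiny_schedule, seed=30)
        for diff in (res.diff_m3_m1, res.diff_m3_m2):
            lo, hi = diff.hdi95
            assert lo <= 0.0 <= hi

    def test_elevated_m3_cv_detected(self, small_study, tiny_schedule):
        sim, _, summaries, _ = small_study
        rng = np.random.default_rng(31)
        bumped = summaries.copy()
        for k in (1, 2, 3):
            bumped[f"cv_{k}"] = 0.06 + 0.005 * rng.standard_normal(len(bumped))
        bumped["cv_3"] = bumped["cv_3"] + 0.02
        res = run_cv_comparison(bumped, sim.tree, schedule=tiny_schedule, seed=31)
        assert res.diff_m3_m1.mean == pytest.approx(0.02, abs=0.01)
        assert res.diff_m3_m1.hdi95[0] > 0.0

    def test_species_order_invariance(self, small_study, tiny_schedule):
        sim, _, summaries, _ = small_study
        flat = summaries.copy()
        for k in (1, 2, 3):
            flat[f"cv_{k}"] = 0.05 + 0.01 * (np.arange(len(flat)) % 3)
        a = run_cv_comparison(flat, sim.tree, schedule=tiny_schedule, seed=32)
        shuffled = flat.sample(frac=1.0, random_state=0).reset_index(drop=True)
        b = run_cv_comparison(shuffled, sim.tree, schedule=tiny_schedule, seed=32)
        assert a.diff_m3_m1.mean == pytest.approx(b.diff_m3_m1.mean)


class TestAgenesis:
    @staticmethod
    def _study_with_agenesis(seed, ag_level):
        config = synthetic.SimulationConfig(
            n_species=30, n_specimens_per_species=8, seed=seed,
            wear_rate=0.0, indeterminate_sex_rate=0.0,
        )
        sim = synthetic.simulate_dataset(config)
        _, summaries, _ = analyses.prepare_specimens(sim.specimens)
        flags = np.zeros(len(summaries), dtype=bool)
        flags[:6] = True
        summaries = summaries.copy()
        summaries["m3_agenesis"] = flags
        summaries.loc[flags, "m2m1"] = ag_level
        return sim, summaries

    def test_high_ratio_agenesis(self, tiny_schedule):
        sim, summaries = self._study_with_agenesis(33, 0.9)
        res = run_agenesis_anthropoid(summaries, sim.tree, schedule=tiny_schedule, seed=33)
        assert res.m2m1_agenesis.mean == pytest.approx(0.9, abs=0.1)
        assert res.prob_below_half < 0.05

    def test_low_ratio_agenesis(self, tiny_schedule):
        sim, summaries = self._study_with_agenesis(34, 0.3)
        res = run_agenesis_anthropoid(summaries, sim.tree, schedule=tiny_schedule, seed=34)
        assert res.prob_below_half > 0.95

    def test_requires_both_groups(self, small_study, tiny_schedule):
        sim, _, summaries, _ = small_study
        clean = summaries.copy()
        clean["m3_agenesis"] = False
        with pytest.raises(ValueError, match="agenesis"):
            run_agenesis_anthropoid(clean, sim.tree, schedule=tiny_schedule, seed=35)

    def test_human_recovery_at_study_values(self, tiny_schedule):
        df = synthetic.simulate_human_agenesis(
            n_individuals=200, seed=36, mean_agenesis=0.92, mean_retained=0.95
        )
        res = run_agenesis_human(df, schedule=tiny_schedule, seed=36)
        lo, hi = res.m2m1_agenesis.hdi95
        assert lo <= 0.92 <= hi
        lo, hi = res.m2m1_retained.hdi95
        assert lo <= 0.95 <= hi
        assert res.difference.mean == pytest.approx(-0.03, abs=0.02)

    def test_single_population_warns(self, tiny_schedule):
        df = synthetic.simulate_human_agenesis(seed=37, n_populations=1)
        with pytest.warns(UserWarning, match="population"):
            run_agenesis_human(df, schedule=tiny_schedule, seed=37)


class TestDietModel:
    def test_null_odds_ratio_covers_one(self, small_study):
        sim, _, summaries, _ = small_study
        rng = np.random.default_rng(38)
        shuffled = summaries.copy()
        shuffled["diet"] = rng.permutation(
            np.where(rng.random(len(shuffled)) < 0.4, "fruit", "leaves")
        )
        res = run_diet_logistic(
            shuffled, sim.tree, schedule=MCMCSchedule(8000, 2000, 6), seed=38
        )
        lo, hi = res.odds_ratio.hdi95
        assert lo <= 1.0 <= hi

    def test_percent_increase_consistent_with_odds(self, small_study):
        sim, _, summaries, _ = small_study
        res = run_diet_logistic(
            summaries, sim.tree, schedule=MCMCSchedule(8000, 2000, 6), seed=39
        )
        assert res.percent_increase.mean == pytest.approx(
            (res.odds_ratio.mean - 1.0) * 100.0, rel=1e-9
        )


class TestAreaCorrection:
    @staticmethod
    def _calibration(seed, shape=0.55, jitter=0.0):
        config = synthetic.SimulationConfig(
            n_species=6, n_specimens_per_species=10, seed=seed,
            wear_rate=0.0, indeterminate_sex_rate=0.0,
        )
        sim = synthetic.simulate_dataset(config)
        specimens, _, _ = analyses.prepare_specimens(sim.specimens)
        rng = np.random.default_rng(seed)
        cal = specimens.copy()
        for k in (1, 2, 3):
            cal[f"m{k}_outline_area"] = cal[f"m{k}_ra"] * shape + cal[
                f"m{k}_ea"
            ] * (1 - shape) + jitter * rng.standard_normal(len(cal))
        return cal

    def test_exact_shape_coefficient_centres_on_zero(self, tiny_schedule):
        cal = self._calibration(40)
        res = run_area_correction_check(cal, schedule=tiny_schedule, seed=40)
        lo, hi = res.mean_oa_minus_ca.hdi95
        assert lo <= 0.0 <= hi
        assert res.mean_oa_minus_ra.mean < 0.0  # rectangle overestimates

    def test_correction_beats_rectangle(self, tiny_schedule):
        cal = self._calibration(41, jitter=0.05)
        res = run_area_correction_check(cal, schedule=tiny_schedule, seed=41)
        assert abs(res.mean_oa_minus_ca.mean) < abs(res.mean_oa_minus_ra.mean)

    def test_requires_outlines(self, small_study, tiny_schedule):
        _, specimens, _, _ = small_study
        with pytest.raises(ValueError):
            run_area_correction_check(specimens, schedule=tiny_schedule, seed=42)


def test_mean_of_ratios_between_variant(small_study, tiny_schedule):
    """Both species-baseline definitions recover the line on clean data."""
    sim, specimens, _, _ = small_study
    alt = run_proportion_regression(
        specimens, sim.tree, schedule=tiny_schedule, seed=43,
        between="mean_of_ratios",
    )
    assert alt.slope_between.posterior_mean == pytest.approx(2.0, abs=0.15)
    with pytest.raises(ValueError, match="between"):
        run_proportion_regression(
            specimens, sim.tree, schedule=tiny_schedule, seed=43,
            between="nonsense",
        )


def test_morphospace_plot_smoke(small_study, tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    _, _, summaries, _ = small_study
    ax = analyses.plot_morphospace(summaries)
    assert ax.get_xlabel() == "M2/M1 area"
    fig = ax.get_figure()
    fig.savefig(tmp_path / "morphospace.png")
    assert (tmp_path / "morphospace.png").stat().st_size > 0


class TestM2Relative:
    def test_cascade_data_recover_one_third(self, small_study, tiny_schedule):
        from dicascade.analyses import run_m2_relative

        sim, specimens, _, _ = small_study
        res = run_m2_relative(specimens, sim.tree, schedule=tiny_schedule, seed=44)
        assert res.slope_between.posterior_mean == pytest.approx(
            1.0 / 3.0, abs=0.01
        )
        assert res.slope_between.posterior_probability > 0.5

    def test_inflated_m2_exceeds_rope(self, tiny_schedule):
        from dicascade.analyses import run_m2_relative

        config = synthetic.SimulationConfig(
            n_species=25, n_specimens_per_species=8, seed=45,
            m2_inflation=1.2, m2_inflation_clade_fraction=0.95,
            wear_rate=0.0, indeterminate_sex_rate=0.0,
        )
        sim = synthetic.simulate_dataset(config)
        specimens, _, _ = analyses.prepare_specimens(sim.specimens)
        res = run_m2_relative(specimens, sim.tree, schedule=tiny_schedule, seed=45)
        assert res.slope_between.hdi95[0] > 0.343

    def test_clade_subset_api(self, small_study, tiny_schedule):
        from dicascade.analyses import run_m2_relative

        sim, specimens, summaries, _ = small_study
        clade = sorted(summaries.species.unique())[:10]
        res = run_m2_relative(
            specimens, sim.tree, clade=clade, schedule=tiny_schedule, seed=46
        )
        assert 0.2 < res.slope_between.posterior_mean < 0.5


def test_diet_odds_ratio_recovery():
    """A strong simulated frugivory association is recovered by the
    logistic model (truth inside the odds-ratio 95 % HDI)."""
    config = synthetic.SimulationConfig(
        n_species=100, n_specimens_per_species=6, seed=47,
        ai_log_sd=0.35, diet_or_true=9.5,
    )
    sim = synthetic.simulate_dataset(config)
    _, summaries, _ = analyses.prepare_specimens(sim.specimens)
    res = run_diet_logistic(
        summaries, sim.tree, schedule=MCMCSchedule(12000, 2000, 10), seed=47
    )
    lo, hi = res.odds_ratio.hdi95
    assert lo <= 9.5 <= hi
    assert res.odds_ratio.mean > 1.0
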