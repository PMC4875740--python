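"""The study analyses: morphospace, regressions, mediation, ROPE reports.

Each ``run_*`` function prepares a tidy frame from specimen- or
species-level data, fits the corresponding phylogenetic mixed model, and
wraps the posterior draws in a typed result carrying ROPE decisions
against the cascade model's point predictions:

* molar-proportion regression — between-species slope/intercept of
  M3/M1 on M2/M1, ROPEs [1.90, 2.10] and [-1.10, -0.90];
* relative M2 area — slope of M2 on total molar area, ROPE [0.323, 0.343]
  around the predicted one-third share;
* posterior-draw mediation — proportion of the M1-M3 association carried
  by M2, ROPE [0.9, 1];
* body mass on deviation from the model line; coefficient-of-variation
  contrasts; third-molar agenesis (comparative and within-species); and a
  logistic model of frugivory on M2-dominant morphospace occupancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dic_core, morphometrics
from .dic_core import MorphospaceRegion, ProportionPoint
from .pglmm import (
    FAST_BERNOULLI,
    FAST_GAUSSIAN,
    MCMCSchedule,
    PGLMM,
    PGLMMResults,
    RopeDecision,
    center_within_groups,
    hdi,
    rope_probability,
)
from .phylo import Phylogeny, covariance_from_tree

__all__ = [
    "ROPE_SLOPE",
    "ROPE_INTERCEPT",
    "ROPE_M2_SHARE",
    "ROPE_PR_M",
    "PosteriorSummary",
    "MorphospaceSummary",
    "ProportionRegressionResult",
    "M2RelativeResult",
    "MediationResult",
    "MassDeviationResult",
    "CvComparisonResult",
    "AgenesisResult",
    "DietResult",
    "AreaCorrectionResult",
    "prepare_specimens",
    "summarize_morphospace",
    "run_proportion_regression",
    "run_m2_relative",
    "run_mediation",
    "run_mass_deviation",
    "run_cv_comparison",
    "run_agenesis_anthropoid",
    "run_agenesis_human",
    "run_diet_logistic",
    "run_area_correction_check",
    "plot_morphospace",
]

#: Regions of practical equivalence around the cascade point predictions.
ROPE_SLOPE = (1.90, 2.10)
ROPE_INTERCEPT = (-1.10, -0.90)
ROPE_M2_SHARE = (0.323, 0.343)
ROPE_PR_M = (0.9, 1.0)


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    sd: float
    hdi95: tuple[float, float]

    @classmethod
    def from_draws(cls, draws) -> "PosteriorSummary":
        x = np.asarray(draws, dtype=float)
        return cls(float(x.mean()), float(x.std(ddof=1)), hdi(x))

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "hdi95": list(self.hdi95)}


def _rope(draws, interval) -> RopeDecision:
    x = np.asarray(draws, dtype=float)
    return RopeDecision(
        interval=tuple(interval),
        posterior_probability=rope_probability(x, interval),
        hdi95=hdi(x),
        posterior_mean=float(x.mean()),
    )


# ---------------------------------------------------------------------------
# preparation

def prepare_specimens(
    raw: pd.DataFrame, coefficients: dict[int, float] | None = None
):
    """Filter raw specimens and attach corrected areas and summaries.

    Returns ``(specimens, summaries, exclusion_log)``; if no shape
    coefficients are given and the table carries outline areas they are
    calibrated from it.
    """
    retained, log = morphometrics.filter_specimens(raw)
    if coefficients is None and any(
        f"m{k}_outline_area" in retained.columns for k in (1, 2, 3)
    ):
        try:
            coefficients = morphometrics.calibrate_shape_coefficients(retained)
        except ValueError:
            coefficients = None
    specimens = morphometrics.compute_specimen_areas(retained, coefficients)
    summaries = morphometrics.species_summaries(specimens)
    return specimens, summaries, log


def _clade_subset(
    specimens: pd.DataFrame,
    tree: Phylogeny,
    clade: list[str] | None,
    min_species: int = 5,
):
    """Restrict data and covariance to a named clade (or the full sample)."""
    if clade is not None:
        wanted = {str(s) for s in clade}
        specimens = specimens[specimens["species"].astype(str).isin(wanted)]
    species = sorted(specimens["species"].astype(str).unique())
    if len(species) < min_species:
        raise ValueError(
            f"clade subset retains only {len(species)} species "
            f"(need at least {min_species})"
        )
    sub_tree = tree.prune_to(species) if len(species) < tree.n_taxa else tree
    cov = covariance_from_tree(sub_tree)
    return specimens.reset_index(drop=True), cov


def _weighted_mean_map(specimens: pd.DataFrame) -> pd.DataFrame:
    """Species-level sex-pooled weighted mean areas, indexed by species."""
    return morphometrics.species_summaries(specimens).set_index("species")


# ---------------------------------------------------------------------------
# morphospace

@dataclass
class MorphospaceSummary:
    n_species: int
    n_consistent: int
    percent_consistent: float
    region_counts: dict[str, int]
    n_excluded_agenesis: int

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "n_consistent": self.n_consistent,
            "percent_consistent": self.percent_consistent,
            "region_counts": self.region_counts,
            "n_excluded_agenesis": self.n_excluded_agenesis,
        }


def summarize_morphospace(
    summaries: pd.DataFrame,
    line_tol: float = 0.0,
    tol: float = dic_core.DEFAULT_TIE_TOL,
) -> MorphospaceSummary:
    """Fraction of species centroids consistent with the cascade model.

    Species without a third molar have no centroid and are excluded from
    the denominator; the count of such exclusions is reported.
    """
    counts = {r.name: 0 for r in MorphospaceRegion}
    n_total = n_consistent = n_agenesis = 0
    for _, row in summaries.iterrows():
        try:
            point = morphometrics.species_centroid(row)
        except ValueError:
            n_agenesis += 1
            continue
        n_total += 1
        region = dic_core.classify_region(point, tol)
        if region not in (
            MorphospaceRegion.M2_PEAK,
            MorphospaceRegion.M2_TROUGH,
        ) or dic_core.perpendicular_distance(point) <= line_tol:
            n_consistent += 1
            if region in (MorphospaceRegion.M2_PEAK, MorphospaceRegion.M2_TROUGH):
                region = MorphospaceRegion.ON_LINE
        counts[region.name] += 1
    if n_total == 0:
        raise ValueError("no species with all three molar areas")
    return MorphospaceSummary(
        n_species=n_total,
        n_consistent=n_consistent,
        percent_consistent=100.0 * n_consistent / n_total,
        region_counts=counts,
        n_excluded_agenesis=n_agenesis,
    )


# ---------------------------------------------------------------------------
# molar proportion regression

@dataclass
class ProportionRegressionResult:
    slope_between: RopeDecision
    intercept: RopeDecision
    slope_within: PosteriorSummary
    lam: PosteriorSummary
    fit: PGLMMResults

    def to_dict(self) -> dict:
        return {
            "slope_between": {
                "mean": self.slope_between.posterior_mean,
                "hdi95": list(self.slope_between.hdi95),
                "rope": list(self.slope_between.interval),
                "rope_probability": self.slope_between.posterior_probability,
            },
            "intercept": {
                "mean": self.intercept.posterior_mean,
                "hdi95": list(self.intercept.hdi95),
                "rope": list(self.intercept.interval),
                "rope_probability": self.intercept.posterior_probability,
            },
            "slope_within": self.slope_within.to_dict(),
            "lambda": self.lam.to_dict(),
        }


def _ratio_frame(
    specimens: pd.DataFrame, between: str = "ratio_of_means"
) -> pd.DataFrame:
    """Specimen-level proportions with species baselines.

    The between-species value of M2/M1 is the ratio of sex-pooled weighted
    mean areas (default) or, with ``between="mean_of_ratios"``, the plain
    mean of specimen-level ratios; the within deviation is the specimen
    ratio minus the species value either way.
    """
    if between not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError("between must be 'ratio_of_means' or 'mean_of_ratios'")
    means = _weighted_mean_map(specimens)
    df = specimens.dropna(
        subset=["m1_area", "m2_area", "m3_area"]
    ).copy()
    df = df[~df["species"].map(means["m3_agenesis"]).astype(bool)]
    df["m3m1_spec"] = df["m3_area"] / df["m1_area"]
    ratio_spec = df["m2_area"] / df["m1_area"]
    if between == "ratio_of_means":
        df["m2m1_between"] = df["species"].map(means["m2m1"])
    else:
        df["m2m1_between"], _ = center_within_groups(
            ratio_spec.to_numpy(), df["species"].to_numpy()
        )
    df["m2m1_within"] = ratio_spec - df["m2m1_between"]
    return df


def run_proportion_regression(
    specimens: pd.DataFrame,
    tree: Phylogeny,
    clade: list[str] | None = None,
    schedule: MCMCSchedule | None = None,
    seed: int = 0,
    rope_slope=ROPE_SLOPE,
    rope_intercept=ROPE_INTERCEPT,
    between: str = "ratio_of_means",
) -> ProportionRegressionResult:
    """Specimen-level regression of M3/M1 on between/within-split M2/M1.

    The cascade model predicts a between-species slope of 2 and intercept
    of -1; posterior mass inside the ROPEs quantifies practical agreement.
    ``between`` selects how the species-level M2/M1 is formed (ratio of
    weighted mean areas, or mean of specimen ratios).
    """
    data, cov = _clade_subset(specimens, tree, clade)
    frame = _ratio_frame(data, between=between)
    model = PGLMM.from_dataframe(
        frame,
        response="m3m1_spec",
        terms=[("m2m1_between", "plain"), ("m2m1_within", "plain")],
        covariance=cov.reorder(sorted(frame["species"].unique())),
        random=("phylo", "species"),
    )
    fit = model.fit(schedule or FAST_GAUSSIAN, seed=seed)
    return ProportionRegressionResult(
        slope_between=_rope(fit.draws["m2m1_between"], rope_slope),
        intercept=_rope(fit.draws["intercept"], rope_intercept),
        slope_within=PosteriorSummary.from_draws(fit.draws["m2m1_within"]),
        lam=PosteriorSummary.from_draws(fit.draws["lambda"]),
        fit=fit,
    )


# ---------------------------------------------------------------------------
# relative M2 area

@dataclass
class M2RelativeResult:
    slope_between: RopeDecision
    slope_within: PosteriorSummary
    lam: PosteriorSummary
    fit: PGLMMResults

    def to_dict(self) -> dict:
        return {
            "slope_between": {
                "mean": self.slope_between.posterior_mean,
                "hdi95": list(self.slope_between.hdi95),
                "rope": list(self.slope_between.interval),
                "rope_probability": self.slope_between.posterior_probability,
            },
            "slope_within": self.slope_within.to_dict(),
            "lambda": self.lam.to_dict(),
        }


def run_m2_relative(
    specimens: pd.DataFrame,
    tree: Phylogeny,
    clade: list[str] | None = None,
    schedule: MCMCSchedule | None = None,
    seed: int = 0,
    rope=ROPE_M2_SHARE,
) -> M2RelativeResult:
    """Regression of M2 area on total molar area (predicted slope 1/3)."""
    data, cov = _clade_subset(specimens, tree, clade)
    means = _weighted_mean_map(data)
    df = data.dropna(subset=["m1_area", "m2_area", "m3_area"]).copy()
    df = df[~df["species"].map(means["m3_agenesis"]).astype(bool)]
    total_spec = df["m1_area"] + df["m2_area"] + df["m3_area"]
    df["mt_between"] = df["species"].map(means["total_area"])
    df["mt_within"] = total_spec - df["mt_between"]
    model = PGLMM.from_dataframe(
        df,
        response="m2_area",
        terms=[("mt_between", "plain"), ("mt_within", "plain")],
        covariance=cov.reorder(sorted(df["species"].unique())),
        random=("phylo", "species"),
    )
    fit = model.fit(schedule or FAST_GAUSSIAN, seed=seed)
    return M2RelativeResult(
        slope_between=_rope(fit.draws["mt_between"], rope),
        slope_within=PosteriorSummary.from_draws(fit.draws["mt_within"]),
        lam=PosteriorSummary.from_draws(fit.draws["lambda"]),
        fit=fit,
    )


# ---------------------------------------------------------------------------
# mediation

@dataclass
class MediationResult:
    """Posterior mediation decomposition of the M1-to-M3 association.

    Per retained draw t: ab(t) = beta_2B(t) * beta'_1B(t) is the indirect
    effect through M2, |c'|(t) = |beta_1B(t)| the direct effect, and
    pr_m(t) = ab/(ab + |c'|) the proportion mediated.
    """

    ab: PosteriorSummary
    c_prime_abs: PosteriorSummary
    pr_m: RopeDecision
    ab_hat: float  # mean-of-draws point estimates
    c_prime_hat: float
    pr_m_hat: float
    draws: pd.DataFrame = field(repr=False)
    outcome_fit: PGLMMResults = field(repr=False)
    mediator_fit: PGLMMResults = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "ab": self.ab.to_dict(),
            "c_prime_abs": self.c_prime_abs.to_dict(),
            "pr_m": {
                "mean": self.pr_m.posterior_mean,
                "hdi95": list(self.pr_m.hdi95),
                "rope": list(self.pr_m.interval),
                "rope_probability": self.pr_m.posterior_probability,
            },
            "point_estimates": {
                "ab_hat": self.ab_hat,
                "c_prime_hat": self.c_prime_hat,
                "pr_m_hat": self.pr_m_hat,
            },
        }


def mediation_from_draws(
    beta_1b, beta_2b, beta_1b_prime, rope=ROPE_PR_M
) -> tuple[pd.DataFrame, dict]:
    """Per-draw mediation algebra from the two fits' slope draws."""
    b1 = np.asarray(beta_1b, dtype=float)
    b2 = np.asarray(beta_2b, dtype=float)
    b1p = np.asarray(beta_1b_prime, dtype=float)
    if not (b1.size == b2.size == b1p.size):
        raise ValueError(
            "mediation needs equal retained-draw counts from both fits"
        )
    ab = b2 * b1p
    c_abs = np.abs(b1)
    pr_m = ab / (ab + c_abs)
    ab_hat, c_hat = float(ab.mean()), float(c_abs.mean())
    point = {
        "ab_hat": ab_hat,
        "c_prime_hat": c_hat,
        "pr_m_hat": ab_hat / (ab_hat + c_hat),
    }
    return pd.DataFrame({"ab": ab, "c_prime_abs": c_abs, "pr_m": pr_m}), point


def run_mediation(
    specimens: pd.DataFrame,
    tree: Phylogeny,
    clade: list[str] | None = None,
    schedule: MCMCSchedule | None = None,
    seed: int = 0,
    rope=ROPE_PR_M,
) -> MediationResult:
    """How much of the M1-M3 area relationship is mediated by M2.

    Fits the outcome model (M3 on M1 and M2, between/within split) and the
    mediator model (M2 on M1), then combines their slope draws per
    iteration.  Under a strict cascade, pr_m = 1.
    """
    data, cov = _clade_subset(specimens, tree, clade)
    means = _weighted_mean_map(data)
    df = data.dropna(subset=["m1_area", "m2_area", "m3_area"]).copy()
    df = df[~df["species"].map(means["m3_agenesis"]).astype(bool)]
    for k in (1, 2):
        df[f"m{k}_between"] = df["species"].map(means[f"mean_area_{k}"])
        df[f"m{k}_within"] = df[f"m{k}_area"] - df[f"m{k}_between"]
    cov = cov.reorder(sorted(df["species"].unique()))
    sched = schedule or FAST_GAUSSIAN

    outcome = PGLMM.from_dataframe(
        df,
        response="m3_area",
        terms=[
            ("m1_between", "plain"),
            ("m1_within", "plain"),
            ("m2_between", "plain"),
            ("m2_within", "plain"),
        ],
        covariance=cov,
        random=("phylo", "species"),
    ).fit(sched, seed=seed)
    mediator = PGLMM.from_dataframe(
        df,
        response="m2_area",
        terms=[("m1_between", "plain"), ("m1_within", "plain")],
        covariance=cov,
        random=("phylo", "species"),
    ).fit(sched, seed=seed + 1)

    draws, point = mediation_from_draws(
        outcome.draws["m1_between"],
        outcome.draws["m2_between"],
        mediator.draws["m1_between"],
        rope,
    )
    return MediationResult(
        ab=PosteriorSummary.from_draws(draws["ab"]),
        c_prime_abs=PosteriorSummary.from_draws(draws["c_prime_abs"]),
        pr_m=_rope(draws["pr_m"], rope),
        ab_hat=point["ab_hat"],
        c_prime_hat=point["c_prime_hat"],
        pr_m_hat=point["pr_m_hat"],
        draws=draws,
        outcome_fit=outcome,
        mediator_fit=mediator,
    )


# ---------------------------------------------------------------------------
# body mass vs deviation from the model line

@dataclass
class MassDeviationResult:
    slope_between: PosteriorSummary
    slope_within: PosteriorSummary
    lam: PosteriorSummary
    fit: PGLMMResults

    def to_dict(self) -> dict:
        return {
            "slope_between": self.slope_between.to_dict(),
            "slope_within": self.slope_within.to_dict(),
            "lambda": self.lam.to_dict(),
        }


def run_mass_deviation(
    specimens: pd.DataFrame,
    tree: Phylogeny,
    clade: list[str] | None = None,
    exclude: list[str] | None = None,
    schedule: MCMCSchedule | None = None,
    seed: int = 0,
) -> MassDeviationResult:
    """ln(body mass) on absolute perpendicular deviation from the line.

    The species-level response (log mean body mass) is replicated across
    its specimens; the specimen-level deviations are between/within split.
    ``exclude`` drops named species (e.g. a deviant small-bodied clade)
    before fitting.
    """
    if exclude:
        drop = {str(s) for s in exclude}
        specimens = specimens[~specimens["species"].astype(str).isin(drop)]
    data, cov = _clade_subset(specimens, tree, clade)
    df = data.dropna(
        subset=["m1_area", "m2_area", "m3_area", "body_mass_kg"]
    ).copy()
    point = np.abs(
        2.0 * df["m2_area"] / df["m1_area"]
        - df["m3_area"] / df["m1_area"]
        - 1.0
    ) / np.sqrt(5.0)
    between, within = center_within_groups(
        point.to_numpy(), df["species"].to_numpy()
    )
    df["dev_between"] = between
    df["dev_within"] = within
    df["ln_mass"] = np.log(
        df.groupby("species")["body_mass_kg"].transform("mean")
    )
    model = PGLMM.from_dataframe(
        df,
        response="ln_mass",
        terms=[("dev_between", "plain"), ("dev_within", "plain")],
        covariance=cov.reorder(sorted(df["species"].unique())),
        random=("phylo", "species"),
    )
    fit = model.fit(schedule or FAST_GAUSSIAN, seed=seed)
    return MassDeviationResult(
        slope_between=PosteriorSummary.from_draws(fit.draws["dev_between"]),
        slope_within=PosteriorSummary.from_draws(fit.draws["dev_within"]),
        lam=PosteriorSummary.from_draws(fit.draws["lambda"]),
        fit=fit,
    )


# ---------------------------------------------------------------------------
# coefficient-of-variation comparison

@dataclass
class CvComparisonResult:
    diff_m3_m1: PosteriorSummary
    diff_m3_m2: PosteriorSummary
    lam: PosteriorSummary
    fit: PGLMMResults

    def to_dict(self) -> dict:
        return {
            "diff_m3_m1": self.diff_m3_m1.to_dict(),
            "diff_m3_m2": self.diff_m3_m2.to_dict(),
            "lambda": self.lam.to_dict(),
        }


def run_cv_comparison(
    summaries: pd.DataFrame,
    tree: Phylogeny,
    schedule: MCMCSchedule | None = None,
    seed: int = 0,
) -> CvComparisonResult:
    """Is the third molar the most size-variable tooth?

    Stacks the per-species small-sample CVs of the three molars with
    indicator coding (M3 as the reference level) and reports the M3-M1 and
    M3-M2 differences.  Species without a third molar contribute no CVs
    and are skipped; a missing CV on a molar that exists is an error.
    """
    rows = []
    for _, s in summaries.iterrows():
        if bool(s.get("m3_agenesis", False)):
            continue
        cvs = [s.get(f"cv_{k}") for k in (1, 2, 3)]
        if any(cv is None or not np.isfinite(cv) for cv in cvs):
            raise ValueError(
                f"species {s['species']!r} is missing a molar CV"
            )
        for k, cv in zip((1, 2, 3), cvs):
            rows.append(
                {
                    "species": s["species"],
                    "cv": cv,
                    "is_m1": 1.0 if k == 1 else 0.0,
                    "is_m2": 1.0 if k == 2 else 0.0,
                }
            )
    df = pd.DataFrame(rows)
    cov = covariance_from_tree(tree).reorder(sorted(df["species"].unique()))
    model = PGLMM.from_dataframe(
        df,
        response="cv",
        terms=[("is_m1", "indicator"), ("is_m2", "indicator")],
        covariance=cov,
        random=("phylo", "species"),
    )
    fit = model.fit(schedule or FAST_GAUSSIAN, seed=seed)
    return CvComparisonResult(
        diff_m3_m1=PosteriorSummary.from_draws(-fit.draws["is_m1"]),
        diff_m3_m2=PosteriorSummary.from_draws(-fit.draws["is_m2"]),
        lam=PosteriorSummary.from_draws(fit.draws["lambda"]),
        fit=fit,
    )


# ---------------------------------------------------------------------------
# third-molar agenesis

@dataclass
class AgenesisResult:
    m2m1_agenesis: PosteriorSummary
    m2m1_retained: PosteriorSummary
    difference: PosteriorSummary
    prob_below_half: float
    fit: PGLMMResults

    def to_dict(self) -> dict:
        return {
            "m2m1_agenesis": self.m2m1_agenesis.to_dict(),
            "m2m1_retained": self.m2m1_retained.to_dict(),
            "difference": self.difference.to_dict(),
            "prob_below_half": self.prob_below_half,
        }


def _agenesis_result(fit: PGLMMResults) -> AgenesisResult:
    ag = fit.draws["agenesis"].to_numpy()
    re = fit.draws["retained"].to_numpy()
    return AgenesisResult(
        m2m1_agenesis=PosteriorSummary.from_draws(ag),
        m2m1_retained=PosteriorSummary.from_draws(re),
        difference=PosteriorSummary.from_draws(ag - re),
        prob_below_half=float(np.mean(ag < 0.5)),
        fit=fit,
    )


def run_agenesis_anthropoid(
    summaries: pd.DataFrame,
    tree: Phylogeny,
    schedule: MCMCSchedule | None = None,
    seed: int = 0,
) -> AgenesisResult:
    """Does comparative third-molar loss line up with M2/M1 < 0.5?

    Cell-means coding (no intercept): one mean for agenesis species, one
    for species retaining M3, with phylogenetic and species random
    effects.  ``prob_below_half`` is the posterior probability that the
    agenesis-group mean is below the predicted threshold of one half.
    """
    df = summaries[["species", "m2m1", "m3_agenesis"]].dropna(
        subset=["m2m1"]
    ).copy()
    flags = df["m3_agenesis"].astype(bool)
    if not flags.any():
        raise ValueError("no species with third-molar agenesis")
    if flags.all():
        raise ValueError("no species retaining the third molar")
    df["agenesis"] = flags.astype(float)
    df["retained"] = (~flags).astype(float)
    cov = covariance_from_tree(tree).reorder(sorted(df["species"].unique()))
    model = PGLMM.from_dataframe(
        df,
        response="m2m1",
        terms=[("agenesis", "indicator"), ("retained", "indicator")],
        covariance=cov,
        random=("phylo", "species"),
        intercept=False,
    )
    return _agenesis_result(model.fit(schedule or FAST_GAUSSIAN, seed=seed))


def run_agenesis_human(
    individuals: pd.DataFrame,
    schedule: MCMCSchedule | None = None,
    seed: int = 0,
) -> AgenesisResult:
    """Within-species agenesis contrast with a population random effect."""
    df = individuals.copy()
    flags = df["m3_agenesis"].astype(bool)
    if not flags.any() or flags.all():
        raise ValueError("need both agenesis and retained individuals")
    if df["population"].nunique() < 2:
        warnings.warn(
            "single population: the population variance is unidentifiable",
            stacklevel=2,
        )
    df["agenesis"] = flags.astype(float)
    df["retained"] = (~flags).astype(float)
    model = PGLMM.from_dataframe(
        df,
        response="m2m1",
        terms=[("agenesis", "indicator"), ("retained", "indicator")],
        random=(("iid", "population"),),
        intercept=False,
    )
    return _agenesis_result(model.fit(schedule or FAST_GAUSSIAN, seed=seed))


# ---------------------------------------------------------------------------
# diet logistic model

@dataclass
class DietResult:
    odds_ratio: PosteriorSummary
    percent_increase: PosteriorSummary
    lam: PosteriorSummary
    fit: PGLMMResults

    def to_dict(self) -> dict:
        return {
            "odds_ratio": self.odds_ratio.to_dict(),
            "percent_increase": self.percent_increase.to_dict(),
            "lambda": self.lam.to_dict(),
        }


def run_diet_logistic(
    summaries: pd.DataFrame,
    tree: Phylogeny,
    schedule: MCMCSchedule | None = None,
    seed: int = 0,
) -> DietResult:
    """Odds of occupying the M1<M2>M3 region for frugivorous species.

    Bernoulli logit-link model of M2-peak morphospace membership on a
    frugivore indicator; the odds ratio exp(beta_fruit) and its percent
    increase (OR - 1) * 100 are computed per draw.
    """
    rows = []
    for _, s in summaries.iterrows():
        try:
            point = morphometrics.species_centroid(s)
        except ValueError:
            continue
        region = dic_core.classify_region(point)
        rows.append(
            {
                "species": s["species"],
                "m2_peak": 1.0 if region is MorphospaceRegion.M2_PEAK else 0.0,
                "fruit": 1.0 if str(s.get("diet")) == "fruit" else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    if df["m2_peak"].nunique() < 2:
        warnings.warn(
            "response is constant (complete separation); the Cauchy prior "
            "regularizes but estimates are prior-driven",
            stacklevel=2,
        )
    cov = covariance_from_tree(tree).reorder(sorted(df["species"].unique()))
    model = PGLMM.from_dataframe(
        df,
        response="m2_peak",
        terms=[("fruit", "indicator")],
        covariance=cov,
        random=("phylo", "species"),
        family="bernoulli",
    )
    fit = model.fit(schedule or FAST_BERNOULLI, seed=seed)
    odds = np.exp(fit.draws["fruit"].to_numpy())
    return DietResult(
        odds_ratio=PosteriorSummary.from_draws(odds),
        percent_increase=PosteriorSummary.from_draws((odds - 1.0) * 100.0),
        lam=PosteriorSummary.from_draws(fit.draws["lambda"]),
        fit=fit,
    )


# ---------------------------------------------------------------------------
# area-correction validation

@dataclass
class AreaCorrectionResult:
    mean_oa_minus_ca: PosteriorSummary
    mean_oa_minus_ra: PosteriorSummary
    corrected_fit: PGLMMResults
    rectangular_fit: PGLMMResults

    def to_dict(self) -> dict:
        return {
            "mean_oa_minus_ca": self.mean_oa_minus_ca.to_dict(),
            "mean_oa_minus_ra": self.mean_oa_minus_ra.to_dict(),
        }


def run_area_correction_check(
    calibration: pd.DataFrame,
    schedule: MCMCSchedule | None = None,
    seed: int = 0,
) -> AreaCorrectionResult:
    """Validate the shape correction on specimens with outline areas.

    Fits one mixed model (intercept plus species random effect) per
    per-tooth difference — outline minus corrected, and outline minus
    rectangular — and reports both posterior means with HDIs; a useful
    correction leaves the first centred much nearer zero.
    """
    coeffs = morphometrics.calibrate_shape_coefficients(calibration)
    rows = []
    for _, spec in calibration.iterrows():
        for k in (1, 2, 3):
            col = f"m{k}_outline_area"
            if col not in calibration.columns or not np.isfinite(spec[col]):
                continue
            ra = morphometrics.crown_area(
                spec[f"m{k}_length"],
                spec[f"m{k}_breadth_trigonid"],
                spec[f"m{k}_breadth_talonid"],
            )
            ea = morphometrics.elliptical_area(ra)
            ca = morphometrics.corrected_area(ra, ea, coeffs[k])
            rows.append(
                {
                    "species": spec["species"],
                    "d_ca": spec[col] - ca,
                    "d_ra": spec[col] - ra,
                }
            )
    if not rows:
        raise ValueError("no outline areas in the calibration table")
    df = pd.DataFrame(rows)
    sched = schedule or FAST_GAUSSIAN
    fits = {}
    for i, resp in enumerate(("d_ca", "d_ra")):
        model = PGLMM.from_dataframe(
            df,
            response=resp,
            terms=[],
            random=(("iid", "species"),),
        )
        fits[resp] = model.fit(sched, seed=seed + i)
    return AreaCorrectionResult(
        mean_oa_minus_ca=PosteriorSummary.from_draws(
            fits["d_ca"].draws["intercept"]
        ),
        mean_oa_minus_ra=PosteriorSummary.from_draws(
            fits["d_ra"].draws["intercept"]
        ),
        corrected_fit=fits["d_ca"],
        rectangular_fit=fits["d_ra"],
    )


# ---------------------------------------------------------------------------
# plotting

def plot_morphospace(summaries: pd.DataFrame, ax=None, hull_by: str | None = None):
    """Scatter of species centroids with the cascade model line.

    Optionally draws convex hulls around groups given by a column of
    ``summaries`` (e.g. a clade label).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pts = []
    for _, row in summaries.iterrows():
        try:
            p = morphometrics.species_centroid(row)
        except ValueError:
            continue
        pts.append((p.m2m1, p.m3m1))
    pts = np.asarray(pts)
    ax.scatter(pts[:, 0], pts[:, 1], s=18, alpha=0.7, edgecolor="none")
    x = np.linspace(max(0.3, pts[:, 0].min() * 0.9), pts[:, 0].max() * 1.1, 50)
    ax.plot(x, 2.0 * x - 1.0, "k--", lw=1, label="M3/M1 = 2 M2/M1 - 1")
    if hull_by is not None and hull_by in summaries.columns:
        from scipy.spatial import ConvexHull

        for _, grp in summaries.groupby(hull_by):
            gp = []
            for _, row in grp.iterrows():
                try:
                    p = morphometrics.species_centroid(row)
                except ValueError:
                    continue
                gp.append((p.m2m1, p.m3m1))
            gp = np.asarray(gp)
            if len(gp) >= 3:
                hull = ConvexHull(gp)
                cycle = np.append(hull.vertices, hull.vertices[0])
                ax.plot(gp[cycle, 0], gp[cycle, 1], lw=0.8, alpha=0.5)
    ax.set_xlabel("M2/M1 area")
    ax.set_ylabel("M3/M1 area")
    ax.legend(frameon=False, fontsize=8)
    return ax
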