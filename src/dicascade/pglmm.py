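"""Bayesian phylogenetic generalized linear mixed models fitted by MCMC.

The model, in GLMM form, is

    y ~ D(mu, phi),   mu = g^{-1}(l),   l = X beta + Z gamma + e,

with a Gaussian identity-link family (``phi = sigma2_e`` estimated) or a
Bernoulli logit-link family (latent logistic residual with ``phi``
fixed at pi^2/3).  Random intercepts can follow a phylogenetic covariance
(``p ~ N(0, sigma2_p * Sigma)``), a species-level i.i.d. structure
(``s ~ N(0, sigma2_s * I)``) or an arbitrary i.i.d. grouping factor.
Fixed effects receive diffuse normal priors (variance 1e8) for Gaussian
responses and Cauchy priors (scale pi^2/3 + v, with v the current total
random-plus-residual variance) for Bernoulli responses.  Random-effect
variances use parameter-expanded priors (scale 1, one degree of freedom,
working parameter with mean 0 and variance 1e3).

Sampling is blocked Gibbs: all location effects are drawn jointly from
their Gaussian full conditional; variance components from inverse-gamma
full conditionals; the expansion parameters from scalar normal
conditionals; Bernoulli latent values by an elementwise random-walk
Metropolis step.  Usage follows the statsmodels pattern::

    model = PGLMM.from_dataframe(df, response="m3m1",
                                 terms=[("m2m1", "between"), ("m2m1", "within")],
                                 species="species", covariance=cov,
                                 random=("phylo", "species"))
    result = model.fit(schedule=FAST_GAUSSIAN, seed=7)
    result.summary()
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .diagnostics import HeidelbergerWelchResult, heidelberger_welch, lag_autocorrelation
from .phylo import LOGISTIC_RESIDUAL_VARIANCE, PhyloCovariance

__all__ = [
    "MCMCSchedule",
    "PriorSpec",
    "RandomTerm",
    "PGLMM",
    "PGLMMResults",
    "RopeDecision",
    "ConvergenceReport",
    "FAST_GAUSSIAN",
    "FAST_BERNOULLI",
    "STUDY_GAUSSIAN",
    "STUDY_BERNOULLI",
    "center_within_groups",
    "retained_draw_count",
    "hdi",
    "rope_probability",
]


# ---------------------------------------------------------------------------
# schedules and priors

@dataclass(frozen=True)
class MCMCSchedule:
    """Iteration, burn-in and thinning plan for one chain."""

    iterations: int
    burn_in: int
    thin: int = 1

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.iterations - self.burn_in) % self.thin:
            raise ValueError("(iterations - burn_in) must be divisible by thin")

    @property
    def retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


def retained_draw_count(schedule: MCMCSchedule) -> int:
    """Number of posterior draws a schedule retains."""
    return schedule.retained


#: Study-scale schedules (10,000 retained draws each).
STUDY_GAUSSIAN = MCMCSchedule(11_000_000, 1_000_000, 1000)
STUDY_BERNOULLI = MCMCSchedule(15_000_000, 3_000_000, 1200)

#: Desk-scale schedules, also retaining 10,000 draws.
FAST_GAUSSIAN = MCMCSchedule(110_000, 10_000, 10)
FAST_BERNOULLI = MCMCSchedule(110_000, 10_000, 10)


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters for fixed and random effects.

    ``cauchy_scale=None`` means the Bernoulli fixed-effect Cauchy scale is
    re-evaluated each iteration as pi^2/3 + v with v the current total
    random-plus-residual variance; a positive value fixes it.
    """

    fixed_effect_variance: float = 1e8
    cauchy_scale: float | None = None
    px_scale: float = 1.0
    px_dof: float = 1.0
    px_alpha_mean: float = 0.0
    px_alpha_variance: float = 1e3
    residual_shape: float = 0.001
    residual_rate: float = 0.001


# ---------------------------------------------------------------------------
# design helpers

def center_within_groups(values, groups):
    """Split a specimen-level predictor into between and within components.

    Returns ``(between, within)`` where ``between`` is the group mean
    broadcast to members and ``within`` the deviation from it; the two sum
    back to the original values and ``within`` sums to zero in each group.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    if values.size == 0:
        raise ValueError("empty input")
    ser = pd.Series(values)
    between = ser.groupby(pd.Series(groups)).transform("mean").to_numpy()
    return between, values - between


@dataclass
class RandomTerm:
    """A random-intercept term: grouping codes plus prior covariance.

    ``cov=None`` means i.i.d. levels (identity prior covariance).
    ``fix_variance`` holds the term's variance at a known value instead of
    sampling it (useful for conjugate closed-form checks).
    """

    name: str
    codes: np.ndarray  # observation -> level index
    levels: list
    cov: np.ndarray | None = None
    fix_variance: float | None = None

    @property
    def n_levels(self) -> int:
        return len(self.levels)


# ---------------------------------------------------------------------------
# posterior summaries

def hdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 draws for an HDI")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    m = int(math.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def rope_probability(draws, interval) -> float:
    """Fraction of draws inside a closed region of practical equivalence."""
    lo, hi = interval
    if not lo < hi:
        raise ValueError("ROPE interval must satisfy lo < hi")
    x = np.asarray(draws, dtype=float)
    return float(np.mean((x >= lo) & (x <= hi)))


@dataclass(frozen=True)
class RopeDecision:
    """Posterior mass inside a ROPE together with the 95 % HDI."""

    interval: tuple[float, float]
    posterior_probability: float
    hdi95: tuple[float, float]
    posterior_mean: float


@dataclass
class ConvergenceReport:
    heidelberger_welch: dict[str, HeidelbergerWelchResult]
    lag1_autocorrelation: dict[str, float]

    @property
    def all_passed(self) -> bool:
        return all(r.passed for r in self.heidelberger_welch.values())


# ---------------------------------------------------------------------------
# the model

class PGLMM:
    """Phylogenetic generalized linear mixed model.

    Parameters
    ----------
    endog : array (n,)
        Response; 0/1 for the Bernoulli family.
    exog : array (n, k)
        Fixed-effect design matrix (include the intercept column yourself
        or use :meth:`from_dataframe`).
    exog_names : list of str
    family : {"gaussian", "bernoulli"}
    random_terms : list of RandomTerm
    fix_resid_var : float, optional
        Hold the residual variance at a known value (Gaussian only; the
        Bernoulli family always fixes it at pi^2/3).
    """

    def __init__(
        self,
        endog,
        exog,
        exog_names,
        family: str = "gaussian",
        random_terms: list[RandomTerm] | None = None,
        fix_resid_var: float | None = None,
    ) -> None:
        self.y = np.asarray(endog, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.X.shape[0] != self.y.size:
            raise ValueError("endog and exog lengths differ")
        if len(exog_names) != self.X.shape[1]:
            raise ValueError("exog_names length must match design columns")
        if family not in ("gaussian", "bernoulli"):
            raise ValueError("family must be 'gaussian' or 'bernoulli'")
        if family == "bernoulli":
            if not np.isin(self.y, (0.0, 1.0)).all():
                raise ValueError("bernoulli response must be 0/1")
            fix_resid_var = LOGISTIC_RESIDUAL_VARIANCE
        self.exog_names = list(exog_names)
        self.family = family
        self.random_terms = list(random_terms or [])
        self.fix_resid_var = fix_resid_var
        for term in self.random_terms:
            if term.cov is not None:
                c = np.asarray(term.cov, dtype=float)
                if c.shape != (term.n_levels, term.n_levels):
                    raise ValueError(
                        f"random term {term.name!r}: covariance order "
                        f"{c.shape} does not match {term.n_levels} levels"
                    )

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        terms: list[tuple[str, str]],
        species: str = "species",
        covariance: PhyloCovariance | None = None,
        random: tuple = ("phylo", "species"),
        family: str = "gaussian",
        intercept: bool = True,
        fix_resid_var: float | None = None,
    ) -> "PGLMM":
        """Build the model from a tidy DataFrame.

        ``terms`` is a list of ``(column, kind)`` pairs with kind one of
        ``between`` (species mean broadcast), ``within`` (deviation from
        the species mean), ``plain`` or ``indicator`` (column used as-is).
        ``random`` may contain ``"phylo"`` (requires ``covariance``),
        ``"species"``, and ``("iid", column)`` entries.
        """
        n = len(data)
        cols, names = [], []
        if intercept:
            cols.append(np.ones(n))
            names.append("intercept")
        for col, kind in terms:
            x = data[col].to_numpy(dtype=float)
            if kind == "between":
                b, _ = center_within_groups(x, data[species].to_numpy())
                cols.append(b)
                names.append(f"{col}_between")
            elif kind == "within":
                _, w = center_within_groups(x, data[species].to_numpy())
                cols.append(w)
                names.append(f"{col}_within")
            elif kind in ("plain", "indicator"):
                cols.append(x)
                names.append(col)
            else:
                raise ValueError(f"unknown term kind {kind!r}")
        X = np.column_stack(cols)

        random_terms = []
        for spec in random:
            if spec == "phylo":
                if covariance is None:
                    raise ValueError("phylo random term requires a covariance")
                sp = data[species].astype(str)
                levels = list(covariance.taxa)
                index = {t: i for i, t in enumerate(levels)}
                from .phylo import match_taxa, normalize_label

                match_taxa(levels, sp.unique())
                codes = sp.map(lambda s: index[normalize_label(s)]).to_numpy()
                random_terms.append(
                    RandomTerm("phylo", codes, levels, covariance.matrix)
                )
            elif spec == "species":
                sp = data[species].astype(str)
                levels = sorted(sp.unique())
                index = {t: i for i, t in enumerate(levels)}
                codes = sp.map(index).to_numpy()
                random_terms.append(RandomTerm("species", codes, levels))
            elif isinstance(spec, tuple) and spec[0] == "iid":
                col = spec[1]
                g = data[col].astype(str)
                levels = sorted(g.unique())
                index = {t: i for i, t in enumerate(levels)}
                codes = g.map(index).to_numpy()
                random_terms.append(RandomTerm(col, codes, levels))
            else:
                raise ValueError(f"unknown random term {spec!r}")
        return cls(
            data[response].to_numpy(dtype=float),
            X,
            names,
            family=family,
            random_terms=random_terms,
            fix_resid_var=fix_resid_var,
        )

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        schedule: MCMCSchedule | None = None,
        seed: int | None = None,
        priors: PriorSpec = PriorSpec(),
        progress: bool = False,
    ) -> "PGLMMResults":
        if schedule is None:
            schedule = FAST_GAUSSIAN if self.family == "gaussian" else FAST_BERNOULLI
        if seed is None:
            raise ValueError("a seed is required for every fit")
        rng = np.random.default_rng(seed)

        y, X = self.y, self.X
        n, k = X.shape
        R = len(self.random_terms)
        qs = [t.n_levels for t in self.random_terms]
        p = k + sum(qs)
        offsets = np.cumsum([k] + qs)[:-1] if R else np.array([], dtype=int)

        # unscaled joint design cross-products (fixed across iterations)
        Zs = []
        for t in self.random_terms:
            Z = np.zeros((n, t.n_levels))
            Z[np.arange(n), t.codes] = 1.0
            Zs.append(Z)
        W0 = np.hstack([X] + Zs) if R else X
        A = W0.T @ W0
        W0ty = W0.T @ y

        Kinvs = []
        for t in self.random_terms:
            if t.cov is None:
                Kinvs.append(None)  # identity
            else:
                K = np.asarray(t.cov, dtype=float) + 1e-10 * np.eye(t.n_levels)
                Kinvs.append(cho_solve(cho_factor(K, lower=True), np.eye(t.n_levels)))

        gaussian = self.family == "gaussian"
        fixed_resid = self.fix_resid_var
        sigma2_e = fixed_resid if fixed_resid is not None else max(np.var(y), 1e-6)

        beta = np.zeros(k)
        xis = [np.zeros(q) for q in qs]
        alphas = np.ones(R)
        sigma2_xi = np.array(
            [
                1.0 if t.fix_variance is None else float(t.fix_variance)
                for t in self.random_terms
            ]
        )
        var_fixed = [t.fix_variance is not None for t in self.random_terms]
        omega = np.full(k, priors.fixed_effect_variance)  # per-coef prior var
        latent = y.copy() if gaussian else np.where(y > 0.5, 1.0, -1.0)

        a_xi = priors.px_dof / 2.0
        b_xi = priors.px_dof * priors.px_scale / 2.0
        alpha_prec = 1.0 / priors.px_alpha_variance

        n_store = schedule.retained
        names = (
            self.exog_names
            + [f"sigma2_{t.name}" for t in self.random_terms]
            + ["sigma2_e"]
        )
        store = np.empty((n_store, len(names)))
        stored = 0

        scale_vec = np.ones(p)
        codes = [t.codes for t in self.random_terms]
        mh_sd = 2.2  # proposal sd for the latent Metropolis step
        eye_k = np.arange(k)

        for it in range(schedule.iterations):
            # -- latent update (Bernoulli) ----------------------------------
            if not gaussian:
                eta = X @ beta
                for r in range(R):
                    eta += alphas[r] * xis[r][codes[r]]
                prop = latent + rng.normal(0.0, mh_sd, size=n)
                def _logp(l):
                    return (
                        -0.5 * (l - eta) ** 2 / sigma2_e
                        + y * l
                        - np.log1p(np.exp(-np.abs(l)))
                        - np.maximum(l, 0.0)
                    )
                accept = np.log(rng.random(n)) < _logp(prop) - _logp(latent)
                latent = np.where(accept, prop, latent)
                W0ty = W0.T @ latent
                target = latent
            else:
                target = y

            # -- joint location update --------------------------------------
            for r in range(R):
                scale_vec[offsets[r] : offsets[r] + qs[r]] = alphas[r]
            M = A * np.outer(scale_vec, scale_vec)
            M /= sigma2_e
            b = (W0ty * scale_vec) / sigma2_e
            M[eye_k, eye_k] += 1.0 / omega
            for r in range(R):
                sl = slice(offsets[r], offsets[r] + qs[r])
                if Kinvs[r] is None:
                    M[sl, sl][np.arange(qs[r]), np.arange(qs[r])] += 1.0 / sigma2_xi[r]
                else:
                    M[sl, sl] += Kinvs[r] / sigma2_xi[r]
            L, low = cho_factor(M, lower=True, overwrite_a=True, check_finite=False)
            mean = cho_solve((L, low), b, check_finite=False)
            z = rng.standard_normal(p)
            theta = mean + solve_triangular(
                L, z, trans="T", lower=True, check_finite=False
            )
            beta = theta[:k]
            for r in range(R):
                xis[r] = theta[offsets[r] : offsets[r] + qs[r]]

            # -- fitted values and residual variance ------------------------
            fitted = X @ beta
            for r in range(R):
                fitted += alphas[r] * xis[r][codes[r]]
            resid = target - fitted
            if fixed_resid is None:
                rss = float(resid @ resid)
                sigma2_e = (priors.residual_rate + 0.5 * rss) / rng.gamma(
                    priors.residual_shape + 0.5 * n
                )

            # -- expansion parameters and variance components ---------------
            for r in range(R):
                if var_fixed[r]:
                    continue  # variance held: alpha stays 1, no IG update
                v = xis[r][codes[r]]
                partial = resid + alphas[r] * v
                prec = float(v @ v) / sigma2_e + alpha_prec
                mu = (float(v @ partial) / sigma2_e + alpha_prec * priors.px_alpha_mean) / prec
                alphas[r] = mu + rng.standard_normal() / math.sqrt(prec)
                resid = partial - alphas[r] * v
                if Kinvs[r] is None:
                    quad = float(xis[r] @ xis[r])
                else:
                    quad = float(xis[r] @ (Kinvs[r] @ xis[r]))
                sigma2_xi[r] = (b_xi + 0.5 * quad) / rng.gamma(a_xi + 0.5 * qs[r])

            # -- fixed-effect prior scale -----------------------------------
            if gaussian:
                pass  # omega constant (diffuse normal)
            else:
                v_total = sigma2_e + sum(
                    alphas[r] ** 2 * sigma2_xi[r] for r in range(R)
                )
                gb = (
                    priors.cauchy_scale
                    if priors.cauchy_scale is not None
                    else LOGISTIC_RESIDUAL_VARIANCE + v_total
                )
                omega = (gb**2 + beta**2) / (2.0 * rng.gamma(1.0, size=k))

            # -- record ------------------------------------------------------
            if it >= schedule.burn_in and (it - schedule.burn_in) % schedule.thin == 0:
                row = store[stored]
                row[:k] = beta
                for r in range(R):
                    row[k + r] = alphas[r] ** 2 * sigma2_xi[r]
                row[k + R] = sigma2_e
                stored += 1

        draws = pd.DataFrame(store[:stored], columns=names)
        if any(t.name == "phylo" for t in self.random_terms):
            others = [
                f"sigma2_{t.name}" for t in self.random_terms if t.name != "phylo"
            ]
            denom = draws["sigma2_phylo"] + draws["sigma2_e"]
            for c in others:
                denom = denom + draws[c]
            draws["lambda"] = draws["sigma2_phylo"] / denom
        return PGLMMResults(self, draws, schedule, seed)


def fit_from_config(config, data: pd.DataFrame, covariance=None) -> "PGLMMResults":
    """Fit a model described by a YAML/dict configuration.

    Keys: ``response``; ``terms`` (list of ``[column, kind]``);
    ``family``; ``random`` (list of ``"phylo"``/``"species"`` or
    ``["iid", column]``); ``intercept``; ``species``; ``schedule``
    (mapping with iterations/burn_in/thin); ``seed`` (required); and
    optional ``priors`` overrides matching :class:`PriorSpec` fields.
    """
    if isinstance(config, str):
        import yaml

        config = yaml.safe_load(config)
    random = tuple(
        tuple(r) if isinstance(r, list) else r for r in config.get("random", [])
    )
    model = PGLMM.from_dataframe(
        data,
        response=config["response"],
        terms=[tuple(t) for t in config.get("terms", [])],
        species=config.get("species", "species"),
        covariance=covariance,
        random=random,
        family=config.get("family", "gaussian"),
        intercept=config.get("intercept", True),
    )
    sched_cfg = config.get("schedule")
    schedule = MCMCSchedule(**sched_cfg) if sched_cfg else None
    priors = PriorSpec(**config.get("priors", {}))
    return model.fit(schedule, seed=config["seed"], priors=priors)


class PGLMMResults:
    """Posterior sample and summaries from a fitted :class:`PGLMM`."""

    def __init__(self, model: PGLMM, draws: pd.DataFrame, schedule, seed) -> None:
        self.model = model
        self.draws = draws
        self.schedule = schedule
        self.seed = seed

    @property
    def parameter_names(self) -> list[str]:
        return list(self.draws.columns)

    def posterior_mean(self, name: str) -> float:
        return float(self.draws[name].mean())

    def hdi(self, name: str, mass: float = 0.95) -> tuple[float, float]:
        return hdi(self.draws[name].to_numpy(), mass)

    def rope(self, name: str, interval) -> RopeDecision:
        x = self.draws[name].to_numpy()
        return RopeDecision(
            interval=tuple(interval),
            posterior_probability=rope_probability(x, interval),
            hdi95=hdi(x),
            posterior_mean=float(x.mean()),
        )

    def convergence(self) -> ConvergenceReport:
        hw, ac = {}, {}
        for name in self.draws.columns:
            x = self.draws[name].to_numpy()
            hw[name] = heidelberger_welch(x)
            ac[name] = lag_autocorrelation(x, 1)
        return ConvergenceReport(hw, ac)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.draws.columns:
            x = self.draws[name].to_numpy()
            lo, hi = hdi(x)
            rows.append(
                {
                    "parameter": name,
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    "hdi95_lo": lo,
                    "hdi95_hi": hi,
                    "lag1_autocorr": lag_autocorrelation(x, 1),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def save(self, prefix) -> None:
        """Write draws as CSV plus a JSON sidecar (schedule, seed, convergence)."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.draws.to_csv(f"{prefix}_draws.csv", index=False)
        report = self.convergence()
        meta = {
            "family": self.model.family,
            "seed": self.seed,
            "schedule": asdict(self.schedule),
            "convergence": {
                name: {
                    "heidelberger_welch_passed": hw.passed,
                    "pvalue": hw.pvalue,
                    "lag1_autocorrelation": report.lag1_autocorrelation[name],
                }
                for name, hw in report.heidelberger_welch.items()
            },
        }
        Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<PGLMMResults family={self.model.family} "
            f"draws={len(self.draws)} seed={self.seed}>"
        )
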