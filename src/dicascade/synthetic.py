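"""Synthetic phylogenies and morphometric datasets with known ground truth.

Emulates the statistical structure the analyses assume: a pure-birth
ultrametric phylogeny; species log activation/inhibition ratios evolving
with tunable phylogenetic signal (a Pagel-transform blend of the Brownian
covariance with the identity); species mean molar areas generated from the
cascade identities ``(1, a/i, 2(a/i)-1)`` scaled by an evolving M1 size,
with optional clade-specific M2 inflation as a controlled violation;
specimen-level multiplicative lognormal noise and sex dimorphism; diet
labels whose odds of frugivory shift when M2 is the largest molar; and
third-molar agenesis.  Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import dic_core
from .phylo import Phylogeny, covariance_from_tree, normalize_label

__all__ = [
    "SimulationConfig",
    "SimulatedData",
    "simulate_tree",
    "simulate_species_traits",
    "simulate_specimens",
    "simulate_dataset",
    "simulate_strict_mediation",
    "simulate_human_agenesis",
]


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 100 species, ~29 specimens each.

    ``ai_log_sd`` is the Brownian root-to-tip standard deviation of
    log(a/i); ``lambda_true`` blends the phylogenetic covariance with the
    identity and is the estimand of the phylogenetic-signal summary.
    ``m2_inflation`` multiplies M2 areas inside one clade (the internal
    node whose tip count is closest to ``m2_inflation_clade_fraction`` of
    the species), producing a controlled cascade violation.
    """

    n_species: int = 100
    n_specimens_per_species: int = 29
    tree_model: str = "pure_birth"  # or a newick string
    lambda_true: float = 1.0
    ai_log_mean: float = 0.0
    ai_log_sd: float = 0.25
    m1_log_mean: float = 3.4  # ~30 mm^2
    m1_log_sd: float = 0.5
    m2_inflation: float = 1.0
    m2_inflation_clade_fraction: float = 0.3
    specimen_cv: float = 0.05
    sex_dimorphism: float = 1.05
    diet_or_true: float = 9.5
    diet_base_rate: float = 0.3
    agenesis_rule: str = "dic_threshold"  # or "independent"
    agenesis_p: float = 0.02
    wear_rate: float = 0.04
    indeterminate_sex_rate: float = 0.01
    zoo_rate: float = 0.002
    mass_log_intercept: float = 2.0  # ln kg at the mean M1 size
    mass_log_slope: float = 1.4
    mass_log_sd: float = 0.3
    seed: int = 0


def simulate_tree(n_species: int, seed: int) -> Phylogeny:
    """Pure-birth ultrametric tree with height normalised to one."""
    if n_species < 3:
        raise ValueError("need at least 3 species")
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=_random.Random(int(seed)),
    )
    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height
    return Phylogeny(tree)._validate()


def _inflation_clade(tree: Phylogeny, fraction: float) -> list[str]:
    """Tips of the internal node whose clade size best matches ``fraction``."""
    n = tree.n_taxa
    target = max(2, round(fraction * n))
    best, best_tips = None, []
    for node in tree.tree.preorder_internal_node_iter():
        tips = [l.taxon.label for l in node.leaf_iter()]
        if len(tips) >= n:
            continue
        score = abs(len(tips) - target)
        if best is None or score < best:
            best, best_tips = score, tips
    return [normalize_label(t) for t in best_tips]


def simulate_species_traits(
    tree: Phylogeny, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Species-level latent values: a/i, mean areas, diet, agenesis, mass."""
    cov = covariance_from_tree(tree)
    taxa = cov.taxa
    n = len(taxa)
    lam = config.lambda_true
    blended = lam * cov.matrix + (1.0 - lam) * np.eye(n)
    L = np.linalg.cholesky(blended + 1e-10 * np.eye(n))

    log_ai = config.ai_log_mean + config.ai_log_sd * (L @ rng.standard_normal(n))
    log_m1 = config.m1_log_mean + config.m1_log_sd * (L @ rng.standard_normal(n))
    ai = np.exp(log_ai)
    m1 = np.exp(log_m1)

    inflated = set()
    if config.m2_inflation != 1.0:
        inflated = set(_inflation_clade(tree, config.m2_inflation_clade_fraction))

    if config.agenesis_rule == "dic_threshold":
        agenesis = ai < dic_core.agenesis_threshold_ratio()
    elif config.agenesis_rule == "independent":
        agenesis = rng.random(n) < config.agenesis_p
    else:
        raise ValueError(f"unknown agenesis rule {config.agenesis_rule!r}")

    m2 = m1 * ai
    m2 = np.where([t in inflated for t in taxa], m2 * config.m2_inflation, m2)
    m3_rel = np.maximum(2.0 * ai - 1.0, 0.0)
    m3 = np.where(agenesis, np.nan, m1 * m3_rel)

    m2_largest = (m2 > m1) & (np.nan_to_num(m3, nan=-np.inf) < m2)
    base_logit = np.log(config.diet_base_rate / (1.0 - config.diet_base_rate))
    logit = base_logit + np.log(config.diet_or_true) * m2_largest
    frugivore = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    other_diets = np.array(["leaves", "insects", "seeds", "omnivore"])
    diet = np.where(frugivore, "fruit", other_diets[rng.integers(0, 4, size=n)])

    centered_logm1 = log_m1 - config.m1_log_mean
    log_mass = (
        config.mass_log_intercept
        + config.mass_log_slope * centered_logm1
        + config.mass_log_sd * rng.standard_normal(n)
    )

    return pd.DataFrame(
        {
            "species": taxa,
            "ai_ratio": ai,
            "mean_m1": m1,
            "mean_m2": m2,
            "mean_m3": m3,
            "m3_agenesis": agenesis,
            "m2_inflated": [t in inflated for t in taxa],
            "diet": diet,
            "body_mass_kg": np.exp(log_mass),
        }
    )


def simulate_specimens(
    traits: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Specimen rows with lengths and breadths that round-trip to areas.

    Each molar area is the species mean times lognormal noise (median one,
    coefficient of variation ``specimen_cv``) times a sex factor
    (sqrt(dimorphism) for males, its inverse for females).  Areas are
    decomposed as length = sqrt(area * aspect) and mean breadth =
    area/length with a per-species aspect ratio, splitting the breadth
    unevenly between trigonid and talonid, so the rectangular crown-area
    computation recovers the simulated area exactly.
    """
    sigma = float(np.sqrt(np.log1p(config.specimen_cv**2)))
    male_f = float(np.sqrt(config.sex_dimorphism))
    rows = []
    for trait in traits.itertuples(index=False):
        aspect = rng.uniform(1.05, 1.30)
        split = rng.uniform(0.0, 0.08)
        for j in range(config.n_specimens_per_species):
            sex = "male" if j % 2 == 0 else "female"
            if rng.random() < config.indeterminate_sex_rate:
                sex = "indeterminate"
            wear = "high" if rng.random() < config.wear_rate else "acceptable"
            provenance = "zoo" if rng.random() < config.zoo_rate else "wild"
            sex_factor = male_f if sex == "male" else 1.0 / male_f
            row = {
                "species": trait.species,
                "sex": sex,
                "wear": wear,
                "provenance": provenance,
                "body_mass_kg": trait.body_mass_kg,
                "diet": trait.diet,
                "m3_agenesis": bool(trait.m3_agenesis),
            }
            for k, mean in (
                (1, trait.mean_m1),
                (2, trait.mean_m2),
                (3, trait.mean_m3),
            ):
                if not np.isfinite(mean):
                    row[f"m{k}_length"] = np.nan
                    row[f"m{k}_breadth_trigonid"] = np.nan
                    row[f"m{k}_breadth_talonid"] = np.nan
                    continue
                area = mean * np.exp(sigma * rng.standard_normal()) * sex_factor
                length = np.sqrt(area * aspect)
                breadth = area / length
                row[f"m{k}_length"] = length
                row[f"m{k}_breadth_trigonid"] = breadth * (1.0 + split)
                row[f"m{k}_breadth_talonid"] = breadth * (1.0 - split)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SimulatedData:
    """A generated study: tree, specimen table, latent truth, parameters."""

    tree: Phylogeny
    specimens: pd.DataFrame
    traits: pd.DataFrame
    config: SimulationConfig

    def ground_truth(self) -> dict:
        truth = asdict(self.config)
        truth["proportion_slope"] = 2.0
        truth["proportion_intercept"] = -1.0
        truth["m2_share_of_total"] = 1.0 / 3.0
        return truth

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.specimens.to_csv(directory / "specimens.csv", index=False)
        self.traits.to_csv(directory / "species_truth.csv", index=False)
        (directory / "tree.nwk").write_text(self.tree.write_newick() + "\n")
        (directory / "ground_truth.json").write_text(
            json.dumps(self.ground_truth(), indent=2, default=str)
        )


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedData:
    """Full pipeline: tree, species traits, specimen table."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    if config.tree_model == "pure_birth":
        tree = simulate_tree(config.n_species, config.seed)
    else:
        tree = Phylogeny.from_string(config.tree_model)
    traits = simulate_species_traits(tree, config, rng)
    specimens = simulate_specimens(traits, config, rng)
    return SimulatedData(tree, specimens, traits, config)


def simulate_strict_mediation(
    n_species: int,
    tree: Phylogeny | None = None,
    seed: int = 0,
    n_specimens: int = 10,
    m1_mean: float = 10.0,
    m1_sd: float = 2.5,
    a_coef: float = 1.1,
    b_coef: float = 1.2,
    direct_coef: float = 0.0,
    mediator_noise_sd: float = 1.0,
    outcome_noise_sd: float = 0.3,
    specimen_cv: float = 0.05,
) -> SimulatedData:
    """Dataset in which M3 depends on M1 only through M2 (pr_m = 1).

    Species mean areas follow M2 = a*M1 + noise and
    M3 = b*M2 + direct*M1 + noise; with ``direct_coef`` zero the entire
    M1-to-M3 association is carried by the mediator.  The mediator noise
    is kept comparable to the M1 spread so the direct path is
    identifiable: with nearly collinear species means the posterior of
    the direct slope widens and its folded mean |c'| is inflated purely
    by design conditioning, not by a true direct effect.  Setting ``b_coef=0``
    with a nonzero ``direct_coef`` gives the direct-path-only variant
    (pr_m = 0).
    """
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = simulate_tree(n_species, seed)
    taxa = tree.taxa
    m1 = np.maximum(m1_mean + m1_sd * rng.standard_normal(n_species), 1.0)
    m2 = np.maximum(
        a_coef * m1 + mediator_noise_sd * rng.standard_normal(n_species), 0.5
    )
    m3 = np.maximum(
        b_coef * m2
        + direct_coef * m1
        + outcome_noise_sd * rng.standard_normal(n_species),
        0.1,
    )
    traits = pd.DataFrame(
        {
            "species": taxa,
            "mean_m1": m1,
            "mean_m2": m2,
            "mean_m3": m3,
            "ai_ratio": m2 / m1,
            "m3_agenesis": False,
            "m2_inflated": False,
            "diet": "fruit",
            "body_mass_kg": 5.0,
        }
    )
    config = SimulationConfig(
        n_species=n_species,
        n_specimens_per_species=n_specimens,
        specimen_cv=specimen_cv,
        sex_dimorphism=1.0,
        wear_rate=0.0,
        indeterminate_sex_rate=0.0,
        zoo_rate=0.0,
        seed=seed,
    )
    specimens = simulate_specimens(traits, config, rng)
    return SimulatedData(tree, specimens, traits, config)


def simulate_human_agenesis(
    n_individuals: int = 66,
    n_populations: int = 6,
    mean_agenesis: float = 0.92,
    mean_retained: float = 0.95,
    seed: int = 0,
    agenesis_rate: float = 0.3,
    population_sd: float = 0.01,
    individual_sd: float = 0.03,
) -> pd.DataFrame:
    """Individual M2/M1 values across populations with agenesis flags.

    Mirrors the shape of a polymorphic single-species sample: individuals
    nested in populations (i.i.d. population offsets), each flagged for
    third-molar agenesis, with group means set near the supplied values.
    """
    if min(mean_agenesis, mean_retained) <= 0:
        raise ValueError("group means must be positive")
    rng = np.random.default_rng(seed)
    pops = np.array([f"pop{i+1}" for i in range(n_populations)])
    pop_offsets = population_sd * rng.standard_normal(n_populations)
    assignment = rng.integers(0, n_populations, size=n_individuals)
    agenesis = rng.random(n_individuals) < agenesis_rate
    means = np.where(agenesis, mean_agenesis, mean_retained)
    m2m1 = (
        means
        + pop_offsets[assignment]
        + individual_sd * rng.standard_normal(n_individuals)
    )
    return pd.DataFrame(
        {
            "individual": [f"ind{i+1:03d}" for i in range(n_individuals)],
            "population": pops[assignment],
            "m3_agenesis": agenesis,
            "m2m1": m2m1,
        }
    )
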