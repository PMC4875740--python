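"""Specimen-level molar measurements to species-level occlusal areas.

Crown area for each molar is approximated as mesio-distal length times the
average of trigonid and talonid bucco-lingual breadths.  Because that
rectangular product overestimates true occlusal area, a shape coefficient
``x`` — calibrated on specimens for which a traced outline area is available
— interpolates between the rectangular (``ra``) and inscribed elliptical
(``ea = pi*ra/4``) areas:

    x  = (oa - ea) / (ra - ea)
    ca = ra*x + ea*(1 - x)

so ``ca`` reconstructs ``oa`` exactly on the calibration set.  The module
also applies the study-design exclusion rules (wear, sex, provenance,
incomplete dentitions, minimum sample size), aggregates to sex-pooled
species mean areas, and computes the small-sample coefficient of variation
``(1 + 1/(4n)) * s/xbar``.

The in-memory container throughout is a pandas DataFrame with one row per
specimen; see :data:`SPECIMEN_COLUMNS` for the schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dic_core import ProportionPoint

__all__ = [
    "SPECIMEN_COLUMNS",
    "ExclusionLog",
    "crown_area",
    "elliptical_area",
    "shape_coefficient",
    "corrected_area",
    "read_specimen_csv",
    "compute_specimen_areas",
    "calibrate_shape_coefficients",
    "filter_specimens",
    "species_weighted_mean",
    "small_sample_cv",
    "species_summaries",
    "species_centroid",
]

MOLARS = (1, 2, 3)

#: Required columns of the specimen-level CSV (one row per specimen).
SPECIMEN_COLUMNS = ["species", "sex", "wear", "provenance"] + [
    f"m{k}_{part}"
    for k in MOLARS
    for part in ("length", "breadth_trigonid", "breadth_talonid")
]

OPTIONAL_COLUMNS = [f"m{k}_outline_area" for k in MOLARS] + [
    "body_mass_kg",
    "diet",
    "m3_agenesis",
]


# ---------------------------------------------------------------------------
# elementary area operations

def crown_area(length, breadth_trigonid, breadth_talonid):
    """Rectangular crown area: length times mean bucco-lingual breadth."""
    length = np.asarray(length, dtype=float)
    bt = np.asarray(breadth_trigonid, dtype=float)
    bl = np.asarray(breadth_talonid, dtype=float)
    if np.any(length[~np.isnan(length)] <= 0) or np.any(
        bt[~np.isnan(bt)] <= 0
    ) or np.any(bl[~np.isnan(bl)] <= 0):
        raise ValueError("lengths and breadths must be positive")
    out = length * (bt + bl) / 2.0
    return float(out) if out.ndim == 0 else out


def elliptical_area(rectangular):
    """Area of the ellipse inscribed in the rectangular estimate: pi*ra/4."""
    ra = np.asarray(rectangular, dtype=float)
    if np.any(ra[~np.isnan(ra)] < 0):
        raise ValueError("rectangular area must be non-negative")
    out = math.pi * ra / 4.0
    return float(out) if out.ndim == 0 else out


def shape_coefficient(outline, rectangular, elliptical):
    """Molar shape coefficient x = (oa - ea)/(ra - ea).

    Values outside [0, 1] are legal (an outline can undershoot the ellipse
    or overshoot the rectangle) and are not clamped.
    """
    oa = np.asarray(outline, dtype=float)
    ra = np.asarray(rectangular, dtype=float)
    ea = np.asarray(elliptical, dtype=float)
    denom = ra - ea
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError(
            "degenerate geometry: rectangular and elliptical areas coincide"
        )
    out = (oa - ea) / denom
    return float(out) if out.ndim == 0 else out


def corrected_area(rectangular, elliptical, x):
    """Corrected area ca = ra*x + ea*(1 - x)."""
    ra = np.asarray(rectangular, dtype=float)
    ea = np.asarray(elliptical, dtype=float)
    x = np.asarray(x, dtype=float)
    out = ra * x + ea * (1.0 - x)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# I/O and per-specimen derived columns

def read_specimen_csv(path) -> pd.DataFrame:
    """Read a specimen-level CSV, checking the required schema."""
    df = pd.read_csv(path)
    missing = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"specimen CSV missing required columns: {missing}")
    if "m3_agenesis" in df.columns:
        df["m3_agenesis"] = df["m3_agenesis"].astype(bool)
    return df


def compute_specimen_areas(
    df: pd.DataFrame, coefficients: dict[int, float] | None = None
) -> pd.DataFrame:
    """Add rectangular/elliptical/corrected area columns per molar.

    ``coefficients`` maps molar position to a shape coefficient; without it
    the corrected area defaults to the rectangular area (x = 1).
    """
    out = df.copy()
    for k in MOLARS:
        ra = crown_area(
            out[f"m{k}_length"],
            out[f"m{k}_breadth_trigonid"],
            out[f"m{k}_breadth_talonid"],
        )
        ea = elliptical_area(ra)
        x = 1.0 if coefficients is None else coefficients[k]
        out[f"m{k}_ra"] = ra
        out[f"m{k}_ea"] = ea
        out[f"m{k}_area"] = corrected_area(ra, ea, x)
    return out


def calibrate_shape_coefficients(
    df: pd.DataFrame, level: str = "molar"
) -> dict:
    """Estimate shape coefficients from specimens with outline areas.

    Each calibration specimen-molar with an outline area yields one
    coefficient; these are averaged per species within each molar position,
    then across species, so unequal calibration sample sizes do not bias the
    result.  ``level='molar'`` (default) returns one coefficient per molar
    position, applied dataset-wide; ``level='species'`` returns a nested
    ``{species: {k: x}}`` mapping.
    """
    if level not in ("molar", "species"):
        raise ValueError("level must be 'molar' or 'species'")
    per_species: dict[str, dict[int, float]] = {}
    for species, grp in df.groupby("species", sort=True):
        coeffs = {}
        for k in MOLARS:
            col = f"m{k}_outline_area"
            if col not in grp.columns:
                continue
            sub = grp.dropna(subset=[col])
            if sub.empty:
                continue
            ra = crown_area(
                sub[f"m{k}_length"],
                sub[f"m{k}_breadth_trigonid"],
                sub[f"m{k}_breadth_talonid"],
            )
            ea = elliptical_area(ra)
            coeffs[k] = float(np.mean(shape_coefficient(sub[col], ra, ea)))
        if coeffs:
            per_species[species] = coeffs
    if not per_species:
        raise ValueError("no specimens with outline areas to calibrate on")
    if level == "species":
        return per_species
    return {
        k: float(
            np.mean([c[k] for c in per_species.values() if k in c])
        )
        for k in MOLARS
        if any(k in c for c in per_species.values())
    }


# ---------------------------------------------------------------------------
# filtering

@dataclass
class ExclusionLog:
    """Per-rule counts of excluded specimens and species."""

    wear: int = 0
    indeterminate_sex: int = 0
    zoo: int = 0
    incomplete: int = 0
    small_species_specimens: int = 0
    dropped_species: list = field(default_factory=list)

    def total_specimens(self) -> int:
        return (
            self.wear
            + self.indeterminate_sex
            + self.zoo
            + self.incomplete
            + self.small_species_specimens
        )


def _incomplete_mask(df: pd.DataFrame) -> pd.Series:
    """True for specimens missing measurements of a molar that should exist.

    Species flagged with third-molar agenesis are not penalised for a
    missing M3.
    """
    agenesis = (
        df["m3_agenesis"].astype(bool)
        if "m3_agenesis" in df.columns
        else pd.Series(False, index=df.index)
    )
    mask = pd.Series(False, index=df.index)
    for k in MOLARS:
        cols = [
            f"m{k}_length",
            f"m{k}_breadth_trigonid",
            f"m{k}_breadth_talonid",
        ]
        molar_missing = df[cols].isna().any(axis=1)
        if k == 3:
            molar_missing &= ~agenesis
        mask |= molar_missing
    return mask


def filter_specimens(
    df: pd.DataFrame, min_specimens: int = 4
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the study exclusion rules, in order, logging a count per rule.

    1. high or unreported wear; 2. indeterminate sex; 3. zoo provenance;
    4. incomplete lower molar dentitions; 5. species with fewer than
    ``min_specimens`` specimens or lacking either sex are dropped whole.
    """
    log = ExclusionLog()
    if df.empty:
        return df.copy(), log

    out = df.copy()
    wear = out["wear"].fillna("unreported").astype(str).str.lower()
    bad_wear = wear.isin(["high", "unreported"])
    log.wear = int(bad_wear.sum())
    out = out[~bad_wear]

    indet = out["sex"].astype(str).str.lower() == "indeterminate"
    log.indeterminate_sex = int(indet.sum())
    out = out[~indet]

    zoo = out["provenance"].astype(str).str.lower() == "zoo"
    log.zoo = int(zoo.sum())
    out = out[~zoo]

    incomplete = _incomplete_mask(out)
    log.incomplete = int(incomplete.sum())
    out = out[~incomplete]

    for species, grp in out.groupby("species", sort=True):
        sexes = set(grp["sex"].astype(str).str.lower())
        if len(grp) < min_specimens or not {"male", "female"} <= sexes:
            log.small_species_specimens += len(grp)
            log.dropped_species.append(species)
            out = out[out["species"] != species]
    return out.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# aggregation

def species_weighted_mean(df: pd.DataFrame) -> dict[int, float]:
    """Sex-pooled species mean area per molar for one species' specimens.

    Two-stage aggregation: mean over specimens within each sex, then the
    unweighted mean of the two sex means, so an unbalanced sex ratio does
    not pull the species mean toward the better-sampled sex.
    """
    species = df["species"].unique()
    if len(species) != 1:
        raise ValueError(f"expected one species, got {list(species)}")
    sexes = set(df["sex"].astype(str).str.lower())
    for needed in ("male", "female"):
        if needed not in sexes:
            raise ValueError(
                f"species {species[0]!r} lacks {needed} specimens; "
                "sex-pooled means need both sexes"
            )
    means = {}
    sex = df["sex"].astype(str).str.lower()
    for k in MOLARS:
        col = f"m{k}_area"
        if df[col].isna().all():
            means[k] = float("nan")
            continue
        sex_means = df.groupby(sex)[col].mean()
        means[k] = float(sex_means.loc[["male", "female"]].mean())
    return means


def small_sample_cv(values) -> float:
    """Coefficient of variation with the small-sample correction.

    ``(1 + 1/(4n)) * s / xbar`` with ``s`` the n-1 sample standard
    deviation.  Scale-invariant; requires n >= 2 and a positive mean.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    xbar = v.mean()
    if xbar <= 0:
        raise ValueError("coefficient of variation needs a positive mean")
    s = v.std(ddof=1)
    return float((1.0 + 1.0 / (4.0 * n)) * s / xbar)


def species_summaries(df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate filtered, area-bearing specimens to one row per species.

    Returns mean areas, small-sample CVs, molar proportions, total area and
    carried-through covariates (body mass, diet, agenesis flag).
    """
    rows = []
    for species, grp in df.groupby("species", sort=True):
        means = species_weighted_mean(grp)
        agenesis = (
            bool(grp["m3_agenesis"].iloc[0])
            if "m3_agenesis" in grp.columns
            else False
        )
        row = {
            "species": species,
            "n_specimens": len(grp),
            "m3_agenesis": agenesis,
        }
        for k in MOLARS:
            row[f"mean_area_{k}"] = means[k]
            vals = grp[f"m{k}_area"].dropna()
            row[f"cv_{k}"] = (
                small_sample_cv(vals) if len(vals) >= 2 else float("nan")
            )
        row["m2m1"] = means[2] / means[1]
        row["m3m1"] = (
            means[3] / means[1] if not math.isnan(means[3]) else float("nan")
        )
        row["total_area"] = means[1] + means[2] + (
            0.0 if math.isnan(means[3]) else means[3]
        )
        for col in ("body_mass_kg", "diet"):
            row[col] = grp[col].iloc[0] if col in grp.columns else None
        rows.append(row)
    return pd.DataFrame(rows)


def species_centroid(summary) -> ProportionPoint:
    """Morphospace centroid (M2/M1, M3/M1) of a species-summary row."""
    m1, m2, m3 = (summary[f"mean_area_{k}"] for k in MOLARS)
    if any(math.isnan(v) or v <= 0 for v in (m1, m2, m3)):
        raise ValueError(
            "species lacks a positive mean area for all three molars "
            "(third-molar agenesis?); use the agenesis analysis instead"
        )
    return ProportionPoint(m2 / m1, m3 / m1)
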