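"""Per-pathway copy-number enrichment in immunomodulatory species.

Each pathway's species-stratified, length-normalized copy numbers are fit
with the log-linear model

    ln y = b0 + b_d * ln(read depth) + b_m * rel_abundance
           + b_e_pos * 1[positive] + b_e_neg * 1[negative] + noise

with neutral species as the reference class, so a significant positive
coefficient for the positive dummy means gene copies of the pathway are
over-represented in positive-class (cytokine-increasing) species relative
to neutral ones.  Raw relative abundance (not ranks) enters this model.
Significance stars follow the raw two-sided t-test p-values:
* p < 0.1, ** p < 0.01, *** p < 0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import AbundanceTable, PathwayCopyTable
from .immunomod import SpeciesEffect
from .stats_core import adjust_pvalues, fit_linear_model

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayObservation",
    "PathwayEffect",
    "build_pathway_observations",
    "fit_pathway_effect",
    "fit_all_pathways",
    "significance_stars",
]


@dataclass
class PathwayObservation:
    """Long-format (pathway, species, sample) rows ready for fitting."""

    frame: pd.DataFrame
    # columns: pathway_id, species_id, sample_id, log_copies, log_depth,
    #          rel_abundance, effect_class


@dataclass
class PathwayEffect:
    pathway_id: str
    beta_e_positive: float = np.nan
    beta_e_negative: float = np.nan
    p_positive: float = np.nan
    p_negative: float = np.nan
    n_rows: int = 0
    classes_present: tuple = ()
    notes: str = ""
    p_positive_fdr: float = np.nan
    p_negative_fdr: float = np.nan
    coefficients: dict = field(default_factory=dict)


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def build_pathway_observations(
    copies: PathwayCopyTable,
    abundances: AbundanceTable,
    effects: list[SpeciesEffect],
) -> PathwayObservation:
    """Join copy numbers with abundances and effect classes.

    Zero-copy rows are excluded (the log is undefined and absence carries
    no signal here); species without a classification default to neutral.
    """
    if not copies.read_depth:
        raise ValueError("pathway table carries no read depths")
    cls = {e.species_id: e.classification for e in effects}
    frame = copies.frame.copy()
    frame = frame[frame["copies"] > 0].reset_index(drop=True)
    unknown = set(frame["species_id"]) - set(cls)
    if unknown:
        logger.info("%d species lack classification; treated neutral", len(unknown))
    ab = abundances.to_frame()
    sample = frame["sample_id"].astype(str)
    species = frame["species_id"].astype(str)
    rel = np.array([ab.at[s, m] for s, m in zip(sample, species)], dtype=float)
    depth = sample.map(copies.read_depth).to_numpy(float)
    if np.any(depth <= 0) or np.isnan(depth).any():
        raise ValueError("missing or non-positive read depth for some samples")
    out = pd.DataFrame(
        {
            "pathway_id": frame["pathway_id"].astype(str),
            "species_id": species,
            "sample_id": sample,
            "log_copies": np.log(frame["copies"].to_numpy(float)),
            "log_depth": np.log(depth),
            "rel_abundance": rel,
            "effect_class": [cls.get(m, "neutral") for m in species],
        }
    )
    return PathwayObservation(out)


def fit_pathway_effect(obs: pd.DataFrame, pathway_id: str = "") -> PathwayEffect:
    """Fit the copy-number model for one pathway's rows.

    With only neutral contributors both class coefficients are undefined
    and the result says so (no exception); a missing single class leaves
    just that coefficient undefined.
    """
    present = tuple(sorted(obs["effect_class"].unique()))
    n = len(obs)
    res = PathwayEffect(pathway_id=pathway_id, n_rows=n, classes_present=present)
    cols = [np.ones(n), obs["log_depth"].to_numpy(float),
            obs["rel_abundance"].to_numpy(float)]
    names = ["intercept", "log_depth", "rel_abundance"]
    for cls in ("positive", "negative"):
        if cls in present:
            cols.append((obs["effect_class"] == cls).to_numpy(float))
            names.append(cls)
    if len(names) == 3:
        res.notes = "only neutral species present; class effects undefined"
        return res
    fit = fit_linear_model(np.column_stack(cols), obs["log_copies"].to_numpy(float), names)
    res.coefficients = dict(fit.coefficients)
    if "positive" in names:
        res.beta_e_positive = fit.coefficients["positive"]
        res.p_positive = fit.p_values["positive"]
    if "negative" in names:
        res.beta_e_negative = fit.coefficients["negative"]
        res.p_negative = fit.p_values["negative"]
    missing = {"positive", "negative"} - set(present)
    if missing:
        res.notes = f"no {sorted(missing)[0]}-class contributors"
    return res


def fit_all_pathways(
    observations: PathwayObservation, fdr: bool = False
) -> list[PathwayEffect]:
    """Fit every pathway independently; optional BH across pathways."""
    results = [
        fit_pathway_effect(grp, pid)
        for pid, grp in observations.frame.groupby("pathway_id", sort=True)
    ]
    if fdr:
        for attr, target in (("p_positive", "p_positive_fdr"),
                             ("p_negative", "p_negative_fdr")):
            idx = [i for i, r in enumerate(results) if np.isfinite(getattr(r, attr))]
            if idx:
                adj = adjust_pvalues([getattr(results[i], attr) for i in idx], "BH")
                for i, q in zip(idx, adj):
                    setattr(results[i], target, float(q))
    return results
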