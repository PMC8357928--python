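"""Per-microbe pooled log-linear model of ex vivo cytokine responses.

All (cytokine, stimulus, subject) records are pooled into one model per
candidate microbe:

    ln y = b0 + b_{c,s} + b_a*age + b_s*sex + b_m*rank(abundance) + noise

where b_{c,s} are cytokine-by-stimulus interaction dummies (one reference
level) and the microbe's relative abundance is rank-transformed over the
included subjects with zeros anchored at rank 0.  Records are treated as
independent; the stringent Bonferroni threshold guards against the
resulting optimism.  A species is called immunomodulatory (positive or
negative by the sign of b_m) when the Bonferroni-adjusted two-sided t-test
p-value clears the threshold and the species passes the prevalence filter;
everything else is neutral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AbundanceTable, CytokineMeasurements, SubjectMetadata, \
    rank_transform_abundance
from .stats_core import LinearFit, fit_linear_model

__all__ = [
    "ObservationTable",
    "SpeciesEffect",
    "build_observation_table",
    "fit_species_effect",
    "fit_all_species",
    "classify_species",
]

DEFAULT_EXCLUDED_STIMULI = frozenset({"Poly:IC", "PolyIC"})


@dataclass
class ObservationTable:
    """Pooled long-format observations plus per-subject microbe ranks."""

    frame: pd.DataFrame          # subject_id, cytokine, stimulus, log_response, age, sex
    subjects: list[str]          # included subjects, fixed order
    ranks: pd.DataFrame          # subjects x species zero-anchored ranks
    prevalence: pd.Series        # per-species detection fraction among subjects

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def species(self) -> list[str]:
        return [str(c) for c in self.ranks.columns]

    def full_grid_size(self) -> int:
        """Rows the complete cytokine x stimulus x subject grid would have."""
        return (
            self.frame["cytokine"].nunique()
            * self.frame["stimulus"].nunique()
            * len(self.subjects)
        )


@dataclass
class SpeciesEffect:
    species_id: str
    beta_m: float
    p_raw: float
    prevalence: float
    p_bonferroni: float = np.nan
    classification: str = "unclassified"
    std_error: float = np.nan


def build_observation_table(
    cytokines: CytokineMeasurements,
    metadata: SubjectMetadata,
    abundances: AbundanceTable,
    excluded_stimuli=DEFAULT_EXCLUDED_STIMULI,
) -> ObservationTable:
    """Assemble the pooled observation table.

    Subjects enter when they have a microbial profile, metadata, and at
    least one cytokine record; excluded stimuli (Poly:IC by default) are
    dropped first.  Non-positive concentrations were already removed at
    parse time.  Microbe ranks are computed over the included subjects
    only, so the maximum rank is ``n_subjects - 1``.
    """
    recs = cytokines.frame
    if excluded_stimuli:
        recs = recs[~recs["stimulus"].isin(set(excluded_stimuli))]
    have_cyto = set(recs["subject_id"].astype(str))
    subjects = [
        s for s in abundances.sample_ids
        if s in have_cyto and s in set(metadata.frame.index.astype(str))
    ]
    if not subjects:
        raise ValueError("no subjects with cytokines, metadata and abundances")
    recs = recs[recs["subject_id"].astype(str).isin(set(subjects))].copy()
    meta = metadata.frame.loc[subjects]
    recs["log_response"] = np.log(recs["concentration"].to_numpy(float))
    recs["age"] = recs["subject_id"].map(meta["age"]).astype(float)
    recs["sex"] = recs["subject_id"].map(meta["sex"]).astype(float)

    sub_tab = abundances.subset_samples(subjects)
    rank_mat = np.column_stack(
        [rank_transform_abundance(sub_tab.values[:, j])
         for j in range(len(sub_tab.taxon_ids))]
    )
    ranks = pd.DataFrame(rank_mat, index=subjects, columns=sub_tab.taxon_ids)
    prev = pd.Series(
        (sub_tab.values > 0).mean(axis=0), index=sub_tab.taxon_ids, name="prevalence"
    )
    cols = ["subject_id", "cytokine", "stimulus", "log_response", "age", "sex"]
    return ObservationTable(recs[cols].reset_index(drop=True), subjects, ranks, prev)


def _base_design(obs: ObservationTable) -> tuple[np.ndarray, list[str]]:
    """Intercept + cytokine x stimulus dummies (one reference) + age + sex."""
    cs = obs.frame["cytokine"].astype(str) + "|" + obs.frame["stimulus"].astype(str)
    dummies = pd.get_dummies(cs, prefix="cs", drop_first=True, dtype=float)
    n = len(obs.frame)
    X0 = np.column_stack(
        [np.ones(n), dummies.to_numpy(), obs.frame["age"], obs.frame["sex"]]
    )
    names = ["intercept"] + list(dummies.columns) + ["age", "sex"]
    return X0, names


def fit_species_effect(obs: ObservationTable, species: str) -> tuple[SpeciesEffect, LinearFit]:
    """One full OLS fit for one microbe; returns the effect and the raw fit."""
    X0, names = _base_design(obs)
    rank_row = obs.frame["subject_id"].map(obs.ranks[species]).to_numpy(float)
    X = np.column_stack([X0, rank_row])
    fit = fit_linear_model(X, obs.frame["log_response"].to_numpy(), names + ["rank_abundance"])
    eff = SpeciesEffect(
        species_id=species,
        beta_m=fit.coefficients["rank_abundance"],
        p_raw=fit.p_values["rank_abundance"],
        prevalence=float(obs.prevalence[species]),
        std_error=fit.std_errors["rank_abundance"],
    )
    return eff, fit


def fit_all_species(obs: ObservationTable, species: list[str] | None = None) -> list[SpeciesEffect]:
    """Fit the per-microbe model for every species via residualization.

    Algebraically identical to :func:`fit_species_effect` per species
    (Frisch-Waugh-Lovell): response and each rank column are residualized
    against the shared covariates once, then each slope is a simple
    regression with the full model's residual degrees of freedom.
    """
    if species is None:
        species = obs.species
    X0, _ = _base_design(obs)
    y = obs.frame["log_response"].to_numpy(float)
    Q, _ = np.linalg.qr(X0)
    ry = y - Q @ (Q.T @ y)
    p0 = np.linalg.matrix_rank(X0)
    n = len(y)
    df = n - p0 - 1
    sub_idx = pd.Index(obs.subjects).get_indexer(obs.frame["subject_id"].astype(str))
    out = []
    rank_block = obs.ranks[species].to_numpy(float)[sub_idx]  # rows x species
    R = rank_block - Q @ (Q.T @ rank_block)
    ss_m = (R * R).sum(axis=0)
    ss_y = float(ry @ ry)
    for k, sp in enumerate(species):
        if ss_m[k] <= 1e-10 * n:  # constant rank vector: effect undefined
            out.append(SpeciesEffect(sp, np.nan, np.nan,
                                     float(obs.prevalence[sp])))
            continue
        beta = float(R[:, k] @ ry / ss_m[k])
        rss = ss_y - beta * beta * ss_m[k]
        sigma2 = rss / df
        se = float(np.sqrt(sigma2 / ss_m[k]))
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        out.append(SpeciesEffect(sp, beta, p, float(obs.prevalence[sp]),
                                 std_error=se))
    return out


def classify_species(
    effects: list[SpeciesEffect],
    n_tested: int | None = None,
    p_threshold: float = 0.005,
    prevalence_min: float = 0.20,
) -> tuple[list[SpeciesEffect], dict]:
    """Bonferroni-adjust and label species positive / negative / neutral.

    ``n_tested`` defaults to the number of fitted effects (the Bonferroni
    m); the classification is positive (negative) when the adjusted p is
    below ``p_threshold``, prevalence exceeds ``prevalence_min``, and the
    coefficient is positive (negative) — otherwise neutral.
    """
    if n_tested is None:
        n_tested = sum(1 for e in effects if np.isfinite(e.p_raw))
    counts = {"positive": 0, "negative": 0, "neutral": 0}
    for e in effects:
        e.p_bonferroni = float(min(1.0, e.p_raw * n_tested)) if np.isfinite(e.p_raw) else np.nan
        if (
            np.isfinite(e.p_bonferroni)
            and e.p_bonferroni < p_threshold
            and e.prevalence > prevalence_min
            and e.beta_m != 0
        ):
            e.classification = "positive" if e.beta_m > 0 else "negative"
        else:
            e.classification = "neutral"
        counts[e.classification] += 1
    return effects, counts
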