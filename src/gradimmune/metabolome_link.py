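"""Metabolome integration stage.

Links circulating metabolite peaks to (i) species abundances — each
species' metabolome effect is the maximum absolute Spearman correlation
over all peaks, with significance from a single Benjamini-Hochberg pass
over the whole species x peak grid; (ii) cytokine responses — per
(peak, cytokine, stimulus) Spearman tests with global BH; and (iii)
pathway annotations — counting positively / negatively associated peaks
per pathway subject to a detected-enzyme floor.  Peak clustering is
k-means on z-scored peaks with the cluster count chosen by maximal
adjusted Rand index against the molecular-class labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import adjusted_rand_score

from .data_model import AbundanceTable, CytokineMeasurements, MetaboliteTable, \
    PathwayAnnotation
from .immunomod import SpeciesEffect
from .stats_core import adjust_pvalues, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolomeEffect",
    "PathwayTally",
    "species_metabolome_effects",
    "compare_effect_distributions",
    "metabolite_cytokine_correlations",
    "tally_pathways",
    "cluster_metabolites",
]


@dataclass
class MetabolomeEffect:
    species_id: str
    best_metabolite: str
    max_abs_rho: float
    best_pair_p_fdr: float
    significant: bool
    effect_class: str = "neutral"


@dataclass
class PathwayTally:
    pathway_id: str
    n_enzymes_detected: int
    n_metabolites: int
    n_positive_assoc: int = 0
    n_negative_assoc: int = 0
    n_immunomod_metabolites: int = 0


def _spearman_grid(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and t-approximation p between columns of X and Y.

    Constant columns yield NaN rho/p (callers skip them).
    """
    n = X.shape[0]
    rx = stats.rankdata(X, axis=0)
    ry = stats.rankdata(Y, axis=0)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean(axis=0)
    sx = np.sqrt((rx * rx).sum(axis=0))
    sy = np.sqrt((ry * ry).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx.T @ ry) / np.outer(sx, sy)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p[~np.isfinite(rho)] = np.nan
    return rho, p


def species_metabolome_effects(
    abundances: AbundanceTable,
    metabolites: MetaboliteTable,
    effects: list[SpeciesEffect] | None = None,
    alpha: float = 0.05,
) -> list[MetabolomeEffect]:
    """Per-species maximum |Spearman| over all metabolite peaks.

    BH is computed once over the full species x peak grid (one global
    significance line); each species' flag comes from its best pair's
    adjusted p-value.
    """
    if abundances.sample_ids != metabolites.sample_ids:
        raise ValueError("abundances and metabolites must be sample-aligned")
    if len(abundances.sample_ids) < 3:
        raise ValueError("need at least 3 samples")
    cls = {e.species_id: e.classification for e in (effects or [])}
    rho, p = _spearman_grid(abundances.values, metabolites.intensities)
    flat = p.ravel()
    ok = np.isfinite(flat)
    if (~ok).any():
        logger.info("skipped %d constant species/peak pairs", int((~ok).sum()))
    q = np.full(flat.shape, np.nan)
    q[ok] = adjust_pvalues(flat[ok], "BH")
    q = q.reshape(p.shape)
    out = []
    for i, sp in enumerate(abundances.taxon_ids):
        absr = np.abs(rho[i])
        if not np.isfinite(absr).any():
            continue
        j = int(np.nanargmax(absr))
        out.append(
            MetabolomeEffect(
                species_id=sp,
                best_metabolite=metabolites.peak_ids[j],
                max_abs_rho=float(absr[j]),
                best_pair_p_fdr=float(q[i, j]),
                significant=bool(q[i, j] < alpha),
                effect_class=cls.get(sp, "neutral"),
            )
        )
    return out


def compare_effect_distributions(
    effects: list[MetabolomeEffect],
) -> dict[str, object]:
    """One-sided rank-sum contrasts of max-|rho| by species class.

    Tests whether positive- (and separately negative-) class species have
    systematically larger metabolome effects than neutral ones.  Empty
    classes skip their contrast with a note.
    """
    by_class: dict[str, list[float]] = {"positive": [], "negative": [], "neutral": []}
    for e in effects:
        by_class.setdefault(e.effect_class, []).append(e.max_abs_rho)
    out: dict[str, object] = {}
    for cls in ("positive", "negative"):
        key = f"{cls}_vs_neutral"
        if not by_class[cls] or not by_class["neutral"]:
            out[key] = None
            logger.info("contrast %s skipped: empty class", key)
            continue
        out[key] = wilcoxon_rank_sum(
            by_class[cls], by_class["neutral"], alternative="greater"
        )
    return out


def metabolite_cytokine_correlations(
    metabolites: MetaboliteTable,
    cytokines: CytokineMeasurements,
    alpha: float = 0.05,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Spearman tests per (peak, cytokine, stimulus) with global BH flags.

    Each cytokine x stimulus response vector is matched to peak
    intensities over subjects carrying both measurements; pairs with fewer
    than ``min_pairs`` shared subjects, or a constant vector, are skipped.
    Returns a tidy frame with rho, p, p_fdr and a significance flag.
    """
    sample_pos = {s: i for i, s in enumerate(metabolites.sample_ids)}
    rows = []
    for (cyt, stim), grp in cytokines.frame.groupby(["cytokine", "stimulus"], sort=True):
        subj = grp["subject_id"].astype(str)
        keep = subj.isin(sample_pos)
        if keep.sum() < min_pairs:
            continue
        idx = [sample_pos[s] for s in subj[keep]]
        resp = np.log(grp.loc[keep, "concentration"].to_numpy(float))
        if np.ptp(resp) == 0:
            continue
        X = metabolites.intensities[idx]  # subjects x peaks
        rho, p = _spearman_grid(X, resp[:, None])
        for j, peak in enumerate(metabolites.peak_ids):
            if np.isfinite(rho[j, 0]):
                rows.append((peak, cyt, stim, float(rho[j, 0]), float(p[j, 0])))
    result = pd.DataFrame(rows, columns=["peak_id", "cytokine", "stimulus", "rho", "p"])
    if len(result):
        result["p_fdr"] = adjust_pvalues(result["p"].to_numpy(), "BH")
        result["significant"] = result["p_fdr"] < alpha
    else:
        result["p_fdr"] = []
        result["significant"] = []
    return result


def tally_pathways(
    annotation: PathwayAnnotation,
    detected_enzymes: dict[str, set],
    metab_cyto: pd.DataFrame,
    peak_compounds: dict[str, frozenset],
    metab_species_flags: dict[str, bool] | None = None,
    enzyme_floor: int = 10,
    metabolite_floor: int = 3,
) -> list[PathwayTally]:
    """Count significant metabolite associations per annotated pathway.

    A pathway enters the cytokine-association tally only when at least
    ``enzyme_floor`` of its enzymes were detected in the cohort.  Peaks map
    to pathways through shared compound identifiers.  A peak counts as
    positively (negatively) associated when it has any significant
    metabolite-cytokine correlation and its strongest significant rho is
    positive (negative).  ``n_immunomod_metabolites`` counts the pathway's
    peaks significantly correlated with an immunomodulatory species; the
    ``metabolite_floor`` marks pathways worth reporting on that axis.
    """
    sig = metab_cyto[metab_cyto.get("significant", pd.Series(dtype=bool)) == True]  # noqa: E712
    peak_sign: dict[str, int] = {}
    if len(sig):
        best = sig.loc[sig.groupby("peak_id")["p_fdr"].idxmin()]
        peak_sign = {r.peak_id: int(np.sign(r.rho)) for r in best.itertuples()}
    metab_species_flags = metab_species_flags or {}

    compound_to_peaks: dict[str, set] = {}
    for peak, comps in peak_compounds.items():
        for c in comps:
            compound_to_peaks.setdefault(c, set()).add(peak)

    tallies = []
    for pwy, comps in sorted(annotation.compounds.items()):
        peaks = set()
        for c in comps:
            peaks |= compound_to_peaks.get(c, set())
        n_enz = len(detected_enzymes.get(pwy, set()))
        tally = PathwayTally(pwy, n_enz, len(peaks))
        if n_enz >= enzyme_floor:
            tally.n_positive_assoc = sum(1 for p in peaks if peak_sign.get(p) == 1)
            tally.n_negative_assoc = sum(1 for p in peaks if peak_sign.get(p) == -1)
        tally.n_immunomod_metabolites = sum(
            1 for p in peaks if metab_species_flags.get(p, False)
        )
        tallies.append(tally)
    return tallies


def cluster_metabolites(
    metabolites: MetaboliteTable,
    k_range=range(2, 31),
    restarts: int = 25,
    seed: int = 0,
) -> dict:
    """K-means over z-scored peaks with ARI-selected cluster count.

    Peaks are standardized across samples and clustered (peaks as points
    in sample space).  For each k the best-inertia partition over seeded
    restarts is scored by adjusted Rand index against the molecular-class
    labels; the k with maximal ARI wins, ties broken toward smaller k.
    Each cluster is annotated with its most prevalent molecular class.
    """
    n_peaks = len(metabolites.peak_ids)
    if n_peaks < 2:
        raise ValueError("need at least 2 peaks")
    labels_true = [metabolites.molecular_class.get(p, "") for p in metabolites.peak_ids]
    X = metabolites.intensities.T.astype(float)  # peaks x samples
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd

    best = {"k": None, "ari": -np.inf, "labels": None}
    for k in k_range:
        if k > n_peaks:
            continue
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        with warnings.catch_warnings():
            # duplicate points (zero-noise peaks) legitimately collapse clusters
            warnings.simplefilter("ignore", ConvergenceWarning)
            part = km.fit_predict(Z)
        ari = adjusted_rand_score(labels_true, part)
        if ari > best["ari"]:  # strict: ties keep the smaller k
            best = {"k": k, "ari": ari, "labels": part}
    clusters: dict[int, str] = {}
    for c in np.unique(best["labels"]):
        members = [labels_true[i] for i in np.flatnonzero(best["labels"] == c)]
        clusters[int(c)] = pd.Series(members).mode().iloc[0]
    return {
        "chosen_k": int(best["k"]),
        "ari": float(best["ari"]),
        "labels": np.asarray(best["labels"]),
        "dominant_class": clusters,
    }
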