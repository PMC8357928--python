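"""Three-group monotone-change screen over species ("double Wilcoxon").

For each species and each candidate ordering of the three groups, two
two-sided rank-sum tests compare consecutive group pairs; the combined
p-value is the larger of the two, so a species is significant only when it
shifts in *both* steps of the gradient.  Benjamini-Hochberg FDR is applied
per ordering across the species that pass the prevalence filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import AbundanceTable
from .stats_core import adjust_pvalues, wilcoxon_rank_sum

__all__ = ["GradientResult", "ORDERINGS", "double_wilcoxon", "scan_gradient"]

# Orderings name the group sequence along which monotone change is tested:
# RUN rural->urban->external, URN urban->rural->external,
# RNU rural->external->urban.
ORDERINGS = {
    "RUN": ("rural", "urban", "external"),
    "URN": ("urban", "rural", "external"),
    "RNU": ("rural", "external", "urban"),
}


@dataclass
class GradientResult:
    species_id: str
    ordering: str
    p_first: float
    p_second: float
    p_combined: float
    direction: str  # "increasing" | "decreasing" | "inconsistent" | "undefined"
    prevalence: float
    p_fdr: float = np.nan

    @property
    def consistent(self) -> bool:
        return self.direction in ("increasing", "decreasing")


def double_wilcoxon(values, groups, ordering: str = "RUN",
                    species_id: str = "") -> GradientResult:
    """Two consecutive-pair rank-sum tests under one ordering.

    ``direction`` is increasing/decreasing only when both pairwise shifts
    share sign; opposite signs are flagged inconsistent and a null shift
    leaves it undefined.
    """
    if ordering not in ORDERINGS:
        raise ValueError(f"unknown ordering {ordering!r}")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    seq = ORDERINGS[ordering]
    parts = []
    for g in seq:
        sel = values[groups == g]
        if sel.size == 0:
            raise ValueError(f"group {g!r} is empty or missing")
        parts.append(sel)
    r1 = wilcoxon_rank_sum(parts[0], parts[1])
    r2 = wilcoxon_rank_sum(parts[1], parts[2])
    p_comb = max(r1.p_value, r2.p_value)
    # rank-biserial signs: positive means first group larger
    if r1.direction == 0 or r2.direction == 0:
        direction = "undefined"
    elif r1.direction == r2.direction:
        direction = "decreasing" if r1.direction > 0 else "increasing"
    else:
        direction = "inconsistent"
    prev = float(np.mean(values > 0))
    return GradientResult(species_id, ordering, r1.p_value, r2.p_value,
                          p_comb, direction, prev)


def scan_gradient(
    table: AbundanceTable,
    orderings=("RUN", "URN", "RNU"),
    prevalence_min: float = 0.20,
    fdr_alpha: float = 0.05,
) -> tuple[list[GradientResult], dict]:
    """Screen all species across orderings with prevalence and FDR filters.

    Species detected in at most ``prevalence_min`` of samples are excluded
    before testing.  BH adjustment of the combined p-values runs within
    each ordering over the tested species.  The summary counts species with
    uncorrected p < 0.05 and FDR-significant species per ordering;
    direction-inconsistent species are retained in the output but never
    counted significant.
    """
    if table.group_labels is None:
        raise ValueError("abundance table carries no group labels")
    groups = np.asarray(table.group_labels)
    prev = np.mean(table.values > 0, axis=0)
    tested = [j for j in range(len(table.taxon_ids)) if prev[j] > prevalence_min]
    results: list[GradientResult] = []
    summary = {
        "n_tested": len(tested),
        "per_ordering": {},
    }
    for ordering in orderings:
        batch = [
            double_wilcoxon(table.values[:, j], groups, ordering, table.taxon_ids[j])
            for j in tested
        ]
        if batch:
            fdr = adjust_pvalues([r.p_combined for r in batch], "BH")
            for r, q in zip(batch, fdr):
                r.p_fdr = float(q)
        n_unc = sum(1 for r in batch if r.p_combined < 0.05 and r.consistent)
        n_sig = sum(1 for r in batch if r.p_fdr < fdr_alpha and r.consistent)
        summary["per_ordering"][ordering] = {
            "uncorrected": n_unc,
            "fdr_significant": n_sig,
        }
        results.extend(batch)
    if not tested:
        import logging

        logging.getLogger(__name__).warning("no species pass the prevalence filter")
    return results, summary
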