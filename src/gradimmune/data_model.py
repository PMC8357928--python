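"""Typed containers and TSV I/O for the five cohort table kinds.

All tables are tab-separated UTF-8 text with a header row; lines starting
with ``#`` are ignored.  Relative abundances are stored as fractions of the
community (0-1); tables whose rows sum to ~100 are auto-detected as percent
and rescaled.  Sample and subject identifiers share one namespace (one stool
sample per subject).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "SubjectMetadata",
    "CytokineMeasurements",
    "MetaboliteTable",
    "PathwayCopyTable",
    "PathwayAnnotation",
    "AlignedCohort",
    "read_table",
    "write_table",
    "align_cohort",
    "prevalence",
    "rank_transform_abundance",
    "fold_change",
]

_ABUNDANCE_SUM_TOL = 1e-6


class ParseError(ValueError):
    """Raised when an input table violates its contract."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    seen: set = set()
    for i in ids:
        if i in seen:
            raise ParseError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class AbundanceTable:
    """Samples x taxa relative abundances with optional group labels.

    ``values`` holds fractions in [0, 1]; per-sample totals may be below 1
    (sub-communities such as a species subset are allowed) but never exceed
    it beyond tolerance.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray  # (n_samples, n_taxa)
    group_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.sample_ids, "sample ID")
        _check_unique(self.taxon_ids, "taxon ID")
        if self.values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ParseError("abundance matrix shape mismatch")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ParseError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        totals = self.values.sum(axis=1)
        if (totals > 1.0 + _ABUNDANCE_SUM_TOL).any():
            # percent-scale auto-detection: row sums near 100
            if np.allclose(totals[totals > 0], 100.0, rtol=0.25):
                logger.info("abundance table looks percent-scaled; dividing by 100")
                self.values = self.values / 100.0
            else:
                bad = int(np.argmax(totals))
                raise ParseError(
                    f"sample {self.sample_ids[bad]!r} abundance total {totals[bad]:.4f} > 1"
                )
        if self.group_labels is not None and len(self.group_labels) != len(self.sample_ids):
            raise ParseError("group_labels length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def taxon_vector(self, taxon: str) -> np.ndarray:
        try:
            j = self.taxon_ids.index(taxon)
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None
        return self.values[:, j]

    def subset_samples(self, ids: list[str]) -> "AbundanceTable":
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        groups = [self.group_labels[k] for k in idx] if self.group_labels else None
        return AbundanceTable(list(ids), list(self.taxon_ids), self.values[idx], groups)


@dataclass
class SubjectMetadata:
    """Per-subject covariates: age (years), sex, residency, survey variables."""

    frame: pd.DataFrame  # index = subject_id

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "subject ID")
        for col in ("age", "sex"):
            if col not in self.frame.columns:
                raise ParseError(f"metadata missing required column {col!r}")
        if (pd.to_numeric(self.frame["age"], errors="raise") <= 0).any():
            raise ParseError("age must be positive")

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def subset_samples(self, ids: list[str]) -> "SubjectMetadata":
        return SubjectMetadata(self.frame.loc[list(ids)].copy())


@dataclass
class CytokineMeasurements:
    """Long-format ex vivo cytokine responses (pg/mL) per subject/cytokine/stimulus."""

    frame: pd.DataFrame  # columns subject_id, cytokine, stimulus, concentration

    REQUIRED = ("subject_id", "cytokine", "stimulus", "concentration")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ParseError(f"cytokine table missing column {col!r}")
        dup = self.frame.duplicated(["subject_id", "cytokine", "stimulus"])
        if dup.any():
            row = self.frame[dup].iloc[0]
            raise ParseError(
                "duplicate (subject, cytokine, stimulus) triple: "
                f"({row.subject_id!r}, {row.cytokine!r}, {row.stimulus!r})"
            )
        n_bad = int((self.frame["concentration"] <= 0).sum()
                    + self.frame["concentration"].isna().sum())
        if n_bad:
            logger.info("dropping %d non-positive/missing cytokine concentrations", n_bad)
            keep = self.frame["concentration"] > 0
            self.frame = self.frame[keep.fillna(False)].reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.frame["subject_id"].astype(str).unique())

    def subset_samples(self, ids: list[str]) -> "CytokineMeasurements":
        keep = self.frame["subject_id"].astype(str).isin(set(ids))
        return CytokineMeasurements(self.frame[keep].reset_index(drop=True))


@dataclass
class MetaboliteTable:
    """Samples x LC-MS peak intensities with per-peak annotations."""

    sample_ids: list[str]
    peak_ids: list[str]
    intensities: np.ndarray  # (n_samples, n_peaks)
    molecular_class: dict[str, str] = field(default_factory=dict)
    pathway_ids: dict[str, frozenset] = field(default_factory=dict)
    compound_ids: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        _check_unique(self.sample_ids, "sample ID")
        _check_unique(self.peak_ids, "peak ID")
        if self.intensities.shape != (len(self.sample_ids), len(self.peak_ids)):
            raise ParseError("intensity matrix shape mismatch")
        if (self.intensities < 0).any():
            raise ParseError("negative intensity")
        known = set(self.peak_ids)
        for name, mapping in (
            ("molecular_class", self.molecular_class),
            ("pathway_ids", self.pathway_ids),
            ("compound_ids", self.compound_ids),
        ):
            extra = set(mapping) - known
            if extra:
                raise ParseError(f"{name} annotates unknown peaks: {sorted(extra)[:3]}")

    def subset_samples(self, ids: list[str]) -> "MetaboliteTable":
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return MetaboliteTable(
            list(ids), list(self.peak_ids), self.intensities[idx],
            dict(self.molecular_class), dict(self.pathway_ids), dict(self.compound_ids),
        )


@dataclass
class PathwayCopyTable:
    """Species-stratified, length-normalized pathway copy numbers per sample."""

    frame: pd.DataFrame  # columns sample_id, species_id, pathway_id, copies
    read_depth: dict[str, int] = field(default_factory=dict)  # sample -> total reads

    REQUIRED = ("sample_id", "species_id", "pathway_id", "copies")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ParseError(f"pathway table missing column {col!r}")
        if (self.frame["copies"] < 0).any():
            raise ParseError("negative pathway copies")
        for s, d in self.read_depth.items():
            if d <= 0:
                raise ParseError(f"non-positive read depth for sample {s!r}")

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.frame["sample_id"].astype(str).unique())

    def subset_samples(self, ids: list[str]) -> "PathwayCopyTable":
        keep = self.frame["sample_id"].astype(str).isin(set(ids))
        depth = {s: d for s, d in self.read_depth.items() if s in set(ids)}
        return PathwayCopyTable(self.frame[keep].reset_index(drop=True), depth)


@dataclass
class PathwayAnnotation:
    """Pathway -> enzyme-set and pathway -> compound-set maps."""

    enzymes: dict[str, frozenset] = field(default_factory=dict)
    compounds: dict[str, frozenset] = field(default_factory=dict)


@dataclass
class AlignedCohort:
    """Tables restricted to the shared sample set, in one consistent order."""

    sample_ids: list[str]
    tables: dict[str, object]
    dropped: dict[str, int]

    def __getitem__(self, kind: str):
        return self.tables[kind]


# ---------------------------------------------------------------------------
# TSV I/O

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str}, encoding="utf-8")


def read_table(path, kind: str, orientation: str = "samples_by_taxa"):
    """Read one of the five table kinds from TSV.

    ``kind`` is one of abundance | cytokine | metabolite | pathway | metadata.
    Abundance tables accept MetaPhlAn-style orientation (taxon rows, sample
    columns) via ``orientation="taxa_by_samples"``.
    """
    df = _read_tsv(path)
    logger.info("read %s table %s: %d rows x %d cols", kind, path, *df.shape)
    if kind == "abundance":
        if "group" in df.columns:
            groups = [str(g) for g in df["group"]]
            mat = df.drop(columns=["group"])
        else:
            groups = None
            mat = df
        mat = mat.set_index(mat.columns[0])
        values = mat.to_numpy(dtype=float)
        if orientation == "taxa_by_samples":
            return AbundanceTable(
                [str(c) for c in mat.columns], [str(i) for i in mat.index], values.T, groups
            )
        return AbundanceTable(
            [str(i) for i in mat.index], [str(c) for c in mat.columns], values, groups
        )
    if kind == "cytokine":
        return CytokineMeasurements(df)
    if kind == "metadata":
        return SubjectMetadata(df.set_index(df.columns[0]))
    if kind == "metabolite":
        ann_cols = [c for c in ("molecular_class", "pathway_ids", "compound_ids") if c in df.columns]
        first = df.columns[0]
        if first == "peak_id":  # peak rows with annotation columns
            mclass = dict(zip(df["peak_id"].astype(str), df.get("molecular_class", "")))
            pways = {
                p: frozenset(str(v).split(",")) - {"", "nan"}
                for p, v in zip(df["peak_id"].astype(str), df.get("pathway_ids", ""))
            }
            comps = {
                p: frozenset(str(v).split(",")) - {"", "nan"}
                for p, v in zip(df["peak_id"].astype(str), df.get("compound_ids", ""))
            }
            mat = df.drop(columns=ann_cols).set_index("peak_id")
            return MetaboliteTable(
                [str(c) for c in mat.columns],
                [str(i) for i in mat.index],
                mat.to_numpy(dtype=float).T,
                {k: str(v) for k, v in mclass.items()},
                pways,
                comps,
            )
        mat = df.set_index(first)
        return MetaboliteTable(
            [str(i) for i in mat.index], [str(c) for c in mat.columns],
            mat.to_numpy(dtype=float),
        )
    if kind == "pathway":
        depth = {}
        if "read_depth" in df.columns:
            depth = {
                str(s): int(d)
                for s, d in df.groupby("sample_id")["read_depth"].first().items()
            }
            df = df.drop(columns=["read_depth"])
        return PathwayCopyTable(df, depth)
    raise ValueError(f"unknown table kind {kind!r}")


def write_table(obj, path, orientation: str = "samples_by_taxa") -> None:
    """Write a typed table back to TSV (inverse of :func:`read_table`)."""
    if isinstance(obj, AbundanceTable):
        df = obj.to_frame()
        if orientation == "taxa_by_samples":
            df = df.T
            df.index.name = "taxon_id"
        else:
            df.index.name = "sample_id"
            if obj.group_labels is not None:
                df.insert(0, "group", obj.group_labels)
        df.to_csv(path, sep="\t")
    elif isinstance(obj, (CytokineMeasurements,)):
        obj.frame.to_csv(path, sep="\t", index=False)
    elif isinstance(obj, SubjectMetadata):
        out = obj.frame.copy()
        out.index.name = "subject_id"
        out.to_csv(path, sep="\t")
    elif isinstance(obj, MetaboliteTable):
        df = pd.DataFrame(obj.intensities.T, index=obj.peak_ids, columns=obj.sample_ids)
        df.index.name = "peak_id"
        df.insert(0, "molecular_class",
                  [obj.molecular_class.get(p, "") for p in obj.peak_ids])
        df.insert(1, "pathway_ids",
                  [",".join(sorted(obj.pathway_ids.get(p, frozenset()))) for p in obj.peak_ids])
        df.insert(2, "compound_ids",
                  [",".join(sorted(obj.compound_ids.get(p, frozenset()))) for p in obj.peak_ids])
        df.to_csv(path, sep="\t")
    elif isinstance(obj, PathwayCopyTable):
        out = obj.frame.copy()
        if obj.read_depth:
            out["read_depth"] = out["sample_id"].astype(str).map(obj.read_depth)
        out.to_csv(path, sep="\t", index=False)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# Cohort alignment and abundance transforms

def _ids_of(table) -> list[str]:
    if isinstance(table, AbundanceTable) or isinstance(table, MetaboliteTable):
        return list(table.sample_ids)
    return list(table.subject_ids)


def align_cohort(tables: dict[str, object]) -> AlignedCohort:
    """Restrict every table to the intersection of sample/subject IDs.

    Order follows the first table's ID order.  Idempotent; raises on an
    empty intersection.
    """
    if not tables:
        raise ValueError("need at least one table")
    id_sets = {name: _ids_of(t) for name, t in tables.items()}
    shared = None
    for ids in id_sets.values():
        shared = set(ids) if shared is None else shared & set(ids)
    if not shared:
        raise ValueError("no samples shared across tables")
    first = next(iter(id_sets.values()))
    ordered = [s for s in first if s in shared]
    dropped = {name: len(ids) - len(ordered) for name, ids in id_sets.items()}
    for name, n in dropped.items():
        if n:
            logger.info("align_cohort: dropped %d samples from %s", n, name)
    aligned = {name: t.subset_samples(ordered) for name, t in tables.items()}
    return AlignedCohort(ordered, aligned, dropped)


def prevalence(table: AbundanceTable, taxon: str) -> float:
    """Fraction of samples where the taxon is detected (abundance > 0)."""
    return float(np.mean(table.taxon_vector(taxon) > 0))


def rank_transform_abundance(values) -> np.ndarray:
    """Zero-anchored rank transform of one taxon's abundances.

    All zeros map to rank 0; detected values receive ranks
    ``n_zero, n_zero + 1, ..., n - 1`` in ascending abundance order with
    mid-ranks for ties, so a unique maximum always gets rank ``n - 1``.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("abundances must be non-negative")
    ranks = np.zeros(len(v), dtype=float)
    nz = v > 0
    n_zero = int((~nz).sum())
    if nz.any():
        # mid-ranks among detected values, shifted to start at n_zero
        from scipy.stats import rankdata

        ranks[nz] = rankdata(v[nz], method="average") + n_zero - 1
    return ranks


def fold_change(a: float, b: float) -> float:
    """Ratio a/b of two non-negative means; b must be positive."""
    if b <= 0:
        raise ValueError("denominator must be positive")
    if a < 0:
        raise ValueError("numerator must be non-negative")
    return a / b
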