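"""End-to-end pipeline driver.

A single structured config (YAML-compatible dict) either points at the
five input TSVs or embeds a simulate-block; the stages then run in order
gradient scan -> cytokine models -> pathway enrichment -> metabolome
integration -> composition statistics.  Every output TSV carries a header
comment with the config hash and seed, and a JSON manifest lists each file
with a content checksum, so identical (config, seed) reruns are verifiable
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition_stats as cs
from . import data_model as dm
from . import gradient_scan as gs
from . import immunomod as im
from . import metabolome_link as ml
from . import pathway_enrichment as pe
from . import synthetic_cohort as sc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_THRESHOLDS = {
    "p_threshold": 0.005,     # Bonferroni cut for immunomodulatory calls
    "prevalence": 0.20,
    "alpha": 0.05,            # FDR level for gradient / metabolome stages
    "enzyme_floor": 10,
    "metabolite_floor": 3,
    "n_perm": 999,
}

STAGES = ("gradient", "immunomod", "enrich", "metabolome", "composition")


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``inputs`` (paths keyed abundance/cytokine/metabolite/
    pathway/metadata) or ``simulate`` (SimulationConfig field overrides)
    must be provided.
    """

    inputs: dict | None = None
    simulate: dict | None = None
    stages: tuple = STAGES
    thresholds: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    outdir: str = "gradimmune_out"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("provide exactly one of inputs or simulate")
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        if not (0 < self.thresholds["p_threshold"] <= 1):
            raise ValueError("p_threshold out of range")
        if not (0 <= self.thresholds["prevalence"] < 1):
            raise ValueError("prevalence out of range")
        if not (0 < self.thresholds["alpha"] < 1):
            raise ValueError("alpha out of range")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.inputs is not None:
            needed = {"abundance", "metadata"}
            if "immunomod" in self.stages or "metabolome" in self.stages:
                needed.add("cytokine")
            if "metabolome" in self.stages:
                needed.add("metabolite")
            if "enrich" in self.stages:
                needed |= {"cytokine", "pathway"}
            missing = needed - set(self.inputs)
            if missing:
                raise ValueError(f"stage set requires inputs {sorted(missing)}")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # where results land must not change what they are
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {k: raw[k] for k in
                  ("inputs", "simulate", "thresholds", "seed", "outdir") if k in raw}
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        return cls(**kwargs)


def _write_tsv(df: pd.DataFrame, path: Path, header_note: str) -> None:
    with open(path, "w") as fh:
        fh.write(header_note)
        df.to_csv(fh, sep="\t", index=False)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohort(config: PipelineConfig) -> dict:
    if config.simulate is not None:
        sim = sc.SimulationConfig(**config.simulate)
        return sc.simulate_cohort(sim, config.seed)
    tables = {}
    kinds = {"abundance": "abundance", "cytokine": "cytokine",
             "metabolite": "metabolite", "pathway": "pathway",
             "metadata": "metadata"}
    for key, kind in kinds.items():
        if key in config.inputs:
            tables[key] = dm.read_table(config.inputs[key], kind)
    cohort = {
        "abundance": tables["abundance"],
        "metadata": tables["metadata"],
        "cytokines": tables.get("cytokine"),
        "metabolites": tables.get("metabolite"),
        "pathway_copies": tables.get("pathway"),
        "annotation": None,
        "truth": None,
    }
    ab = tables["abundance"]
    if ab.group_labels is not None:
        tz = [s for s, g in zip(ab.sample_ids, ab.group_labels)
              if g in ("rural", "urban")]
        cohort["tz_abundance"] = ab.subset_samples(tz) if tz else ab
    else:
        cohort["tz_abundance"] = ab
    return cohort


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and write results + manifest under outdir.

    Returns the manifest dict (also written as ``manifest.json``).  A
    stage failure aborts the run; files written so far are renamed with a
    ``.partial`` suffix so an interrupted run is never mistaken for a
    complete one.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    note = f"# gradimmune config={config.config_hash()} seed={config.seed}\n"
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                      "files": {}, "summaries": {}, "stages": list(config.stages)}
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        _write_tsv(df, path, note)
        written.append(path)
        manifest["files"][name] = _checksum(path)

    current = "setup"
    try:
        cohort = _load_cohort(config)
        if cohort.get("truth") is not None:
            tpath = outdir / "truth.json"
            cohort["truth"].to_json(tpath)
            written.append(tpath)
            manifest["files"]["truth.json"] = _checksum(tpath)

        effects = None
        if "gradient" in config.stages:
            current = "gradient"
            t0 = time.perf_counter()
            results, summary = gs.scan_gradient(
                cohort["abundance"], prevalence_min=th["prevalence"],
                fdr_alpha=th["alpha"])
            emit("gradient_scan.tsv", pd.DataFrame(
                [dataclasses.asdict(r) for r in results]))
            manifest["summaries"]["gradient"] = summary
            logger.info("gradient stage: %.2fs", time.perf_counter() - t0)

        if "immunomod" in config.stages:
            current = "immunomod"
            t0 = time.perf_counter()
            obs = im.build_observation_table(
                cohort["cytokines"], cohort["metadata"], cohort["tz_abundance"])
            tested = [s for s in obs.species
                      if obs.prevalence[s] > th["prevalence"]]
            fits = im.fit_all_species(obs, tested)
            effects, counts = im.classify_species(
                fits, p_threshold=th["p_threshold"],
                prevalence_min=th["prevalence"])
            emit("species_effects.tsv", pd.DataFrame(
                [dataclasses.asdict(e) for e in effects]))
            manifest["summaries"]["immunomod"] = {
                "n_obs": obs.n_rows, "n_tested": len(tested), "counts": counts}
            logger.info("immunomod stage: %.2fs", time.perf_counter() - t0)

        if "enrich" in config.stages:
            current = "enrich"
            t0 = time.perf_counter()
            pobs = pe.build_pathway_observations(
                cohort["pathway_copies"], cohort["tz_abundance"], effects or [])
            peffects = pe.fit_all_pathways(pobs)
            rows = []
            for r in peffects:
                rows.append({
                    "pathway_id": r.pathway_id,
                    "beta_e_positive": r.beta_e_positive,
                    "p_positive": r.p_positive,
                    "stars_positive": pe.significance_stars(r.p_positive),
                    "beta_e_negative": r.beta_e_negative,
                    "p_negative": r.p_negative,
                    "stars_negative": pe.significance_stars(r.p_negative),
                    "n_rows": r.n_rows, "notes": r.notes,
                })
            emit("pathway_effects.tsv", pd.DataFrame(rows))
            manifest["summaries"]["enrich"] = {"n_pathways": len(peffects)}
            logger.info("enrich stage: %.2fs", time.perf_counter() - t0)

        if "metabolome" in config.stages:
            current = "metabolome"
            t0 = time.perf_counter()
            aligned = dm.align_cohort({
                "abundance": cohort["tz_abundance"],
                "metabolites": cohort["metabolites"],
            })
            m_eff = ml.species_metabolome_effects(
                aligned["abundance"], aligned["metabolites"],
                effects, alpha=th["alpha"])
            emit("metabolome_effects.tsv", pd.DataFrame(
                [dataclasses.asdict(e) for e in m_eff]))
            contrasts = ml.compare_effect_distributions(m_eff)
            mc = ml.metabolite_cytokine_correlations(
                aligned["metabolites"], cohort["cytokines"], alpha=th["alpha"])
            emit("metabolite_cytokine.tsv", mc)
            clust = ml.cluster_metabolites(aligned["metabolites"], seed=config.seed)
            manifest["summaries"]["metabolome"] = {
                "n_species_effects": len(m_eff),
                "n_significant": int(sum(e.significant for e in m_eff)),
                "n_metab_cyto_significant": int(mc["significant"].sum()) if len(mc) else 0,
                "chosen_k": clust["chosen_k"],
                "ari": clust["ari"],
                "contrasts": {
                    k: (None if v is None else
                        {"statistic": v.statistic, "p_value": v.p_value})
                    for k, v in contrasts.items()},
            }
            logger.info("metabolome stage: %.2fs", time.perf_counter() - t0)

        if "composition" in config.stages:
            current = "composition"
            t0 = time.perf_counter()
            ab = cohort["abundance"]
            dist = cs.jensen_shannon_matrix(ab)
            heights = cs.merge_heights(dist)
            k = cs.cluster_count_by_height(heights, len(ab.sample_ids))
            labels = cs.cut_clusters(dist, k)
            summary = {"n_clusters": int(k)}
            if ab.group_labels is not None:
                res = cs.permanova(dist, ab.group_labels,
                                   n_perm=th["n_perm"], seed=config.seed)
                summary["permanova"] = {
                    "pseudo_F": res.pseudo_F, "r_squared": res.r_squared,
                    "p": res.p_perm, "n_permutations": res.n_permutations}
            emit("composition_clusters.tsv", pd.DataFrame(
                {"sample_id": ab.sample_ids, "cluster": labels,
                 "group": ab.group_labels if ab.group_labels else ""}))
            manifest["summaries"]["composition"] = summary
            logger.info("composition stage: %.2fs", time.perf_counter() - t0)

    except Exception as exc:
        for path in written:
            path.rename(path.with_suffix(path.suffix + ".partial"))
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_jsonable)
    return manifest


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")
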