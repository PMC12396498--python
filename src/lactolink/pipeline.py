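"""End-to-end orchestration: simulate/load -> pseudobulk -> analyses -> manifest.

Stages run in dependency order (io -> pseudobulk -> {coexpr, assoc, de} ->
enrich). Every run writes a manifest recording the effective configuration,
SHA-256 checksums of inputs and outputs, the package version, and per-stage
row counts and wall times; results go to TSV/CSV, logs to stderr.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import time
import tomllib
from pathlib import Path

import pandas as pd

from . import __version__
from .association import ProportionAssociationLMM, TimeAssociationLMM
from .coexpression import CooccurrenceAnalyzer
from .data import hmo_columns, load_cell_data, load_gmt, load_hmo_panel
from .de import PseudobulkDE, correlate_lfc_time, per_sample_log2fc
from .enrichment import MeanRankTF, PrerankedGSEA, rank_metric
from .pseudobulk import aggregate_pseudobulk, cell_type_proportions
from .simulate import SimConfig, simulate_dataset, write_fixture

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "coexpr", "assoc", "de", "enrich")


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream output."""


@dataclasses.dataclass
class RunConfig:
    """Effective configuration of one pipeline run; ``seed`` is mandatory."""

    out_dir: str
    seed: int
    stages: tuple[str, ...] = STAGE_ORDER
    input_dir: str | None = None  # fixture dir when 'simulate' is not requested
    cell_types: tuple[str, ...] = ("LC1", "LC2")
    coexpr_cell_type: str = "LC2"
    coexpr_pairs: list[tuple[str, str]] | None = None
    alpha: float = 0.05
    top_n: int = 200
    pseudocount: float = 1.0
    n_perm: int = 200
    hmo: str | None = None
    sim: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages and self.input_dir is None:
            raise DependencyError("without the simulate stage, input_dir is required")
        if "enrich" in self.stages and "de" not in self.stages:
            raise DependencyError("the enrich stage needs the de stage's output")

    @classmethod
    def from_toml(cls, path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _default_pairs(gene_names, truth: dict | None, limit: int = 8):
    pairs = set()
    if truth:
        for a, b, _, _ in truth.get("planted_pairs", []):
            pairs.add((a, b))
    pairs.update(itertools.combinations(list(gene_names)[:limit], 2))
    return sorted(pairs)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages; returns the manifest (also written)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_ORDER if s in cfg.stages]
    manifest: dict = {
        "package_version": __version__,
        "config": dataclasses.asdict(cfg),
        "stages": {},
        "inputs": {},
        "outputs": {},
    }
    outputs: dict[str, Path] = {}

    def finish_stage(name, t0, **counts):
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **counts}
        logger.info("stage %s done in %.2fs", name, manifest["stages"][name]["seconds"])

    # --- io / simulate
    t0 = time.perf_counter()
    truth = None
    if "simulate" in stages:
        sim = SimConfig(seed=cfg.seed, **cfg.sim)
        dataset = simulate_dataset(sim)
        fixture_dir = out / "fixture"
        paths = write_fixture(dataset, fixture_dir)
        adata, panel, truth = dataset.cells, dataset.hmo_panel, dataset.truth
        library = load_gmt(paths["gene_sets"])
        for key, p in paths.items():
            outputs[f"fixture_{key}"] = Path(p)
        finish_stage("simulate", t0, n_cells=int(adata.n_obs), n_samples=int(panel.shape[0]))
    else:
        src = Path(cfg.input_dir)
        for required in ("matrix.mtx", "genes.tsv", "cells.tsv", "hmo_panel.csv"):
            if not (src / required).exists():
                raise DependencyError(f"input file missing: {src / required}")
        adata = load_cell_data(src / "matrix.mtx", src / "genes.tsv", src / "cells.tsv")
        panel = load_hmo_panel(src / "hmo_panel.csv")
        gmt = src / "gene_sets.gmt"
        library = load_gmt(gmt) if gmt.exists() else None
        truth_path = src / "truth.json"
        if truth_path.exists():
            truth = json.loads(truth_path.read_text())
        for p in src.iterdir():
            manifest["inputs"][p.name] = _sha256(p)

    pb = aggregate_pseudobulk(adata, cfg.cell_types)
    props = cell_type_proportions(adata)
    props.to_csv(out / "cell_type_proportions.tsv", sep="\t")
    outputs["proportions"] = out / "cell_type_proportions.tsv"
    hmos = hmo_columns(panel)
    hmo = cfg.hmo or hmos[0]

    # --- coexpression
    if "coexpr" in stages:
        t0 = time.perf_counter()
        pairs = cfg.coexpr_pairs or _default_pairs(adata.var_names, truth)
        coex = CooccurrenceAnalyzer(
            cell_type=cfg.coexpr_cell_type, alpha=cfg.alpha, top_n=cfg.top_n
        ).fit(adata, pairs)
        coex.records_.to_csv(out / "coexpression_records.tsv", sep="\t", index=False)
        coex.summary_.to_csv(out / "coexpression_summary.tsv", sep="\t", index=False)
        outputs["coexpr_records"] = out / "coexpression_records.tsv"
        outputs["coexpr_summary"] = out / "coexpression_summary.tsv"
        finish_stage("coexpr", t0, n_records=len(coex.records_), n_pairs=len(coex.summary_))

    # --- mixed-model associations
    if "assoc" in stages:
        t0 = time.perf_counter()
        time_res = TimeAssociationLMM().fit(panel, hmos).results_
        prop_cts = [ct for ct in cfg.cell_types if ct in props.columns]
        prop_res = ProportionAssociationLMM(cell_types=prop_cts).fit(panel, props, hmos).results_
        assoc = pd.concat([time_res, prop_res], ignore_index=True)
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
        outputs["assoc"] = out / "associations.tsv"
        finish_stage("assoc", t0, n_tests=len(assoc))

    # --- differential expression
    de_results = None
    if "de" in stages:
        t0 = time.perf_counter()
        wald = PseudobulkDE(design="cluster").fit(pb).results_
        wald.to_csv(out / "de_cluster_wald.tsv", sep="\t", index=False)
        outputs["de_wald"] = out / "de_cluster_wald.tsv"
        de_results = PseudobulkDE(design="hmo", hmo=hmo, cell_type=cfg.cell_types[-1]).fit(
            pb, panel
        ).results_
        de_results.to_csv(out / f"de_hmo_lrt.tsv", sep="\t", index=False)
        outputs["de_hmo"] = out / "de_hmo_lrt.tsv"
        lfc = per_sample_log2fc(pb, *cfg.cell_types[:2], pseudocount=cfg.pseudocount)
        lfc.to_csv(out / "per_sample_log2fc.tsv", sep="\t")
        outputs["lfc"] = out / "per_sample_log2fc.tsv"
        times = panel["time_postpartum_days"]
        corr = correlate_lfc_time(lfc, times, method="spearman")
        corr.to_csv(out / "lfc_time_correlation.tsv", sep="\t", index=False)
        outputs["lfc_time"] = out / "lfc_time_correlation.tsv"
        finish_stage("de", t0, n_genes=len(wald))

    # --- enrichment
    if "enrich" in stages:
        if de_results is None:
            raise DependencyError("enrich requested but no DE output available")
        if library is None:
            raise DependencyError("enrich requested but no gene-set library found")
        t0 = time.perf_counter()
        ranked = rank_metric(de_results)
        gsea = PrerankedGSEA(n_perm=cfg.n_perm, seed=cfg.seed).fit(ranked, library).results_
        gsea_out = gsea.copy()
        gsea_out["leading_edge"] = gsea_out["leading_edge"].map(",".join)
        gsea_out.to_csv(out / "gsea.tsv", sep="\t", index=False)
        outputs["gsea"] = out / "gsea.tsv"
        sig_up = ranked.loc[(ranked["score"] > 0), "gene"].head(25)
        mr = MeanRankTF(background_size=adata.n_vars).fit(set(sig_up), [library]).results_
        mr_out = mr.copy()
        mr_out["library_ranks"] = mr_out["library_ranks"].map(json.dumps)
        mr_out.to_csv(out / "tf_meanrank.tsv", sep="\t", index=False)
        outputs["tf_meanrank"] = out / "tf_meanrank.tsv"
        finish_stage("enrich", t0, n_sets=len(gsea), n_tfs=len(mr))

    for name, path in outputs.items():
        manifest["outputs"][name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
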