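"""End-to-end orchestration: simulate (or load) -> quantify -> differential
expression per model -> GSEA -> cross-model concordance -> annotation and
promoter TFBS ranking, written as a reproducible report bundle.

A single study seed feeds a deterministic per-stage seed derivation keyed
by stage name, so each stage is reproducible in isolation and two runs with
the same configuration are bit-identical.  The bundle's manifest records
the configuration, derived seeds, package version and SHA-256 checksums of
every written file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .annotate import class_fraction, tfbs_enrichment
from .crossmodel import ConcordanceCriteria, concordance_filter, heatmap_matrix, overlap_counts
from .diffexpr import de_table
from .gsea import gsea_suite, results_frame
from .simulate import (
    default_config,
    simulate_atlas,
    simulate_counts,
    simulate_gene_sets,
    simulate_promoter_hits,
)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "derive_seed"]

log = logging.getLogger("isletkit.pipeline")


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed keyed by stage name (below 2**31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything a run needs: inputs (real paths or a simulation block),
    stage parameters, seed and output directory."""

    outdir: str
    seed: int = 0
    simulation: dict | None = None
    counts_path: str | None = None
    lengths_path: str | None = None
    gmt_path: str | None = None
    atlas_expr_path: str | None = None
    atlas_class_path: str | None = None
    promoter_hits_path: str | None = None
    index_model: str | None = None
    corroborating_models: list | None = None
    gsea_mode: str = "absolute"
    gsea_shuffles: int = 10_000
    gsea_weight: float = 1.0
    fdr_threshold: float = 0.30
    fc_threshold: float = 1.4
    e_threshold: float = 0.1
    p_threshold: float = 0.05
    min_further_models: int = 1
    tissue_factor: float = 5.0
    top_k: int = 12
    tfbs_n_tfs: int = 200
    tfbs_genome_promoters: int = 25_000
    tfbs_planted: list = field(default_factory=lambda: [["Zfp206", 5.0], ["HIF1", 3.0]])
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.simulation is None and self.counts_path is None:
            raise ValueError("config needs either a simulation block or input paths")
        if self.counts_path is not None and self.lengths_path is None:
            raise ValueError("counts_path requires lengths_path")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        # outdir identifies where the bundle lives, not what the run computes;
        # keeping it out of the manifest makes replays bit-comparable
        d = dict(self.__dict__)
        d.pop("outdir", None)
        return d


@dataclass
class ReportBundle:
    outdir: Path
    files: dict
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _timed(name: str, fn, *args, **kw):
    t0 = time.perf_counter()
    out = fn(*args, **kw)
    log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
    return out


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and write the report bundle.

    Inputs are validated and loaded before anything is written; on error no
    partial bundle is left behind (outputs land in a temporary directory
    that is renamed into place only on success).
    """
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()):
        raise ValueError(f"output directory {outdir} exists and is not empty")

    # ---- load or simulate inputs (no writes yet) -------------------------
    sim_truth = None
    kinase_of: dict = {}
    if config.simulation is not None:
        sim_cfg = default_config(seed=derive_seed(config.seed, "simulate"), **config.simulation)
        study, sim_truth = _timed("simulate", simulate_counts, sim_cfg)
        matrices = study.models
        lengths = study.lengths
        kinase_of = {m.name: m.kinase for m in sim_cfg.models}
        sets = simulate_gene_sets(sim_truth, seed=derive_seed(config.seed, "gene_sets"))
        atlas = simulate_atlas(sim_truth, seed=derive_seed(config.seed, "atlas"))
        hits = None  # simulated later, once the submitted list size is known
    else:
        combined = io.read_counts(config.counts_path, config.lengths_path)
        lengths = combined.lengths
        matrices = {m: combined.for_model(m) for m in combined.models}
        sets = io.read_gmt(config.gmt_path) if config.gmt_path else []
        atlas = (
            io.read_atlas(config.atlas_expr_path, config.atlas_class_path)
            if config.atlas_expr_path
            else None
        )
        hits = io.read_promoter_hits(config.promoter_hits_path) if config.promoter_hits_path else None

    model_names = list(matrices)
    index_model = config.index_model or model_names[0]
    if index_model not in matrices:
        raise ValueError(f"unknown index model {index_model!r}")

    # ---- compute all stages in memory ------------------------------------
    de_tables = {
        name: _timed(f"de:{name}", de_table, cm, name) for name, cm in matrices.items()
    }
    for name, de in de_tables.items():
        log.info("model %s: %d genes, %d tested", name, len(de), int(de["tested"].sum()))

    gsea_frames = {}
    if sets:
        for name, de in de_tables.items():
            res = _timed(
                f"gsea:{name}",
                gsea_suite,
                de,
                sets,
                mode=config.gsea_mode,
                B=config.gsea_shuffles,
                weight=config.gsea_weight,
                seed=derive_seed(config.seed, f"gsea:{name}"),
                fdr_threshold=config.fdr_threshold,
            )
            gsea_frames[name] = results_frame(res)

    criteria = ConcordanceCriteria(
        fc_threshold=config.fc_threshold,
        e_threshold=config.e_threshold,
        p_threshold=config.p_threshold,
        min_further_models=config.min_further_models,
    )
    if config.corroborating_models is not None:
        corroborating = list(config.corroborating_models)
    elif kinase_of:
        corroborating = [
            m for m in model_names if m != index_model and kinase_of[m] == kinase_of[index_model]
        ]
    else:
        corroborating = [m for m in model_names if m != index_model]
    display = [m for m in model_names if m != index_model and m not in corroborating]
    conc = _timed(
        "crossmodel",
        concordance_filter,
        de_tables[index_model],
        [de_tables[m] for m in corroborating],
        criteria,
        display_only=[de_tables[m] for m in display],
    )
    top_k = min(config.top_k, int(conc.index_rank.notna().sum()))
    per_model, per_m = overlap_counts(conc, top_k)
    matrix, mask = heatmap_matrix(conc)

    passed_up = conc.status.loc[conc.passed, index_model] == "up"
    up_genes = list(passed_up.index[passed_up])

    fractions = None
    if atlas is not None and up_genes:
        in_atlas = [g for g in up_genes if g in atlas.expression.index]
        rows = []
        for cls in atlas.classes:
            count, total, pct = class_fraction(in_atlas, atlas, cls, config.tissue_factor)
            rows.append({"class": cls, "count": count, "total": total, "percent": pct})
        fractions = pd.DataFrame(rows)

    if config.simulation is not None:
        n_submitted = max(len(up_genes), 100)
        hits = simulate_promoter_hits(
            n_tfs=config.tfbs_n_tfs,
            n_submitted=n_submitted,
            genome_promoters=config.tfbs_genome_promoters,
            planted=[tuple(p) for p in config.tfbs_planted],
            seed=derive_seed(config.seed, "promoter_hits"),
        )
    tfbs = tfbs_enrichment(hits) if hits is not None else None

    # ---- write the bundle atomically -------------------------------------
    tmp = outdir.parent / (outdir.name + ".partial")
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    files: dict = {}

    def emit(name: str, writer, *args) -> None:
        path = tmp / name
        writer(*args, path)
        files[name] = path

    try:
        if config.simulation is not None:
            for name, cm in matrices.items():
                emit(f"counts_{name}.tsv", io.write_counts, cm)
            emit("lengths.tsv", io.write_lengths, lengths)
            emit("gene_sets.gmt", io.write_gmt, sets)
            emit("atlas_expression.tsv", lambda a, p: io.write_atlas(a, p, tmp / "atlas_classes.tsv"), atlas)
            files["atlas_classes.tsv"] = tmp / "atlas_classes.tsv"
            truth_df = sim_truth.fold_changes.add_prefix("fc:").join(
                sim_truth.absent.add_prefix("absent:")
            )
            truth_df.insert(0, "group", sim_truth.groups)
            truth_df.insert(0, "gene", truth_df.index)
            emit("truth.tsv", io.write_table, truth_df)
        for name, de in de_tables.items():
            emit(f"de_{name}.tsv", io.write_table, de)
        for name, gf in gsea_frames.items():
            emit(f"gsea_{name}.tsv", io.write_table, gf)
        emit("concordance.tsv", io.write_concordance, conc)
        emit("heatmap.tsv", lambda m, mk, p: io.write_heatmap_tsv(m, mk, p), matrix, mask)
        emit(
            "overlap_counts.tsv",
            io.write_table,
            per_model.reset_index(names="model"),
        )
        emit(
            "overlap_per_m.tsv",
            io.write_table,
            per_m.reset_index(),
        )
        if fractions is not None:
            emit("annotation_fractions.tsv", io.write_table, fractions)
        if tfbs is not None:
            emit("tfbs_ranking.tsv", io.write_table, tfbs)
        if config.make_plots:
            from .crossmodel import plot_heatmap

            plot_heatmap(conc, tmp / "heatmap.png")
            files["heatmap.png"] = tmp / "heatmap.png"

        manifest = {
            "tool": "isletkit",
            "version": __version__,
            "seed": config.seed,
            "stage_seeds": {
                s: derive_seed(config.seed, s)
                for s in ["simulate", "gene_sets", "atlas", "promoter_hits"]
                + [f"gsea:{m}" for m in model_names]
            },
            "config": config.to_dict(),
            "index_model": index_model,
            "corroborating_models": corroborating,
            "n_passed": int(conc.passed.sum()),
            "files": {},
        }
        for name in sorted(files):
            manifest["files"][name] = _sha256(files[name])
        with open(tmp / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        files["manifest.json"] = tmp / "manifest.json"
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise

    if outdir.exists():
        outdir.rmdir()
    tmp.rename(outdir)
    files = {name: outdir / name for name in files}
    return ReportBundle(outdir=outdir, files=files, manifest=manifest)
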