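"""End-to-end pipeline: simulate/load -> QC -> tile -> segment -> DMR -> panel.

Stages hand files off as plain TSV/BED so each one is independently
testable; ``run_all`` chains them and writes a single JSON report whose
arithmetic is internally consistent (libraries in = kept + discarded).
Libraries discarded by QC never reach any downstream stage, mirroring how
contaminated samples are dropped from the study.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as oio
from . import qc as oqc
from . import simulate as osim
from . import stats as ostats
from . import tiling as otile

logger = logging.getLogger("oometh")

__all__ = ["PipelineConfig", "validate_config", "run_all", "load_cov_dir"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for the full pipeline.

    Threshold defaults are the analysis constants used throughout: 500-CG
    tiles with >=5 observed CGs for the unbiased landscape, 100-CG tiles
    with >=10 observed CGs per merged domain for the segmented analysis,
    hyper/hypo tile cutoffs at 75/25, the 50% domain-state cutoff, a 10-point
    minimum absolute change, alpha 0.05, and the 2.5% CH / 10% exemplar /
    30% ChrX CGI contamination filters.
    """

    seed: int = 0
    simulate: bool = True
    cov_dir: str | None = None
    fasta: str | None = None
    cgi_bed: str | None = None
    genes_bed: str | None = None
    panel_bed: str | None = None
    extra_bed: str | None = None
    exemplar: str | None = None  # "chrom:start-end"
    # QC thresholds
    ch_min: float = 2.5
    ref_region_max: float = 10.0
    chrx_max: float = 30.0
    x_chrom: str = "chrX"
    # tiling / segmentation
    tile_cg: int = 500
    min_cg: int = 5
    seg_tile_cg: int = 100
    seg_min_cg: int = 10
    hyper_cutoff: float = 75.0
    hypo_cutoff: float = 25.0
    domain_threshold: float = 50.0
    # DMR statistics
    alpha: float = 0.05
    min_abs_diff: float = 10.0
    correction: str = "none"  # pooled-mode correction: none | bh
    m_override: int | None = None
    log_level: str = "INFO"
    # optional SimulationConfig field overrides for the simulate stage
    sim: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("tile_cg", "seg_tile_cg", "min_cg", "seg_min_cg"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("ch_min", "ref_region_max", "chrx_max", "hyper_cutoff",
                     "hypo_cutoff", "domain_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be within [0, 100], got {v}")
        if self.min_abs_diff < 0:
            raise ValueError("min_abs_diff must be >= 0")
        if self.correction not in ("none", "bh"):
            raise ValueError(f"correction must be 'none' or 'bh', got {self.correction}")

    def qc_thresholds(self, ref_region: tuple[str, int, int] | None) -> oqc.QCThresholds:
        return oqc.QCThresholds(
            ch_meth_min_pct=self.ch_min,
            ref_region=ref_region,
            ref_region_max_pct=self.ref_region_max,
            chrx_cgi_max_pct=self.chrx_max,
            x_chrom=self.x_chrom,
        )


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (0-based half-open)."""
    try:
        chrom, span = text.split(":")
        start, end = (int(x) for x in span.split("-"))
    except ValueError as exc:
        raise ValueError(f"cannot parse region {text!r}: expected chrom:start-end") from exc
    if start >= end:
        raise ValueError(f"region {text!r}: start must be < end")
    return chrom, start, end


def validate_config(source: str | Path | Mapping[str, Any] | None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file or mapping, defaults filled.

    Unknown keys and out-of-range values are rejected with the field name.
    """
    if source is None:
        return PipelineConfig()
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return PipelineConfig(**data)


def load_cov_dir(cov_dir: str | Path) -> list[oio.MethylomeLibrary]:
    """Load every ``*.CpG.cov`` (+ sibling ``*.CHH.cov``) in a directory.

    Library metadata comes from ``manifest.tsv`` when present, otherwise
    the ``GROUP_DONOR_NN`` filename convention.
    """
    cov_dir = Path(cov_dir)
    meta: dict[str, tuple[str, str]] = {}
    manifest = cov_dir / "manifest.tsv"
    if not manifest.exists():
        manifest = cov_dir.parent / "manifest.tsv"
    if manifest.exists():
        df = pd.read_csv(manifest, sep="\t")
        meta = {
            r["library_id"]: (str(r.get("donor_id", "")), str(r.get("group", "")))
            for _, r in df.iterrows()
        }
    libs = []
    paths = sorted(cov_dir.glob("*.CpG.cov")) + sorted(cov_dir.glob("*.CpG.cov.gz"))
    for path in paths:
        lib_id = path.name.split(".CpG.cov")[0]
        donor, group = meta.get(lib_id, ("", ""))
        if not group:
            group = lib_id.split("_")[0]
        calls = oio.read_coverage(path)
        ch_path = path.with_name(path.name.replace(".CpG.cov", ".CHH.cov"))
        ch_calls = oio.read_coverage(ch_path, context="CH") if ch_path.exists() else {}
        libs.append(
            oio.MethylomeLibrary(
                library_id=lib_id,
                donor_id=donor,
                group=group,
                calls=calls,
                ch_calls=ch_calls,
            )
        )
    return libs


def _domains_to_bed(domains: Sequence[otile.Domain], path: Path) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.state}\n")


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage in order and write the run report.

    Returns the report dict; raises with a stage-named message on failure.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed}

    # --- stage: inputs -----------------------------------------------------
    stage = "simulate" if config.simulate else "load"
    try:
        if config.simulate:
            sim_cfg = osim.SimulationConfig(seed=config.seed, **(config.sim or {}))
            study = osim.simulate_study(sim_cfg, out_dir=out / "simulated")
            libs = study.libraries
            index = study.genome.index
            cgi_track = study.genome.cgi_track
            gene_track = study.genome.gene_track
            panel_track = study.genome.panel_track
            ref_region = study.genome.exemplar_region
        else:
            if not config.cov_dir or not Path(config.cov_dir).exists():
                raise FileNotFoundError(
                    f"coverage directory {config.cov_dir!r} not found (use simulate=true "
                    "to generate a synthetic study)"
                )
            libs = load_cov_dir(config.cov_dir)
            if not libs:
                raise FileNotFoundError(f"no *.CpG.cov files in {config.cov_dir}")
            if not config.fasta:
                raise ValueError("fasta is required when loading real coverage data")
            index = oio.build_genome_index(config.fasta)
            cgi_track = oio.read_bed(config.cgi_bed) if config.cgi_bed else None
            gene_track = oio.read_bed(config.genes_bed) if config.genes_bed else None
            panel_track = oio.read_bed(config.panel_bed) if config.panel_bed else None
            ref_region = parse_region(config.exemplar) if config.exemplar else None
        if config.extra_bed:
            extra = oio.read_bed(config.extra_bed)
            feats = (list(panel_track) if panel_track else []) + list(extra)
            panel_track = oio.AnnotationTrack("panel+extra", feats)
    except Exception as exc:
        raise RuntimeError(f"stage {stage}: {exc}") from exc
    report["n_libraries_in"] = len(libs)
    logger.info("%s: %d libraries", stage, len(libs))

    # --- stage: qc ---------------------------------------------------------
    try:
        thresholds = config.qc_thresholds(ref_region)
        qc_report = oqc.qc_study(libs, cgi_track, thresholds, index)
        qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        kept_ids = set(qc_report.loc[qc_report["decision"] == "keep", "library_id"])
        kept = [lib for lib in libs if lib.library_id in kept_ids]
    except Exception as exc:
        raise RuntimeError(f"stage qc: {exc}") from exc
    report["n_kept"] = len(kept)
    report["n_discarded"] = len(libs) - len(kept)
    logger.info("qc: kept %d, discarded %d", report["n_kept"], report["n_discarded"])
    if not kept:
        raise RuntimeError("stage qc: no library passed QC")
    ns = [l for l in kept if l.group == "NS"]
    s = [l for l in kept if l.group == "S"]
    report["n_kept_NS"], report["n_kept_S"] = len(ns), len(s)

    # --- stage: tile (unbiased landscape) ----------------------------------
    try:
        tiles = otile.make_cg_tiles(index, config.tile_cg)
        q_all = otile.quantitate_tiles(tiles, kept, config.min_cg)
        q_ns = otile.quantitate_tiles(tiles, ns, config.min_cg)
        q_s = otile.quantitate_tiles(tiles, s, config.min_cg)
        report["n_tiles"] = len(tiles)
        report["n_tiles_quantified"] = sum(q is not None for q in q_all)
        classes_all = {
            t.region_id: otile.classify_tile(q.pct, config.hyper_cutoff, config.hypo_cutoff)
            for t, q in zip(tiles, q_all)
            if q is not None
        }
        report["n_hyper_tiles"] = sum(v == "hyper" for v in classes_all.values())
        report["n_hypo_tiles"] = sum(v == "hypo" for v in classes_all.values())
        report["global_mean_pct"] = otile.global_mean(kept)
        report["global_mean_pct_NS"] = otile.global_mean(ns) if ns else None
        report["global_mean_pct_S"] = otile.global_mean(s) if s else None

        tile_dmrs = ostats.call_dmrs_pooled(
            q_ns, q_s, config.alpha, config.min_abs_diff,
            None if config.correction == "none" else config.correction,
        )
        for r, t in zip(
            tile_dmrs,
            (t for t, qa, qb in zip(tiles, q_ns, q_s) if qa is not None and qb is not None),
        ):
            r.chrom, r.start, r.end = t.chrom, t.start, t.end
        oio.write_results_table(tile_dmrs, out / "dmrs_tiles.tsv")
        report["n_tile_dmrs"] = sum(r.passes for r in tile_dmrs)

        cls_ns = {
            t.region_id: otile.classify_tile(q.pct, config.hyper_cutoff, config.hypo_cutoff)
            for t, q in zip(tiles, q_ns)
            if q is not None
        }
        cls_s = {
            t.region_id: otile.classify_tile(q.pct, config.hyper_cutoff, config.hypo_cutoff)
            for t, q in zip(tiles, q_s)
            if q is not None
        }
        dmr_by_tile = {r.region_id: r for r in tile_dmrs}
        venn = ostats.venn_partition(cls_ns, cls_s, dmr_by_tile)
        report["venn"] = {
            label: {
                "NS_total": v.n_a_total,
                "S_total": v.n_b_total,
                "common": v.n_common,
                "NS_only": v.n_a_only,
                "S_only": v.n_b_only,
                "NS_only_significant": v.n_a_only_significant,
                "S_only_significant": v.n_b_only_significant,
            }
            for label, v in venn.items()
        }
        if gene_track is not None:
            ostats.export_gene_lists(tile_dmrs, gene_track, out / "gene_lists")
    except Exception as exc:
        raise RuntimeError(f"stage tile: {exc}") from exc
    logger.info("tile: %d tiles, %d quantified", report["n_tiles"], report["n_tiles_quantified"])

    # --- stage: segment ----------------------------------------------------
    try:
        seg_tiles = otile.make_cg_tiles(index, config.seg_tile_cg)
        seg_q = otile.quantitate_tiles(seg_tiles, kept, min_cg_obs=1)
        domains = otile.segment_domains(seg_tiles, seg_q, config.domain_threshold)
        _domains_to_bed(domains, out / "domains.bed")
        report["n_domains"] = len(domains)
        report["n_domains_M"] = sum(d.state == "M" for d in domains)
        report["n_domains_U"] = sum(d.state == "U" for d in domains)

        dq_ns = otile.quantitate_domains(domains, ns, config.seg_min_cg)
        dq_s = otile.quantitate_domains(domains, s, config.seg_min_cg)
        dom_dmrs = ostats.call_dmrs_pooled(
            dq_ns, dq_s, config.alpha, config.min_abs_diff,
            None if config.correction == "none" else config.correction,
        )
        oio.write_results_table(dom_dmrs, out / "dmrs_domains_pooled.tsv")
        report["n_domain_dmrs_pooled"] = sum(r.passes for r in dom_dmrs)

        per_cell_ns = [otile.quantitate_domains(domains, l, config.seg_min_cg) for l in ns]
        per_cell_s = [otile.quantitate_domains(domains, l, config.seg_min_cg) for l in s]
        region_ids = [d.region_id for d in domains]
        pcts_a = [
            [None if qs[i] is None else qs[i].pct for qs in per_cell_ns]
            for i in range(len(domains))
        ]
        pcts_b = [
            [None if qs[i] is None else qs[i].pct for qs in per_cell_s]
            for i in range(len(domains))
        ]
        rep_dmrs = ostats.call_dmrs_replicates(region_ids, pcts_a, pcts_b, config.alpha)
        oio.write_results_table(rep_dmrs, out / "dmrs_domains_replicates.tsv")
        report["n_domain_dmrs_replicates"] = sum(r.passes for r in rep_dmrs)
        report["n_domains_tested_replicates"] = sum(
            r.p_raw is not None for r in rep_dmrs
        )
    except Exception as exc:
        raise RuntimeError(f"stage segment: {exc}") from exc
    logger.info("segment: %d domains", report["n_domains"])

    # --- stage: panel ------------------------------------------------------
    try:
        if panel_track is not None and len(panel_track) and ns and s:
            panel = ostats.panel_analysis(
                panel_track, ns, s, index,
                alpha=config.alpha, m_override=config.m_override,
            )
            panel.to_csv(out / "panel.tsv", sep="\t", index=False)
            report["n_panel_features"] = len(panel)
            report["n_panel_significant"] = int(panel["significant"].sum())
    except Exception as exc:
        raise RuntimeError(f"stage panel: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    logger.info("report written to %s", out / "report.json")
    return report
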