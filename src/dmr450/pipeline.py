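"""End-to-end orchestration of the comparative methylome analysis.

Stage order: probe filtering → probe-design normalization → β→M transform
→ moderated differential test → BH FDR → hyper/hypo classification →
de novo calling → region detection (merge, permutation calibration, rank,
de novo flag) → cytoband and chromatin-mark enrichment.  Every written
artifact carries a header comment with tool version, config hash, and
seed; re-running with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .core import BetaMatrix, IntervalTrack, Region, regions_to_frame
from .diffmeth import bh_fdr, call_de_novo, classify_loci, moderated_test
from .enrichment import EnrichmentResult, cgi_breakdown, fisher_enrichment, overlap_probes
from .io import (
    read_bed,
    read_beta_tsv,
    read_manifest_csv,
    read_sample_sheet_csv,
    write_beta_tsv,
    write_regions_bed,
    write_table_tsv,
)
from .preprocess import beta_to_m, bmiq_normalize, filter_probes
from .regions import (
    band_enrichment,
    calibrate_regions,
    flag_de_novo_regions,
    merge_adjacent,
    permutation_calibrate,
    rank_and_select,
)

log = logging.getLogger("dmr450")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    filtered_beta: BetaMatrix
    normalized_beta: BetaMatrix
    diffmeth: pd.DataFrame
    regions: list[Region]
    top_regions: list[Region]
    band_table: pd.DataFrame
    mark_enrichment: list[EnrichmentResult]
    cgi_props: pd.Series | None
    cgi_aggregate: float | None
    stage_counts: dict[str, int] = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


def run_all(
    config: PipelineConfig,
    beta: BetaMatrix | None = None,
    manifest: pd.DataFrame | None = None,
    sheet: pd.DataFrame | None = None,
    tracks: dict[str, IntervalTrack] | None = None,
    write: bool = True,
) -> PipelineResult:
    """Run the whole pipeline; inputs come from ``config`` paths unless the
    in-memory objects are supplied directly."""
    config.validate()
    header = f"dmr450 v{__version__} config={config.hash()} seed={config.seed}"
    counts: dict[str, int] = {}

    if beta is None:
        beta = _stage("read_inputs")(read_beta_tsv)(config.beta_path, config.detection_p_path)
    if manifest is None:
        manifest = _stage("read_inputs")(read_manifest_csv)(config.manifest_path)
    if sheet is None:
        sheet = _stage("read_inputs")(read_sample_sheet_csv)(config.sheet_path)
    if tracks is None:
        tracks = {
            name: _stage("read_inputs")(read_bed)(path, name)
            for name, path in config.track_paths.items()
        }
    counts["probes_in"] = len(beta.probes)
    counts["samples_in"] = len(beta.samples)

    filtered, report = _stage("filter")(filter_probes)(
        beta,
        manifest,
        detect_p_cut=config.detect_p_cut,
        fail_fraction=config.fail_fraction,
        drop_cross_reactive=config.drop_cross_reactive,
        drop_snp_proximal=config.drop_snp_proximal,
        strict=False,
    )
    counts["probes_after_filter"] = len(filtered.probes)
    log.info("filter: %d -> %d probes", counts["probes_in"], counts["probes_after_filter"])

    normalized = _stage("bmiq")(bmiq_normalize)(filtered, manifest)
    m = _stage("m_transform")(beta_to_m)(normalized)

    stats = _stage("moderated_test")(moderated_test)(m, sheet, design=config.design)
    stats["fdr"] = bh_fdr(stats["p"].to_numpy())
    stats = _stage("classify")(classify_loci)(
        stats, normalized, sheet, fdr_cut=config.fdr_diff, delta_cut=config.delta_cut
    )
    counts["diff_loci"] = int((stats["status"] != "ns").sum())
    counts["hyper_loci"] = int((stats["status"] == "hyper").sum())
    counts["hypo_loci"] = int((stats["status"] == "hypo").sum())

    stats = _stage("de_novo")(call_de_novo)(
        stats,
        normalized,
        sheet,
        manifest,
        mode=config.de_novo_mode,
        beta_ref_cut=config.beta_ref_cut,
        delta_cut=config.delta_cut,
        tumor_beta_cut=config.tumor_beta_cut,
        freq_cut=config.freq_cut,
        autosomes_only=config.autosomes_only,
    )
    counts["de_novo_loci"] = int(stats["de_novo"].sum())
    log.info(
        "differential: %d loci (hyper %d / hypo %d), de novo %d",
        counts["diff_loci"], counts["hyper_loci"], counts["hypo_loci"], counts["de_novo_loci"],
    )

    regs = _stage("regions_merge")(merge_adjacent)(
        stats, manifest,
        fdr_cut=config.region_fdr_cut, gap_bp=config.gap_bp,
        min_probes=config.min_probes, direction=config.region_direction,
    )
    null_table = _stage("regions_calibrate")(permutation_calibrate)(
        stats, manifest,
        n_perm=config.n_perm, seed=config.seed,
        fdr_cut=config.region_fdr_cut, gap_bp=config.gap_bp,
        min_probes=config.min_probes, direction=config.region_direction,
    )
    regs = _stage("regions_calibrate")(calibrate_regions)(regs, null_table)
    top = _stage("regions_rank")(rank_and_select)(regs, top_n=config.top_n)
    top = _stage("regions_flag")(flag_de_novo_regions)(
        top, normalized, sheet, beta_ref_cut=config.beta_ref_cut
    )
    counts["regions"] = len(regs)
    counts["top_regions"] = len(top)

    band_tab = _stage("band_enrichment")(band_enrichment)(
        top, manifest, universe="probes", universe_probe_ids=list(stats.index)
    ) if top else pd.DataFrame(columns=["band", "n_target", "n_universe", "p", "fdr"])

    de_novo_probes = set(stats.index[stats["de_novo"]])
    universe = set(stats.index)
    mark_results: list[EnrichmentResult] = []
    fmani = manifest[manifest["probe_id"].isin(universe)]
    for name, track in tracks.items():
        ov = _stage("mark_enrichment")(overlap_probes)(
            fmani, track, harmonize_chrom=config.harmonize_chrom
        )
        if de_novo_probes and de_novo_probes != universe:
            mark_results.append(
                _stage("mark_enrichment")(fisher_enrichment)(
                    de_novo_probes, universe, ov, track_name=name
                )
            )

    cgi_props = cgi_agg = None
    if de_novo_probes:
        cgi_props, cgi_agg = _stage("cgi_breakdown")(cgi_breakdown)(de_novo_probes, manifest)

    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _stage("write")(write_beta_tsv)(normalized, outdir / "normalized_beta.tsv",
                                        header_comment=header)
        _stage("write")(write_table_tsv)(report, outdir / "filter_report.tsv",
                                         header_comment=header)
        _stage("write")(write_table_tsv)(stats, outdir / "diffmeth.tsv",
                                         header_comment=header, index=True,
                                         index_label="probe_id")
        _stage("write")(write_regions_bed)(top, outdir / "regions.bed", header_comment=header)
        _stage("write")(write_table_tsv)(band_tab, outdir / "band_enrichment.tsv",
                                         header_comment=header)
        enr_tab = pd.DataFrame(
            [
                {"track": e.track_name, "a": e.a, "b": e.b, "c": e.c, "d": e.d,
                 "odds_ratio": e.odds_ratio, "p": e.p}
                for e in mark_results
            ]
        )
        _stage("write")(write_table_tsv)(enr_tab, outdir / "mark_enrichment.tsv",
                                         header_comment=header)
        with open(outdir / "run_log.txt", "w") as fh:
            fh.write(f"# {header}\n")
            for k, v in counts.items():
                fh.write(f"{k}\t{v}\n")

    return PipelineResult(
        filtered_beta=filtered,
        normalized_beta=normalized,
        diffmeth=stats,
        regions=regs,
        top_regions=top,
        band_table=band_tab,
        mark_enrichment=mark_results,
        cgi_props=cgi_props,
        cgi_aggregate=cgi_agg,
        stage_counts=counts,
    )
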