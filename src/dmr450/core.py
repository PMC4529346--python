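"""Shared data containers for the 450k methylome analysis pipeline.

Conventions used throughout the package:

* Probe manifests carry 1-based probe positions (array-annotation
  convention); all BED-style intervals are 0-based half-open.  The
  conversion between the two happens in exactly one place,
  :func:`dmr450.enrichment.overlap_probes`.
* β matrices are probes × samples pandas DataFrames with values in [0, 1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: CpG-island relation categories on the array, in reporting order.
CGI_CATEGORIES = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: Required probe-manifest columns.
MANIFEST_COLUMNS = (
    "probe_id",
    "chrom",
    "pos",
    "cgi_relation",
    "cytoband",
    "genes",
    "design_type",
    "cross_reactive",
    "snp_proximal",
)

#: Required sample-sheet columns.
SHEET_COLUMNS = ("sample_id", "subject_id", "group", "pair_id")

SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})


def is_autosome(chrom: str) -> bool:
    return chrom not in SEX_CHROMS


def validate_manifest(manifest: pd.DataFrame) -> None:
    """Check structural invariants of a probe manifest.

    Raises ``ValueError`` on the first violated invariant.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    if manifest["probe_id"].duplicated().any():
        dup = manifest.loc[manifest["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id in manifest: {dup!r}")
    if (manifest["pos"] < 1).any():
        raise ValueError("manifest positions must be >= 1 (1-based)")
    if manifest.duplicated(subset=["chrom", "pos"]).any():
        raise ValueError("duplicate (chrom, pos) in manifest")
    bad_cgi = set(manifest["cgi_relation"]) - set(CGI_CATEGORIES)
    if bad_cgi:
        raise ValueError(f"unknown cgi_relation categories: {sorted(bad_cgi)}")
    bad_design = set(manifest["design_type"]) - {"I", "II"}
    if bad_design:
        raise ValueError(f"unknown design_type values: {sorted(bad_design)}")
    # cytoband chromosome prefix must match chrom ("chr6" probes carry "6p..." bands)
    chrom_num = manifest["chrom"].astype(str).str.removeprefix("chr")
    band = manifest["cytoband"].astype(str)
    ok = [b.startswith(c) for b, c in zip(band, chrom_num)]
    if not all(ok):
        i = ok.index(False)
        raise ValueError(
            f"cytoband {band.iloc[i]!r} does not match chrom {manifest['chrom'].iloc[i]!r}"
        )


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    """Check the paired tumor/normal + PBMC-panel structure of a sample sheet."""
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet is missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id: {dup!r}")
    bad = set(sheet["group"]) - {"tumor", "normal", "pbmc"}
    if bad:
        raise ValueError(f"unknown sample groups: {sorted(bad)}")
    pbmc = sheet[sheet["group"] == "pbmc"]
    if pbmc["pair_id"].notna().any():
        raise ValueError("pbmc samples must have null pair_id")
    tumors = sheet[(sheet["group"] == "tumor") & sheet["pair_id"].notna()]
    normals = sheet[(sheet["group"] == "normal") & sheet["pair_id"].notna()]
    counts = normals["pair_id"].value_counts()
    for pid in tumors["pair_id"]:
        if counts.get(pid, 0) != 1:
            raise ValueError(
                f"tumor pair_id {pid!r} must match exactly one normal sample"
            )


def paired_ids(sheet: pd.DataFrame) -> tuple[list[str], list[str], list[str]]:
    """Return (tumor_ids, normal_ids, pair_ids) aligned by pair_id."""
    tum = sheet[(sheet["group"] == "tumor") & sheet["pair_id"].notna()]
    nor = sheet[(sheet["group"] == "normal") & sheet["pair_id"].notna()]
    nor_by_pair = dict(zip(nor["pair_id"], nor["sample_id"]))
    tumor_ids, normal_ids, pids = [], [], []
    for _, row in tum.iterrows():
        pid = row["pair_id"]
        if pid not in nor_by_pair:
            raise ValueError(f"unmatched pair_id {pid!r}: no normal sample")
        tumor_ids.append(row["sample_id"])
        normal_ids.append(nor_by_pair[pid])
        pids.append(pid)
    return tumor_ids, normal_ids, pids


def group_ids(sheet: pd.DataFrame, group: str) -> list[str]:
    return sheet.loc[sheet["group"] == group, "sample_id"].tolist()


@dataclass
class BetaMatrix:
    """Probes × samples methylation fractions with optional detection p-values."""

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if self.detection_p is not None:
            if self.detection_p.shape != self.beta.shape:
                raise ValueError("detection_p shape differs from beta shape")
            if not self.detection_p.index.equals(self.beta.index):
                raise ValueError("detection_p probe index differs from beta")
            if not self.detection_p.columns.equals(self.beta.columns):
                raise ValueError("detection_p sample columns differ from beta")

    @property
    def probes(self) -> list[str]:
        return list(self.beta.index)

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        keep = self.beta.index.isin(set(probe_ids))
        dp = self.detection_p.loc[keep] if self.detection_p is not None else None
        return BetaMatrix(self.beta.loc[keep], dp)


@dataclass
class MMatrix:
    """Probes × samples logit-2 methylation values (finite everywhere)."""

    m: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.m.to_numpy()).all():
            raise ValueError("M-values must be finite (clip beta before transform)")

    @property
    def probes(self) -> list[str]:
        return list(self.m.index)

    @property
    def samples(self) -> list[str]:
        return list(self.m.columns)


@dataclass
class IntervalTrack:
    """Named genomic intervals, 0-based half-open, possibly overlapping."""

    name: str
    intervals: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self) -> None:
        cols = list(self.intervals.columns)
        for c in ("chrom", "start", "end"):
            if c not in cols:
                raise ValueError(f"interval table missing column {c!r}")
        iv = self.intervals
        if len(iv) and not (iv["start"] < iv["end"]).all():
            bad = iv[~(iv["start"] < iv["end"])].iloc[0]
            raise ValueError(
                f"interval with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}"
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def sorted(self) -> "IntervalTrack":
        iv = self.intervals.sort_values(["chrom", "start", "end"], kind="mergesort")
        return IntervalTrack(self.name, iv.reset_index(drop=True))


@dataclass
class Region:
    """A merged run of significant CpGs scored by the product of member FDRs.

    ``raw_score`` may underflow to 0.0 for long/strong regions; all
    comparisons therefore use ``log10_score`` (= Σ log10 member FDR).
    """

    chrom: str
    start: int  # 0-based half-open span covering member probes
    end: int
    probe_ids: list[str]
    k: int
    raw_score: float
    log10_score: float
    calibrated_p: float | None = None
    calibrated_fdr: float | None = None
    rank: int | None = None
    de_novo_region: bool | None = None

    def replace(self, **kw) -> "Region":
        return dataclasses.replace(self, **kw)


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    """Tabular view of a region list (one row per region)."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "k": [r.k for r in regions],
            "raw_score": [r.raw_score for r in regions],
            "log10_score": [r.log10_score for r in regions],
            "calibrated_p": [r.calibrated_p for r in regions],
            "calibrated_fdr": [r.calibrated_fdr for r in regions],
            "rank": [r.rank for r in regions],
            "de_novo_region": [r.de_novo_region for r in regions],
            "probe_ids": [";".join(r.probe_ids) for r in regions],
        }
    )
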