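"""Readers and writers for the plain-text formats the pipeline touches.

Matrices are TSV (probes as rows, header = sample ids), manifests and
sample sheets CSV, interval tracks and regions BED (0-based half-open).
All writers accept an optional header comment (prefixed ``#``) so pipeline
outputs can carry version, config hash, and seed; readers skip ``#`` lines.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BetaMatrix, IntervalTrack, Region, validate_manifest, validate_sample_sheet


def _write_comment(fh, comment: str | None) -> None:
    if comment:
        for line in comment.splitlines():
            fh.write(f"# {line}\n")


# ---------------------------------------------------------------------------
# matrices


def write_matrix_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_comment(fh, header_comment)
        df.to_csv(fh, sep="\t", float_format="%.12g", index_label="probe_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    path = Path(path)
    # manual ragged-row check: pandas pads short rows silently
    n_fields = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            n = line.rstrip("\n").count("\t") + 1
            if n_fields is None:
                n_fields = n
            elif n != n_fields:
                raise ValueError(f"{path}: ragged row at line {ln} ({n} fields, expected {n_fields})")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix ({exc})") from exc
    return df


def write_beta_tsv(beta: BetaMatrix, path, detection_path=None,
                   header_comment: str | None = None) -> None:
    write_matrix_tsv(beta.beta, path, header_comment)
    if detection_path is not None and beta.detection_p is not None:
        write_matrix_tsv(beta.detection_p, detection_path, header_comment)


def read_beta_tsv(path, detection_path=None) -> BetaMatrix:
    beta = read_matrix_tsv(path)
    detp = read_matrix_tsv(detection_path) if detection_path else None
    return BetaMatrix(beta, detp)


# ---------------------------------------------------------------------------
# manifest and sample sheet


def write_manifest_csv(manifest: pd.DataFrame, path, header_comment: str | None = None) -> None:
    out = manifest.copy()
    out["genes"] = out["genes"].map(lambda g: ";".join(g))
    with open(path, "w") as fh:
        _write_comment(fh, header_comment)
        out.to_csv(fh, index=False)


def read_manifest_csv(path) -> pd.DataFrame:
    mani = pd.read_csv(path, comment="#", dtype={"cytoband": str})
    mani["genes"] = mani["genes"].fillna("").map(lambda s: [g for g in str(s).split(";") if g])
    mani["cross_reactive"] = mani["cross_reactive"].astype(bool)
    mani["snp_proximal"] = mani["snp_proximal"].astype(bool)
    validate_manifest(mani)
    return mani


def write_sample_sheet_csv(sheet: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        _write_comment(fh, header_comment)
        sheet.to_csv(fh, index=False)


def read_sample_sheet_csv(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, comment="#", dtype={"pair_id": "string"})
    sheet["pair_id"] = sheet["pair_id"].astype(object).where(sheet["pair_id"].notna(), None)
    validate_sample_sheet(sheet)
    return sheet


# ---------------------------------------------------------------------------
# BED


def read_bed(path, name: str | None = None) -> IntervalTrack:
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {ln}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}: line {ln}: end <= start ({start} >= {end})")
            rows.append((chrom, start, end))
    return IntervalTrack(
        name or path.stem, pd.DataFrame(rows, columns=["chrom", "start", "end"])
    )


def write_bed(track: IntervalTrack, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        _write_comment(fh, header_comment)
        for _, row in track.sorted().intervals.iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\n")


def write_regions_bed(regions: list[Region], path, header_comment: str | None = None) -> None:
    """BED6+ region output: score = −log10 calibrated FDR (capped at 1000),
    extra columns k, log10 raw score, calibrated p, de novo flag."""
    with open(path, "w") as fh:
        _write_comment(fh, header_comment)
        for i, r in enumerate(regions):
            if r.calibrated_fdr is None or r.calibrated_fdr <= 0:
                score = 1000.0
            else:
                score = min(-math.log10(r.calibrated_fdr), 1000.0)
            name = f"region_{r.rank if r.rank is not None else i + 1}"
            extra = "\t".join(
                [
                    str(r.k),
                    f"{r.log10_score:.6g}",
                    "NA" if r.calibrated_p is None else f"{r.calibrated_p:.6g}",
                    "NA" if r.de_novo_region is None else str(bool(r.de_novo_region)),
                ]
            )
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score:.4g}\t.\t{extra}\n")


def write_truth_bed(truths, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        _write_comment(fh, header_comment)
        for t in truths:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{';'.join(t.probe_ids)}\n")


# ---------------------------------------------------------------------------
# tables


def write_table_tsv(df: pd.DataFrame, path, header_comment: str | None = None,
                    index: bool = False, index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        _write_comment(fh, header_comment)
        df.to_csv(fh, sep="\t", float_format="%.12g", index=index, index_label=index_label)


def read_table_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
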