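"""Overlap of methylated loci with chromatin-mark tracks and category breakdowns.

The 2×2 enrichment contract: the universe is the post-filtering probe set
(the array background actually analyzed), the target is a probe subset
(e.g. de novo methylated loci), and a track membership vector splits both.
Manifest positions are 1-based; BED intervals are 0-based half-open, and
the conversion (pos − 1) happens here and only here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CGI_CATEGORIES, IntervalTrack


def _harmonize(name: str) -> str:
    return name.removeprefix("chr")


def overlap_probes(
    manifest: pd.DataFrame,
    track: IntervalTrack,
    harmonize_chrom: bool = False,
) -> pd.Series:
    """Boolean per-probe track overlap: pos−1 ∈ [start, end) for some interval.

    Chromosome naming conventions are not silently reconciled: if the
    manifest and track chromosome name sets are disjoint, an error lists
    the offending names unless ``harmonize_chrom`` is set.
    """
    probe_chroms = set(manifest["chrom"].astype(str))
    track_chroms = set(track.intervals["chrom"].astype(str)) if len(track) else set()
    key = _harmonize if harmonize_chrom else (lambda s: s)
    if track_chroms and not ({key(c) for c in probe_chroms} & {key(c) for c in track_chroms}):
        raise ValueError(
            "no shared chromosome names between manifest and track "
            f"(manifest: {sorted(probe_chroms)[:4]}, track: {sorted(track_chroms)[:4]}); "
            "set harmonize_chrom=True to strip 'chr' prefixes"
        )

    out = np.zeros(len(manifest), dtype=bool)
    if len(track):
        iv = track.intervals.copy()
        iv["chrom"] = iv["chrom"].astype(str).map(key)
        pos0 = manifest["pos"].to_numpy(dtype=np.int64) - 1
        mchrom = manifest["chrom"].astype(str).map(key).to_numpy()
        for chrom, grp in iv.groupby("chrom"):
            # merge to disjoint sorted intervals so searchsorted is valid
            grp = grp.sort_values("start")
            starts, ends = [], []
            for s, e in zip(grp["start"], grp["end"]):
                if ends and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            starts = np.asarray(starts)
            ends = np.asarray(ends)
            sel = mchrom == chrom
            p = pos0[sel]
            idx = np.searchsorted(starts, p, side="right") - 1
            hit = (idx >= 0) & (p < ends[np.clip(idx, 0, len(ends) - 1)])
            out[sel] = hit
    return pd.Series(out, index=pd.Index(manifest["probe_id"], name="probe_id"))


@dataclass
class EnrichmentResult:
    """One-sided Fisher enrichment of a track among a probe target set."""

    track_name: str
    a: int  # in target & in track
    b: int  # in target & out of track
    c: int  # out of target & in track
    d: int  # out of target & out of track
    odds_ratio: float
    p: float


def fisher_enrichment(
    target: set[str],
    universe: set[str],
    track_overlap: pd.Series,
    track_name: str = "track",
) -> EnrichmentResult:
    """One-sided (enrichment) Fisher's exact test of track overlap in the
    target set against the rest of the universe."""
    target = set(target)
    universe = set(universe)
    if not target:
        raise ValueError("target set is empty")
    if not target <= universe:
        raise ValueError("target must be a subset of the universe")
    if target == universe:
        raise ValueError("target equals the universe: nothing to compare against")
    missing = universe - set(track_overlap.index)
    if missing:
        raise ValueError(f"track overlap vector missing probes: {sorted(missing)[:5]}")

    ov = track_overlap.loc[list(universe)]
    in_t = ov.index.isin(target)
    a = int((in_t & ov.to_numpy()).sum())
    b = int(in_t.sum()) - a
    c = int(ov.to_numpy().sum()) - a
    d = len(universe) - a - b - c
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentResult(track_name, a, b, c, d, float(odds), float(p))


def bivalent_overlap(
    target: list[str] | set[str],
    track_a_overlap: pd.Series,
    track_b_overlap: pd.Series,
) -> dict[str, int]:
    """Joint mark membership among target probes: counts of a-only, b-only,
    both, and neither (disjoint; sums to |target|)."""
    target = list(target)
    ova = track_a_overlap.loc[target].to_numpy(dtype=bool)
    ovb = track_b_overlap.loc[target].to_numpy(dtype=bool)
    return {
        "a_only": int((ova & ~ovb).sum()),
        "b_only": int((~ova & ovb).sum()),
        "both": int((ova & ovb).sum()),
        "neither": int((~ova & ~ovb).sum()),
    }


def cgi_breakdown(
    target: list[str] | set[str],
    manifest: pd.DataFrame,
) -> tuple[pd.Series, float]:
    """Proportion of target probes per CpG-island relation category, plus the
    aggregate 'within or close to CGI' (Island + both shores)."""
    target = set(target)
    if not target:
        raise ValueError("target set is empty")
    mani = manifest.set_index("probe_id")
    missing = target - set(mani.index)
    if missing:
        raise ValueError(f"target probes not in manifest: {sorted(missing)[:5]}")
    cats = mani.loc[sorted(target), "cgi_relation"]
    props = cats.value_counts(normalize=True).reindex(CGI_CATEGORIES, fill_value=0.0)
    aggregate = float(props["Island"] + props["N_Shore"] + props["S_Shore"])
    return props, aggregate
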