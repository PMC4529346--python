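"""Region detection: merge adjacent significant CpGs, score by multiplicative
FDR, and calibrate against array design bias by probe-label permutation.

The region score — the product of member CpG FDRs — decreases with every
member added, so probe-dense stretches of the array (CpG islands in
gene-rich regions) produce extreme scores more easily than sparse ones.
The calibration conditions on the array's probe positions: the per-probe
FDR column is permuted across positions, regions are re-derived, and the
null score distribution is pooled by region probe-count k.  A region's
calibrated p is the (pseudo-counted) fraction of matching-k null scores at
least as extreme as its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import BetaMatrix, Region, group_ids
from .diffmeth import bh_fdr


def _effect_column(stats_table: pd.DataFrame) -> np.ndarray:
    """Signed evidence of direction: moderated t if present, else Δβ."""
    for col in ("t_mod", "delta_beta", "mean_diff"):
        if col in stats_table.columns:
            return stats_table[col].to_numpy(dtype=float)
    raise ValueError("stats table has no direction column (t_mod/delta_beta/mean_diff)")


def _sorted_probe_arrays(
    stats_table: pd.DataFrame, manifest: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Position-sorted (chrom_code, pos, fdr, effect, probe_id) arrays."""
    mani = manifest.set_index("probe_id")
    missing = [p for p in stats_table.index if p not in mani.index]
    if missing:
        raise ValueError(f"probes missing from manifest: {missing[:10]}")
    ann = mani.loc[stats_table.index]
    chroms = ann["chrom"].to_numpy()
    pos = ann["pos"].to_numpy(dtype=np.int64)
    fdr = stats_table["fdr"].to_numpy(dtype=float)
    eff = _effect_column(stats_table)
    # stable order: chromosome name then position
    uniq = sorted(set(chroms))
    code = np.array([uniq.index(c) for c in chroms])
    order = np.lexsort((pos, code))
    return (
        code[order],
        pos[order],
        fdr[order],
        eff[order],
        stats_table.index.to_numpy()[order],
    )


def _run_merge(
    chrom_code: np.ndarray,
    pos: np.ndarray,
    fdr: np.ndarray,
    effect: np.ndarray,
    fdr_cut: float,
    gap_bp: int,
    min_probes: int,
    direction: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Single linear sweep over position-sorted probes.

    Returns (k, log10_score, first_index, last_index) per surviving run,
    where indices refer to positions in the qualifying-probe subsequence
    mapped back to the sorted input via the returned index arrays.
    """
    if direction == "hyper":
        dir_ok = effect > 0
    elif direction == "hypo":
        dir_ok = effect < 0
    elif direction == "both":
        dir_ok = np.ones_like(effect, dtype=bool)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    qual = np.flatnonzero((fdr < fdr_cut) & dir_ok)
    if qual.size == 0:
        return (np.empty(0, int), np.empty(0), np.empty(0, int), np.empty(0, int))
    new_run = np.ones(qual.size, dtype=bool)
    if qual.size > 1:
        same_chrom = chrom_code[qual[1:]] == chrom_code[qual[:-1]]
        close = (pos[qual[1:]] - pos[qual[:-1]]) <= gap_bp
        new_run[1:] = ~(same_chrom & close)
    run_id = np.cumsum(new_run) - 1
    n_runs = run_id[-1] + 1
    k = np.bincount(run_id, minlength=n_runs)
    score = np.bincount(run_id, weights=np.log10(fdr[qual]), minlength=n_runs)
    starts = np.flatnonzero(new_run)
    ends = np.append(starts[1:], qual.size) - 1
    keep = k >= min_probes
    return k[keep], score[keep], qual[starts[keep]], qual[ends[keep]]


def merge_adjacent(
    stats_table: pd.DataFrame,
    manifest: pd.DataFrame,
    fdr_cut: float = 0.05,
    gap_bp: int = 50,
    min_probes: int = 2,
    direction: str = "hyper",
) -> list[Region]:
    """Merge qualifying CpGs (FDR < cut, matching direction) within
    ``gap_bp`` of the previous qualifying probe into regions.

    The gap rule chains between consecutive qualifying probes, so a region
    may span far more than ``gap_bp``.  Output is sorted by (chrom, start)
    and independent of input row order.
    """
    code, pos, fdr, eff, pids = _sorted_probe_arrays(stats_table, manifest)
    chrom_names = sorted(set(manifest.set_index("probe_id").loc[stats_table.index, "chrom"]))
    k, score, first, last = _run_merge(code, pos, fdr, eff, fdr_cut, gap_bp, min_probes, direction)
    regions = []
    for kk, sc, f, l in zip(k, score, first, last):
        # member probes are the qualifying probes between first and last index
        dir_ok = eff > 0 if direction == "hyper" else (eff < 0 if direction == "hypo" else np.ones_like(eff, bool))
        member_mask = np.zeros(len(pos), dtype=bool)
        member_mask[f : l + 1] = (fdr[f : l + 1] < fdr_cut) & dir_ok[f : l + 1]
        members = np.flatnonzero(member_mask)
        regions.append(
            Region(
                chrom=chrom_names[code[f]],
                start=int(pos[f]) - 1,
                end=int(pos[l]),
                probe_ids=list(pids[members]),
                k=int(kk),
                raw_score=float(10.0 ** sc) if sc > -300 else 0.0,
                log10_score=float(sc),
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


@dataclass
class NullScoreTable:
    """Permutation null: per region size k, sorted log10 multiplicative scores."""

    scores_by_k: dict[int, np.ndarray]
    n_perm: int
    seed: int
    n_probes: int
    pooled_ks: set[int] = field(default_factory=set)

    @property
    def total_scores(self) -> int:
        return sum(len(v) for v in self.scores_by_k.values())


def permutation_calibrate(
    stats_table: pd.DataFrame,
    manifest: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_cut: float = 0.05,
    gap_bp: int = 50,
    min_probes: int = 2,
    direction: str = "hyper",
) -> NullScoreTable:
    """Null region-score distribution under probe-label permutation.

    Probe positions stay fixed; the per-probe (FDR, direction) labels are
    shuffled jointly across all positions, and merging is re-run.  Each
    permutation uses an independent seed stream spawned from ``seed``, so
    extending ``n_perm`` keeps the earlier permutations identical.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for usable null resolution")
    code, pos, fdr, eff, _ = _sorted_probe_arrays(stats_table, manifest)
    n = len(pos)
    pooled: dict[int, list[np.ndarray]] = {}
    for i in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        perm = rng.permutation(n)
        k, score, _, _ = _run_merge(
            code, pos, fdr[perm], eff[perm], fdr_cut, gap_bp, min_probes, direction
        )
        for kk, sc in zip(k, score):
            pooled.setdefault(int(kk), []).append(sc)
    scores_by_k = {k: np.sort(np.asarray(v, dtype=float)) for k, v in pooled.items()}
    return NullScoreTable(scores_by_k=scores_by_k, n_perm=n_perm, seed=seed, n_probes=n)


def _null_pool(table: NullScoreTable, k: int, min_null: int) -> tuple[np.ndarray, bool]:
    """Null scores for size k, pooling adjacent k outward until ``min_null``."""
    ks = sorted(table.scores_by_k)
    if not ks:
        return np.empty(0), True
    exact = table.scores_by_k.get(k, np.empty(0))
    if len(exact) >= min_null:
        return exact, False
    chosen = [exact]
    total = len(exact)
    for kk in sorted(ks, key=lambda q: (abs(q - k), q)):
        if kk == k:
            continue
        chosen.append(table.scores_by_k[kk])
        total += len(table.scores_by_k[kk])
        if total >= min_null:
            break
    return np.sort(np.concatenate(chosen)), True


def calibrate_regions(
    regions: list[Region],
    null_table: NullScoreTable,
    min_null: int = 30,
) -> list[Region]:
    """Fill calibrated_p (pseudo-counted permutation tail) and calibrated_fdr.

    ``calibrated_p = (1 + #{null scores of matching k <= observed}) / (1 + N)``;
    smaller multiplicative scores are more extreme.  Sparse k strata are
    pooled with neighboring k (recorded on the null table).
    """
    if not regions:
        return []
    ps = []
    for r in regions:
        pool, was_pooled = _null_pool(null_table, r.k, min_null)
        if was_pooled:
            null_table.pooled_ks.add(r.k)
        count = int(np.searchsorted(pool, r.log10_score, side="right"))
        ps.append((1.0 + count) / (1.0 + len(pool)))
    fdrs = bh_fdr(np.asarray(ps))
    return [
        r.replace(calibrated_p=float(p), calibrated_fdr=float(f))
        for r, p, f in zip(regions, ps, fdrs)
    ]


def rank_and_select(regions: list[Region], top_n: int = 500) -> list[Region]:
    """Deterministic total order: calibrated p, then raw score, then coordinates."""
    for r in regions:
        if r.calibrated_p is None:
            raise ValueError("calibrate_regions must run before rank_and_select")
    ordered = sorted(
        regions, key=lambda r: (r.calibrated_p, r.log10_score, r.chrom, r.start)
    )
    ranked = [r.replace(rank=i + 1) for i, r in enumerate(ordered)]
    return ranked[:top_n]


def flag_de_novo_regions(
    regions: list[Region],
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    beta_ref_cut: float = 0.3,
) -> list[Region]:
    """Flag regions whose member-probe mean β is below ``beta_ref_cut`` in
    both normals and the PBMC panel."""
    n_ids = group_ids(sheet, "normal")
    p_ids = group_ids(sheet, "pbmc")
    out = []
    for r in regions:
        sub = beta.beta.loc[[p for p in r.probe_ids if p in beta.beta.index]]
        if len(sub) == 0:
            raise ValueError(f"region {r.chrom}:{r.start}-{r.end} has no probes in beta")
        mean_n = float(sub[n_ids].to_numpy().mean()) if n_ids else np.nan
        mean_p = float(sub[p_ids].to_numpy().mean()) if p_ids else np.nan
        flag = bool(mean_n < beta_ref_cut) and (not p_ids or mean_p < beta_ref_cut)
        out.append(r.replace(de_novo_region=flag))
    return out


def band_enrichment(
    top_regions: list[Region],
    manifest: pd.DataFrame,
    universe: str = "probes",
    universe_probe_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of cytobands among top-region
    elements against the array background.

    ``universe="probes"`` counts probes; ``universe="genes"`` maps probes
    to gene symbols (a gene's band is taken from its lowest-position probe).
    Returns a table (band, n_target, n_universe, p, fdr) sorted by p.
    """
    mani = manifest.set_index("probe_id")
    if universe_probe_ids is not None:
        mani = mani.loc[[p for p in universe_probe_ids if p in mani.index]]
    if mani["cytoband"].isna().any() or (mani["cytoband"].astype(str) == "").any():
        raise ValueError("cytoband annotation missing for some probes")

    target_probes = {p for r in top_regions for p in r.probe_ids}
    missing = target_probes - set(mani.index)
    if missing:
        raise ValueError(f"top-region probes outside universe: {sorted(missing)[:5]}")

    if universe == "probes":
        elem_band = mani["cytoband"]
        target_elems = set(target_probes)
        universe_elems = pd.Series(elem_band.values, index=mani.index)
    elif universe == "genes":
        rows = []
        for pid, row in mani.sort_values(["chrom", "pos"]).iterrows():
            for g in row["genes"]:
                rows.append((g, row["cytoband"], pid))
        gene_tab = pd.DataFrame(rows, columns=["gene", "band", "probe_id"])
        first = gene_tab.drop_duplicates("gene")  # lowest-position probe per gene
        universe_elems = pd.Series(first["band"].values, index=first["gene"].values)
        target_elems = set(
            gene_tab.loc[gene_tab["probe_id"].isin(target_probes), "gene"]
        )
    else:
        raise ValueError(f"unknown universe {universe!r}")

    N = len(universe_elems)
    n_draw = len(target_elems)
    records = []
    is_target = universe_elems.index.isin(target_elems)
    for band, grp in universe_elems.groupby(universe_elems.values):
        K = len(grp)
        x = int(is_target[universe_elems.index.isin(grp.index)].sum())
        p = float(sps.hypergeom.sf(x - 1, N, K, n_draw)) if x > 0 else 1.0
        records.append((band, x, K, p))
    tab = pd.DataFrame(records, columns=["band", "n_target", "n_universe", "p"])
    tab["fdr"] = bh_fdr(tab["p"].to_numpy())
    return tab.sort_values(["p", "band"], kind="mergesort").reset_index(drop=True)
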