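"""Synthetic 450k-style data with the statistical structure the pipeline assumes.

The generator emulates the features the analysis depends on: a probe
manifest whose probes cluster in CpG-island-like clumps (the array's
design bias toward gene-dense regions), paired tumor/normal β values
drawn from a three-state beta mixture, a blood (PBMC) reference panel,
type-II probe compression toward 0.5 (the distortion BMIQ removes),
spiked hypermethylated probe clusters within tight bp neighborhoods on a
chosen chromosome arm, detection p-values with a configurable failure
rate, and interval tracks with known overlap enrichment.

Defaults mirror the study design the pipeline targets: 25 tumor/normal
pairs, a 100-sample PBMC panel, trimodal β states with means ≈
0.08/0.5/0.85, and Δβ = 0.3 spikes carried by 60% of pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BetaMatrix, IntervalTrack, validate_manifest

#: Per-state beta-distribution shape parameters (unmethylated / hemi / methylated);
#: means ≈ 0.08, 0.50, 0.85 — the trimodal shape BMIQ assumes.  Concentrations
#: keep β off the boundaries, as the array's intensity offset in
#: β = M/(M+U+100) does for real data.
DEFAULT_STATE_PARAMS: dict[str, tuple[float, float]] = {
    "U": (5.0, 57.0),
    "H": (10.0, 10.0),
    "M": (52.0, 9.0),
}

#: Marginal probe-state frequencies (U, H, M).
DEFAULT_STATE_PROBS = (0.55, 0.12, 0.33)

#: 450k-like CpG-island relation mix.
DEFAULT_CGI_MIX: dict[str, float] = {
    "Island": 0.31,
    "N_Shore": 0.13,
    "S_Shore": 0.10,
    "N_Shelf": 0.05,
    "S_Shelf": 0.04,
    "OpenSea": 0.37,
}

#: Small packaged cytoband table: (fraction_of_chromosome_end, band name).
#: Only a few bands per chromosome are needed for positional enrichment tests.
BAND_TABLE: dict[str, list[tuple[float, str]]] = {
    "chr1": [(0.12, "1p36"), (0.30, "1p31"), (0.50, "1p13"), (0.75, "1q21"), (1.0, "1q42")],
    "chr2": [(0.20, "2p25"), (0.45, "2p16"), (0.70, "2q22"), (1.0, "2q37")],
    "chr3": [(0.25, "3p25"), (0.48, "3p14"), (0.75, "3q21"), (1.0, "3q27")],
    "chr6": [
        (0.06, "6p25"),
        (0.16, "6p22.1"),
        (0.30, "6p21.3"),
        (0.40, "6p21.1"),
        (0.60, "6q12"),
        (0.85, "6q21"),
        (1.0, "6q27"),
    ],
    "chr7": [(0.25, "7p21"), (0.50, "7p11"), (0.75, "7q21"), (1.0, "7q36")],
    "chr17": [(0.25, "17p13"), (0.45, "17p11"), (0.75, "17q21"), (1.0, "17q25")],
}


def _bands_for(chrom: str) -> list[tuple[float, str]]:
    if chrom in BAND_TABLE:
        return BAND_TABLE[chrom]
    stem = chrom.removeprefix("chr")
    return [
        (0.25, f"{stem}p22"),
        (0.50, f"{stem}p21"),
        (0.75, f"{stem}q21"),
        (1.0, f"{stem}q24"),
    ]


def _band_at(chrom: str, pos: int, length: int) -> str:
    frac = pos / length
    for upper, name in _bands_for(chrom):
        if frac <= upper:
            return name
    return _bands_for(chrom)[-1][1]


def _arm_span(chrom: str, arm: str, length: int) -> tuple[int, int]:
    """1-based position span of a chromosome arm ('p' or 'q')."""
    bands = _bands_for(chrom)
    p_end_frac = max((u for u, n in bands if "p" in n.removeprefix(chrom.removeprefix("chr"))), default=0.5)
    boundary = int(p_end_frac * length)
    if arm == "p":
        return 1, boundary
    return boundary + 1, length


@dataclass
class SpikeSpec:
    """Ground-truth hypermethylated clusters to spike into tumor samples."""

    n_regions: int = 5
    probes_per_region: int = 4
    intra_gap_bp: int = 40
    delta_beta: float = 0.3
    carrier_fraction: float = 0.6
    target_arm: str = "6p"

    def __post_init__(self) -> None:
        if self.probes_per_region < 2:
            raise ValueError("probes_per_region must be >= 2")
        if self.intra_gap_bp > 50:
            raise ValueError("intra_gap_bp must be <= 50 (region merging rule)")
        if not (0 < self.carrier_fraction <= 1):
            raise ValueError("carrier_fraction must be in (0, 1]")


@dataclass
class SpikedRegionTruth:
    chrom: str
    start: int  # 0-based half-open
    end: int
    probe_ids: list[str]


@dataclass
class SyntheticCohort:
    """Bundle returned by :func:`generate_cohort`.

    ``manifest`` may be an augmented copy of the input when spike
    clusters had to be inserted as new probes.
    """

    manifest: pd.DataFrame
    beta: BetaMatrix
    sheet: pd.DataFrame
    truth_regions: list[SpikedRegionTruth] = field(default_factory=list)


def _clustered_positions(rng: np.random.Generator, count: int, length: int,
                         cluster_size_mean: float, gap_lo: int, gap_hi: int) -> np.ndarray:
    """Strictly increasing positions grouped into island-like clumps.

    Probes arrive in clusters with intra-cluster gaps in [gap_lo, gap_hi] bp,
    mimicking the CpG-island concentration of array probes (and producing the
    ≤50 bp adjacency the region-merging rule operates on).
    """
    if count == 0:
        return np.empty(0, dtype=np.int64)
    pos: list[int] = []
    # oversample, then thin to the requested count
    while len(pos) < count * 1.2 + 8:
        anchor = int(rng.integers(1, max(2, length - 2000)))
        size = 1 + int(rng.poisson(max(cluster_size_mean - 1.0, 0.0)))
        gaps = rng.integers(gap_lo, gap_hi + 1, size=max(size - 1, 0))
        p = anchor
        pos.append(p)
        for g in gaps:
            p += int(g)
            if p > length:
                break
            pos.append(p)
    uniq = np.unique(np.asarray(pos, dtype=np.int64))
    while len(uniq) < count:  # rare: top up with uniform singles
        extra = rng.integers(1, length + 1, size=count)
        uniq = np.unique(np.concatenate([uniq, extra]))
    if len(uniq) > count:
        keep = rng.choice(len(uniq), size=count, replace=False)
        uniq = uniq[np.sort(keep)]
    return uniq


def generate_manifest(
    n_probes: int,
    chrom_plan: dict[str, tuple[int, float]],
    cgi_mix: dict[str, float] | None = None,
    type2_fraction: float = 0.72,
    seed: int = 0,
    cross_reactive_rate: float = 0.01,
    snp_proximal_rate: float = 0.02,
    cluster_size_mean: float = 3.0,
) -> pd.DataFrame:
    """Generate a probe manifest over the given chromosome plan.

    Parameters
    ----------
    n_probes
        Total probe count (allocated to chromosomes multinomially by weight).
    chrom_plan
        Mapping ``chrom -> (length_bp, weight)``; weights must sum to 1.
    cgi_mix
        CpG-island relation proportions (must sum to 1); 450k-like default.
    type2_fraction
        Expected fraction of Infinium type-II probes.
    """
    if n_probes <= 0:
        raise ValueError("n_probes must be positive")
    if not chrom_plan:
        raise ValueError("chrom_plan must not be empty")
    cgi_mix = dict(DEFAULT_CGI_MIX) if cgi_mix is None else dict(cgi_mix)
    weights = np.array([w for _, w in chrom_plan.values()], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("chrom_plan weights must sum to 1")
    mix_vals = np.array(list(cgi_mix.values()), dtype=float)
    if abs(mix_vals.sum() - 1.0) > 1e-9:
        raise ValueError("cgi_mix proportions must sum to 1")

    rng = np.random.default_rng(seed)
    chroms = list(chrom_plan)
    counts = rng.multinomial(n_probes, weights)
    frames = []
    for chrom, cnt in zip(chroms, counts):
        length = int(chrom_plan[chrom][0])
        pos = _clustered_positions(rng, int(cnt), length, cluster_size_mean, 10, 40)
        n = len(pos)
        cgi = rng.choice(list(cgi_mix), size=n, p=mix_vals)
        design = np.where(rng.random(n) < type2_fraction, "II", "I")
        xr = rng.random(n) < cross_reactive_rate
        snp = rng.random(n) < snp_proximal_rate
        bands = [_band_at(chrom, int(p), length) for p in pos]
        genes = []
        for p, c in zip(pos, cgi):
            if c == "OpenSea" and rng.random() < 0.5:
                genes.append([])
            else:
                genes.append([f"G{chrom.removeprefix('chr')}_{int(p) // 20000}"])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "cgi_relation": cgi,
                    "cytoband": bands,
                    "genes": genes,
                    "design_type": design,
                    "cross_reactive": xr,
                    "snp_proximal": snp,
                }
            )
        )
    manifest = pd.concat(frames, ignore_index=True)
    manifest = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    manifest.insert(0, "probe_id", [f"cg{i:08d}" for i in range(len(manifest))])
    validate_manifest(manifest)
    return manifest


def _place_spikes(
    manifest: pd.DataFrame,
    spike: SpikeSpec,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[SpikedRegionTruth]]:
    """Select or insert tight probe clusters on the target arm.

    Existing maximal runs with gaps <= intra_gap_bp are used first; when the
    manifest lacks enough tight clusters, new probes are inserted (and the
    augmented manifest re-emitted) so the ground truth always exists.
    """
    arm = spike.target_arm
    chrom, arm_letter = "chr" + arm[:-1], arm[-1]
    if chrom not in set(manifest["chrom"]):
        raise ValueError(f"spike target arm {arm!r}: chromosome {chrom!r} not in manifest")
    length = chrom_lengths.get(chrom)
    if length is None:
        length = int(manifest.loc[manifest["chrom"] == chrom, "pos"].max() * 1.05)
    lo, hi = _arm_span(chrom, arm_letter, length)

    arm_probes = manifest[
        (manifest["chrom"] == chrom)
        & manifest["pos"].between(lo, hi)
        & ~manifest["cross_reactive"].astype(bool)
        & ~manifest["snp_proximal"].astype(bool)
    ]
    arm_probes = arm_probes.sort_values("pos")
    positions = arm_probes["pos"].to_numpy()
    ids = arm_probes["probe_id"].to_numpy()

    truths: list[SpikedRegionTruth] = []
    used: set[str] = set()
    # harvest existing tight runs
    if len(positions) >= spike.probes_per_region:
        run_start = 0
        for i in range(1, len(positions) + 1):
            end_of_run = i == len(positions) or positions[i] - positions[i - 1] > spike.intra_gap_bp
            if end_of_run:
                run = slice(run_start, i)
                run_ids = ids[run]
                run_pos = positions[run]
                j = 0
                while len(truths) < spike.n_regions and j + spike.probes_per_region <= len(run_ids):
                    sel = slice(j, j + spike.probes_per_region)
                    truths.append(
                        SpikedRegionTruth(
                            chrom=chrom,
                            start=int(run_pos[sel][0]) - 1,
                            end=int(run_pos[sel][-1]),
                            probe_ids=list(run_ids[sel]),
                        )
                    )
                    used.update(run_ids[sel])
                    j += spike.probes_per_region
                run_start = i
            if len(truths) >= spike.n_regions:
                break

    # insert fresh clusters for any shortfall
    new_rows = []
    existing = set(manifest.loc[manifest["chrom"] == chrom, "pos"].tolist())
    n_insert = 0
    while len(truths) < spike.n_regions:
        for _ in range(1000):
            start = int(rng.integers(lo, max(lo + 1, hi - spike.probes_per_region * spike.intra_gap_bp - 10)))
            gaps = rng.integers(10, spike.intra_gap_bp + 1, size=spike.probes_per_region - 1)
            cand = np.concatenate([[start], start + np.cumsum(gaps)])
            near = any(
                any(abs(int(c) - e) < 200 for e in existing if abs(int(c) - e) < 200)
                for c in cand
            )
            if not near and len(set(map(int, cand))) == len(cand):
                break
        else:
            raise ValueError(f"could not place spike cluster on arm {arm!r}")
        pids = [f"cgspk{n_insert:03d}{j:02d}" for j in range(spike.probes_per_region)]
        n_insert += 1
        for pid, p in zip(pids, cand):
            existing.add(int(p))
            new_rows.append(
                {
                    "probe_id": pid,
                    "chrom": chrom,
                    "pos": int(p),
                    "cgi_relation": "Island",
                    "cytoband": _band_at(chrom, int(p), length),
                    "genes": [f"G{chrom.removeprefix('chr')}_{int(p) // 20000}"],
                    "design_type": "I",
                    "cross_reactive": False,
                    "snp_proximal": False,
                }
            )
        truths.append(
            SpikedRegionTruth(
                chrom=chrom,
                start=int(cand[0]) - 1,
                end=int(cand[-1]),
                probe_ids=pids,
            )
        )
    if new_rows:
        manifest = pd.concat([manifest, pd.DataFrame(new_rows)], ignore_index=True)
        manifest = manifest.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return manifest, truths


def generate_cohort(
    manifest: pd.DataFrame,
    n_pairs: int = 25,
    n_pbmc: int = 100,
    state_params: dict[str, tuple[float, float]] | None = None,
    state_probs: tuple[float, float, float] = DEFAULT_STATE_PROBS,
    type2_compression: float = 0.3,
    spike: SpikeSpec | None = None,
    noise_sd: float = 0.03,
    failed_probe_fraction: float = 0.005,
    chrom_lengths: dict[str, int] | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate paired tumor/normal β values plus a PBMC reference panel.

    Per probe, a methylation state (U/H/M) is drawn once; each tumor/normal
    pair then shares a per-subject baseline β drawn from that state's beta
    distribution (the within-subject correlation a paired design exploits),
    while PBMC samples draw independently.  With ``spike=None`` (or
    ``delta_beta=0``) tumor and normal marginals are identical up to noise.
    Type-II probes are compressed toward 0.5 by ``type2_compression``
    (affine, pre-noise), spikes are added to carrier tumors after
    compression so carriers are elevated by ≈ ``delta_beta``, and Gaussian
    measurement noise is applied last.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    params = dict(DEFAULT_STATE_PARAMS) if state_params is None else dict(state_params)
    for s, (a, b) in params.items():
        if a <= 0 or b <= 0:
            raise ValueError(f"state {s!r}: beta-distribution shapes must be positive")
    if not (0 <= type2_compression < 1):
        raise ValueError("type2_compression must be in [0, 1)")

    rng = np.random.default_rng(seed)
    manifest = manifest.copy()
    truths: list[SpikedRegionTruth] = []
    if spike is not None:
        manifest, truths = _place_spikes(manifest, spike, chrom_lengths or {}, rng)

    n = len(manifest)
    states = rng.choice(np.array(["U", "H", "M"]), size=n, p=np.asarray(state_probs))
    spiked_ids = {pid for t in truths for pid in t.probe_ids}
    if spiked_ids:
        states[manifest["probe_id"].isin(spiked_ids).to_numpy()] = "U"

    tumor_ids = [f"T{i:02d}" for i in range(n_pairs)]
    normal_ids = [f"N{i:02d}" for i in range(n_pairs)]
    pbmc_ids = [f"PB{i:03d}" for i in range(n_pbmc)]
    samples = tumor_ids + normal_ids + pbmc_ids
    n_samp = len(samples)

    beta = np.empty((n, n_samp), dtype=float)
    for s, (a, b) in params.items():
        mask = states == s
        if not mask.any():
            continue
        nm = int(mask.sum())
        baseline = rng.beta(a, b, size=(nm, n_pairs))  # shared within pair
        block = np.empty((nm, n_samp))
        block[:, :n_pairs] = baseline  # tumors
        block[:, n_pairs : 2 * n_pairs] = baseline  # matched normals
        if n_pbmc:
            block[:, 2 * n_pairs :] = rng.beta(a, b, size=(nm, n_pbmc))
        beta[mask, :] = block

    # type-II compression toward 0.5 (pre-noise): the bias BMIQ must remove
    if type2_compression > 0:
        ii = (manifest["design_type"] == "II").to_numpy()
        beta[ii, :] = 0.5 + (1.0 - type2_compression) * (beta[ii, :] - 0.5)

    # spike carrier tumors after compression so elevation ≈ delta_beta
    probe_index = {pid: i for i, pid in enumerate(manifest["probe_id"])}
    for t in truths:
        n_carriers = max(1, int(round(spike.carrier_fraction * n_pairs)))
        carriers = rng.choice(n_pairs, size=n_carriers, replace=False)
        rows = np.array([probe_index[pid] for pid in t.probe_ids])
        beta[np.ix_(rows, carriers)] += spike.delta_beta

    if noise_sd > 0:
        # heteroscedastic measurement noise: β-scale variance shrinks toward
        # the 0/1 boundaries (sd = noise_sd at β = 0.5), matching the
        # mean-variance relation of beta-valued array data
        scale = noise_sd * 4.0 * beta * (1.0 - beta)
        beta += rng.normal(0.0, 1.0, size=beta.shape) * scale
    np.clip(beta, 1e-3, 1 - 1e-3, out=beta)

    detp = rng.uniform(1e-6, 0.009, size=beta.shape)
    failed = rng.random(n) < failed_probe_fraction
    if spiked_ids:  # ground-truth probes must survive detection filtering
        failed &= ~manifest["probe_id"].isin(spiked_ids).to_numpy()
    if failed.any():
        detp[failed, :] = rng.uniform(0.02, 1.0, size=(int(failed.sum()), n_samp))

    idx = pd.Index(manifest["probe_id"], name="probe_id")
    bm = BetaMatrix(
        pd.DataFrame(beta, index=idx, columns=samples),
        pd.DataFrame(detp, index=idx, columns=samples),
    )
    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "subject_id": [f"S{i:02d}" for i in range(n_pairs)] * 2
            + [f"PBS{i:03d}" for i in range(n_pbmc)],
            "group": ["tumor"] * n_pairs + ["normal"] * n_pairs + ["pbmc"] * n_pbmc,
            "pair_id": [f"P{i:02d}" for i in range(n_pairs)] * 2 + [None] * n_pbmc,
        }
    )
    return SyntheticCohort(manifest=manifest, beta=bm, sheet=sheet, truth_regions=truths)


def merge_intervals(intervals: list[tuple[str, int, int]]) -> pd.DataFrame:
    """Merge overlapping/adjacent 0-based half-open intervals per chromosome."""
    out: list[tuple[str, int, int]] = []
    for chrom in sorted({c for c, _, _ in intervals}):
        ivs = sorted((s, e) for c, s, e in intervals if c == chrom)
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def generate_track(
    manifest: pd.DataFrame,
    target_probe_ids: set[str],
    inside_rate: float,
    outside_rate: float,
    seed: int = 0,
    window_bp: int = 100,
    name: str = "track",
) -> IntervalTrack:
    """Interval track covering target probes at ``inside_rate`` and the rest
    at ``outside_rate`` (±window_bp around the probe, merged if overlapping)."""
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    for r in (inside_rate, outside_rate):
        if not (0 <= r <= 1):
            raise ValueError("rates must be in [0, 1]")
    unknown = set(target_probe_ids) - set(manifest["probe_id"])
    if unknown:
        raise ValueError(f"target probes not in manifest: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    is_target = manifest["probe_id"].isin(target_probe_ids).to_numpy()
    rate = np.where(is_target, inside_rate, outside_rate)
    covered = rng.random(len(manifest)) < rate
    intervals = []
    for chrom, pos in zip(manifest.loc[covered, "chrom"], manifest.loc[covered, "pos"]):
        p0 = int(pos) - 1
        intervals.append((chrom, max(0, p0 - window_bp), p0 + window_bp + 1))
    if not intervals:
        return IntervalTrack(name, pd.DataFrame(columns=["chrom", "start", "end"]))
    return IntervalTrack(name, merge_intervals(intervals))
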