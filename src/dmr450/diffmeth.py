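"""Moderated differential-methylation testing and locus classification.

Testing is done on M-values with an empirical-Bayes moderated t-statistic:
per-probe variances are shrunk toward a prior ``s0²`` with prior degrees of
freedom ``d0`` estimated from the marginal distribution of log sample
variances (scaled inverse-chi-square model, trigamma moment inversion).
Thresholds for hyper/hypo and de novo classification operate on β-values,
matching standard practice for 450k studies: test on M, interpret on β.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import BetaMatrix, MMatrix, group_ids, is_autosome, paired_ids


@dataclass
class ModerationPrior:
    """Empirical-Bayes hyperparameters: prior df (may be +inf) and prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive (or +inf)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def estimate_prior(s2: np.ndarray, df: int) -> ModerationPrior:
    """Moment estimator of (d0, s0²) from per-probe sample variances.

    Under the scaled inverse-chi-square model, log s² has variance
    trigamma(df/2) + trigamma(d0/2); excess empirical variance of log s²
    over trigamma(df/2) identifies d0.  No excess (or negative excess)
    means no detectable heterogeneity: d0 = +inf.
    """
    s2 = np.asarray(s2, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    s2 = s2[np.isfinite(s2)]
    if np.all(s2 <= 0):
        raise ValueError("all variances are zero: degenerate input")
    s2 = s2[s2 > 0]
    if len(s2) < 10:
        raise ValueError("need >= 10 probes with positive variance")
    z = np.log(s2)
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = float("inf")
        s0_sq = math.exp(emean)
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def moderated_test(
    m: MMatrix,
    sheet: pd.DataFrame,
    design: str = "paired",
    prior: ModerationPrior | None = None,
) -> pd.DataFrame:
    """Moderated t-test per probe; paired (one-sample on within-pair
    differences) or two-group (pooled variance).

    Returns a DataFrame indexed by probe_id with columns ``mean_diff``,
    ``s2``, ``df_resid``, ``t_mod``, ``p``; the prior actually used is
    attached as ``result.attrs["prior"]``.  ``prior`` with ``d0=0``
    reproduces the ordinary t-test; ``d0=inf`` uses ``s0`` exactly with a
    normal reference distribution.
    """
    mat = m.m
    if design == "paired":
        tumor_ids, normal_ids, _ = paired_ids(sheet)
        if len(tumor_ids) < 3:
            raise ValueError("paired design needs >= 3 complete pairs")
        diffs = mat[tumor_ids].to_numpy() - mat[normal_ids].to_numpy()
        n = diffs.shape[1]
        mean = diffs.mean(axis=1)
        s2 = diffs.var(axis=1, ddof=1)
        df_resid = n - 1
        c = 1.0 / math.sqrt(n)
    elif design == "two_group":
        t_ids = group_ids(sheet, "tumor")
        n_ids = group_ids(sheet, "normal")
        if len(t_ids) < 3 or len(n_ids) < 3:
            raise ValueError("two_group design needs >= 3 samples per group")
        xt = mat[t_ids].to_numpy()
        xn = mat[n_ids].to_numpy()
        n1, n2 = xt.shape[1], xn.shape[1]
        mean = xt.mean(axis=1) - xn.mean(axis=1)
        s2 = (xt.var(axis=1, ddof=1) * (n1 - 1) + xn.var(axis=1, ddof=1) * (n2 - 1)) / (
            n1 + n2 - 2
        )
        df_resid = n1 + n2 - 2
        c = math.sqrt(1.0 / n1 + 1.0 / n2)
    else:
        raise ValueError(f"unknown design {design!r}")

    if prior is None:
        prior = estimate_prior(s2, df_resid)

    if math.isinf(prior.d0):
        s2_tilde = np.full_like(s2, prior.s0_sq)
        t = mean / (np.sqrt(s2_tilde) * c)
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        if prior.d0 == 0:
            s2_tilde = s2
        else:
            s2_tilde = (prior.d0 * prior.s0_sq + df_resid * s2) / (prior.d0 + df_resid)
        t = mean / (np.sqrt(s2_tilde) * c)
        p = 2.0 * stats.t.sf(np.abs(t), prior.d0 + df_resid)

    out = pd.DataFrame(
        {"mean_diff": mean, "s2": s2, "df_resid": df_resid, "t_mod": t, "p": p},
        index=mat.index,
    )
    out.attrs["prior"] = prior
    out.attrs["design"] = design
    return out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _pair_delta_beta(beta: BetaMatrix, sheet: pd.DataFrame) -> pd.DataFrame | None:
    """Per-pair tumor−normal Δβ matrix (probes × pairs), or None if unpaired."""
    try:
        tumor_ids, normal_ids, pids = paired_ids(sheet)
    except ValueError:
        return None
    if not tumor_ids:
        return None
    d = beta.beta[tumor_ids].to_numpy() - beta.beta[normal_ids].to_numpy()
    return pd.DataFrame(d, index=beta.beta.index, columns=pids)


def classify_loci(
    stats_table: pd.DataFrame,
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    fdr_cut: float = 0.001,
    delta_cut: float = 0.2,
) -> pd.DataFrame:
    """Fill β-scale summaries and hyper/hypo/ns status.

    A probe is ``hyper`` when its FDR clears ``fdr_cut``, at least one
    pair shows Δβ > ``delta_cut``, and the mean Δβ is positive
    (symmetrically for ``hypo``).  In an unpaired design the per-pair rule
    degrades to |mean Δβ| > ``delta_cut``.
    """
    out = stats_table.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_fdr(out["p"].to_numpy())

    t_ids = group_ids(sheet, "tumor")
    n_ids = group_ids(sheet, "normal")
    p_ids = group_ids(sheet, "pbmc")
    bb = beta.beta.loc[out.index]
    out["mean_beta_tumor"] = bb[t_ids].mean(axis=1)
    out["mean_beta_normal"] = bb[n_ids].mean(axis=1)
    out["mean_beta_pbmc"] = bb[p_ids].mean(axis=1) if p_ids else np.nan
    out["delta_beta"] = out["mean_beta_tumor"] - out["mean_beta_normal"]

    pair_d = _pair_delta_beta(beta.subset_probes(out.index), sheet)
    if pair_d is not None:
        pair_d = pair_d.loc[out.index]
        out["n_pairs_hyper"] = (pair_d > delta_cut).sum(axis=1)
        out["n_pairs_hypo"] = (pair_d < -delta_cut).sum(axis=1)
        hyper_evidence = out["n_pairs_hyper"] >= 1
        hypo_evidence = out["n_pairs_hypo"] >= 1
    else:
        out["n_pairs_hyper"] = 0
        out["n_pairs_hypo"] = 0
        hyper_evidence = out["delta_beta"] > delta_cut
        hypo_evidence = out["delta_beta"] < -delta_cut

    sig = out["fdr"] < fdr_cut
    status = np.where(
        sig & hyper_evidence & (out["delta_beta"] > 0),
        "hyper",
        np.where(sig & hypo_evidence & (out["delta_beta"] < 0), "hypo", "ns"),
    )
    out["status"] = status
    return out


def call_de_novo(
    stats_table: pd.DataFrame,
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    manifest: pd.DataFrame,
    mode: str = "paired",
    beta_ref_cut: float = 0.3,
    delta_cut: float = 0.2,
    tumor_beta_cut: float = 0.2,
    freq_cut: float = 0.40,
    autosomes_only: bool = True,
    require_pbmc: bool = True,
) -> pd.DataFrame:
    """Flag de novo methylated loci: unmethylated in normals and in the
    PBMC reference panel, but methylated in at least ``freq_cut`` of
    tumors (per-pair Δβ > ``delta_cut`` in paired mode; β_tumor >
    ``tumor_beta_cut`` in unpaired mode).

    Calls are hyper-directional by construction (mean Δβ > 0 is required).
    """
    out = stats_table.copy()
    for col in ("mean_beta_tumor", "mean_beta_normal", "delta_beta"):
        if col not in out.columns:
            raise ValueError("run classify_loci before call_de_novo")

    p_ids = group_ids(sheet, "pbmc")
    if not p_ids:
        if require_pbmc:
            raise ValueError("no PBMC samples in sheet (set require_pbmc=False to skip)")
        pbmc_ok = pd.Series(True, index=out.index)
    else:
        pbmc_ok = beta.beta.loc[out.index, p_ids].mean(axis=1) < beta_ref_cut

    normal_ok = out["mean_beta_normal"] < beta_ref_cut

    if mode == "paired":
        pair_d = _pair_delta_beta(beta.subset_probes(out.index), sheet)
        if pair_d is None:
            raise ValueError("paired de novo calling requires paired samples")
        freq = (pair_d.loc[out.index] > delta_cut).mean(axis=1)
    elif mode == "unpaired":
        t_ids = group_ids(sheet, "tumor")
        freq = (beta.beta.loc[out.index, t_ids] > tumor_beta_cut).mean(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    mani = manifest.set_index("probe_id")
    missing = [p for p in out.index if p not in mani.index]
    if missing:
        raise ValueError(f"probes missing chrom annotation: {missing[:5]}")
    chrom = mani.loc[out.index, "chrom"]
    auto_ok = chrom.map(is_autosome) if autosomes_only else pd.Series(True, index=out.index)

    out["de_novo"] = (
        auto_ok
        & normal_ok
        & pbmc_ok
        & (freq >= freq_cut)
        & (out["delta_beta"] > 0)
    )
    return out


def gene_set_rank_test(
    gene_stats: pd.Series,
    set_members: set[str],
    alternative: str = "down",
) -> float:
    """One-sided mean-rank (Wilcoxon rank-sum) gene-set test.

    Compares set members' statistics against non-members with the normal
    approximation and tie correction; ``alternative="down"`` asks whether
    members rank lower (e.g. downregulated expression t-statistics).
    """
    members = set(set_members) & set(gene_stats.index)
    if not members:
        raise ValueError("gene set does not intersect the statistic vector")
    if len(members) == len(gene_stats):
        raise ValueError("gene set covers all genes: no complement to rank against")
    in_set = gene_stats.index.isin(members)
    alt = {"down": "less", "up": "greater"}.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    res = stats.mannwhitneyu(
        gene_stats[in_set], gene_stats[~in_set], alternative=alt, method="asymptotic"
    )
    return float(res.pvalue)
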