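import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import dmr450 as d

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

CHROM_PLAN = {"chr6": (1_200_000, 0.6), "chr2": (800_000, 0.4)}
CHROM_LENGTHS = {c: l for c, (l, _) in CHROM_PLAN.items()}


def make_spiked_cohort(seed: int, n_probes: int = 5000, n_pairs: int = 25,
                       n_pbmc: int = 100, spike: d.SpikeSpec | None = None):
    """Study-scale spiked cohort: 25 pairs, 100 PBMCs, 5 truth regions on 6p."""
    manifest = d.generate_manifest(n_probes, CHROM_PLAN, seed=seed)
    return d.generate_cohort(
        manifest,
        n_pairs=n_pairs,
        n_pbmc=n_pbmc,
        spike=spike if spike is not None else d.SpikeSpec(),
        chrom_lengths=CHROM_LENGTHS,
        seed=seed + 1000,
    )


def run_diffmeth(cohort, de_novo: bool = True) -> tuple[pd.DataFrame, d.BetaMatrix]:
    """Filter -> M -> moderated test -> BH -> classify (-> de novo)."""
    filt, _ = d.filter_probes(cohort.beta, cohort.manifest)
    m = d.beta_to_m(filt)
    stats = d.moderated_test(m, cohort.sheet, design="paired")
    stats["fdr"] = d.bh_fdr(stats["p"].to_numpy())
    stats = d.classify_loci(stats, filt, cohort.sheet)
    if de_novo:
        stats = d.call_de_novo(stats, filt, cohort.sheet, cohort.manifest)
    return stats, filt


@pytest.fixture(scope="session")
def spiked_cohort():
    return make_spiked_cohort(seed=0)


@pytest.fixture(scope="session")
def spiked_stats(spiked_cohort):
    return run_diffmeth(spiked_cohort)


@pytest.fixture(scope="session")
def small_manifest():
    return d.generate_manifest(2000, {"chr6": (600_000, 1.0)}, seed=3)


@pytest.fixture(scope="session")
def compressed_cohort(small_manifest):
    """Small cohort with strong type-II compression for normalization tests."""
    return d.generate_cohort(
        small_manifest, n_pairs=2, n_pbmc=0, type2_compression=0.3, seed=4
    )


def toy_manifest(positions, chrom="chr6", **overrides) -> pd.DataFrame:
    """Hand-built manifest from explicit probe positions."""
    n = len(positions)
    base = {
        "probe_id": [f"p{i}" for i in range(n)],
        "chrom": [chrom] * n,
        "pos": list(positions),
        "cgi_relation": ["Island"] * n,
        "cytoband": [chrom.removeprefix("chr") + "p21"] * n,
        "genes": [[f"g{i}"] for i in range(n)],
        "design_type": ["I"] * n,
        "cross_reactive": [False] * n,
        "snp_proximal": [False] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)
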