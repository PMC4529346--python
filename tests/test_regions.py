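"""Region merging, permutation calibration, ranking, and band enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

import dmr450 as d
from dmr450.core import Region
from dmr450.regions import NullScoreTable

from conftest import toy_manifest


def _stats(fdrs, t=None, probes=None):
    probes = probes or [f"p{i}" for i in range(len(fdrs))]
    return pd.DataFrame(
        {"fdr": fdrs, "t_mod": t if t is not None else [1.0] * len(fdrs)},
        index=pd.Index(probes, name="probe_id"),
    )


def brute_force_regions(positions, fdrs, signs, fdr_cut=0.05, gap_bp=50, min_probes=2):
    """Independent oracle: enumerate maximal runs of qualifying probes."""
    qual = [
        i for i in range(len(positions)) if fdrs[i] < fdr_cut and signs[i] > 0
    ]
    runs, current = [], []
    for i in qual:
        if current and positions[i] - positions[current[-1]] > gap_bp:
            runs.append(current)
            current = []
        current.append(i)
    if current:
        runs.append(current)
    out = []
    for run in runs:
        if len(run) >= min_probes:
            score = 1.0
            for i in run:
                score *= fdrs[i]
            out.append(
                (positions[run[0]] - 1, positions[run[-1]], len(run), score)
            )
    return out


class TestMergeAdjacent:
    def test_gap_rule_positions_100_140_260(self):
        """Gaps 40 and 120: first two merge, the singleton at 260 is dropped."""
        mani = toy_manifest([100, 140, 260])
        regs = d.merge_adjacent(_stats([0.01, 0.01, 0.01]), mani)
        assert len(regs) == 1
        assert (regs[0].start, regs[0].end, regs[0].k) == (99, 140, 2)
        regs1 = d.merge_adjacent(_stats([0.01, 0.01, 0.01]), mani, min_probes=1)
        assert [(r.start, r.end) for r in regs1] == [(99, 140), (259, 260)]

    def test_raw_score_is_product_of_member_fdrs(self):
        mani = toy_manifest([100, 140])
        regs = d.merge_adjacent(_stats([0.01, 0.02]), mani)
        assert regs[0].raw_score == pytest.approx(2e-4, rel=1e-9)
        assert regs[0].log10_score == pytest.approx(math.log10(2e-4), rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        positions = np.sort(rng.choice(np.arange(1, 2000), 30, replace=False))
        fdrs = rng.uniform(0, 0.2, 30)
        signs = rng.choice([-1.0, 1.0], 30)
        mani = toy_manifest(positions)
        regs = d.merge_adjacent(_stats(fdrs, t=signs), mani)
        expected = brute_force_regions(list(positions), list(fdrs), list(signs))
        assert [(r.start, r.end, r.k) for r in regs] == [e[:3] for e in expected]
        for r, e in zip(regs, expected):
            assert r.raw_score == pytest.approx(e[3], rel=1e-9)

    def test_invariant_to_input_row_order(self):
        rng = np.random.default_rng(10)
        positions = np.sort(rng.choice(np.arange(1, 3000), 40, replace=False))
        mani = toy_manifest(positions)
        st = _stats(rng.uniform(0, 0.1, 40))
        a = d.merge_adjacent(st, mani)
        b = d.merge_adjacent(st.sample(frac=1, random_state=1), mani)
        assert [(r.start, r.end, r.probe_ids) for r in a] == [
            (r.start, r.end, r.probe_ids) for r in b
        ]

    def test_split_by_chromosome_and_concatenate(self):
        rng = np.random.default_rng(12)
        m6 = toy_manifest(np.sort(rng.choice(np.arange(1, 2000), 20, replace=False)), chrom="chr6")
        m2 = toy_manifest(np.sort(rng.choice(np.arange(1, 2000), 20, replace=False)), chrom="chr2")
        m2["probe_id"] = [f"q{i}" for i in range(20)]
        m2["cytoband"] = "2p21"
        mani = pd.concat([m2, m6], ignore_index=True)
        st = _stats(rng.uniform(0, 0.1, 40), probes=list(m6["probe_id"]) + list(m2["probe_id"]))
        joint = d.merge_adjacent(st, mani)
        part6 = d.merge_adjacent(st.loc[m6["probe_id"]], m6)
        part2 = d.merge_adjacent(st.loc[m2["probe_id"]], m2)
        key = lambda rs: [(r.chrom, r.start, r.end, tuple(r.probe_ids)) for r in rs]
        assert key(joint) == key(sorted(part2 + part6, key=lambda r: (r.chrom, r.start)))

    def test_direction_filter(self):
        mani = toy_manifest([100, 120, 140])
        st = _stats([0.01, 0.01, 0.01], t=[1.0, -1.0, 1.0])
        hyper = d.merge_adjacent(st, mani, direction="hyper")
        both = d.merge_adjacent(st, mani, direction="both")
        assert [r.probe_ids for r in hyper] == [["p0", "p2"]]  # chained through the gap
        assert [r.probe_ids for r in both] == [["p0", "p1", "p2"]]

    def test_missing_probe_in_manifest(self):
        mani = toy_manifest([100, 140])
        with pytest.raises(ValueError, match="missing from manifest"):
            d.merge_adjacent(_stats([0.01, 0.01, 0.01]), mani)


class TestPermutationCalibrate:
    def test_identical_fdrs_give_constant_null(self):
        """Permuting an exchangeable column leaves region counts unchanged."""
        mani = toy_manifest(np.arange(1, 31) * 30)  # all gaps 30 <= 50
        st = _stats([0.01] * 30)
        table = d.permutation_calibrate(st, mani, n_perm=100, seed=1)
        # every permutation yields exactly one 30-probe region
        assert set(table.scores_by_k) == {30}
        assert len(table.scores_by_k[30]) == 100
        assert np.allclose(table.scores_by_k[30], 30 * math.log10(0.01))

    def test_first_half_of_longer_run_is_identical(self):
        rng = np.random.default_rng(3)
        mani = toy_manifest(np.sort(rng.choice(np.arange(1, 5000), 60, replace=False)))
        st = _stats(rng.uniform(0, 0.2, 60))
        t100 = d.permutation_calibrate(st, mani, n_perm=100, seed=5)
        t200 = d.permutation_calibrate(st, mani, n_perm=200, seed=5)
        for k, scores in t100.scores_by_k.items():
            larger = list(np.round(t200.scores_by_k[k], 9))
            for s in np.round(scores, 9):
                assert s in larger
                larger.remove(s)

    def test_probe_density_drives_null_region_count(self):
        """The array-design bias being corrected: dense chromosomes produce
        more null regions than sparse ones under label permutation."""
        rng = np.random.default_rng(6)
        dense = toy_manifest(np.arange(1, 301) * 25, chrom="chr6")  # gaps 25 bp
        sparse = toy_manifest(np.arange(1, 301) * 5000, chrom="chr2")  # gaps 5 kb
        sparse["probe_id"] = [f"q{i}" for i in range(300)]
        sparse["cytoband"] = "2p21"
        mani = pd.concat([dense, sparse], ignore_index=True)
        fdrs = rng.uniform(0, 0.15, 600)
        probes = list(dense["probe_id"]) + list(sparse["probe_id"])
        n_dense = n_sparse = 0
        for perm_seed in range(10):
            perm = np.random.default_rng(perm_seed).permutation(600)
            st = _stats(fdrs[perm], probes=probes)
            regs = d.merge_adjacent(st, mani)
            n_dense += sum(r.chrom == "chr6" for r in regs)
            n_sparse += sum(r.chrom == "chr2" for r in regs)
        assert n_dense > 10 * max(n_sparse, 1)

    def test_insufficient_permutations_rejected(self):
        mani = toy_manifest([100, 140])
        with pytest.raises(ValueError, match="100"):
            d.permutation_calibrate(_stats([0.01, 0.01]), mani, n_perm=50, seed=1)


class TestCalibrateRegions:
    def _region(self, log10_score, k=2):
        return Region(
            chrom="chr6", start=0, end=100, probe_ids=["a", "b"][:k], k=k,
            raw_score=10.0 ** log10_score, log10_score=log10_score,
        )

    def _table(self, scores, k=2):
        return NullScoreTable(
            scores_by_k={k: np.sort(np.asarray(scores, dtype=float))},
            n_perm=100, seed=0, n_probes=100,
        )

    def test_score_below_all_nulls(self):
        table = self._table(np.linspace(-3, -1, 99))
        out = d.calibrate_regions([self._region(-10.0)], table)
        assert out[0].calibrated_p == pytest.approx(1 / 100)

    def test_score_at_null_median(self):
        table = self._table(np.linspace(-3, -1, 101))
        out = d.calibrate_regions([self._region(-2.0)], table)
        assert out[0].calibrated_p == pytest.approx(0.5, abs=0.02)

    def test_empty_region_list(self):
        assert d.calibrate_regions([], self._table([-1.0])) == []

    def test_sparse_k_pools_neighbours(self):
        table = NullScoreTable(
            scores_by_k={2: np.linspace(-3, -1, 50), 5: np.array([-4.0])},
            n_perm=100, seed=0, n_probes=100,
        )
        out = d.calibrate_regions([self._region(-10.0, k=5)], table)
        assert out[0].calibrated_p == pytest.approx(1 / 52)
        assert 5 in table.pooled_ks

    def test_fdr_is_bh_over_calibrated_p(self):
        table = self._table(np.linspace(-5, -1, 99))
        regs = [self._region(s) for s in (-6.0, -4.0, -1.5)]
        out = d.calibrate_regions(regs, table)
        ps = np.array([r.calibrated_p for r in out])
        assert np.allclose([r.calibrated_fdr for r in out], d.bh_fdr(ps))


class TestRankAndSelect:
    def _regions(self, triples):
        out = []
        for i, (p, score, start) in enumerate(triples):
            out.append(
                Region(chrom="chr6", start=start, end=start + 50,
                       probe_ids=[f"x{i}a", f"x{i}b"], k=2,
                       raw_score=10.0 ** score, log10_score=score,
                       calibrated_p=p, calibrated_fdr=p)
            )
        return out

    def test_ranks_follow_calibrated_p(self):
        regs = self._regions([(0.3, -2, 0), (0.1, -2, 100), (0.2, -2, 200)])
        top = d.rank_and_select(regs, top_n=3)
        assert [r.calibrated_p for r in top] == [0.1, 0.2, 0.3]
        assert [r.rank for r in top] == [1, 2, 3]

    def test_ties_broken_by_score_then_coordinates(self):
        regs = self._regions([(0.1, -2, 300), (0.1, -4, 100), (0.1, -2, 200)])
        top = d.rank_and_select(regs, top_n=3)
        assert [(r.log10_score, r.start) for r in top] == [(-4, 100), (-2, 200), (-2, 300)]

    def test_top_n_larger_than_region_count(self):
        regs = self._regions([(0.1, -2, 0), (0.2, -2, 100)])
        assert len(d.rank_and_select(regs, top_n=500)) == 2

    def test_uncalibrated_regions_rejected(self):
        r = Region("chr6", 0, 50, ["a", "b"], 2, 1e-4, -4.0)
        with pytest.raises(ValueError, match="calibrate"):
            d.rank_and_select([r])


class TestFlagDeNovoRegions:
    def test_flags_match_hand_computation(self):
        sheet = pd.DataFrame(
            {
                "sample_id": ["T0", "N0", "PB0"],
                "subject_id": ["S0", "S0", "PS0"],
                "group": ["tumor", "normal", "pbmc"],
                "pair_id": ["P0", "P0", None],
            }
        )
        beta = d.BetaMatrix(
            pd.DataFrame(
                {
                    "T0": [0.6, 0.6, 0.6, 0.6],
                    "N0": [0.12, 0.31, 0.1, 0.29],
                    "PB0": [0.08, 0.1, 0.45, 0.29],
                },
                index=["a", "b", "c", "e"],
            )
        )
        regs = [
            Region("chr6", 0, 10, ["a"], 1, 0.01, -2),   # normal 0.12, pbmc 0.08 -> True
            Region("chr6", 20, 30, ["b"], 1, 0.01, -2),  # normal 0.31 -> False
            Region("chr6", 40, 50, ["c"], 1, 0.01, -2),  # pbmc 0.45 -> False
            Region("chr6", 60, 70, ["e"], 1, 0.01, -2),  # 0.29/0.29 -> True
        ]
        out = d.flag_de_novo_regions(regs, beta, sheet)
        assert [r.de_novo_region for r in out] == [True, False, False, True]


class TestBandEnrichment:
    def _manifest(self, n=5000, n_bands=10):
        mani = toy_manifest(np.arange(1, n + 1) * 100)
        mani["cytoband"] = [f"6p{i % n_bands}" for i in range(n)]
        return mani

    def test_concentrated_band_closed_form(self):
        """50 draws all on one of 10 equal bands: hypergeometric tail by
        explicit binomial-coefficient summation agrees and is tiny."""
        mani = self._manifest()
        members = list(mani.loc[mani["cytoband"] == "6p0", "probe_id"][:50])
        regs = [
            Region("chr6", 0, 1, members[i : i + 2], 2, 1e-4, -4.0,
                   calibrated_p=0.01, calibrated_fdr=0.01)
            for i in range(0, 50, 2)
        ]
        tab = d.band_enrichment(regs, mani)
        top = tab.iloc[0]
        assert top["band"] == "6p0"
        N, K, n_draw, x = 5000, 500, 50, 50
        tail = sum(
            math.comb(K, i) * math.comb(N - K, n_draw - i) / math.comb(N, n_draw)
            for i in range(x, min(K, n_draw) + 1)
        )
        assert top["p"] == pytest.approx(tail, rel=1e-9)
        assert top["p"] < 1e-6

    def test_band_with_zero_overlap_has_p_one(self):
        mani = self._manifest(n=100, n_bands=4)
        members = list(mani.loc[mani["cytoband"] == "6p0", "probe_id"][:4])
        regs = [Region("chr6", 0, 1, members[:2], 2, 1e-4, -4.0, 0.01, 0.01),
                Region("chr6", 2, 3, members[2:], 2, 1e-4, -4.0, 0.01, 0.01)]
        tab = d.band_enrichment(regs, mani).set_index("band")
        assert tab.loc["6p1", "p"] == 1.0
        assert tab.loc["6p1", "n_target"] == 0

    def test_uniformly_drawn_targets_rarely_significant(self):
        mani = self._manifest(n=2000, n_bands=8)
        hits = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            members = list(rng.choice(mani["probe_id"], 40, replace=False))
            regs = [
                Region("chr6", 0, 1, members[i : i + 2], 2, 1e-4, -4.0, 0.01, 0.01)
                for i in range(0, 40, 2)
            ]
            tab = d.band_enrichment(regs, mani)
            hits += tab["fdr"].min() < 0.05
        assert hits <= 0.1 * reps

    def test_gene_universe_mode(self):
        mani = self._manifest(n=200, n_bands=4)
        members = list(mani.loc[mani["cytoband"] == "6p0", "probe_id"][:10])
        regs = [
            Region("chr6", 0, 1, members[i : i + 2], 2, 1e-4, -4.0, 0.01, 0.01)
            for i in range(0, 10, 2)
        ]
        tab = d.band_enrichment(regs, mani, universe="genes")
        assert tab.iloc[0]["band"] == "6p0"
        assert tab.iloc[0]["p"] < 0.01

    def test_missing_cytoband_rejected(self):
        mani = self._manifest(n=10, n_bands=2)
        mani.loc[0, "cytoband"] = ""
        regs = [Region("chr6", 0, 1, list(mani["probe_id"][:2]), 2, 1e-4, -4.0, 0.01, 0.01)]
        with pytest.raises(ValueError, match="cytoband"):
            d.band_enrichment(regs, mani)
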