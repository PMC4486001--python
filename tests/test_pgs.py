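"""Polygenic scoring: allele alignment, clumping against an exhaustive
oracle, score arithmetic, and incremental-R^2 evaluation."""

import numpy as np
import pandas as pd
import pytest

from snpherit import (
    ClumpParams,
    ConfigError,
    PolygenicScorer,
    SimConfig,
    SummaryStats,
    align_alleles,
    clump,
    evaluate,
    score,
    simulate_cohort,
    simulate_discovery_gwas,
)

from conftest import make_geno


def stats_from(rows, discovery_n=1000):
    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "a1", "a2",
                                     "beta", "p"])
    df["se"] = 0.01
    return SummaryStats(df, discovery_n=discovery_n)


class TestAlignAlleles:
    def test_matching_alleles_unchanged(self):
        g = make_geno([[0, 1], [2, 1]], a1="A", a2="G")
        s = stats_from([("s0", 1, 1000, "A", "G", 0.2, 0.01),
                        ("s1", 1, 2000, "A", "G", -0.1, 0.5)])
        out = align_alleles(s, g.snp_meta)
        assert np.allclose(out.table["beta"], [0.2, -0.1])

    def test_swapped_alleles_flip_sign(self):
        g = make_geno([[0], [2]], a1="A", a2="G")
        s = stats_from([("s0", 1, 1000, "G", "A", 0.2, 0.01)])
        out = align_alleles(s, g.snp_meta)
        assert np.isclose(out.table["beta"].iloc[0], -0.2)

    def test_mixed_panel_hand_table(self):
        # 10 SNPs: 6 matching, 2 swapped, 2 strand-ambiguous -> 8 kept
        meta = pd.DataFrame({
            "snp": [f"s{i}" for i in range(10)],
            "chrom": 1, "pos": np.arange(10) * 1000 + 1000,
            "a1": ["A", "A", "C", "G", "A", "T", "A", "C", "A", "C"],
            "a2": ["G", "C", "T", "A", "G", "A", "G", "A", "T", "G"],
            "maf": 0.3,
        })
        rows = [
            ("s0", 1, 1000, "A", "G", 0.1, 0.1),   # match
            ("s1", 1, 2000, "C", "A", 0.2, 0.1),   # swapped -> -0.2
            ("s2", 1, 3000, "C", "T", 0.3, 0.1),   # match
            ("s3", 1, 4000, "G", "A", 0.4, 0.1),   # match
            ("s4", 1, 5000, "G", "A", 0.5, 0.1),   # swapped -> -0.5
            ("s5", 1, 6000, "T", "A", 0.6, 0.1),   # ambiguous A/T
            ("s6", 1, 7000, "A", "G", 0.7, 0.1),   # match
            ("s7", 1, 8000, "C", "A", 0.8, 0.1),   # match
            ("s8", 1, 9000, "A", "T", 0.9, 0.1),   # ambiguous A/T
            ("s9", 1, 10000, "C", "G", 1.0, 0.1),  # ambiguous C/G
        ]
        out = align_alleles(stats_from(rows), meta)
        got = dict(zip(out.table["snp"], out.table["beta"]))
        assert len(out) == 7  # 3 ambiguous dropped here (s5, s8, s9)
        assert np.isclose(got["s1"], -0.2)
        assert np.isclose(got["s4"], -0.5)
        assert np.isclose(got["s0"], 0.1)

    def test_no_overlap_rejected(self):
        g = make_geno([[0], [1]], a1="A", a2="G")
        s = stats_from([("other", 1, 1000, "A", "G", 0.2, 0.01)])
        with pytest.raises(ConfigError):
            align_alleles(s, g.snp_meta)


def oracle_clump(stats_df, dosages, positions, chroms, r2_max, window,
                 exclude=()):
    """Independent reference implementation of P-value-informed clumping."""
    x = np.asarray(dosages, float)
    x = x - x.mean(0)
    order = stats_df.sort_values(["p", "chrom", "pos"], kind="mergesort")
    chosen = []
    for _, row in order.iterrows():
        j = int(row["snp"][1:])
        if any(c == chroms[j] and lo <= positions[j] < hi for c, lo, hi in exclude):
            continue
        blocked = False
        for k in chosen:
            if chroms[k] == chroms[j] and abs(positions[k] - positions[j]) <= window:
                r = np.corrcoef(x[:, j], x[:, k])[0, 1]
                if r * r > r2_max:
                    blocked = True
                    break
        if not blocked:
            chosen.append(j)
    return [f"s{j}" for j in sorted(chosen)]


class TestClump:
    def test_uncorrelated_far_apart_all_indexed(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, (300, 5)).astype(np.int8)
        g = make_geno(d, pos=np.arange(5) * 10**6 + 1)
        s = stats_from([(f"s{i}", 1, int(g.snp_meta["pos"][i]), "A", "G", 0.1,
                         0.01 * (i + 1)) for i in range(5)])
        idx = clump(s, g, ClumpParams())
        assert sorted(idx) == [f"s{i}" for i in range(5)]

    def test_perfect_ld_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, (200, 1)).astype(np.int8)
        g = make_geno(np.hstack([col, col]), pos=[1000, 2000])
        s = stats_from([("s0", 1, 1000, "A", "G", 0.2, 1e-4),
                        ("s1", 1, 2000, "A", "G", 0.2, 1e-8)])
        idx = clump(s, g, ClumpParams())
        assert idx == ["s1"]

    def test_twelve_snp_toy_matches_oracle(self):
        rng = np.random.default_rng(2)
        n = 400
        blocks = []
        for b in range(4):  # 4 LD blocks of 3 SNPs
            base = rng.integers(0, 3, (n, 1))
            trio = [base]
            for _ in range(2):
                noisy = np.where(rng.random((n, 1)) < 0.15,
                                 rng.integers(0, 3, (n, 1)), base)
                trio.append(noisy)
            blocks.append(np.hstack(trio))
        d = np.hstack(blocks).astype(np.int8)
        pos = np.concatenate([b * 10**6 + np.array([0, 40_000, 80_000])
                              for b in range(4)]) + 1
        g = make_geno(d, pos=pos)
        pvals = rng.uniform(1e-8, 0.5, 12)
        s = stats_from([(f"s{i}", 1, int(pos[i]), "A", "G", 0.1, pvals[i])
                        for i in range(12)])
        params = ClumpParams(r2_max=0.25, window_bp=100_000)
        got = clump(s, g, params)
        expected = oracle_clump(s.table, d, pos, np.ones(12, int), 0.25, 100_000)
        assert set(got) == set(expected)

    def test_excluded_region_never_indexed(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, (200, 4)).astype(np.int8)
        pos = [1000, 2000, 30_000_000, 60_000_000]
        g = make_geno(d, pos=pos)
        s = stats_from([(f"s{i}", 1, pos[i], "A", "G", 0.1, 1e-6)
                        for i in range(4)])
        params = ClumpParams(exclude_regions=[(1, 25_000_000, 35_000_000)])
        idx = clump(s, g, params)
        assert "s2" not in idx and len(idx) == 3


class TestScore:
    def test_hand_arithmetic(self):
        g = make_geno([[1, 2]])
        s = stats_from([("s0", 1, 1000, "A", "G", 0.1, 0.01),
                        ("s1", 1, 2000, "A", "G", -0.05, 0.01)])
        got = score(g, s, threshold=0.05)
        assert np.allclose(got, [0.0])  # 1*0.1 + 2*(-0.05)

    def test_null_weights_and_linearity(self):
        rng = np.random.default_rng(4)
        g = make_geno(rng.integers(0, 3, (20, 6)).astype(np.int8))
        rows = [(f"s{i}", 1, 1000 * (i + 1), "A", "G", 0.0, 0.2)
                for i in range(6)]
        assert np.allclose(score(g, stats_from(rows), 0.5), 0.0)
        rows = [(f"s{i}", 1, 1000 * (i + 1), "A", "G", 0.1 * i, 0.2)
                for i in range(6)]
        s1 = score(g, stats_from(rows), 0.5)
        rows2 = [(r[0], r[1], r[2], r[3], r[4], 2 * r[5], r[6]) for r in rows]
        assert np.allclose(score(g, stats_from(rows2), 0.5), 2 * s1)

    def test_empty_threshold_rejected(self):
        g = make_geno([[1], [2]])
        s = stats_from([("s0", 1, 1000, "A", "G", 0.1, 0.9)])
        with pytest.raises(ConfigError, match="0.01"):
            score(g, s, threshold=0.01)

    def test_allele_flip_invariance_end_to_end(self):
        cfg = SimConfig(n_individuals=150, n_snps=60, n_causal_shared=20, seed=5)
        co = simulate_cohort(cfg)
        stats = simulate_discovery_gwas(co.truth, co.children.snp_meta,
                                        discovery_n=5000, seed=6)
        aligned = align_alleles(stats, co.children.snp_meta)
        base = score(co.children, aligned, 0.5)
        # flip the stored allele labels and dosages of one SNP
        flipped = co.children.subset_snps(np.arange(co.children.n_snps))
        d = flipped.dosages.copy()
        d[:, 7] = 2 - d[:, 7]
        flipped.dosages = d
        meta = flipped.snp_meta.copy()
        meta.loc[7, ["a1", "a2"]] = meta.loc[7, ["a2", "a1"]].to_numpy()
        meta.loc[7, "maf"] = 1 - meta.loc[7, "maf"]
        flipped.snp_meta = meta
        re_aligned = align_alleles(stats, flipped.snp_meta)
        got = score(flipped, re_aligned, 0.5)
        shift = got - base  # scores differ by a constant offset (2*beta)
        assert np.max(np.abs(shift - shift[0])) < 1e-12
        assert np.max(np.abs(np.corrcoef(got, base)[0, 1] - 1.0)) < 1e-12


class TestEvaluate:
    def test_perfect_predictor(self):
        rng = np.random.default_rng(7)
        s = rng.standard_normal(100)
        traits = pd.DataFrame({"t": s})
        res = evaluate({0.5: s}, traits)
        assert np.isclose(res.summary["t_incremental_r2"].iloc[0], 1.0)

    def test_null_score(self):
        rng = np.random.default_rng(8)
        traits = pd.DataFrame({"t": rng.standard_normal(2000)})
        res = evaluate({0.5: rng.standard_normal(2000)}, traits)
        assert res.summary["t_incremental_r2"].iloc[0] < 0.01

    def test_too_few_cases(self):
        traits = pd.DataFrame({"t": np.arange(10.0)})
        with pytest.raises(ConfigError, match="30"):
            evaluate({0.5: np.arange(10.0)}, traits)

    def test_scorer_grid_monotone_snp_count(self, small_cohort):
        co = small_cohort
        stats = simulate_discovery_gwas(co.truth, co.children.snp_meta,
                                        discovery_n=20_000, seed=9)
        scorer = PolygenicScorer().fit(stats, co.children)
        res = scorer.evaluate(co.children, co.phenotypes,
                              trait_columns=["achievement"])
        counts = res.summary["n_snps_in_score"].to_numpy()
        assert np.all(np.diff(counts) >= 0)
        assert np.isfinite(res.summary["achievement_incremental_r2"]).all()
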