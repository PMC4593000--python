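"""Interaction stage: slope, Welch tests, BH-FDR, calling and gene stripping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qfa.interaction import (
    GeneLocus,
    StrainSummary,
    adjust_fdr,
    estimate_slope,
    strip_genes,
    summarize_screen,
)
from qfa.interaction import test_interactions as call_interactions
from qfa.synthetic_data import simulate_fitness_screens


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j)*n/j."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    for rank_i in range(n):
        q_sorted[rank_i] = min(
            min(p[order[j]] * n / (j + 1) for j in range(rank_i, n)), 1.0
        )
    q = np.empty(n)
    q[order] = q_sorted
    return q


def summaries(d, background=""):
    return {
        g: StrainSummary(g, background, tuple(map(float, reps)))
        for g, reps in d.items()
    }


class TestSummarize:
    def test_mean_and_count(self):
        df = pd.DataFrame({"gene": ["A"] * 3 + ["B"], "fitness": [1, 2, 3, 7.0]})
        s = summarize_screen(df)
        assert s["A"].mean_fitness == pytest.approx(2.0) and s["A"].n == 3
        assert s["B"].mean_fitness == pytest.approx(7.0) and s["B"].n == 1

    def test_nonfinite_dropped_before_averaging(self):
        df = pd.DataFrame(
            {"gene": ["A"] * 3 + ["B"], "fitness": [1.0, np.nan, 3.0, np.inf]}
        )
        s = summarize_screen(df)
        assert s["A"].n == 2 and s["A"].mean_fitness == pytest.approx(2.0)
        assert "B" not in s  # no finite replicate left


class TestSlope:
    @pytest.mark.parametrize(
        "pairs,expected",
        [
            ([(1, 0.5), (2, 1), (3, 1.5)], 0.5),
            ([(1, 1), (2, 2), (5, 5)], 1.0),
            ([(1, 1), (2, 1)], 0.6),  # (1*1 + 2*1) / (1 + 4)
        ],
    )
    def test_closed_form(self, pairs, expected):
        assert estimate_slope(pairs) == pytest.approx(expected)

    def test_minimizes_through_origin_rss_vs_grid(self, rng):
        for _ in range(50):
            c = rng.uniform(0.1, 10, 30)
            q = 0.7 * c + rng.normal(0, 0.5, 30)
            m = estimate_slope(list(zip(c, q)))
            grid = np.linspace(max(m - 1, 0.0), m + 1, 4001)
            rss = ((q[None, :] - grid[:, None] * c[None, :]) ** 2).sum(axis=1)
            m_grid = grid[np.argmin(rss)]
            assert m == pytest.approx(m_grid, abs=1e-3)
            assert np.sum((q - m * c) ** 2) <= rss.min() + 1e-9

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            estimate_slope([(1.0, 1.0)])
        with pytest.raises(ValueError):
            estimate_slope([(0.0, 1.0), (0.0, 2.0)])


class TestFDR:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.05], [0.05]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_step_up_examples(self, p, expected):
        assert adjust_fdr(p) == pytest.approx(expected)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            assert adjust_fdr(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(0, 1, 25)
        perm = rng.permutation(25)
        assert adjust_fdr(p[perm]) == pytest.approx(adjust_fdr(p)[perm])

    def test_preserves_order_of_distinct_pvalues(self, rng):
        p = np.sort(rng.uniform(0, 1, 20))
        q = adjust_fdr(p)
        assert np.all(np.diff(q) >= -1e-15)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            adjust_fdr([-0.1])


class TestInteractions:
    def test_welch_example(self):
        # observed {1,2,3} vs predicted {2,3,4}: t = -1.2247, df = 4, p ~ 0.2879
        ctrl = summaries({"A": [2.0, 3.0, 4.0]})
        qry = summaries({"A": [1.0, 2.0, 3.0]})
        rec = call_interactions(ctrl, qry, m=1.0)[0]
        assert rec.p == pytest.approx(0.2879, abs=2e-4)
        assert rec.gis == pytest.approx(-1.0)
        assert rec.q == pytest.approx(rec.p)  # single-gene FDR vector

    def test_exact_null_gives_p_one(self):
        ctrl = summaries({"A": [1.0, 2.0, 3.0]})
        qry = summaries({"A": [0.5, 1.0, 1.5]})
        rec = call_interactions(ctrl, qry, m=0.5)[0]
        assert rec.p == pytest.approx(1.0)
        assert rec.call == "none" and rec.gis == pytest.approx(0.0)

    def test_single_replicate_excluded_from_fdr_vector(self):
        ctrl = summaries({"A": [1.0, 2.0], "B": [5.0]})
        qry = summaries({"A": [0.9, 2.2], "B": [4.0, 5.0]})
        recs = {r.gene: r for r in call_interactions(ctrl, qry, m=1.0)}
        assert np.isnan(recs["B"].p) and np.isnan(recs["B"].q)
        assert recs["B"].call == "none"
        assert recs["A"].q == pytest.approx(recs["A"].p)  # BH over 1 gene only

    def test_sign_convention_switch(self):
        ctrl = summaries({"A": [2.0, 3.0, 4.0]})
        qry = summaries({"A": [1.0, 2.0, 3.0]})
        fwd = call_interactions(ctrl, qry, m=1.0)[0]
        rev = call_interactions(ctrl, qry, m=1.0, sign_convention="pred_minus_obs")[0]
        assert rev.gis == pytest.approx(-fwd.gis)

    def test_gene_order_invariance(self, rng):
        genes = {f"G{i}": rng.uniform(1, 5, 4).tolist() for i in range(10)}
        qgenes = {g: (0.5 * np.array(v)).tolist() for g, v in genes.items()}
        a = call_interactions(summaries(genes), summaries(qgenes), m=0.5)
        shuffled = dict(reversed(list(genes.items())))
        b = call_interactions(summaries(shuffled), summaries(qgenes), m=0.5)
        assert [(r.gene, r.p, r.q, r.call) for r in a] == [
            (r.gene, r.p, r.q, r.call) for r in b
        ]

    def test_planted_negatives_dominate_calls(self):
        # 5% of 1000 genes at x0.5 fitness effect, 8 replicates, 5% noise
        fdps, senss = [], []
        for seed in range(5):
            ctrl, qry, truth = simulate_fitness_screens(
                n_genes=1000, n_replicates=8, m_true=0.5,
                planted_fraction=0.05, planted_effect_range=(0.5, 0.5),
                noise_sigma=0.05, seed=seed,
            )
            from qfa.pipeline import run_gis

            records, m = run_gis(ctrl, qry)
            neg = {r.gene for r in records if r.call == "negative"}
            planted = set(truth.loc[truth.interacting, "gene"])
            fdps.append(len(neg - planted) / max(len(neg), 1))
            senss.append(len(neg & planted) / len(planted))
        assert np.mean(fdps) <= 0.1
        assert np.mean(senss) > 0.8


LOCI = {
    "NEAR": GeneLocus("NEAR", "chrI", 85_000, 85_500),    # gap 14.5 kb
    "FAR": GeneLocus("FAR", "chrI", 125_000, 125_800),    # gap 24 kb
    "EDGE": GeneLocus("EDGE", "chrI", 121_000, 121_900),  # gap exactly 20 kb
    "OTHER": GeneLocus("OTHER", "chrII", 100_000, 101_000),
}
QUERY = [GeneLocus("QRY", "chrI", 100_000, 101_000)]


class TestStripGenes:
    def _summaries(self):
        return summaries({g: [1.0, 2.0] for g in LOCI} | {"NOLOC": [3.0, 4.0]})

    def test_linkage_window_arithmetic(self):
        kept = strip_genes(self._summaries(), LOCI, QUERY, window=20_000)
        assert "NEAR" not in kept          # 14.5 kb gap: stripped
        assert "FAR" in kept               # 24 kb gap: retained
        assert "EDGE" not in kept          # exactly 20 kb: stripped (inclusive)
        assert "OTHER" in kept             # different chromosome
        assert "NOLOC" in kept             # unknown locus retained

    def test_explicit_exclusions(self):
        kept = strip_genes(self._summaries(), LOCI, QUERY, exclusions={"FAR", "NOLOC"})
        assert "FAR" not in kept and "NOLOC" not in kept

    def test_idempotent(self):
        once = strip_genes(self._summaries(), LOCI, QUERY, exclusions={"FAR"})
        twice = strip_genes(once, LOCI, QUERY, exclusions={"FAR"})
        assert once == twice

    @given(
        start=st.integers(1, 300_000),
        length=st.integers(1, 5_000),
        window=st.integers(0, 50_000),
    )
    def test_never_strips_beyond_window_same_chromosome(self, start, length, window):
        locus = GeneLocus("G", "chrI", start, start + length)
        kept = strip_genes(
            summaries({"G": [1.0]}), {"G": locus}, QUERY, window=window
        )
        gap = max(0, max(locus.start, 100_000) - min(locus.end, 101_000))
        assert ("G" in kept) == (gap > window)
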