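import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from drgepi import (
    BackgroundSpec,
    binomial_z,
    by_adjust,
    eligible_pool,
    fisher_term_enrichment,
    g_statistic,
    mc_enrichment_z,
    sample_background,
)


# ---------------------------------------------------------------------------
# independently coded oracles
# ---------------------------------------------------------------------------

def by_stepup_oracle(pvals):
    """Step-up BY: adj_(i) = min_{j>=i} p_(j)·m·c(m)/j, clipped at 1."""
    m = len(pvals)
    c = sum(1.0 / k for k in range(1, m + 1))
    order = sorted(range(m), key=lambda i: pvals[i])
    adj_sorted = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m * c / rank)
        adj_sorted[rank - 1] = min(1.0, running)
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = adj_sorted[rank]
    return out


def g_formula_oracle(table):
    """Direct 2·Σ O·ln(O/E) with margin-based expectations, 0·ln(0)=0."""
    o = np.asarray(table, dtype=float)
    n = o.sum()
    e = np.outer(o.sum(axis=1), o.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(o > 0, o * np.log(o / e), 0.0)
    return 2.0 * terms.sum()


def hypergeom_tail_oracle(k, n_bg, k_bg, n_set):
    """Exhaustive Σ_{x>=k} C(K,x)C(N-K,n-x)/C(N,n) with exact integers."""
    total = math.comb(n_bg, n_set)
    acc = 0
    for x in range(k, min(k_bg, n_set) + 1):
        acc += math.comb(k_bg, x) * math.comb(n_bg - k_bg, n_set - x)
    return acc / total


# ---------------------------------------------------------------------------
# background sampling
# ---------------------------------------------------------------------------

def _gene_table(n, n_te=0, n_pseudo=0):
    roles = ["te"] * n_te + ["pseudo"] * n_pseudo + ["ok"] * (n - n_te - n_pseudo)
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "chrom": "chr1", "start": 1, "end": 100, "strand": "+",
        "is_te": [r == "te" for r in roles],
        "is_pseudogene": [r == "pseudo" for r in roles],
    })


class TestSampleBackground:
    def test_te_and_pseudo_excluded(self):
        genes = _gene_table(10, n_te=2)
        spec = BackgroundSpec(pool=frozenset(genes["gene_id"]), size=8, seed=1)
        sample = sample_background(genes, spec)
        assert len(sample) == 8
        assert not any(g in sample for g in ("g0", "g1"))  # the TE genes

    def test_oversized_request_errors(self):
        genes = _gene_table(10, n_te=2)
        spec = BackgroundSpec(pool=frozenset(genes["gene_id"]), size=9, seed=1)
        with pytest.raises(ValueError):
            sample_background(genes, spec)

    def test_deterministic_under_seed(self):
        genes = _gene_table(50)
        spec = BackgroundSpec(pool=frozenset(genes["gene_id"]), size=20, seed=9)
        assert sample_background(genes, spec) == sample_background(genes, spec)

    def test_query_genes_retained_at_pool_prevalence(self):
        """Sampling keeps DRGs in the pool: over 200 seeded draws the mean
        DRG fraction matches their 15% pool prevalence (99% binomial CI)."""
        n, frac = 1000, 0.15
        genes = _gene_table(n)
        drgs = set(genes["gene_id"].iloc[: int(n * frac)])
        size = 300
        fractions = []
        for seed in range(200):
            spec = BackgroundSpec(pool=frozenset(genes["gene_id"]), size=size, seed=seed)
            s = sample_background(genes, spec)
            fractions.append(len(s & drgs) / size)
        mean = float(np.mean(fractions))
        # binomial se upper-bounds the hypergeometric (without-replacement) one
        se = math.sqrt(frac * (1 - frac) / (size * 200))
        assert abs(mean - frac) < 2.58 * se


# ---------------------------------------------------------------------------
# Monte Carlo and binomial z
# ---------------------------------------------------------------------------

class TestEnrichmentZ:
    pool = frozenset(f"g{i}" for i in range(500))

    def test_saturated_feature_is_degenerate(self):
        spec = BackgroundSpec(pool=self.pool, size=500, n_draws=50, seed=0)
        res = mc_enrichment_z(set(list(self.pool)[:50]), self.pool, spec)
        assert res.degenerate and math.isnan(res.z)

    def test_observed_at_background_mean_gives_zero_z(self):
        res = binomial_z(set(f"g{i}" for i in range(100)),
                         set(f"g{i}" for i in range(0, 500, 2)), self.pool)
        assert res.z == 0.0 and res.p_two_sided == 1.0

    def test_binomial_z_arithmetic(self):
        # p0 = 0.1, n = 100, observed = 20 -> z = 10/3
        pool = frozenset(f"g{i}" for i in range(1000))
        positive = frozenset(f"g{i}" for i in range(100))
        query = frozenset(f"g{i}" for i in range(20)) | frozenset(
            f"g{i}" for i in range(100, 180))
        res = binomial_z(query, positive, pool)
        assert res.observed == 20 and res.target_size == 100
        assert res.z == pytest.approx(10.0 / 3.0, abs=1e-12)

    def test_empty_query_rejected(self):
        spec = BackgroundSpec(pool=self.pool, size=100, n_draws=10, seed=0)
        with pytest.raises(ValueError):
            mc_enrichment_z(set(), self.pool, spec)
        with pytest.raises(ValueError):
            binomial_z(set(), self.pool, self.pool)

    def test_mc_deterministic_under_seed(self):
        positive = frozenset(f"g{i}" for i in range(120))
        query = frozenset(f"g{i}" for i in range(50, 150))
        spec = BackgroundSpec(pool=self.pool, size=100, n_draws=100, seed=42)
        r1 = mc_enrichment_z(query, positive, spec)
        r2 = mc_enrichment_z(query, positive, spec)
        assert (r1.z, r1.bg_mean, r1.bg_sd) == (r2.z, r2.bg_mean, r2.bg_sd)

    def test_mc_converges_to_binomial(self):
        """|mc z − binomial z| small at B = 10^4 on a fixed fixture. The mc
        draws are without replacement, so the residual gap reflects the
        finite-pool correction, bounded well inside 0.2 here."""
        positive = frozenset(f"g{i}" for i in range(150))
        query = frozenset(f"g{i}" for i in range(100, 160))
        spec = BackgroundSpec(pool=self.pool, size=60, n_draws=10_000, seed=7)
        mc = mc_enrichment_z(query, positive, spec)
        an = binomial_z(query, positive, self.pool)
        assert not mc.degenerate
        # compare on the hypergeometric scale: rescale binomial sd
        fpc = math.sqrt((len(self.pool) - len(query)) / (len(self.pool) - 1))
        z_hyper = an.z / fpc
        assert abs(mc.z - z_hyper) < 0.2


# ---------------------------------------------------------------------------
# Fisher term enrichment + BY
# ---------------------------------------------------------------------------

def _annotations(term_to_genes):
    rows = [(t, g, float("nan"), "go") for t, genes in term_to_genes.items() for g in genes]
    return pd.DataFrame(rows, columns=["subject_id", "gene_id", "score", "kind"])


class TestFisher:
    background = {f"g{i}" for i in range(100)}
    query = {f"g{i}" for i in range(10)}

    def test_term_annotating_everything_has_p_one(self):
        ann = _annotations({"T1": list(self.background)})
        out = fisher_term_enrichment(self.query, ann, self.background, min_mapped=5)
        assert out.iloc[0]["p_raw"] == pytest.approx(1.0)

    def test_example_matches_exhaustive_enumeration(self):
        genes = [f"g{i}" for i in range(5)] + [f"g{i}" for i in range(20, 25)]
        ann = _annotations({"T1": genes})  # 10 in background, 5 in query
        out = fisher_term_enrichment(self.query, ann, self.background, min_mapped=5)
        expect = hypergeom_tail_oracle(5, 100, 10, 10)
        assert out.iloc[0]["p_raw"] == pytest.approx(expect, abs=1e-12)

    def test_min_mapped_filters_before_testing(self):
        ann = _annotations({
            "small": [f"g{i}" for i in range(3)],      # 3 mapped in query
            "big": [f"g{i}" for i in range(8)],        # 8 mapped in query
        })
        out = fisher_term_enrichment(self.query, ann, self.background, min_mapped=5)
        assert out["term_id"].tolist() == ["big"]
        # the BY universe is the surviving term only: m = 1 leaves p unchanged
        assert out.iloc[0]["p_adjusted"] == pytest.approx(out.iloc[0]["p_raw"])

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            fisher_term_enrichment(self.query, _annotations({}), set())

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            fisher_term_enrichment({"zz"}, _annotations({}), self.background)


class TestByAdjust:
    def test_single_p_unchanged(self):
        assert by_adjust([0.04]) == pytest.approx([0.04])

    def test_equal_ps_stay_equal(self):
        out = by_adjust([0.02] * 5)
        assert all(v == pytest.approx(out[0]) for v in out)

    def test_hand_evaluated_three_p_case(self):
        # p·m·c(m)/rank with m=3, c=11/6 gives 0.055 for every rank
        out = by_adjust([0.01, 0.02, 0.03])
        assert out == pytest.approx([0.055, 0.055, 0.055])

    def test_matches_stepup_oracle_and_dominates_bh(self):
        rng = np.random.default_rng(12)
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.random(rng.integers(1, 40)).tolist()
            adj = by_adjust(p)
            assert adj == pytest.approx(by_stepup_oracle(p), abs=1e-12)
            bh = multipletests(p, method="fdr_bh")[1]
            assert all(a >= b - 1e-12 for a, b in zip(adj, bh))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        p = rng.random(20)
        perm = rng.permutation(20)
        direct = np.array(by_adjust(p))[perm]
        permuted = np.array(by_adjust(p[perm]))
        assert direct == pytest.approx(permuted)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            by_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# G statistic
# ---------------------------------------------------------------------------

class TestGStatistic:
    def test_independent_table_gives_zero(self):
        res = g_statistic([[10, 90], [10, 90]])
        assert res.g == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_known_value(self):
        res = g_statistic([[20, 80], [10, 90]])
        assert res.g == pytest.approx(3.99, abs=0.01)

    def test_row_and_column_swap_invariance(self):
        base = g_statistic([[20, 80], [10, 90]]).g
        assert g_statistic([[10, 90], [20, 80]]).g == pytest.approx(base)
        assert g_statistic([[80, 20], [90, 10]]).g == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            g_statistic([[0, 0], [10, 90]])

    def test_matches_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            t = rng.integers(1, 200, size=(2, 2))
            assert g_statistic(t).g == pytest.approx(g_formula_oracle(t), rel=1e-10)

    def test_williams_correction_shrinks_g(self):
        plain = g_statistic([[20, 80], [10, 90]])
        corr = g_statistic([[20, 80], [10, 90]], williams=True)
        assert 0 < corr.g < plain.g and corr.williams_corrected

    def test_null_distribution_is_chi_square_1df(self):
        """G on independent 2x2 tables follows chi-square(1): KS at alpha=0.01."""
        rng = np.random.default_rng(99)
        n = 2000
        gs = []
        for _ in range(n):
            p_r, p_c = rng.uniform(0.3, 0.7, 2)
            rows = rng.multinomial(500, [p_r * p_c, p_r * (1 - p_c),
                                         (1 - p_r) * p_c, (1 - p_r) * (1 - p_c)])
            t = rows.reshape(2, 2)
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            gs.append(g_statistic(t).g)
        stat = sps.kstest(gs, sps.chi2(df=1).cdf)
        assert stat.pvalue > 0.01


def test_eligible_pool_excludes_flagged_genes():
    genes = _gene_table(10, n_te=2, n_pseudo=1)
    assert len(eligible_pool(genes)) == 7
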