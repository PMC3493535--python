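"""Enrichment statistics for gene sets.

Four pieces of machinery:

* a random-gene background (uniform sample of non-TE, non-pseudogene genes;
  genes of the query set are NOT excluded from the pool, so the sample
  honestly reflects their genome-wide prevalence),
* a Monte Carlo enrichment z-score — the observed feature count in a gene
  set standardized against B size-matched random draws from the pool — with
  a closed-form binomial z as analytic cross-check,
* one-sided Fisher exact (hypergeometric) term enrichment with
  Benjamini–Yekutieli FDR control and a minimum-mapping-entries filter,
* the likelihood-ratio G statistic for 2×2 contingency tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class BackgroundSpec:
    """Background-sampling contract: eligible gene pool, sample size, number
    of Monte Carlo draws B, and the seed all randomness flows from."""

    pool: frozenset
    size: int = 5000
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "pool", frozenset(self.pool))
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        if self.size > len(self.pool):
            raise ValueError(f"size {self.size} exceeds pool of {len(self.pool)}")


@dataclass
class EnrichmentResult:
    feature: str
    observed: int
    target_size: int
    bg_mean: float
    bg_sd: float
    z: float  # NaN when degenerate
    p_two_sided: float
    method: str  # monte_carlo | binomial
    degenerate: bool = False


@dataclass
class GTestResult:
    table: tuple
    g: float
    p: float
    williams_corrected: bool = False


def eligible_pool(genes: pd.DataFrame) -> frozenset:
    """Gene ids eligible for background sampling: TE-related genes and
    pseudogenes excluded."""
    ok = ~(genes["is_te"] | genes["is_pseudogene"])
    return frozenset(genes.loc[ok, "gene_id"])


def sample_background(genes: pd.DataFrame, spec: BackgroundSpec) -> frozenset:
    """Uniform sample without replacement of ``spec.size`` genes from the
    eligible pool; deterministic under ``spec.seed``."""
    pool = sorted(eligible_pool(genes) & spec.pool) if spec.pool else sorted(eligible_pool(genes))
    if spec.size > len(pool):
        raise ValueError(f"requested {spec.size} from eligible pool of {len(pool)}")
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(len(pool), size=spec.size, replace=False)
    return frozenset(pool[i] for i in idx)


def mc_enrichment_z(query, feature_positive, spec: BackgroundSpec) -> EnrichmentResult:
    """Monte Carlo enrichment z-score of a feature in ``query``.

    observed = |query ∩ feature_positive|; B seeded draws of size |query|
    from the pool give the null mean and sd (B−1 denominator);
    z = (observed − mean)/sd with a two-sided normal p. A null sd of 0
    (e.g. the feature saturates the pool) flags the result degenerate.
    """
    query = frozenset(query)
    if not query:
        raise ValueError("empty query set")
    pool = np.array(sorted(spec.pool))
    if len(query) > len(pool):
        raise ValueError("query larger than background pool")
    positive = np.isin(pool, np.array(sorted(frozenset(feature_positive))))
    observed = len(query & frozenset(feature_positive))
    rng = np.random.default_rng(spec.seed)
    counts = np.empty(spec.n_draws, dtype=np.int64)
    for b in range(spec.n_draws):
        idx = rng.choice(len(pool), size=len(query), replace=False)
        counts[b] = int(positive[idx].sum())
    mean, sd = float(counts.mean()), float(counts.std(ddof=1))
    if sd == 0.0:
        return EnrichmentResult("", observed, len(query), mean, sd,
                                float("nan"), float("nan"), "monte_carlo", degenerate=True)
    z = (observed - mean) / sd
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return EnrichmentResult("", observed, len(query), mean, sd, z, p, "monte_carlo")


def binomial_z(query, feature_positive, pool) -> EnrichmentResult:
    """Closed-form normal-approximation cross-check of the Monte Carlo z:
    z = (observed − n·p0) / sqrt(n·p0·(1−p0)) with p0 the pool prevalence."""
    query, positive, pool = frozenset(query), frozenset(feature_positive), frozenset(pool)
    if not pool:
        raise ValueError("empty pool")
    if not query:
        raise ValueError("empty query set")
    p0 = len(pool & positive) / len(pool)
    n = len(query)
    observed = len(query & positive)
    if p0 in (0.0, 1.0):
        return EnrichmentResult("", observed, n, n * p0, 0.0,
                                float("nan"), float("nan"), "binomial", degenerate=True)
    sd = math.sqrt(n * p0 * (1.0 - p0))
    z = (observed - n * p0) / sd
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return EnrichmentResult("", observed, n, n * p0, sd, z, p, "binomial")


def by_adjust(p_values) -> list[float]:
    """Benjamini–Yekutieli step-up adjustment (valid under arbitrary
    dependence): adj_(i) = min_{j>=i} p_(j)·m·c(m)/j with c(m) = Σ 1/k,
    clipped at 1, returned in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_by")
    return [float(x) for x in adj]


def fisher_term_enrichment(
    query,
    annotations: pd.DataFrame,
    background,
    min_mapped: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher exact (hypergeometric upper tail) enrichment of
    annotation terms in ``query`` against ``background``.

    Terms mapping fewer than ``min_mapped`` query genes are dropped before
    testing; Benjamini–Yekutieli adjustment runs across the surviving terms
    only. ``enriched`` marks p_adjusted < alpha.
    """
    query, background = frozenset(query), frozenset(background)
    if not background:
        raise ValueError("empty background")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    n_bg, n_set = len(background), len(query)
    rows = []
    for term, grp in annotations.groupby("subject_id", sort=True):
        genes = frozenset(grp["gene_id"]) & background
        k_bg = len(genes)
        k_set = len(genes & query)
        if k_set < min_mapped:
            continue
        # P(X >= k_set), X ~ Hypergeom(N=n_bg, K=k_bg, n=n_set)
        p_raw = float(sps.hypergeom.sf(k_set - 1, n_bg, k_bg, n_set))
        rows.append((term, k_set, n_set, k_bg, n_bg, min(1.0, p_raw)))
    out = pd.DataFrame(rows, columns=["term_id", "k_set", "n_set", "k_bg", "n_bg", "p_raw"])
    if len(out):
        out["p_adjusted"] = by_adjust(out["p_raw"])
        out["enriched"] = out["p_adjusted"] < alpha
        out = out.sort_values(["p_adjusted", "p_raw", "term_id"]).reset_index(drop=True)
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
        out["enriched"] = pd.Series(dtype=bool)
    return out


def g_statistic(table, williams: bool = False) -> GTestResult:
    """Likelihood-ratio G statistic for a 2×2 table: G = 2·Σ O·ln(O/E)
    with 0·ln(0) = 0 and expectations from the margins under independence;
    p from chi-square with 1 df. ``williams=True`` applies the Williams
    small-sample correction (off by default)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    g, p, _, _ = sps.chi2_contingency(obs, correction=False, lambda_="log-likelihood")
    corrected = False
    if williams:
        n = obs.sum()
        r, c = obs.sum(axis=1), obs.sum(axis=0)
        q = 1.0 + ((n / r[0] + n / r[1] - 1.0) * (n / c[0] + n / c[1] - 1.0)) / (6.0 * n)
        g = g / q
        p = float(sps.chi2.sf(g, df=1))
        corrected = True
    return GTestResult(tuple(map(tuple, obs.astype(int))), float(g), float(p), corrected)
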