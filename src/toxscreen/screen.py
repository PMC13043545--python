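"""Screen statistics: normalization, guide-level NB tests, alpha-RRA gene
ranking with permutation p-values, and dual-threshold candidate calling.

The guide-level test compares the mean exposed count of each sgRNA against
a negative-binomial null whose mean is the control mean and whose variance
comes from a mean-variance trend fitted on control replicates. Guides are
ranked separately for depletion and enrichment; each gene's score is the
alpha-RRA statistic (minimum Beta order-statistic tail probability over
its leading guides), calibrated by permutation against pseudo-genes drawn
from the pooled guide percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from toxscreen.quantify import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RraConfig",
    "NormalizedMatrix",
    "DispersionFit",
    "normalize_median_ratio",
    "estimate_dispersion",
    "sgrna_test",
    "alpha_rra",
    "gene_scores",
    "call_hits",
    "volcano_table",
]

#: variance is clamped to at least mean * (1 + _VAR_EPS)
_VAR_EPS = 1e-6
#: NB sizes above this are evaluated with the Poisson limit
_POISSON_SIZE = 1e6


@dataclass
class RraConfig:
    """Tuning of the gene-ranking stage.

    alpha_cutoff: percentile threshold of alpha-RRA (guides ranked worse
    than this fraction never contribute to a gene's score).
    n_permutations: pseudo-gene draws per guide-count class; the attainable
    p-value floor is 1/(n_permutations + 1).
    pseudocount: added to normalized means for log2FC and zero handling.
    """

    alpha_cutoff: float = 0.25
    n_permutations: int = 100_000
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_cutoff <= 1:
            raise ValueError("alpha_cutoff must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.n_permutations < 1000:
            logger.warning(
                "n_permutations=%d gives p-value resolution %.3g",
                self.n_permutations, 1 / (self.n_permutations + 1),
            )
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass
class NormalizedMatrix:
    """Normalized counts (real-valued) with the size factors that produced
    them; shape and labels mirror the source :class:`CountMatrix`."""

    values: pd.DataFrame
    size_factors: pd.Series
    genes: pd.Series
    conditions: dict[str, str]
    method: str = "median-ratio"

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions[s] == condition]


def normalize_median_ratio(matrix: CountMatrix) -> NormalizedMatrix:
    """Median-of-ratios normalization.

    The reference is the per-guide geometric mean across samples over rows
    with all counts positive; each sample's size factor is the median ratio
    of its counts to the reference. Falls back to total-count factors
    (scaled to mean 1) when no row has all-positive counts.
    """
    counts = matrix.counts
    if counts.shape[1] < 2:
        raise ValueError("normalization needs at least two samples")
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.any():
        logref = np.log(arr[positive]).mean(axis=1)
        ratios = np.log(arr[positive]) - logref[:, None]
        factors = np.exp(np.median(ratios, axis=0))
        method = "median-ratio"
    else:
        logger.warning(
            "no sgRNA with all-positive counts; falling back to total-count "
            "normalization"
        )
        totals = arr.sum(axis=0)
        factors = totals / totals.mean()
        method = "total-count"
    sf = pd.Series(factors, index=counts.columns, name="size_factor")
    values = counts / sf
    return NormalizedMatrix(
        values=values,
        size_factors=sf,
        genes=matrix.genes,
        conditions=dict(matrix.conditions),
        method=method,
    )


@dataclass
class DispersionFit:
    """Mean-variance trend sigma^2(m) = m + scale * m^exponent.

    ``sigma2`` holds the per-sgRNA modeled variance at the control mean,
    clamped to at least m*(1+1e-6) so the NB size stays finite.
    """

    scale: float
    exponent: float
    sigma2: pd.Series
    method: str = "trend"

    def predict(self, mean: np.ndarray) -> np.ndarray:
        m = np.asarray(mean, dtype=float)
        var = m + self.scale * np.power(m, self.exponent, where=m > 0, out=np.zeros_like(m))
        return np.maximum(var, m * (1 + _VAR_EPS))


def estimate_dispersion(
    norm: NormalizedMatrix, condition: str = "control", min_points: int = 30,
    n_bins: int = 20,
) -> DispersionFit:
    """Fit the control-replicate mean-variance trend.

    Guides are grouped into log-spaced abundance bins; within each bin the
    excess variance (v - m) is averaged over all guides — averaging before
    taking logs avoids the downward Jensen bias and the upward selection
    bias that a per-guide log(v - m) regression suffers with few
    replicates. A least-squares line log(mean excess) = b0 + b1 log(mean m)
    over positive-excess bins gives the modeled variance m + exp(b0) m^b1,
    clamped to at least m (1 + 1e-6). With fewer than ``min_points`` guides
    showing v > m, or fewer than 3 usable bins, a pooled constant
    dispersion (method of moments) is used instead.
    """
    cols = norm.samples_in(condition)
    if len(cols) < 2:
        raise ValueError(f"need >= 2 {condition} replicates to estimate dispersion")
    x = norm.values[cols].to_numpy(dtype=float)
    m = x.mean(axis=1)
    v = x.var(axis=1, ddof=1)
    ok = m > 0
    n_over = int(((v > m) & ok).sum())

    scale = exponent = None
    if n_over >= min_points:
        order = np.argsort(m[ok])
        ms, es = m[ok][order], (v - m)[ok][order]
        edges = np.linspace(0, len(ms), min(n_bins, max(len(ms) // 10, 1)) + 1).astype(int)
        mb, eb = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi > lo:
                mb.append(ms[lo:hi].mean())
                eb.append(es[lo:hi].mean())
        mb, eb = np.asarray(mb), np.asarray(eb)
        keep = (eb > 0) & (mb > 0)
        if keep.sum() >= 3:
            b1, b0 = np.polyfit(np.log(mb[keep]), np.log(eb[keep]), 1)
            scale, exponent, method = float(np.exp(b0)), float(b1), "trend"
    if scale is None:
        logger.warning(
            "%d sgRNAs with variance > mean; using pooled constant dispersion",
            n_over,
        )
        denom = float((m ** 2).sum())
        phi = max(0.0, float((v - m).sum()) / denom) if denom > 0 else 0.0
        scale, exponent, method = phi, 2.0, "pooled"
    fit = DispersionFit(scale=scale, exponent=exponent, sigma2=pd.Series(dtype=float),
                        method=method)
    fit.sigma2 = pd.Series(fit.predict(m), index=norm.values.index, name="sigma2")
    return fit


def _nb_tails(mu: np.ndarray, var: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P(X <= x) and P(X >= x) for NB(mean mu, variance var).

    Sizes beyond ``_POISSON_SIZE`` are evaluated with the Poisson limit,
    which is both faster and numerically cleaner when var ~ mu.
    """
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    x = np.asarray(x, dtype=float)
    size = mu ** 2 / (var - mu)
    p_low = np.empty_like(mu)
    p_high = np.empty_like(mu)
    pois = size > _POISSON_SIZE
    if pois.any():
        p_low[pois] = stats.poisson.cdf(x[pois], mu[pois])
        p_high[pois] = stats.poisson.sf(x[pois] - 1, mu[pois])
    nb = ~pois
    if nb.any():
        r = size[nb]
        p = r / (r + mu[nb])
        p_low[nb] = stats.nbinom.cdf(x[nb], r, p)
        p_high[nb] = stats.nbinom.sf(x[nb] - 1, r, p)
    # tails are probabilities of non-empty events, keep them in (0, 1]
    tiny = np.finfo(float).tiny
    return np.clip(p_low, tiny, 1.0), np.clip(p_high, tiny, 1.0)


def _rank_percentiles(p: np.ndarray, ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ranks 1..M ascending in p (ties broken by id) and percentiles rank/M."""
    order = np.lexsort((ids, p))
    ranks = np.empty(len(p), dtype=np.int64)
    ranks[order] = np.arange(1, len(p) + 1)
    return ranks, ranks / len(p)


def sgrna_test(
    norm: NormalizedMatrix,
    dispersion: DispersionFit,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Guide-level depletion/enrichment evidence.

    For each sgRNA the rounded mean exposed normalized count is scored
    against NB(mean = control mean, variance = modeled variance):
    ``p_low`` is the depletion tail P(X <= x) and ``p_high`` the enrichment
    tail P(X >= x). Zero control means are shifted by the pseudocount.
    Returns one row per sgRNA with log2FC, tails, per-direction ranks and
    percentiles.
    """
    ctrl = norm.samples_in("control")
    expo = norm.samples_in("exposed")
    if not ctrl or not expo:
        raise ValueError("both control and exposed samples are required")
    mu_c = norm.values[ctrl].mean(axis=1).to_numpy()
    mu_t = norm.values[expo].mean(axis=1).to_numpy()
    log2fc = np.log2((mu_t + pseudocount) / (mu_c + pseudocount))

    zero = mu_c == 0
    if zero.any():
        logger.info("%d sgRNAs with zero control mean scored at the pseudocount",
                    int(zero.sum()))
    mu_eff = np.where(zero, pseudocount, mu_c)
    sigma2 = dispersion.predict(mu_eff)
    x = np.rint(mu_t)
    p_low, p_high = _nb_tails(mu_eff, sigma2, x)

    ids = norm.values.index.to_numpy().astype(str)
    rank_low, pct_low = _rank_percentiles(p_low, ids)
    rank_high, pct_high = _rank_percentiles(p_high, ids)
    return pd.DataFrame(
        {
            "sgrna": norm.values.index,
            "gene": norm.genes.to_numpy(),
            "control_mean": mu_c,
            "exposed_mean": mu_t,
            "log2fc": log2fc,
            "sigma2": sigma2,
            "p_low": p_low,
            "p_high": p_high,
            "rank_low": rank_low,
            "rank_high": rank_high,
            "percentile_low": pct_low,
            "percentile_high": pct_high,
        }
    ).reset_index(drop=True)


def _rra_rows(r_sorted: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized alpha-RRA over rows of sorted percentiles (n x J).

    rho_k = P(Beta(k, J-k+1) <= r_(k)); the row score is the minimum over
    the leading k whose r_(k) <= alpha, or 1 when no guide passes alpha.
    """
    n, j_max = r_sorted.shape
    k = np.arange(1, j_max + 1, dtype=float)
    rho_k = special.betainc(k[None, :], j_max - k[None, :] + 1, r_sorted)
    rho_k = np.where(r_sorted <= alpha, rho_k, np.inf)
    rho = rho_k.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def alpha_rra(percentiles, alpha_cutoff: float = 0.25) -> float:
    """Alpha-RRA score of one gene from its guides' percentiles.

    With sorted percentiles r_(1) <= ... <= r_(J), only the leading guides
    with r_(k) <= alpha_cutoff are considered; the score is
    min_k P(Beta(k, J-k+1) <= r_(k)), the most surprising prefix under the
    uniform-order-statistic null, or 1 if no guide passes the cutoff.
    """
    r = np.sort(np.asarray(percentiles, dtype=float))
    if r.size == 0:
        raise ValueError("need at least one percentile")
    if (r <= 0).any() or (r > 1).any():
        raise ValueError("percentiles must lie in (0, 1]")
    return float(_rra_rows(r[None, :], alpha_cutoff)[0])


def _sample_pseudo_genes(
    pool: np.ndarray, j: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """n_perm pseudo-genes of j percentiles drawn without replacement."""
    m = len(pool)
    if j > m:
        raise ValueError("guide count exceeds pool size")
    idx = rng.integers(0, m, size=(n_perm, j))
    if j > 1:
        while True:
            sorted_idx = np.sort(idx, axis=1)
            dup = (np.diff(sorted_idx, axis=1) == 0).any(axis=1)
            if not dup.any():
                break
            idx[dup] = rng.integers(0, m, size=(int(dup.sum()), j))
    return np.sort(pool[idx], axis=1)


def _permutation_p(
    rho_obs: np.ndarray,
    gene_j: np.ndarray,
    pool: np.ndarray,
    config: RraConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation p-values: for each guide-count class, compare observed
    rho against pseudo-genes drawn from the pooled percentile vector."""
    p = np.empty_like(rho_obs)
    for j in np.unique(gene_j):
        r = _sample_pseudo_genes(pool, int(j), config.n_permutations, rng)
        null = np.sort(_rra_rows(r, config.alpha_cutoff))
        sel = gene_j == j
        hits = np.searchsorted(null, rho_obs[sel], side="right")
        p[sel] = (1.0 + hits) / (config.n_permutations + 1.0)
    return p


def gene_scores(
    sgrna_results: pd.DataFrame,
    config: RraConfig | None = None,
    p_threshold: float = 0.01,
    lfc_threshold: float = 0.6,
) -> pd.DataFrame:
    """Aggregate guide evidence to genes.

    Per direction (depletion -> sensitive, enrichment -> resistant) each
    gene gets an alpha-RRA score over its guides' percentiles, a
    permutation p-value against pseudo-genes of the same guide count, and
    a BH-adjusted FDR across genes. The gene log2FC is the median of its
    guides' log2FCs, and ``direction`` applies the dual-threshold calling
    rule (p < p_threshold and |log2FC| > lfc_threshold, strict).
    """
    config = config or RraConfig()
    df = sgrna_results.sort_values(["gene", "sgrna"], kind="mergesort")
    grouped = df.groupby("gene", sort=False)
    gene_j = grouped.size().to_numpy()
    gene_lfc = grouped["log2fc"].median().to_numpy()

    rng = np.random.default_rng(config.seed)
    out: dict[str, np.ndarray] = {}
    for tag, col in (("low", "percentile_low"), ("high", "percentile_high")):
        pct = df[col].to_numpy()
        pool = pct  # pooled percentile vector over all guides
        rho = np.array([
            alpha_rra(sub.to_numpy(), config.alpha_cutoff)
            for _, sub in grouped[col]
        ])
        p = _permutation_p(rho, gene_j, pool, config, rng)
        fdr = multipletests(p, method="fdr_bh")[1]
        out[f"rho_{tag}"] = rho
        out[f"p_{tag}"] = p
        out[f"fdr_{tag}"] = fdr

    result = pd.DataFrame({"gene": list(grouped.indices), "n_guides": gene_j})
    for k, v in out.items():
        result[k] = v
    result["gene_log2fc"] = gene_lfc
    sens = (result["p_low"] < p_threshold) & (result["gene_log2fc"] < -lfc_threshold)
    res = (result["p_high"] < p_threshold) & (result["gene_log2fc"] > lfc_threshold)
    result["direction"] = np.where(sens, "sensitive", np.where(res, "resistant", "none"))
    return result


def call_hits(
    gene_results: pd.DataFrame,
    p_threshold: float = 0.01,
    lfc_threshold: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dual-threshold candidate calling.

    sensitive: p_low < p_threshold and gene log2FC < -lfc_threshold;
    resistant: p_high < p_threshold and gene log2FC > +lfc_threshold
    (all strict). Each table is sorted by p ascending, then |log2FC|
    descending, then gene symbol.
    """
    g = gene_results
    sens = g[(g["p_low"] < p_threshold) & (g["gene_log2fc"] < -lfc_threshold)].copy()
    res = g[(g["p_high"] < p_threshold) & (g["gene_log2fc"] > lfc_threshold)].copy()

    def _sorted(df: pd.DataFrame, pcol: str) -> pd.DataFrame:
        df["_abs"] = df["gene_log2fc"].abs()
        df = df.sort_values([pcol, "_abs", "gene"], ascending=[True, False, True])
        return df.drop(columns="_abs").reset_index(drop=True)

    return _sorted(sens, "p_low"), _sorted(res, "p_high")


def volcano_table(
    gene_results: pd.DataFrame,
    p_threshold: float = 0.01,
    lfc_threshold: float = 0.6,
) -> pd.DataFrame:
    """Plot-ready volcano export: gene, log2fc, -log10(p), class.

    The plotted p is the smaller of the two directional p-values; class
    follows the calling rule.
    """
    g = gene_results
    p = np.minimum(g["p_low"].to_numpy(), g["p_high"].to_numpy())
    sens = (g["p_low"] < p_threshold) & (g["gene_log2fc"] < -lfc_threshold)
    res = (g["p_high"] < p_threshold) & (g["gene_log2fc"] > lfc_threshold)
    cls = np.where(sens, "sensitive", np.where(res, "resistant", "other"))
    return pd.DataFrame(
        {
            "gene": g["gene"],
            "log2fc": g["gene_log2fc"],
            "minus_log10_p": -np.log10(p),
            "class": cls,
        }
    )
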