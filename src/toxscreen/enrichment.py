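"""Gene-disease over/under-representation by random-set resampling.

For a candidate gene set of size n, the proportion of candidates annotated
to each disease term is compared with the proportions in equally sized
random gene sets drawn uniformly without replacement from the universe.
The standardized deviation (z-score) of the observed proportion from the
random-set mean, referred to a standard normal, gives one-sided over- and
under-representation p-values per disease. The exact counterpart of this
Monte-Carlo null is hypergeometric and is exposed as an analytic oracle
(:func:`exact_null_moments`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentConfig",
    "GeneDiseaseAnnotation",
    "load_annotation",
    "annotation_from_frame",
    "observed_proportion",
    "resample_null",
    "zscore_test",
    "exact_null_moments",
    "analyze_enrichment",
    "rank_and_report",
    "EnrichmentAnalysis",
]


@dataclass
class EnrichmentConfig:
    """Parameters of the resampling analysis: 1,000 random sets, a 0.001
    observed-proportion reporting floor, a 0.05 significance threshold,
    and a top-15 report, mirroring the screen workflow's defaults."""

    n_random: int = 1000
    min_proportion: float = 0.001
    alpha: float = 0.05
    top_k: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if not 0 <= self.min_proportion < 1:
            raise ValueError("min_proportion must be in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class GeneDiseaseAnnotation:
    """Deduplicated (gene, disease) pairs, the gene universe, and the
    derived per-disease gene sets."""

    pairs: pd.DataFrame
    universe: np.ndarray
    gene_sets: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.universe) < 2:
            raise ValueError("universe must contain at least 2 genes")
        if not self.gene_sets:
            univ = set(self.universe)
            self.gene_sets = {
                d: frozenset(set(g) & univ)
                for d, g in self.pairs.groupby("disease")["gene"]
            }

    @property
    def diseases(self) -> list[str]:
        return sorted(self.gene_sets)


def annotation_from_frame(
    pairs: pd.DataFrame, universe: list[str] | None = None
) -> GeneDiseaseAnnotation:
    """Build an annotation from a (gene, disease) frame.

    The universe defaults to the distinct genes in the table; a supplied
    universe may contain genes with no annotations.
    """
    if not {"gene", "disease"} <= set(pairs.columns):
        raise ValueError("annotation needs gene and disease columns")
    pairs = pairs[["gene", "disease"]].drop_duplicates().reset_index(drop=True)
    if len(pairs) == 0:
        raise ValueError("annotation table is empty")
    if universe is None:
        univ = np.array(sorted(pairs["gene"].unique()))
    else:
        univ = np.array(sorted(set(universe)))
    return GeneDiseaseAnnotation(pairs=pairs, universe=univ)


def load_annotation(
    path: str | Path, universe: list[str] | None = None
) -> GeneDiseaseAnnotation:
    """Read an annotation TSV with columns gene and disease (case-
    insensitive; extra columns, e.g. DiseaseID or DirectEvidence in
    CTD-style exports, are ignored)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    gene_c = cols.get("gene") or cols.get("genesymbol") or cols.get("gene_symbol")
    dis_c = cols.get("disease") or cols.get("diseasename") or cols.get("disease_name")
    if gene_c is None or dis_c is None:
        raise ValueError(f"annotation {path}: needs gene and disease columns")
    return annotation_from_frame(
        df.rename(columns={gene_c: "gene", dis_c: "disease"}), universe
    )


def _restrict_candidates(
    candidates, annotation: GeneDiseaseAnnotation
) -> tuple[set, int]:
    cand = set(candidates)
    in_univ = cand & set(annotation.universe)
    dropped = len(cand) - len(in_univ)
    if dropped:
        logger.info("%d candidate genes outside the universe were dropped", dropped)
    if not in_univ:
        raise ValueError("no candidate genes inside the universe")
    return in_univ, dropped


def observed_proportion(
    candidates, annotation: GeneDiseaseAnnotation, disease: str
) -> tuple[int, int, float]:
    """(n, annotated count, proportion) of the candidate set for one
    disease, after intersecting the candidates with the universe."""
    cand, _ = _restrict_candidates(candidates, annotation)
    members = annotation.gene_sets.get(disease, frozenset())
    count = len(cand & members)
    return len(cand), count, count / len(cand)


def resample_null(
    annotation: GeneDiseaseAnnotation, n: int, config: EnrichmentConfig
) -> pd.DataFrame:
    """Null proportions from random sets: one shared collection of
    ``n_random`` uniform size-n subsets of the universe, scored against
    every disease. Rows are replicate draws, columns diseases."""
    universe = annotation.universe
    n_univ = len(universe)
    if n > n_univ:
        raise ValueError(f"set size {n} exceeds universe size {n_univ}")
    rng = np.random.default_rng(config.seed)
    draws = np.empty((config.n_random, n), dtype=np.int64)
    for i in range(config.n_random):
        draws[i] = rng.choice(n_univ, size=n, replace=False)
    pos = {g: i for i, g in enumerate(universe)}
    cols = {}
    for d in annotation.diseases:
        ind = np.zeros(n_univ, dtype=bool)
        ind[[pos[g] for g in annotation.gene_sets[d]]] = True
        cols[d] = ind[draws].sum(axis=1) / n
    return pd.DataFrame(cols, index=pd.RangeIndex(config.n_random, name="replicate"))


def zscore_test(
    p_obs: float,
    null_proportions: np.ndarray,
    config: EnrichmentConfig,
    disease: str = "",
    n: int = 0,
    observed_count: int = 0,
) -> dict:
    """Standardize one observed proportion against its Monte-Carlo null.

    z = (p_obs - null mean) / null SD (sample SD, n-1 denominator);
    one-sided normal p-values per direction. A null with zero SD is
    flagged degenerate (z and p undefined, excluded from ranking).
    """
    null = np.asarray(null_proportions, dtype=float)
    if len(null) != config.n_random:
        raise ValueError("null vector length does not match n_random")
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if len(null) > 1 else 0.0
    if sd == 0.0:
        logger.warning("degenerate null (sd = 0) for disease %r", disease)
        return {
            "disease": disease, "n": n, "observed_count": observed_count,
            "p_obs": p_obs, "null_mean": mean, "null_sd": 0.0,
            "z": np.nan, "p_over": np.nan, "p_under": np.nan,
            "direction": "none", "degenerate": True,
        }
    z = (p_obs - mean) / sd
    p_over = float(stats.norm.sf(z))
    p_under = float(stats.norm.cdf(z))
    if p_over <= config.alpha:
        direction = "over"
    elif p_under <= config.alpha:
        direction = "under"
    else:
        direction = "none"
    return {
        "disease": disease, "n": n, "observed_count": observed_count,
        "p_obs": p_obs, "null_mean": mean, "null_sd": sd,
        "z": z, "p_over": p_over, "p_under": p_under,
        "direction": direction, "degenerate": False,
    }


def exact_null_moments(
    annotation: GeneDiseaseAnnotation, disease: str, n: int
) -> tuple[float, float]:
    """Analytic mean and SD of the null proportion.

    Under uniform sampling of n genes without replacement, the annotated
    count is Hypergeometric(N, K, n); the proportion has mean K/N and
    SD sqrt(n (K/N)(1-K/N)(N-n)/(N-1)) / n.
    """
    n_univ = len(annotation.universe)
    if n > n_univ:
        raise ValueError("set size exceeds universe")
    k = len(annotation.gene_sets.get(disease, frozenset()))
    p = k / n_univ
    if n_univ == 1:
        return p, 0.0
    var_count = n * p * (1 - p) * (n_univ - n) / (n_univ - 1)
    return p, float(np.sqrt(var_count) / n)


@dataclass
class EnrichmentAnalysis:
    """Full result of one candidate-set analysis."""

    results: pd.DataFrame
    null_proportions: pd.DataFrame
    n_candidates: int
    n_dropped: int


def analyze_enrichment(
    candidates,
    annotation: GeneDiseaseAnnotation,
    config: EnrichmentConfig | None = None,
) -> EnrichmentAnalysis:
    """Score a candidate gene set against every disease.

    Candidates outside the universe are dropped (and counted); one shared
    random-set collection of the post-intersection size is scored against
    all diseases.
    """
    config = config or EnrichmentConfig()
    cand, dropped = _restrict_candidates(candidates, annotation)
    n = len(cand)
    null = resample_null(annotation, n, config)
    rows = []
    for d in annotation.diseases:
        count = len(cand & annotation.gene_sets[d])
        rows.append(
            zscore_test(
                count / n, null[d].to_numpy(), config,
                disease=d, n=n, observed_count=count,
            )
        )
    return EnrichmentAnalysis(
        results=pd.DataFrame(rows),
        null_proportions=null,
        n_candidates=n,
        n_dropped=dropped,
    )


def rank_and_report(
    results: pd.DataFrame, config: EnrichmentConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Ranked over-/under-representation report.

    Degenerate diseases are excluded; the observed proportion must exceed
    ``min_proportion`` (strict); within each direction only significant
    terms (p <= alpha) are kept, sorted by p ascending, then |z|
    descending, then disease name, truncated to ``top_k``.
    """
    config = config or EnrichmentConfig()
    usable = results[
        (~results["degenerate"]) & (results["p_obs"] > config.min_proportion)
    ].copy()
    usable["_absz"] = usable["z"].abs()
    report = {}
    for direction, pcol in (("over", "p_over"), ("under", "p_under")):
        sig = usable[usable[pcol] <= config.alpha]
        sig = sig.sort_values([pcol, "_absz", "disease"],
                              ascending=[True, False, True])
        report[direction] = (
            sig.drop(columns="_absz").head(config.top_k).reset_index(drop=True)
        )
    return report


def null_long_format(null: pd.DataFrame) -> pd.DataFrame:
    """Histogram-ready long export: disease, replicate_index, proportion."""
    long = null.reset_index().melt(
        id_vars="replicate", var_name="disease", value_name="proportion"
    )
    return long.rename(columns={"replicate": "replicate_index"})[
        ["disease", "replicate_index", "proportion"]
    ]
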