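"""Synthetic inputs for the screen pipeline, with known ground truth.

The generators emulate the study conditions of a genome-wide chemical
toxicity knockout screen in a human liver cell line: a minimal two-guides-
per-gene library (~40,000 sgRNAs), negative-binomial sequencing counts over
three control and three exposed replicates at ~400X coverage, planted
depletion (sensitive) and enrichment (resistant) gene effects, a sparse
bipartite gene-disease annotation table, and four-parameter-logistic
viability curves for the exposure-design stage.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from toxscreen.quantify import CountMatrix

__all__ = [
    "ScreenSimConfig",
    "AnnotationSimConfig",
    "DoseResponseSimConfig",
    "INHIBITOR_ASSAY_CONCENTRATIONS",
    "simulate_library",
    "simulate_screen_counts",
    "simulate_fastq",
    "simulate_gene_disease_table",
    "construct_candidate_set",
    "simulate_dose_response",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Concentration series (µM) of the inhibitor-style viability assay design.
INHIBITOR_ASSAY_CONCENTRATIONS = (0.0, 75.0, 150.0, 300.0)


@dataclass
class ScreenSimConfig:
    """Design of a simulated pooled knockout screen.

    Defaults reproduce the study design: a minimal genome-wide library of
    20,000 genes x 2 guides (~40,000 sgRNAs), 3 control + 3 exposed
    replicates, 400 reads per guide per sample on average, mild
    overdispersion, and 5% + 5% of genes planted with a |log2FC| = 1.5
    depletion/enrichment effect.
    """

    n_genes: int = 20_000
    guides_per_gene: int = 2
    n_control: int = 3
    n_exposed: int = 3
    mean_depth: float = 400.0
    dispersion: float = 0.05
    abundance_sigma: float = 0.5
    frac_sensitive: float = 0.05
    frac_resistant: float = 0.05
    effect_lfc: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.guides_per_gene < 1:
            raise ValueError("n_genes and guides_per_gene must be >= 1")
        if self.n_control < 1 or self.n_exposed < 1:
            raise ValueError("need at least one replicate per condition")
        if not np.isfinite(self.mean_depth) or self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive and finite")
        if not np.isfinite(self.dispersion) or self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.abundance_sigma < 0:
            raise ValueError("abundance_sigma must be >= 0")
        if self.frac_sensitive < 0 or self.frac_resistant < 0:
            raise ValueError("class fractions must be >= 0")
        if self.frac_sensitive + self.frac_resistant > 1:
            raise ValueError("frac_sensitive + frac_resistant must be <= 1")
        if self.effect_lfc < 0:
            raise ValueError("effect_lfc is an absolute log2 fold-change, >= 0")


@dataclass
class AnnotationSimConfig:
    """Design of a synthetic sparse gene-disease annotation table.

    ``genes_per_disease`` may be a single integer (constant K per disease)
    or an inclusive ``(low, high)`` range sampled per disease.
    ``enriched_diseases`` lists term names (default naming ``D000``,
    ``D001``, ...) that are later over-represented in a constructed
    candidate set by ``enrichment_factor``.
    """

    n_genes: int = 20_000
    n_diseases: int = 40
    genes_per_disease: int | tuple[int, int] = 200
    enriched_diseases: tuple[str, ...] = ()
    enrichment_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_diseases < 1:
            raise ValueError("n_diseases must be >= 1")
        lo, hi = self.k_range
        if lo < 1 or hi > self.n_genes or lo > hi:
            raise ValueError("genes_per_disease must satisfy 1 <= K <= n_genes")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")

    @property
    def k_range(self) -> tuple[int, int]:
        k = self.genes_per_disease
        if isinstance(k, (tuple, list)):
            return int(k[0]), int(k[1])
        return int(k), int(k)


@dataclass
class DoseResponseSimConfig:
    """Four-parameter-logistic viability assay design.

    The default scenario plants a 25%-inhibitory concentration of 192 µM
    with Hill slope 4 (so the IC50, 192 * 3^(1/4) ~ 253 µM, sits inside
    the 0-300 µM tested range and the response approaches its lower
    plateau by the top dose), nine linearly spaced concentrations,
    triplicate wells, and 5% additive noise. Linear spacing across the
    tested range keeps all four curve parameters identifiable.
    """

    top: float = 1.0
    bottom: float = 0.0
    ic50: float = 192.0 * 3.0 ** (1.0 / 4.0)
    hill: float = 4.0
    concentrations: tuple[float, ...] = (
        0.0, 37.5, 75.0, 112.5, 150.0, 187.5, 225.0, 262.5, 300.0
    )
    n_replicates: int = 3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.top > self.bottom:
            raise ValueError("top must exceed bottom")
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if min(self.concentrations) < 0:
            raise ValueError("concentrations must be >= 0")
        if 0.0 not in self.concentrations:
            raise ValueError("design must include a vehicle (0 µM) condition")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _random_spacers(n: int, rng: np.random.Generator, length: int = 20,
                    max_rounds: int = 50) -> np.ndarray:
    """Draw ``n`` unique random ACGT sequences of the given length."""
    if 4.0 ** length < n:
        raise ValueError(f"cannot draw {n} unique {length}-mers")
    seqs: list[bytes] = []
    seen: set[bytes] = set()
    need = n
    for _ in range(max_rounds):
        block = _BASES[rng.integers(0, 4, size=(need, length))]
        for s in block.view(f"S{length}").ravel():
            if s not in seen:
                seen.add(s)
                seqs.append(s)
        need = n - len(seqs)
        if need == 0:
            return np.array([s.decode() for s in seqs])
    raise RuntimeError("spacer collision retry bound exceeded")


def simulate_library(config: ScreenSimConfig) -> pd.DataFrame:
    """Generate a guide library table (columns sgrna, gene, sequence).

    Gene symbols are ``G00001`` ... and guide ids ``<gene>_sg<k>``; spacers
    are unique random 20-mers over ACGT.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes * config.guides_per_gene
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    gene_col = np.repeat(genes, config.guides_per_gene)
    sgrna_col = [
        f"{g}_sg{k + 1}"
        for g in genes
        for k in range(config.guides_per_gene)
    ]
    spacers = _random_spacers(n, rng)
    return pd.DataFrame({"sgrna": sgrna_col, "gene": gene_col, "sequence": spacers})


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean m, variance m + phi m^2) counts; phi=0 is the Poisson limit."""
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_screen_counts(
    library: pd.DataFrame, config: ScreenSimConfig
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the count matrix of a screen plus its ground-truth table.

    Baseline guide abundance is log-normal (mean-normalized to 1) so that
    ``mean_depth`` is interpretable as coverage; exposed means are scaled
    by ``2**true_lfc`` of the guide's gene; counts are NB per cell.
    Returns ``(CountMatrix, truth)`` where truth has columns
    gene / class / true_lfc.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = library["gene"].to_numpy()
    uniq_genes = pd.unique(genes)
    n_genes = len(uniq_genes)
    n_guides = len(library)

    n_sens = int(round(config.frac_sensitive * n_genes))
    n_res = int(round(config.frac_resistant * n_genes))
    perm = rng.permutation(n_genes)
    cls = np.full(n_genes, "neutral", dtype=object)
    cls[perm[:n_sens]] = "sensitive"
    cls[perm[n_sens:n_sens + n_res]] = "resistant"
    lfc = np.where(
        cls == "sensitive", -config.effect_lfc,
        np.where(cls == "resistant", config.effect_lfc, 0.0),
    )
    truth = pd.DataFrame({"gene": uniq_genes, "class": cls, "true_lfc": lfc})

    gene_lfc = truth.set_index("gene")["true_lfc"]
    guide_lfc = gene_lfc.loc[genes].to_numpy()

    if config.abundance_sigma > 0:
        a = rng.lognormal(0.0, config.abundance_sigma, size=n_guides)
        a /= a.mean()
    else:
        a = np.ones(n_guides)
    mu_control = config.mean_depth * a
    mu_exposed = mu_control * 2.0 ** guide_lfc

    samples = [f"control_{j + 1}" for j in range(config.n_control)] + [
        f"exposed_{j + 1}" for j in range(config.n_exposed)
    ]
    conditions = {s: ("control" if s.startswith("control") else "exposed") for s in samples}
    cols = {}
    for s in samples:
        mu = mu_control if conditions[s] == "control" else mu_exposed
        cols[s] = _nb_draw(rng, mu, config.dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(library["sgrna"], name="sgrna"))
    genes_s = pd.Series(genes, index=counts.index, name="gene")
    cm = CountMatrix(counts=counts, genes=genes_s, conditions=conditions)
    return cm, truth


def simulate_fastq(
    counts: CountMatrix,
    library: pd.DataFrame,
    out_dir: str | Path,
    read_length: int = 150,
    spacer_offset: int = 30,
    seed: int = 0,
    gzip_output: bool = False,
) -> dict[str, Path]:
    """Emit one FASTQ per sample with each spacer embedded count-many times.

    Each read is random ACGT context with the guide's 20-nt spacer placed at
    ``spacer_offset``; quality is a constant ``I`` string (never used
    downstream). Round-tripping through exact-match spacer extraction
    recovers the input counts.
    """
    if read_length < 20:
        raise ValueError("read_length must be >= 20")
    if spacer_offset < 0 or spacer_offset + 20 > read_length:
        raise ValueError("spacer must fit in the read: spacer_offset + 20 <= read_length")
    lib = library.set_index("sgrna").loc[counts.counts.index]
    spacer_idx = np.array(
        [[b"ACGT".index(c.encode()) for c in seq] for seq in lib["sequence"]],
        dtype=np.int64,
    )
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qual = "I" * read_length
    paths: dict[str, Path] = {}
    for sample in counts.samples:
        c = counts.counts[sample].to_numpy()
        total = int(c.sum())
        mat = rng.integers(0, 4, size=(total, read_length))
        mat[:, spacer_offset:spacer_offset + 20] = np.repeat(spacer_idx, c, axis=0)
        reads = _BASES[mat].view(f"S{read_length}").ravel()
        suffix = ".fastq.gz" if gzip_output else ".fastq"
        path = out_dir / f"{sample}{suffix}"
        opener = gzip.open if gzip_output else open
        with opener(path, "wt") as fh:
            for i, seq in enumerate(reads):
                fh.write(f"@{sample}.{i + 1}\n{seq.decode()}\n+\n{qual}\n")
        paths[sample] = path
    return paths


def _default_disease_names(n: int) -> list[str]:
    return [f"D{i:03d}" for i in range(n)]


def simulate_gene_disease_table(
    config: AnnotationSimConfig,
    genes: list[str] | None = None,
    favored_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Simulate a sparse bipartite gene-disease table (columns gene, disease).

    For each disease, K distinct genes are drawn uniformly from the
    universe. Diseases listed in ``config.enriched_diseases`` instead draw
    with sampling weight ``enrichment_factor`` on ``favored_genes`` (when
    supplied), which plants a genuine association between those diseases
    and the favored gene subset. Output is sorted and duplicate-free.
    """
    rng = np.random.default_rng(config.seed)
    if genes is None:
        universe = np.array([f"G{i + 1:05d}" for i in range(config.n_genes)])
    else:
        universe = np.asarray(list(genes))
    n_univ = len(universe)
    lo, hi = config.k_range
    if hi > n_univ:
        raise ValueError("genes_per_disease exceeds universe size")
    diseases = _default_disease_names(config.n_diseases)
    favored_mask = None
    if favored_genes is not None:
        favored_mask = np.isin(universe, list(favored_genes))
    rows = []
    for d in diseases:
        k = int(rng.integers(lo, hi + 1)) if lo != hi else lo
        if (
            d in config.enriched_diseases
            and favored_mask is not None
            and config.enrichment_factor > 1
        ):
            w = np.where(favored_mask, config.enrichment_factor, 1.0)
            w = w / w.sum()
            chosen = rng.choice(n_univ, size=k, replace=False, p=w)
        else:
            chosen = rng.choice(n_univ, size=k, replace=False)
        rows.append(pd.DataFrame({"gene": universe[chosen], "disease": d}))
    table = pd.concat(rows, ignore_index=True)
    return table.sort_values(["gene", "disease"], ignore_index=True)


def construct_candidate_set(
    annotation: pd.DataFrame,
    n: int,
    enriched_diseases: tuple[str, ...] = (),
    enrichment_factor: float = 1.0,
    universe: list[str] | None = None,
    seed: int = 0,
) -> list[str]:
    """Construct a candidate gene set of size ``n`` with planted enrichment.

    For each enriched disease d with K annotated genes out of a universe of
    N, round(f * K/N * n) of its genes enter the set, making the in-set
    annotation rate f times the baseline K/N; the remainder is drawn
    uniformly from genes not annotated to any enriched disease. With
    ``enrichment_factor=1`` (or no enriched diseases) the set is a plain
    uniform draw from the universe.
    """
    rng = np.random.default_rng(seed)
    if universe is None:
        universe = sorted(annotation["gene"].unique())
    universe_arr = np.asarray(list(universe))
    n_univ = len(universe_arr)
    if n > n_univ:
        raise ValueError("candidate set larger than universe")
    if not enriched_diseases or enrichment_factor <= 1:
        idx = rng.choice(n_univ, size=n, replace=False)
        return sorted(universe_arr[idx])

    by_disease = annotation.groupby("disease")["gene"].apply(set)
    chosen: set[str] = set()
    blocked: set[str] = set()
    for d in enriched_diseases:
        members = by_disease.get(d, set()) & set(universe_arr)
        blocked |= members
        quota = int(round(enrichment_factor * len(members) / n_univ * n))
        pool = sorted(members - chosen)
        if quota > len(pool):
            raise ValueError(f"quota for disease {d} exceeds its annotation")
        picked = rng.choice(len(pool), size=quota, replace=False)
        chosen |= {pool[i] for i in picked}
    filler_pool = sorted(set(universe_arr) - blocked - chosen)
    need = n - len(chosen)
    if need < 0:
        raise ValueError("planted quotas exceed candidate set size")
    picked = rng.choice(len(filler_pool), size=need, replace=False)
    chosen |= {filler_pool[i] for i in picked}
    return sorted(chosen)


def simulate_dose_response(config: DoseResponseSimConfig) -> pd.DataFrame:
    """Simulate a long-format viability table (concentration_uM, replicate,
    viability) from a 4PL curve with additive Gaussian noise, clipped at 0."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for c in config.concentrations:
        if c > 0:
            v = config.bottom + (config.top - config.bottom) / (
                1.0 + (c / config.ic50) ** config.hill
            )
        else:
            v = config.top
        for r in range(config.n_replicates):
            obs = v + (rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
            rows.append((c, r + 1, max(obs, 0.0)))
    return pd.DataFrame(rows, columns=["concentration_uM", "replicate", "viability"])
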