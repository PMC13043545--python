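"""End-to-end orchestration: count -> test -> call -> enrich from one
YAML config, with recorded sub-seeds and byte-reproducible TSV outputs.

Sensitive and resistant candidate sets are analyzed for disease
over-representation separately, never pooled. All floats in tabular
outputs are serialized with 6 significant digits.
"""

from __future__ import annotations

import hashlib
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from toxscreen import enrichment as enr
from toxscreen import quantify, screen, simulate

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "make_demo", "load_manifest"]

_FLOAT_FMT = "%.6g"


def load_manifest(path: str | Path) -> list[dict]:
    """Load a sample manifest YAML: a ``samples`` list of records with
    ``name``, ``condition`` (control/exposed) and optionally ``fastq``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    samples = doc.get("samples") if isinstance(doc, dict) else None
    if not samples:
        raise ValueError(f"manifest {path}: needs a non-empty 'samples' list")
    names = [s.get("name") for s in samples]
    if len(set(names)) != len(names):
        raise ValueError(f"manifest {path}: duplicate sample names")
    for s in samples:
        if s.get("condition") not in ("control", "exposed"):
            raise ValueError(
                f"manifest {path}: sample {s.get('name')!r} needs condition "
                "'control' or 'exposed'"
            )
    return samples


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _load_counts_stage(cfg: dict, base: Path) -> quantify.CountMatrix:
    manifest = None
    if cfg.get("manifest"):
        manifest = load_manifest(base / cfg["manifest"])
    if cfg.get("counts"):
        conditions = (
            {s["name"]: s["condition"] for s in manifest} if manifest else None
        )
        return quantify.read_counts(base / cfg["counts"], conditions)
    if manifest is None:
        raise ValueError("config needs either 'counts' or a 'manifest' with fastq paths")
    if not cfg.get("library"):
        raise ValueError("quantifying from FASTQ requires a 'library' path")
    library = quantify.read_library(base / cfg["library"])
    fastqs = {}
    for s in manifest:
        if not s.get("fastq"):
            raise ValueError(f"sample {s['name']!r} has no fastq path and no counts given")
        fastqs[s["name"]] = base / s["fastq"]
    conditions = {s["name"]: s["condition"] for s in manifest}
    return quantify.extract_spacers(
        library, fastqs, conditions, revcomp=bool(cfg.get("revcomp", False))
    )


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> Path:
    """Run the computational screen pipeline from a config mapping or a
    YAML path; returns the output directory.

    Stages: load/quantify counts -> normalize -> dispersion -> guide test
    -> gene ranking -> candidate calling -> per-direction disease
    enrichment. A stage failure aborts with the stage name; partial
    outputs are retained under ``<output_dir>/failed/``.
    """
    if not isinstance(config, dict):
        cfg_path = Path(config)
        with open(cfg_path) as fh:
            cfg = yaml.safe_load(fh)
        base = cfg_path.parent
    else:
        cfg = dict(config)
        base = Path(cfg.get("base_dir", "."))
    out = Path(output_dir) if output_dir else Path(cfg.get("output_dir", "toxscreen_run"))
    if not out.is_absolute() and output_dir is None:
        out = base / out  # config-relative paths stay portable
    out.mkdir(parents=True, exist_ok=True)

    seed = int(cfg.get("seed", 0))
    rra_cfg = screen.RraConfig(seed=seed + 101, **cfg.get("rra", {}))
    calling = {"p_threshold": 0.01, "lfc_threshold": 0.6} | cfg.get("calling", {})

    stage = "count"
    try:
        cm = _load_counts_stage(cfg, base)
        per_sample, per_condition = quantify.coverage_summary(cm)
        _write(per_sample, out / "coverage_per_sample.tsv")
        _write(per_condition, out / "coverage_per_condition.tsv")
        quantify.write_counts(cm, out / "counts.tsv")

        stage = "test"
        norm = screen.normalize_median_ratio(cm)
        disp = screen.estimate_dispersion(norm)
        sg = screen.sgrna_test(norm, disp, pseudocount=rra_cfg.pseudocount)
        _write(sg, out / "sgrna_summary.tsv")
        genes = screen.gene_scores(sg, rra_cfg, **calling)
        _write(genes, out / "gene_summary.tsv")

        stage = "call"
        sens, res = screen.call_hits(genes, **calling)
        _write(sens, out / "hits_sensitive.tsv")
        _write(res, out / "hits_resistant.tsv")
        _write(screen.volcano_table(genes, **calling), out / "volcano.tsv")

        enrich_seeds = {}
        if cfg.get("annotation"):
            stage = "enrich"
            ann = enr.load_annotation(base / cfg["annotation"])
            for tag, hits, sub_seed in (
                ("sensitive", sens, seed + 201),
                ("resistant", res, seed + 202),
            ):
                enrich_seeds[tag] = sub_seed
                ecfg = enr.EnrichmentConfig(seed=sub_seed, **cfg.get("enrichment", {}))
                if len(hits) == 0:
                    logger.warning("no %s hits; skipping enrichment", tag)
                    continue
                analysis = enr.analyze_enrichment(hits["gene"], ann, ecfg)
                report = enr.rank_and_report(analysis.results, ecfg)
                _write(analysis.results, out / f"enrichment_{tag}_all.tsv")
                _write(report["over"], out / f"enrichment_{tag}_over.tsv")
                _write(report["under"], out / f"enrichment_{tag}_under.tsv")
                _write(
                    enr.null_long_format(analysis.null_proportions),
                    out / f"null_distributions_{tag}.tsv",
                )
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for f in out.glob("*.tsv"):
            shutil.move(str(f), failed / f.name)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    inputs = {}
    for key in ("library", "counts", "manifest", "annotation"):
        if cfg.get(key):
            p = base / cfg[key]
            if p.exists():
                inputs[key] = {"path": str(p), "sha256": _sha256(p)}
    from toxscreen import __version__

    manifest_doc = {
        "toxscreen_version": __version__,
        "seed": seed,
        "sub_seeds": {"rra": rra_cfg.seed, "enrichment": enrich_seeds},
        "parameters": {
            "rra": {
                "alpha_cutoff": rra_cfg.alpha_cutoff,
                "n_permutations": rra_cfg.n_permutations,
                "pseudocount": rra_cfg.pseudocount,
            },
            "calling": calling,
            "enrichment": cfg.get("enrichment", {}),
        },
        "inputs": inputs,
        "n_hits": {"sensitive": int(len(sens)), "resistant": int(len(res))},
    }
    with open(out / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest_doc, fh, sort_keys=False)
    return out


def make_demo(seed: int = 0, out_dir: str | Path = "demo",
              n_genes: int = 2000) -> Path:
    """Generate a small synthetic study plus a ready-to-run config.

    2,000 genes x 2 guides, 3 control + 3 exposed replicates at 400X with
    planted 5% sensitive / 5% resistant effects (|log2FC| = 1.5), and a
    synthetic disease annotation over the screened genes in which five
    planted diseases preferentially annotate the truly sensitive genes.
    Returns the path of the written config YAML.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scfg = simulate.ScreenSimConfig(n_genes=n_genes, seed=seed)
    library = simulate.simulate_library(scfg)
    cm, truth = simulate.simulate_screen_counts(library, scfg)
    quantify.write_library(library, out / "library.tsv")
    quantify.write_counts(cm, out / "counts.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    sensitive_truth = set(truth.loc[truth["class"] == "sensitive", "gene"])
    planted = tuple(f"D{i:03d}" for i in range(5))
    acfg = simulate.AnnotationSimConfig(
        n_genes=n_genes, n_diseases=30, genes_per_disease=50,
        enriched_diseases=planted, enrichment_factor=5.0, seed=seed + 7,
    )
    ann = simulate.simulate_gene_disease_table(
        acfg, genes=list(truth["gene"]), favored_genes=sensitive_truth
    )
    ann.to_csv(out / "annotation.tsv", sep="\t", index=False)

    samples = [
        {"name": s, "condition": cm.conditions[s]} for s in cm.samples
    ]
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"samples": samples}, fh, sort_keys=False)

    config = {
        "seed": seed,
        "output_dir": "results",
        "library": "library.tsv",
        "counts": "counts.tsv",
        "manifest": "manifest.yaml",
        "annotation": "annotation.tsv",
        "rra": {"alpha_cutoff": 0.25, "n_permutations": 100_000, "pseudocount": 1.0},
        "calling": {"p_threshold": 0.01, "lfc_threshold": 0.6},
        "enrichment": {"n_random": 1000, "min_proportion": 0.001,
                       "alpha": 0.05, "top_k": 15},
    }
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return cfg_path
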