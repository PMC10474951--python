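"""End-to-end orchestration: contexts -> DE -> permutation impact -> prognosis.

Per cohort, the pipeline (i) aggregates mutations and builds frequency-
filtered contexts, (ii) simulates (or loads cached) permutation nulls for
every frequency category in use, (iii) scores every context's DE count
against its category null, and (iv) runs the composite-expression
prognosis — for impact-significant contexts only, mirroring the gating of
the statistical framework (an override runs it everywhere).  No multiple-
testing correction is applied across contexts: each context's NB-modified
P is thresholded at alpha directly, and downstream interpretation must
account for that.

Null distributions are cached on disk keyed by a content hash of the count
matrix, engine parameters, category, B and seed, so reruns and genes
sharing a category reuse byte-identical nulls.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de_engine import DEEngine
from .enrichment import AnnotationCollection, hypergeom_enrich
from .io_cohort import (
    Cohort,
    aggregate_mutations,
    build_contexts,
    load_cohort,
    read_mutations,
    DEFAULT_NONSILENT,
)
from .perm_null import NullCountDistribution, assess_impact, simulate_null
from .prognosis import run_prognosis

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    mutations: str
    counts: str
    clinical: str | None = None
    annotation: str | None = None
    cancer_type: str = "COHORT"
    fdr_threshold: float = 0.05
    min_freq: float = 0.05
    B_impact: int = 1000
    B_cges: int = 1000
    alpha: float = 0.05
    seed: int = 0
    rounding: str = "nearest"
    min_total_count: int = 10
    dispersion_shrink: float = 0.5
    prognosis_all: bool = False
    outdir: str = "mirimpact_run"
    nonsilent_classes: list[str] | None = None

    def __post_init__(self) -> None:
        for thr in (self.fdr_threshold, self.min_freq, self.alpha):
            if not 0.0 < thr < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")
        if min(self.B_impact, self.B_cges) < 100:
            raise ValueError("permutation counts B must be at least 100")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _counts_hash(engine: DEEngine, category: float, B: int, seed: int, n_mut: int) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(engine.y).tobytes())
    h.update(repr((engine.params, float(category), int(B), int(seed), int(n_mut))).encode())
    return h.hexdigest()[:12]


def get_null(
    engine: DEEngine,
    cohort: Cohort,
    category: float,
    B: int,
    seed: int,
    cache_dir: Path | None = None,
) -> NullCountDistribution:
    """Simulate a category null, or load it from cache when the content
    hash (counts + engine params + category + B + seed) matches."""
    n = cohort.n_patients
    n_mut = int(round(category * n))
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        key = _counts_hash(engine, category, B, seed, n_mut)
        counts_path = cache_dir / f"null_cat{category:.2f}_{key}.tsv"
        meta_path = cache_dir / f"null_cat{category:.2f}_{key}.json"
        if counts_path.exists() and meta_path.exists():
            logger.info("loading cached null for category %.2f (%s)", category, key)
            return NullCountDistribution.load(counts_path, meta_path)
    null = simulate_null(
        cohort, category, engine, B=B, seed=seed, cancer_type=cohort.cancer_type
    )
    if cache_dir is not None:
        null.save(counts_path, meta_path)
    return null


def _category_seed(master_seed: int, category: float) -> int:
    """One independent, reproducible stream per (cohort, category)."""
    idx = int(round(category / 0.05))
    return int(
        np.random.SeedSequence(master_seed, spawn_key=(idx,)).generate_state(1)[0]
        % 2**31
    )


@dataclass
class RunResult:
    outdir: Path
    impact: pd.DataFrame
    prognosis: pd.DataFrame
    manifest: dict
    nulls: dict[float, NullCountDistribution] = field(default_factory=dict)


def run_all(cfg: RunConfig) -> RunResult:
    """Execute the full workflow and write all result tables to cfg.outdir."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "de").mkdir(exist_ok=True)

    cohort = load_cohort(cfg.counts, cfg.clinical, cancer_type=cfg.cancer_type)
    records = read_mutations(cfg.mutations)
    nonsilent = set(cfg.nonsilent_classes) if cfg.nonsilent_classes else DEFAULT_NONSILENT
    mutmatrix = aggregate_mutations(records, cohort.patients, nonsilent)
    mutmatrix.to_csv(outdir / "gene_mutation_matrix.tsv", sep="\t", index_label="gene")
    contexts = build_contexts(mutmatrix, cohort, min_freq=cfg.min_freq, rounding=cfg.rounding)
    logger.info("%d mutation contexts pass the %.0f%% filter", len(contexts), cfg.min_freq * 100)

    engine = DEEngine(
        cohort.counts,
        fdr_threshold=cfg.fdr_threshold,
        min_total_count=cfg.min_total_count,
        dispersion_shrink=cfg.dispersion_shrink,
    )

    categories = sorted({ctx.category for ctx in contexts})
    nulls: dict[float, NullCountDistribution] = {}
    for category in categories:
        nulls[category] = get_null(
            engine,
            cohort,
            category,
            B=cfg.B_impact,
            seed=_category_seed(cfg.seed, category),
            cache_dir=outdir / "nulls",
        )

    impact_rows = []
    impacts = {}
    for ctx in contexts:
        try:
            res = assess_impact(ctx, nulls, engine, alpha=cfg.alpha)
        except Exception as exc:  # soft per-context failure
            logger.warning("impact assessment failed for %s: %s", ctx.gene, exc)
            continue
        impacts[ctx.gene] = res
        impact_rows.append(
            {
                "cohort": ctx.cancer_type,
                "gene": ctx.gene,
                "f": ctx.f,
                "category": ctx.category,
                "N_obs": res.N_obs,
                "p_emp": res.p_emp,
                "z": res.z,
                "p_nb": res.p_nb,
                "significant": int(res.significant),
            }
        )
    impact_df = pd.DataFrame(
        impact_rows,
        columns=["cohort", "gene", "f", "category", "N_obs", "p_emp", "z", "p_nb", "significant"],
    )
    impact_df.to_csv(outdir / "impact.tsv", sep="\t", index=False)

    ann = AnnotationCollection.from_tsv(cfg.annotation, universe=set(
        np.array(engine.features)[engine.tested]
    )) if cfg.annotation else None
    if ann is not None:
        (outdir / "enrichment").mkdir(exist_ok=True)

    prognosis_rows = []
    logcpm = engine.log_cpm()
    feature_arr = np.array(engine.features)
    (outdir / "prognosis_features").mkdir(exist_ok=True)
    for ctx in contexts:
        res = impacts.get(ctx.gene)
        if res is None:
            continue
        if not (res.significant or cfg.prognosis_all):
            continue
        de_res = engine.result(ctx.labels, meta={
            "cohort": ctx.cancer_type, "gene": ctx.gene,
            "f": round(ctx.f, 4), "category": ctx.category,
        })
        de_res.to_tsv(outdir / "de" / f"{ctx.gene}.tsv")
        responsive = de_res.tested & (np.nan_to_num(de_res.q, nan=1.0) < cfg.fdr_threshold)
        if responsive.sum() == 0:
            continue
        if ann is not None:
            try:
                enr = hypergeom_enrich(set(feature_arr[responsive]), ann)
                enr.to_csv(outdir / "enrichment" / f"{ctx.gene}.tsv", sep="\t", index=False)
            except Exception as exc:
                logger.warning("enrichment failed for %s: %s", ctx.gene, exc)
        if cohort.clinical is None:
            continue
        clinical = cohort.clinical.reindex(cohort.patients)
        for endpoint in ("OS", "DSS"):
            try:
                prog = run_prognosis(
                    logcpm[responsive],
                    clinical,
                    endpoint,
                    features=list(feature_arr[responsive]),
                    B=cfg.B_cges,
                    seed=_category_seed(cfg.seed, ctx.category)
                    + zlib.crc32(ctx.gene.encode()) % 10007,
                    cancer_type=ctx.cancer_type,
                    gene=ctx.gene,
                )
            except Exception as exc:
                logger.warning("prognosis failed for %s/%s: %s", ctx.gene, endpoint, exc)
                continue
            prognosis_rows.append(
                {
                    "cohort": ctx.cancer_type,
                    "gene": ctx.gene,
                    "endpoint": endpoint,
                    "n_features": prog.n_features,
                    "s_obs": prog.s_obs,
                    "p_perm": prog.p_perm,
                    "p_beta": prog.p_beta,
                    "alpha": prog.beta_fit.alpha,
                    "beta": prog.beta_fit.beta,
                }
            )
            prog.per_feature.to_csv(
                outdir / "prognosis_features" / f"{ctx.gene}_{endpoint}.tsv",
                sep="\t",
                index=False,
            )
    prognosis_df = pd.DataFrame(
        prognosis_rows,
        columns=["cohort", "gene", "endpoint", "n_features", "s_obs", "p_perm",
                 "p_beta", "alpha", "beta"],
    )
    prognosis_df.to_csv(outdir / "prognosis.tsv", sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(cfg),
        "cancer_type": cfg.cancer_type,
        "n_patients": cohort.n_patients,
        "n_features": len(cohort.features),
        "n_genes_mutated": int(mutmatrix.shape[0]),
        "n_contexts": len(contexts),
        "categories": categories,
        "n_impacting": int(impact_df["significant"].sum()) if len(impact_df) else 0,
        "n_prognostic_os": int(
            ((prognosis_df["endpoint"] == "OS") & (prognosis_df["p_beta"] < cfg.alpha)).sum()
        ) if len(prognosis_df) else 0,
        "n_prognostic_dss": int(
            ((prognosis_df["endpoint"] == "DSS") & (prognosis_df["p_beta"] < cfg.alpha)).sum()
        ) if len(prognosis_df) else 0,
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return RunResult(
        outdir=outdir, impact=impact_df, prognosis=prognosis_df,
        manifest=manifest, nulls=nulls,
    )


def summarize(run_dirs) -> dict[str, pd.DataFrame]:
    """Cross-run summary tables, all re-derivable from stage outputs.

    ``run_dirs`` is a directory containing one or more completed runs (or a
    list of run directories).  Produces per-cohort gene counts
    (mutated >= impacting >= prognostic), cross-cohort responsive-set
    intersection sizes per gene, and a per-patient gene-mutation presence
    matrix (the OncoPrint data table).
    """
    if isinstance(run_dirs, (str, Path)):
        root = Path(run_dirs)
        if (root / "manifest.json").exists():
            dirs = [root]
        else:
            dirs = sorted(p.parent for p in root.glob("*/manifest.json"))
    else:
        dirs = [Path(d) for d in run_dirs]

    count_rows: list = []
    onco_frames: list = []
    responsive: list = []
    for d in dirs:
        try:
            with open(d / "manifest.json") as fh:
                manifest = json.load(fh)
        except FileNotFoundError:
            logger.warning("%s: no manifest; partial run skipped", d)
            continue
        cohort = manifest.get("cancer_type", d.name)
        count_rows.append(
            {
                "cohort": cohort,
                "mutated_genes": manifest.get("n_genes_mutated", 0),
                "contexts": manifest.get("n_contexts", 0),
                "impacting_genes": manifest.get("n_impacting", 0),
                "prognostic_genes_os": manifest.get("n_prognostic_os", 0),
                "prognostic_genes_dss": manifest.get("n_prognostic_dss", 0),
            }
        )
        mm_path = d / "gene_mutation_matrix.tsv"
        if mm_path.exists():
            mm = pd.read_csv(mm_path, sep="\t", index_col=0)
            mm.index = pd.MultiIndex.from_product([[cohort], mm.index], names=["cohort", "gene"])
            onco_frames.append(mm)
        for de_path in sorted((d / "de").glob("*.tsv")) if (d / "de").exists() else []:
            de = pd.read_csv(de_path, sep="\t", comment="#")
            feats = set(de.loc[(de["tested"] == 1) & (de["q"] < 0.05), "feature"])
            responsive.append({"cohort": cohort, "gene": de_path.stem, "features": feats})

    counts_df = pd.DataFrame(
        count_rows,
        columns=["cohort", "mutated_genes", "contexts", "impacting_genes",
                 "prognostic_genes_os", "prognostic_genes_dss"],
    )
    inter_rows = []
    by_gene: dict[str, list] = {}
    for entry in responsive:
        by_gene.setdefault(entry["gene"], []).append(entry)
    for gene, entries in sorted(by_gene.items()):
        if len(entries) < 2:
            continue
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                a, b = entries[i], entries[j]
                inter_rows.append(
                    {
                        "gene": gene,
                        "cohort_a": a["cohort"],
                        "cohort_b": b["cohort"],
                        "n_a": len(a["features"]),
                        "n_b": len(b["features"]),
                        "n_shared": len(a["features"] & b["features"]),
                    }
                )
    inter_df = pd.DataFrame(
        inter_rows, columns=["gene", "cohort_a", "cohort_b", "n_a", "n_b", "n_shared"]
    )
    onco_df = (
        pd.concat(onco_frames) if onco_frames
        else pd.DataFrame(index=pd.MultiIndex.from_arrays([[], []], names=["cohort", "gene"]))
    )
    return {"gene_counts": counts_df, "intersections": inter_df, "oncoprint": onco_df}
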