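"""Synthetic cohorts with the statistical structure the framework assumes.

The generator emulates a bulk miRNA-sequencing cohort: negative-binomial
counts with feature-specific baseline means (log-uniform over 1-1000
counts, spanning the realistic dynamic range) and dispersions (log-uniform
over 0.02-0.8, i.e. biological CV roughly 0.14-0.9, the heterogeneity
typical of miRNA-seq), log-normal library sizes, Bernoulli gene mutation
status at configurable per-gene frequencies, multiplicative 2^log2FC
mutation effects on designated responsive feature subsets, and exponential
survival whose hazard is log-linear in the composite expression of a
designated prognostic feature subset (so the Cox proportional-hazards
assumption holds exactly and parameter recovery is well-defined).

Every draw flows from one seed, and the truth ledger records exactly which
(gene, feature, log2FC) triples are responsive and which features carry
prognostic signal, enabling exact recall/precision accounting downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .de_engine import tmm_normalize, log_cpm
from .io_cohort import Cohort, CLINICAL_COLUMNS


@dataclass
class GeneEffect:
    """Mutation-driven expression effect of one gene on a feature subset."""

    gene: str
    n_responsive: int
    log2fc_magnitude: float = 1.5
    random_sign: bool = True


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort.

    Defaults describe a mid-sized cancer cohort: 200 patients, 300 miRNA
    features, 12 candidate genes with mutation frequencies spread over
    (0.08, 0.45), three of which truly dysregulate 60 features at
    |log2FC| = 1.5; survival is exponential with baseline hazard 1/1000
    per day (median ~2 years), log-HR 0.5 per composite-score unit, ~30%
    uniform censoring, and 15% of patients missing DSS follow-up.
    """

    seed: int = 0
    n_patients: int = 200
    n_features: int = 300
    n_genes: int = 12
    mutation_freqs: list[float] | None = None
    library_meanlog: float = 13.5  # exp(13.5) ~ 7.3e5 reads
    library_sdlog: float = 0.35
    base_mean_range: tuple[float, float] = (1.0, 1000.0)
    dispersion_range: tuple[float, float] = (0.02, 0.8)
    effects: list[GeneEffect] | None = None
    n_impacted_default: int = 3
    baseline_hazard: float = 1e-3  # per day
    survival_log_hr: float = 0.5
    background_hazard_frac: float = 0.3  # other-cause deaths, OS only
    censoring_rate: float = 0.3
    dss_missing_rate: float = 0.15
    prognostic_features: list[int] | None = None  # default: first effect's subset
    subpop_feature_frac: float = 0.0  # fraction of features expressed only in a patient subpopulation
    subpop_expressed_range: tuple[float, float] = (0.1, 0.5)
    cancer_type: str = "SYNTH"

    def __post_init__(self) -> None:
        for rate in (self.censoring_rate, self.dss_missing_rate,
                     self.background_hazard_frac):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.mutation_freqs is None:
            self.mutation_freqs = [
                float(f) for f in np.round(np.linspace(0.08, 0.45, self.n_genes), 3)
            ]
        if len(self.mutation_freqs) != self.n_genes:
            raise ValueError("one mutation frequency per gene required")
        if any(not 0.05 < f < 0.95 for f in self.mutation_freqs):
            raise ValueError("mutation frequencies must respect the context filter (0.05, 0.95)")
        if self.effects is None:
            k = min(60, max(1, self.n_features // 5))
            self.effects = [
                GeneEffect(gene=f"GENE{i + 1:02d}", n_responsive=k)
                for i in range(min(self.n_impacted_default, self.n_genes))
            ]
        for eff in self.effects:
            if eff.n_responsive > self.n_features:
                raise ValueError(f"{eff.gene}: responsive subset exceeds feature count")

    @property
    def genes(self) -> list[str]:
        return [f"GENE{i + 1:02d}" for i in range(self.n_genes)]

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "effects" in raw and raw["effects"] is not None:
            raw["effects"] = [GeneEffect(**e) for e in raw["effects"]]
        if "base_mean_range" in raw:
            raw["base_mean_range"] = tuple(raw["base_mean_range"])
        if "dispersion_range" in raw:
            raw["dispersion_range"] = tuple(raw["dispersion_range"])
        if "subpop_expressed_range" in raw:
            raw["subpop_expressed_range"] = tuple(raw["subpop_expressed_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["base_mean_range"] = list(self.base_mean_range)
        raw["dispersion_range"] = list(self.dispersion_range)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw of NB(mean, dispersion phi), broadcasting."""
    shape = 1.0 / phi
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_cohort(cfg: SimulationConfig):
    """Generate one synthetic cohort.

    Returns ``(cohort, mutmatrix, truth)`` where ``truth`` maps each
    impacted gene to its responsive features and log2FCs and records the
    prognostic feature subset and survival effect size.
    """
    rng = np.random.default_rng(cfg.seed)
    patients = [f"PT{j + 1:04d}" for j in range(cfg.n_patients)]
    features = [f"mir-{i + 1:04d}" for i in range(cfg.n_features)]

    # gene-level mutation status ~ Bernoulli(f_g)
    freqs = np.asarray(cfg.mutation_freqs)
    mut = rng.random((cfg.n_genes, cfg.n_patients)) < freqs[:, None]
    mutmatrix = pd.DataFrame(mut.astype(np.int8), index=cfg.genes, columns=patients)

    lo, hi = cfg.base_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_features))
    dlo, dhi = cfg.dispersion_range
    dispersion = np.exp(rng.uniform(np.log(dlo), np.log(dhi), cfg.n_features))
    lib = rng.lognormal(cfg.library_meanlog, cfg.library_sdlog, cfg.n_patients)

    mu = np.outer(base_mean, lib / lib.mean())
    if cfg.subpop_feature_frac > 0:
        # context-specific features: expressed only in a random patient
        # subpopulation (tissue-context miRNAs), near-zero elsewhere
        bim = np.nonzero(rng.random(cfg.n_features) < cfg.subpop_feature_frac)[0]
        lo_r, hi_r = cfg.subpop_expressed_range
        for i in bim:
            rho = rng.uniform(lo_r, hi_r)
            on = rng.random(cfg.n_patients) < rho
            mu[i] = np.where(on, mu[i] / rho, 0.01)
        truth_subpop = bim.tolist()
    else:
        truth_subpop = []
    truth: dict = {"responsive": {}, "beta": cfg.survival_log_hr,
                   "subpop_features": truth_subpop,
                   "base_mean": base_mean, "dispersion": dispersion,
                   "library_size": lib}
    gene_index = {g: i for i, g in enumerate(cfg.genes)}
    for eff in cfg.effects:
        if eff.gene not in gene_index:
            raise ValueError(f"effect gene {eff.gene} is not simulated")
        subset = rng.choice(cfg.n_features, size=eff.n_responsive, replace=False)
        lfc = np.full(eff.n_responsive, eff.log2fc_magnitude)
        if eff.random_sign:
            lfc *= rng.choice([-1.0, 1.0], size=eff.n_responsive)
        carriers = mut[gene_index[eff.gene]]
        mu[np.ix_(subset, carriers)] *= (2.0 ** lfc)[:, None]
        truth["responsive"][eff.gene] = {
            "features": [features[i] for i in subset],
            "feature_idx": subset.tolist(),
            "log2fc": lfc.tolist(),
        }

    counts = _nb_draw(rng, mu, dispersion[:, None])
    counts_df = pd.DataFrame(counts, index=features, columns=patients)

    # composite expression of the prognostic subset drives the hazard
    if cfg.prognostic_features is not None:
        prog_idx = np.asarray(cfg.prognostic_features, dtype=int)
    elif cfg.effects:
        prog_idx = np.asarray(truth["responsive"][cfg.effects[0].gene]["feature_idx"])
    else:
        prog_idx = np.arange(min(20, cfg.n_features))
    truth["prognostic_features"] = [features[i] for i in prog_idx]
    norm = tmm_normalize(counts)
    lc = log_cpm(counts, norm)[prog_idx]
    sd = lc.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (lc - lc.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1), 0.0)
    score = z.mean(axis=0)
    truth["score"] = score

    hazard = cfg.baseline_hazard * np.exp(cfg.survival_log_hr * score)
    t_disease = rng.exponential(1.0 / hazard)
    if cfg.background_hazard_frac > 0:
        t_other = rng.exponential(1.0 / (cfg.baseline_hazard * cfg.background_hazard_frac),
                                  cfg.n_patients)
    else:
        t_other = np.full(cfg.n_patients, np.inf)
    t_death = np.minimum(t_disease, t_other)

    u = rng.random(cfg.n_patients)
    c_max = _calibrate_uniform_censoring(t_death, u, cfg.censoring_rate)
    t_cens = c_max * u
    os_time = np.minimum(t_death, t_cens)
    os_event = (t_death <= t_cens).astype(float)
    dss_event = ((t_disease <= t_other) & (t_death <= t_cens)).astype(float)
    dss_time = os_time.copy()
    miss = rng.random(cfg.n_patients) < cfg.dss_missing_rate
    dss_time[miss] = np.nan
    dss_event_arr = dss_event.copy()
    dss_event_arr[miss] = np.nan

    clinical = pd.DataFrame(
        {
            "os_time": np.maximum(os_time, 1.0),
            "os_event": os_event,
            "dss_time": np.maximum(dss_time, 1.0),
            "dss_event": dss_event_arr,
        },
        index=pd.Index(patients, name="patient"),
    )[CLINICAL_COLUMNS]

    cohort = Cohort(cancer_type=cfg.cancer_type, counts=counts_df, clinical=clinical)
    return cohort, mutmatrix, truth


def _calibrate_uniform_censoring(t_death, u, rate, tol=1e-3):
    """Scale Uniform(0, c) censoring so the realized censored fraction ~ rate."""
    if rate <= 0:
        return float(np.inf)
    lo, hi = 1e-6, float(np.max(t_death) * 100 + 1)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = np.mean(mid * u < t_death)
        if abs(frac - rate) < tol:
            return mid
        if frac > rate:  # too much censoring -> lengthen follow-up
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def write_cohort(cohort: Cohort, mutmatrix: pd.DataFrame, outdir) -> dict[str, Path]:
    """Emit the TSV dialects the readers consume (MAF-style mutations,
    counts, clinical); the simulator thereby doubles as a fixture generator."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": outdir / "mutations.tsv",
        "counts": outdir / "counts.tsv",
        "clinical": outdir / "clinical.tsv",
    }
    rows = []
    pos = 0
    for gene in mutmatrix.index:
        for patient in mutmatrix.columns:
            if mutmatrix.at[gene, patient]:
                pos += 1
                rows.append(
                    {
                        "Hugo_Symbol": gene,
                        "Tumor_Sample_Barcode": patient,
                        "Chromosome": "1",
                        "Start_Position": pos,
                        "Reference_Allele": "A",
                        "Tumor_Seq_Allele2": "T",
                        "Variant_Classification": "Missense_Mutation",
                    }
                )
    pd.DataFrame(rows).to_csv(paths["mutations"], sep="\t", index=False)
    cohort.counts.to_csv(paths["counts"], sep="\t", index_label="feature")
    if cohort.clinical is not None:
        cohort.clinical.to_csv(paths["clinical"], sep="\t", index_label="patient")
    return paths


def simulate_null_sweep(
    n_grid,
    category_grid,
    reps: int = 100,
    n_features: int = 500,
    seed: int = 0,
    engine_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Survey false-discovery DE counts across sample size and class balance.

    For each (n, category) cell a fresh null cohort (no mutation effects)
    is simulated and ``reps`` random labellings at the category's class
    ratio are pushed through the DE engine.  Returns a tidy table
    (n, category, rep, N) whose medians reproduce the structural trend:
    false discoveries grow with sample size and with class balance.
    """
    from .de_engine import DEEngine
    from .perm_null import permutation_labels

    engine_kwargs = engine_kwargs or {}
    ss = np.random.SeedSequence(seed)
    rows = []
    for n in n_grid:
        cfg = SimulationConfig(
            seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31),
            n_patients=int(n),
            n_features=n_features,
            effects=[],
            n_impacted_default=0,
        )
        cohort, _, _ = simulate_cohort(cfg)
        engine = DEEngine(cohort.counts, **engine_kwargs)
        for category in category_grid:
            rng = np.random.default_rng(
                int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
            )
            for rep in range(reps):
                labels = permutation_labels(int(n), float(category), rng)
                rows.append(
                    {
                        "n": int(n),
                        "category": float(category),
                        "rep": rep,
                        "N": engine.count(labels),
                    }
                )
    return pd.DataFrame(rows)
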