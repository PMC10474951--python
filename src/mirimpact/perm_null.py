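"""Frequency-matched permutation null distributions of DE counts.

The number of dysregulated features N in a mutation context cannot be
compared across genes or cohorts directly: larger cohorts and more balanced
mutant/wild-type splits yield more (false) discoveries even under random
labels.  The framework therefore builds, per cohort and per discrete
mutation-frequency category, a null distribution of DE counts from B
class-ratio-controlled label permutations, and converts an observed N into

* an empirical P (tail proportion of null counts at or above N, add-one
  estimator so the floor is 1/(B+1) ≈ .001 at B = 1000),
* a z-score (N minus null mean over null sd; 1.96 is the customary
  conspicuousness threshold), and
* a Negative-Binomial-modified P — the upper tail of an NB fitted to the
  null counts by method of moments — which resolves ties below the
  empirical floor and is the primary decision statistic.

All genes of one cohort whose frequencies map to the same category are
scored against the byte-identical null distribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import nbinom, poisson

from .io_cohort import CATEGORY_GRID, MutationContext

logger = logging.getLogger(__name__)


@dataclass
class NullCountDistribution:
    """B permutation DE counts for one (cohort, frequency category)."""

    cancer_type: str
    category: float
    counts: np.ndarray
    seed: int | None = None
    mu: float = field(init=False)
    sd: float = field(init=False)
    nb_params: tuple[float, float] | None = field(init=False)
    poisson_lambda: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.mu = float(self.counts.mean())
        self.sd = float(self.counts.std(ddof=1)) if self.B > 1 else 0.0
        var = self.sd**2
        if var > self.mu > 0:
            # method of moments: r = mu^2/(var-mu), p = mu/var
            self.nb_params = (self.mu**2 / (var - self.mu), self.mu / var)
            self.poisson_lambda = None
        else:
            self.nb_params = None
            self.poisson_lambda = self.mu

    @property
    def B(self) -> int:
        return int(self.counts.size)

    def save(self, counts_path, meta_path) -> None:
        np.savetxt(counts_path, self.counts, fmt="%d", header="null_de_count")
        meta = {
            "cancer_type": self.cancer_type,
            "category": self.category,
            "B": self.B,
            "mu": self.mu,
            "sd": self.sd,
            "nb_params": self.nb_params,
            "poisson_lambda": self.poisson_lambda,
            "seed": self.seed,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, counts_path, meta_path) -> "NullCountDistribution":
        with open(meta_path) as fh:
            meta = json.load(fh)
        counts = np.loadtxt(counts_path, dtype=np.int64, ndmin=1)
        return cls(
            cancer_type=meta["cancer_type"],
            category=meta["category"],
            counts=counts,
            seed=meta.get("seed"),
        )


@dataclass
class ImpactResult:
    """Permutation-adjusted impact statistics for one mutation context."""

    context: MutationContext
    N_obs: int
    p_emp: float
    z: float
    p_nb: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return bool(self.p_nb < self.alpha)


def permutation_labels(n: int, category: float, rng: np.random.Generator,
                       n_mutant: int | None = None) -> np.ndarray:
    """One class-ratio-controlled random labelling: exactly
    ``round(category * n)`` mutants (or an explicit ``n_mutant``)."""
    k = int(round(category * n)) if n_mutant is None else int(n_mutant)
    labels = np.zeros(n, dtype=bool)
    labels[rng.choice(n, size=k, replace=False)] = True
    return labels


def simulate_null(
    cohort_or_n,
    category: float,
    de,
    B: int = 1000,
    seed: int | None = None,
    n_mutant: int | None = None,
    cancer_type: str | None = None,
) -> NullCountDistribution:
    """Build the permutation null DE-count distribution for one category.

    Parameters
    ----------
    cohort_or_n : Cohort or int
        The cohort (for its patient count and label) or the number of
        patients directly.
    category : float
        A grid value in {0.05, ..., 0.50}; each permutation assigns exactly
        ``round(category * n)`` patients to the mutant class uniformly at
        random without replacement.
    de : DEEngine or callable
        Engine whose ``count(labels)`` (or direct call) returns the DE
        count for a labelling.
    n_mutant : int, optional
        Exact mutant-class size, overriding ``round(category * n)`` to
        match a real context exactly.
    """
    if not np.any(np.isclose(CATEGORY_GRID, category)):
        raise ValueError(f"category {category} is not on the grid {CATEGORY_GRID.tolist()}")
    if B < 100:
        logger.warning("B=%d < 100 permutations: NB tail fit will be unstable", B)
    if hasattr(cohort_or_n, "n_patients"):
        n = cohort_or_n.n_patients
        cancer_type = cancer_type or cohort_or_n.cancer_type
    else:
        n = int(cohort_or_n)
        cancer_type = cancer_type or "COHORT"
    k = int(round(category * n)) if n_mutant is None else int(n_mutant)
    if k < 2 or n - k < 2:
        raise ValueError(
            f"category {category} at n={n} leaves a class with fewer than 2 patients"
        )
    counter = de.count if hasattr(de, "count") else de
    rng = np.random.default_rng(seed)
    counts = np.empty(B, dtype=np.int64)
    for b in range(B):
        counts[b] = counter(permutation_labels(n, category, rng, n_mutant=k))
    return NullCountDistribution(
        cancer_type=cancer_type, category=float(category), counts=counts, seed=seed
    )


def empirical_p(N_obs: int, null: NullCountDistribution, add_one: bool = True) -> float:
    """Tail proportion of null DE counts at or above ``N_obs``.

    With ``add_one`` (default) the estimator is (r+1)/(B+1), whose floor at
    B=1000 is 1/1001 ≈ .001; the raw r/B variant is available by flag.
    """
    r = int(np.sum(null.counts >= N_obs))
    if add_one:
        return (r + 1) / (null.B + 1)
    return r / null.B


def zscore(N_obs: int, null: NullCountDistribution) -> float:
    """Standardized deviation of ``N_obs`` from the null mean (NaN if sd=0)."""
    if null.sd == 0:
        logger.warning("null sd is zero; z-score undefined")
        return float("nan")
    return (N_obs - null.mu) / null.sd


def nb_modified_p(N_obs: int, null: NullCountDistribution) -> float:
    """Upper tail P(X >= N_obs) of the moment-fitted NB null.

    Falls back to Poisson(mu) when the null counts are not overdispersed,
    and to a vanishing pseudo-rate when the null is all zeros (flagged).
    """
    if N_obs <= 0:
        return 1.0
    if null.nb_params is not None:
        r, p_success = null.nb_params
        return float(nbinom.sf(N_obs - 1, r, p_success))
    lam = null.poisson_lambda
    if lam == 0:
        logger.warning("degenerate all-zero null; using pseudo-rate 0.5/B")
        lam = 0.5 / null.B
    return float(poisson.sf(N_obs - 1, lam))


def assess_impact(
    context: MutationContext,
    nulls: dict[float, NullCountDistribution],
    de,
    alpha: float = 0.05,
    add_one: bool = True,
) -> ImpactResult:
    """Score one mutation context against its category-matched null.

    Runs the DE engine on the context's true labels to obtain the observed
    DE count, then attaches the empirical P, z-score, and NB-modified P
    from the null distribution of the context's frequency category.
    """
    null = nulls.get(context.category)
    if null is None:
        raise KeyError(
            f"no null distribution for category {context.category}; "
            "run simulate_null for this (cohort, category) first"
        )
    counter = de.count if hasattr(de, "count") else de
    N_obs = int(counter(context.labels))
    return ImpactResult(
        context=context,
        N_obs=N_obs,
        p_emp=empirical_p(N_obs, null, add_one=add_one),
        z=zscore(N_obs, null),
        p_nb=nb_modified_p(N_obs, null),
        alpha=alpha,
    )
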