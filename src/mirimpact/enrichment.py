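"""Hypergeometric over-representation of responsive feature sets.

Database-agnostic: annotation sets (e.g. an HMDD-style disease-to-miRNA
map) are supplied by the user as a two-column TSV.  The universe defaults
to all features that entered DE testing, since enrichment against features
that never had a chance to be selected would distort the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de_engine import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCollection:
    """Named annotation sets restricted to a feature universe."""

    universe: frozenset
    sets: dict[str, frozenset]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        clipped = {}
        for term, members in self.sets.items():
            inside = frozenset(members) & self.universe
            if inside:
                clipped[term] = inside
            else:
                logger.info("term %r has no member in the universe; dropped", term)
        self.sets = clipped

    @classmethod
    def from_tsv(cls, path, universe=None) -> "AnnotationCollection":
        """Load a (term, feature) two-column TSV; universe defaults to the
        union of all annotated features."""
        df = pd.read_csv(path, sep="\t", header=None, names=["term", "feature"],
                         dtype=str, comment="#")
        sets: dict[str, set] = {}
        for term, grp in df.groupby("term"):
            sets[str(term)] = set(grp["feature"])
        if universe is None:
            universe = set().union(*sets.values()) if sets else set()
        return cls(universe=frozenset(universe), sets={k: frozenset(v) for k, v in sets.items()})


def hypergeom_enrich(selected, ann: AnnotationCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``selected`` per annotation term.

    For a term annotating K of the N universe features, with k of the n
    selected features annotated: p = P(X >= k) for X ~ Hypergeom(N, K, n);
    gene_ratio = k/n; q by BH across terms.  Selected features outside the
    universe are dropped with a logged count.  Sorted by p.
    """
    selected = set(selected)
    if not selected:
        raise ValueError("selected feature set is empty")
    outside = selected - ann.universe
    if outside:
        logger.warning("%d selected features outside the universe dropped", len(outside))
        selected &= ann.universe
    if not selected:
        raise ValueError("no selected feature lies in the annotation universe")
    N = len(ann.universe)
    n = len(selected)
    rows = []
    for term, members in ann.sets.items():
        K = len(members)
        k = len(members & selected)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "gene_ratio": k / n, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
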