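"""Pharmacology: mechanism-of-action enrichment and structural similarity.

Given phenotypic cluster labels for a compound library, this module asks
(1) which mechanisms of action (MoA) are over-represented in each cluster
(one-sided Fisher exact tests with Benjamini-Hochberg FDR control), after
closing each compound's annotations under a specific-term -> general-term
hierarchy (a compound annotated "HTR1A antagonist" is also an "HTR
antagonist"); and (2) which compounds are structurally similar (Tanimoto /
Jaccard similarity on molecular fingerprint bit sets), reported as a
thresholded structure-phenotype graph whose edges are flagged when the two
compounds share a mechanism of action.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationTable",
    "expand_annotations",
    "fisher_enrichment",
    "enrich_clusters",
    "bh_fdr",
    "FingerprintSet",
    "tanimoto_matrix",
    "structure_phenotype_graph",
]


@dataclass
class AnnotationTable:
    """Compound -> set of MoA terms, with an optional term hierarchy.

    ``hierarchy`` maps a specific term to its more general parent term;
    it must be acyclic.
    """

    annotations: dict[str, set[str]]
    hierarchy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for c, terms in self.annotations.items():
            if any((not isinstance(t, str)) or (not t) for t in terms):
                raise ValueError(f"compound {c!r} has an empty/invalid term")
        # cycle check by following parents from every term
        for t in self.hierarchy:
            seen = {t}
            cur = t
            while cur in self.hierarchy:
                cur = self.hierarchy[cur]
                if cur in seen:
                    raise ValueError(f"cyclic term hierarchy at {cur!r}")
                seen.add(cur)


def expand_annotations(table: AnnotationTable) -> AnnotationTable:
    """Close every compound's term set under the parent relation.

    Transitive: a term's parent, grandparent, ... are all added, so a
    compound annotated with a specific receptor subtype also carries every
    more general mechanism above it.
    """
    out = {}
    for c, terms in table.annotations.items():
        closed = set(terms)
        stack = list(terms)
        while stack:
            t = stack.pop()
            p = table.hierarchy.get(t)
            if p is not None and p not in closed:
                closed.add(p)
                stack.append(p)
        out[c] = closed
    return AnnotationTable(annotations=out, hierarchy=dict(table.hierarchy))


def fisher_enrichment(labels: pd.Series, table: AnnotationTable, term: str,
                      cluster) -> dict | None:
    """One-sided (enrichment) Fisher exact test for one (cluster, term) pair.

    2x2 table over all labelled compounds: membership in ``cluster`` x
    carrying ``term``.  The p-value is the exact hypergeometric upper tail
    P(X >= a) with a = in-cluster annotated compounds, N compounds total,
    K annotated, n in the cluster.  Returns None for a term annotating
    no labelled compound.
    """
    compounds = list(labels.index)
    N = len(compounds)
    annotated = [c for c in compounds if term in table.annotations.get(c, ())]
    K = len(annotated)
    if K == 0:
        return None
    in_cluster = labels.index[labels == cluster]
    n = len(in_cluster)
    a = sum(1 for c in annotated if c in set(in_cluster))
    b = K - a
    c_ = n - a
    d = N - K - n + a
    p = float(hypergeom.sf(a - 1, N, K, n))
    odds = (a * d) / (b * c_) if b * c_ > 0 else np.inf
    return {"cluster": cluster, "term": term, "a": a, "b": b, "c": c_, "d": d,
            "odds_ratio": float(odds), "p": min(p, 1.0)}


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min over j >= i of p_(j) * m / j; monotone in p and <= 1.
    p-values must lie in (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich_clusters(labels: pd.Series, table: AnnotationTable,
                    min_annotated: int = 2) -> pd.DataFrame:
    """Fisher enrichment of every MoA term in every cluster, BH-corrected.

    Terms annotating fewer than ``min_annotated`` labelled compounds are
    excluded.  Returns one row per (cluster, term) with contingency
    counts, odds ratio, p and q.
    """
    universe = set(labels.index)
    term_counts: dict[str, int] = {}
    for c in universe:
        for t in table.annotations.get(c, ()):
            term_counts[t] = term_counts.get(t, 0) + 1
    terms = sorted(t for t, k in term_counts.items() if k >= min_annotated)
    rows = []
    for cluster in sorted(pd.unique(labels)):
        for term in terms:
            r = fisher_enrichment(labels, table, term, cluster)
            if r is not None:
                rows.append(r)
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_fdr(df["p"].values)
    return df


@dataclass(frozen=True)
class FingerprintSet:
    """Fixed-length bit fingerprints for a set of compounds."""

    compounds: tuple[str, ...]
    bits: np.ndarray            # (n_compounds, n_bits) boolean

    def __post_init__(self):
        b = np.asarray(self.bits, dtype=bool)
        if b.ndim != 2 or b.shape[0] != len(self.compounds):
            raise ValueError("bits must be (n_compounds, n_bits)")
        object.__setattr__(self, "bits", b)

    @classmethod
    def from_strings(cls, fp: dict[str, str]) -> "FingerprintSet":
        """Build from 0/1 bitstrings (all the same length)."""
        compounds = tuple(sorted(fp))
        lengths = {len(s) for s in fp.values()}
        if len(lengths) > 1:
            raise ValueError("all fingerprints must share one length")
        bits = np.array([[ch == "1" for ch in fp[c]] for c in compounds], dtype=bool)
        return cls(compounds=compounds, bits=bits)


def tanimoto_matrix(fps: FingerprintSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Tanimoto similarity and its z-score over off-diagonal pairs.

    T(a, b) = |a AND b| / |a OR b|, defined as 0 when both sets are empty;
    the diagonal is 1 for non-empty fingerprints.  z-scores standardise
    the off-diagonal similarities (mean 0, SD 1 over all ordered pairs).
    """
    n = len(fps.compounds)
    if n < 2:
        raise ValueError("need at least 2 fingerprints")
    B = fps.bits.astype(int)
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(T, np.where(sizes > 0, 1.0, 0.0))
    off = T[~np.eye(n, dtype=bool)]
    mu, sd = float(off.mean()), float(off.std(ddof=1))
    Z = (T - mu) / sd if sd > 0 else np.zeros_like(T)
    idx = list(fps.compounds)
    return (pd.DataFrame(T, index=idx, columns=idx),
            pd.DataFrame(Z, index=idx, columns=idx))


def structure_phenotype_graph(
    z_sim: pd.DataFrame,
    labels: pd.Series,
    table: AnnotationTable,
    z_threshold: float = 2.0,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Graph of compounds connected by high structural similarity.

    Edges join pairs with z-scored Tanimoto similarity >= ``z_threshold``;
    each edge carries the rounded z and a ``shared_moa`` flag (term sets
    intersect after hierarchy expansion — the "red edge" condition).
    Nodes carry their phenotypic cluster label.  Also returns the edge
    list as a table.
    """
    expanded = expand_annotations(table)
    G = nx.Graph()
    for c in z_sim.index:
        G.add_node(c, cluster=labels.get(c))
    rows = []
    comps = list(z_sim.index)
    for i, a in enumerate(comps):
        for b in comps[i + 1:]:
            z = float(z_sim.loc[a, b])
            if z >= z_threshold:
                shared = bool(expanded.annotations.get(a, set())
                              & expanded.annotations.get(b, set()))
                G.add_edge(a, b, z=z, z_rounded=int(round(z)), shared_moa=shared)
                rows.append({"compound_a": a, "compound_b": b, "z": z,
                             "z_rounded": int(round(z)), "shared_moa": shared})
    return G, pd.DataFrame(rows, columns=["compound_a", "compound_b", "z",
                                          "z_rounded", "shared_moa"])
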