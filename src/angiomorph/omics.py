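"""Expression meta-analysis for the Alzheimer's validation arm.

Works on a genes x samples expression matrix with per-sample metadata
(Brodmann region BM10/BM22/BM36/BM44, Braak stage 1-6, patient id) and
named gene sets (pro-angiogenic genes; targets of the two glutamate-
receptor-antagonist phenotype groups).  Stages, enforced in order:

    filter_low_expression -> scale_unit -> analyses

Analyses: per-region Braak group change (both the difference of group
means and their ratio, the latter named ``fold_change``), two-sample KS
differential tests, gene-gene Pearson correlation between gene sets,
Ward/Euclidean patient clustering on a gene set, and Fisher enrichment of
high-Braak (stage 5-6) patients per cluster and region.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .pharm import fisher_enrichment
from .screen import ScreenMatrix, ward_cluster

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "PatientClusterResult",
    "filter_low_expression",
    "scale_unit",
    "braak_group_change",
    "ks_differential",
    "gene_gene_correlation",
    "cluster_patients",
    "braak_cluster_enrichment",
]

REGIONS = ("BM10", "BM22", "BM36", "BM44")


@dataclass
class ExpressionStudy:
    """Expression matrix plus sample metadata and named gene sets.

    ``expression``: genes x samples, non-negative.
    ``metadata``: indexed by sample id with columns ``patient``, ``region``
    (one of BM10/BM22/BM36/BM44) and ``braak`` (integer 1-6).
    ``gene_sets``: name -> list of gene symbols.
    ``stage``: 'raw' | 'filtered' | 'scaled'.
    """

    expression: pd.DataFrame
    metadata: pd.DataFrame
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    stage: str = "raw"

    def __post_init__(self):
        if not set(self.expression.columns) <= set(self.metadata.index):
            missing = set(self.expression.columns) - set(self.metadata.index)
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]} ...")
        bad = set(self.metadata["region"].unique()) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown regions: {sorted(bad)}")
        braak = self.metadata["braak"]
        if not braak.isin(range(1, 7)).all():
            raise ValueError("Braak stages must be integers 1-6")

    def samples_in(self, region: str) -> pd.Index:
        meta = self.metadata.loc[self.expression.columns]
        return meta.index[meta["region"] == region]

    def gene_set_coverage(self, name: str) -> tuple[list[str], list[str]]:
        """(present, absent) members of a gene set w.r.t. the current matrix."""
        genes = self.gene_sets.get(name, [])
        present = [g for g in genes if g in self.expression.index]
        absent = [g for g in genes if g not in self.expression.index]
        return present, absent


@dataclass
class PatientClusterResult:
    """Sample -> patient cluster label ('P1', 'P2', ...)."""

    labels: pd.Series
    linkage: np.ndarray
    gene_set: str


def filter_low_expression(study: ExpressionStudy, cutoff: float = 1.00) -> ExpressionStudy:
    """Drop genes whose mean expression over all samples is below ``cutoff``.

    The boundary is inclusive: a gene with mean exactly equal to the
    cutoff is retained.  Reports gene-set members lost to the filter.
    """
    if study.stage != "raw":
        raise ValueError("filter_low_expression expects a raw study")
    means = study.expression.mean(axis=1)
    keep = means >= cutoff
    if not keep.any():
        raise ValueError("low-expression filter removed every gene")
    out = replace(study, expression=study.expression.loc[keep], stage="filtered")
    for name in study.gene_sets:
        _, absent = out.gene_set_coverage(name)
        if absent:
            logger.info("gene set %s: %d member(s) not in filtered matrix: %s",
                        name, len(absent), absent)
    logger.info("low-expression filter: kept %d / %d genes (cutoff %.2f)",
                int(keep.sum()), len(keep), cutoff)
    return out


def scale_unit(study: ExpressionStudy) -> ExpressionStudy:
    """Min-max scale every gene to [0, 1] (constant genes map to 0.5)."""
    if study.stage != "filtered":
        raise ValueError("scale_unit expects a filtered study")
    X = study.expression
    lo = X.min(axis=1)
    span = (X.max(axis=1) - lo).replace(0.0, np.nan)
    scaled = X.sub(lo, axis=0).div(span, axis=0).fillna(0.5)
    return replace(study, expression=scaled, stage="scaled")


def _braak_groups(study: ExpressionStudy, region: str,
                  high_min: int, low_max: int) -> tuple[pd.Index, pd.Index]:
    samples = study.samples_in(region)
    braak = study.metadata.loc[samples, "braak"]
    return samples[braak >= high_min], samples[braak <= low_max]


def braak_group_change(
    study: ExpressionStudy,
    region: str,
    genes: list[str] | None = None,
    high_min: int = 5,
    low_max: int = 3,
) -> pd.DataFrame:
    """Per-gene expression change between high- and low-Braak patients.

    For every gene in ``genes`` (default: all) within ``region``, reports
    both the difference of group means (high mean minus low mean) and
    their ratio, labelled ``fold_change``.  Groups default to Braak >= 5
    vs Braak <= 3; both bounds are parameters.
    """
    hi, lo = _braak_groups(study, region, high_min, low_max)
    if len(hi) == 0 or len(lo) == 0:
        empty = "high" if len(hi) == 0 else "low"
        raise ValueError(f"region {region}: {empty}-Braak group is empty")
    logger.info("braak_group_change %s: %d high / %d low samples", region, len(hi), len(lo))
    X = study.expression if genes is None else study.expression.loc[
        [g for g in genes if g in study.expression.index]]
    mh = X[hi].mean(axis=1)
    ml = X[lo].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mh / ml.replace(0.0, np.nan)
    return pd.DataFrame({
        "region": region, "mean_high": mh, "mean_low": ml,
        "difference": mh - ml, "fold_change": ratio,
        "n_high": len(hi), "n_low": len(lo),
    })


def ks_differential(
    study: ExpressionStudy,
    genes: list[str],
    region: str,
    high_min: int = 5,
    low_max: int = 3,
) -> pd.DataFrame:
    """Two-sample KS test per gene between high- and low-Braak patients."""
    hi, lo = _braak_groups(study, region, high_min, low_max)
    rows = []
    for g in genes:
        if g not in study.expression.index:
            continue
        a = study.expression.loc[g, hi].values
        b = study.expression.loc[g, lo].values
        if len(a) < 3 or len(b) < 3:
            warnings.warn(f"gene {g} in {region}: group too small for KS, skipped")
            continue
        ks = stats.ks_2samp(a, b, method="auto")
        rows.append({"gene": g, "region": region, "ks_stat": float(ks.statistic),
                     "ks_p": float(ks.pvalue), "n_high": len(a), "n_low": len(b)})
    return pd.DataFrame(rows)


def gene_gene_correlation(
    study: ExpressionStudy,
    set_a: list[str],
    set_b: list[str],
    region: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation between two gene sets across a region's samples.

    Returns (r, p) DataFrames indexed by set A genes x set B genes; p is
    two-sided from the t distribution on n-2 degrees of freedom.  Genes
    absent after filtering are dropped (and logged); a zero-variance gene
    yields missing r.
    """
    samples = study.samples_in(region)
    if len(samples) < 10:
        raise ValueError(f"region {region}: fewer than 10 samples")
    A = [g for g in set_a if g in study.expression.index]
    B = [g for g in set_b if g in study.expression.index]
    for name, full, present in (("A", set_a, A), ("B", set_b, B)):
        lost = set(full) - set(present)
        if lost:
            logger.info("correlation set %s: absent genes %s", name, sorted(lost))
    n = len(samples)
    r = pd.DataFrame(np.nan, index=A, columns=B)
    p = pd.DataFrame(np.nan, index=A, columns=B)
    Xa = study.expression.loc[A, samples].values
    Xb = study.expression.loc[B, samples].values
    for i, ga in enumerate(A):
        for j, gb in enumerate(B):
            x, y = Xa[i], Xb[j]
            if x.std() == 0 or y.std() == 0:
                continue
            rr = float(np.corrcoef(x, y)[0, 1])
            r.loc[ga, gb] = rr
            if abs(rr) >= 1.0:
                p.loc[ga, gb] = 0.0
            else:
                t = rr * np.sqrt((n - 2) / (1 - rr * rr))
                p.loc[ga, gb] = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def cluster_patients(study: ExpressionStudy, gene_set: str, k: int = 3,
                     region: str | None = None) -> PatientClusterResult:
    """Ward/Euclidean clustering of patient profiles on one gene set.

    Samples (optionally restricted to one region) are clustered on the
    scaled expression of the gene set's present members; labels are
    'P1'..'Pk'.  Defaults to k = 3 and joint clustering across regions.
    """
    if study.stage != "scaled":
        raise ValueError("cluster_patients expects a scaled study")
    present, absent = study.gene_set_coverage(gene_set)
    if absent:
        logger.info("cluster_patients: %d gene(s) of %s absent: %s",
                    len(absent), gene_set, absent)
    if not present:
        raise ValueError(f"gene set {gene_set!r} has no genes in the matrix")
    samples = study.expression.columns if region is None else study.samples_in(region)
    profiles = study.expression.loc[present, samples].T
    sm = ScreenMatrix(profiles, stage="scaled")
    labels, Z = ward_cluster(sm, k)
    labels = labels.map(lambda i: f"P{i}")
    labels.name = "patient_cluster"
    return PatientClusterResult(labels=labels, linkage=Z, gene_set=gene_set)


def braak_cluster_enrichment(result: PatientClusterResult,
                             study: ExpressionStudy,
                             high_stages: tuple[int, ...] = (5, 6)) -> pd.DataFrame:
    """Fisher enrichment of high-Braak patients per (cluster, region).

    For every cluster and region, a one-sided Fisher exact test on the
    2x2 table {sample in cluster} x {Braak in high_stages} over that
    region's samples; also reports each cluster's overall fraction of
    high-Braak samples.
    """
    meta = study.metadata.loc[result.labels.index]
    is_high = meta["braak"].isin(high_stages)
    table_rows = []
    for region in sorted(meta["region"].unique()):
        m = meta["region"] == region
        labels_r = result.labels[m]
        if labels_r.empty:
            continue
        high_flag = pd.Series(np.where(is_high[m], "high", "low"), index=labels_r.index)
        ann = {s: ({"high"} if high_flag[s] == "high" else set()) for s in labels_r.index}
        from .pharm import AnnotationTable
        tab = AnnotationTable(annotations={s: t for s, t in ann.items() if t})
        for cluster in sorted(labels_r.unique()):
            r = fisher_enrichment(labels_r, tab, "high", cluster)
            if r is None:
                continue
            frac = float(is_high[m][labels_r == cluster].mean())
            table_rows.append({"cluster": cluster, "region": region,
                               "n_in_cluster": int((labels_r == cluster).sum()),
                               "n_high_in_cluster": r["a"],
                               "fraction_high": frac, "p": r["p"]})
    df = pd.DataFrame(table_rows)
    if len(df):
        overall = []
        for cluster in sorted(result.labels.unique()):
            sel = result.labels == cluster
            overall.append({"cluster": cluster, "region": "all",
                            "n_in_cluster": int(sel.sum()),
                            "n_high_in_cluster": int(is_high[sel].sum()),
                            "fraction_high": float(is_high[sel].mean()),
                            "p": np.nan})
        hi_all = pd.Series(np.where(is_high, "high", "low"), index=result.labels.index)
        from .pharm import AnnotationTable
        tab_all = AnnotationTable(annotations={s: {"high"} for s in result.labels.index
                                               if hi_all[s] == "high"})
        for row in overall:
            r = fisher_enrichment(result.labels, tab_all, "high", row["cluster"])
            if r is not None:
                row["p"] = r["p"]
        df = pd.concat([df, pd.DataFrame(overall)], ignore_index=True)
    return df
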