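"""Screen profiling: from per-well feature vectors to phenotypic clusters.

Implements the normalisation and clustering chain used for high-content
screens with vehicle (DMSO) controls:

    raw wells -> exclude artefact wells -> per-plate z-score against DMSO
    -> average compound replicates -> min-max scale to [0, 1]
    -> Ward/Euclidean hierarchical clustering (+ optional t-SNE embedding)

The stages are enforced in order on :class:`ScreenMatrix`; each operation
checks the incoming stage and stamps the outgoing one.  Clusters of
compounds with similar multi-feature phenotypes ("PhenoClusters") are then
summarised per feature against the control-like cluster with two-sample
Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ks_2samp
from sklearn.manifold import TSNE

__all__ = [
    "PlateLayout",
    "ScreenMatrix",
    "exclude_wells",
    "normalize_to_dmso",
    "aggregate_replicates",
    "minmax_scale",
    "ward_cluster",
    "embed_2d",
    "characterize_clusters",
    "silhouette_scan",
]

_STAGES = ("raw", "zscored", "aggregated", "scaled")


@dataclass(frozen=True)
class PlateLayout:
    """Well metadata: plate, compound (or DMSO), replicate, exclusion flag.

    ``table`` is indexed by well id with columns
    ``plate, compound, replicate, is_dmso, excluded, exclusion_reason``.
    Every plate must contain at least two DMSO wells.
    """

    table: pd.DataFrame

    def __post_init__(self):
        req = {"plate", "compound", "replicate", "is_dmso"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"layout missing columns: {sorted(req - set(self.table.columns))}")
        t = self.table.copy()
        if "excluded" not in t.columns:
            t["excluded"] = False
        if "exclusion_reason" not in t.columns:
            t["exclusion_reason"] = ""
        for plate, grp in t[~t["excluded"]].groupby("plate"):
            if int(grp["is_dmso"].sum()) < 2:
                raise ValueError(f"plate {plate!r} has fewer than 2 DMSO wells")
        object.__setattr__(self, "table", t)

    def dmso_wells(self, plate) -> pd.Index:
        t = self.table
        m = (t["plate"] == plate) & t["is_dmso"] & ~t["excluded"]
        return t.index[m]


@dataclass
class ScreenMatrix:
    """Wells (or compounds) x features with a pipeline stage tag."""

    data: pd.DataFrame
    stage: str = "raw"
    cluster_labels: pd.Series | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def _require(self, stage: str):
        if self.stage != stage:
            raise ValueError(f"operation requires stage {stage!r}, matrix is {self.stage!r}")


def exclude_wells(matrix: ScreenMatrix, layout: PlateLayout,
                  exclusion: dict[str, str] | list[str]) -> tuple[ScreenMatrix, PlateLayout]:
    """Drop listed artefact/empty wells, recording a reason for each.

    ``exclusion`` maps well id -> reason (a plain list gets the reason
    "excluded").  Removing every DMSO well of a plate is an error because
    the next stage could not normalise that plate.
    """
    matrix._require("raw")
    if not isinstance(exclusion, dict):
        exclusion = {w: "excluded" for w in exclusion}
    unknown = [w for w in exclusion if w not in matrix.data.index]
    if unknown:
        raise KeyError(f"unknown well ids: {unknown}")
    t = layout.table.copy()
    for w, reason in exclusion.items():
        t.loc[w, "excluded"] = True
        t.loc[w, "exclusion_reason"] = reason
    for plate, grp in t.groupby("plate"):
        if int((grp["is_dmso"] & ~grp["excluded"]).sum()) == 0 and len(grp):
            raise ValueError(f"plate {plate!r} has no controls after exclusion")
    keep = matrix.data.index.difference(list(exclusion))
    out = ScreenMatrix(matrix.data.loc[keep], stage="raw",
                       log=matrix.log + [f"excluded {len(exclusion)} wells"])
    return out, PlateLayout(t)


def normalize_to_dmso(matrix: ScreenMatrix, layout: PlateLayout) -> ScreenMatrix:
    """Per-plate z-score against the DMSO wells of that plate.

    z = (x - mean_DMSO) / SD_DMSO per feature, with the sample (n-1) SD.
    A feature whose DMSO SD is 0 on a plate becomes missing on that plate.
    After this stage the DMSO wells of every plate have mean 0 and SD 1
    per feature by construction.
    """
    matrix._require("raw")
    t = layout.table
    wells = matrix.data.index
    out = pd.DataFrame(np.nan, index=wells, columns=matrix.data.columns)
    for plate in t.loc[wells, "plate"].unique():
        pw = wells[t.loc[wells, "plate"] == plate]
        dmso = layout.dmso_wells(plate).intersection(wells)
        if len(dmso) < 2:
            raise ValueError(f"plate {plate!r} has fewer than 2 usable DMSO wells")
        mu = matrix.data.loc[dmso].mean()
        sd = matrix.data.loc[dmso].std(ddof=1)
        z = (matrix.data.loc[pw] - mu) / sd.replace(0.0, np.nan)
        out.loc[pw] = z
    return ScreenMatrix(out, stage="zscored", log=matrix.log + ["z-scored to plate DMSO"])


def aggregate_replicates(matrix: ScreenMatrix, layout: PlateLayout,
                         keep_dmso: bool = False) -> ScreenMatrix:
    """Average compound replicates (missing-aware) into one row per compound."""
    matrix._require("zscored")
    t = layout.table.loc[matrix.data.index]
    rows = matrix.data.copy()
    rows["__compound"] = np.where(t["is_dmso"], "DMSO", t["compound"])
    agg = rows.groupby("__compound").mean()
    if not keep_dmso and "DMSO" in agg.index:
        agg = agg.drop(index="DMSO")
    empty = agg.index[agg.isna().all(axis=1)]
    if len(empty):
        warnings.warn(f"compounds with no usable wells dropped: {list(empty)}")
        agg = agg.drop(index=empty)
    return ScreenMatrix(agg, stage="aggregated",
                        log=matrix.log + [f"aggregated to {len(agg)} compounds"])


def minmax_scale(matrix: ScreenMatrix, impute: bool = True) -> ScreenMatrix:
    """Scale every feature to [0, 1]; constant features map to 0.5.

    Missing values are imputed to the feature median before scaling so the
    scaled matrix is complete (clustering requires it).
    """
    matrix._require("aggregated")
    df = matrix.data.copy()
    if impute:
        df = df.fillna(df.median())
        df = df.dropna(axis=1, how="all")   # features missing everywhere
    lo, hi = df.min(), df.max()
    span = hi - lo
    const = span == 0
    if const.any():
        warnings.warn(f"constant features set to 0.5: {list(df.columns[const])}")
    scaled = (df - lo) / span.replace(0.0, np.nan)
    scaled.loc[:, const] = 0.5
    return ScreenMatrix(scaled, stage="scaled", log=matrix.log + ["min-max scaled"])


def ward_cluster(matrix: ScreenMatrix, k: int) -> tuple[pd.Series, np.ndarray]:
    """Ward-linkage hierarchical clustering on Euclidean distances.

    Returns integer labels 1..k (a pandas Series on the matrix index) and
    the scipy linkage matrix (the dendrogram).  Deterministic for a given
    row order; merge heights are monotone non-decreasing for Ward linkage.
    """
    matrix._require("scaled")
    n = len(matrix.data)
    if not (2 <= k <= n - 1):
        raise ValueError(f"k must be in [2, {n - 1}], got {k}")
    Z = linkage(matrix.data.values, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.data.index, name="cluster"), Z


def cophenetic_heights(Z: np.ndarray) -> np.ndarray:
    """Merge heights of a linkage matrix (non-decreasing for Ward)."""
    return Z[:, 2]


def dendrogram_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return str(labels[node.id])
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return rec(tree) + ";"


def embed_2d(matrix: ScreenMatrix, seed: int = 0, perplexity: float = 30.0) -> pd.DataFrame:
    """t-SNE embedding for visualisation only.

    Deterministic for a fixed seed.  Requires n >= 10 and
    perplexity < n/3; nothing downstream consumes the coordinates.
    """
    matrix._require("scaled")
    n = len(matrix.data)
    if n < 10:
        raise ValueError("need at least 10 rows for a 2-D embedding")
    if perplexity >= n / 3:
        raise ValueError(f"perplexity must be < n/3 = {n / 3:.1f}")
    ts = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    xy = ts.fit_transform(matrix.data.values)
    return pd.DataFrame(xy, index=matrix.data.index, columns=["tsne_1", "tsne_2"])


def characterize_clusters(
    z_matrix: ScreenMatrix | pd.DataFrame,
    labels: pd.Series,
    control_like_label: int | None = None,
    min_cluster_size: int = 3,
) -> tuple[pd.DataFrame, int]:
    """Per-cluster feature medians and KS tests against the control-like cluster.

    The control-like cluster defaults to the one with the smallest mean
    absolute z-profile (the compounds that barely deviate from DMSO); pass
    ``control_like_label`` to override.  For every other cluster and every
    feature a two-sample Kolmogorov-Smirnov test compares its compound
    values against the control-like cluster's (exact p for small samples
    via scipy's method='auto').  Clusters smaller than ``min_cluster_size``
    get medians but no test.
    """
    df = z_matrix.data if isinstance(z_matrix, ScreenMatrix) else z_matrix
    df = df.loc[labels.index]
    if control_like_label is None:
        mean_abs = df.abs().mean(axis=1).groupby(labels).mean()
        control_like_label = int(mean_abs.idxmin())
    records = []
    ctrl = df[labels == control_like_label]
    for lab in sorted(labels.unique()):
        members = df[labels == lab]
        for feat in df.columns:
            rec = {"cluster": lab, "feature": feat,
                   "median": float(members[feat].median()),
                   "n": int(members[feat].notna().sum())}
            if lab != control_like_label and len(members) >= min_cluster_size:
                a = members[feat].dropna().values
                b = ctrl[feat].dropna().values
                if len(a) and len(b):
                    ks = ks_2samp(a, b, method="auto")
                    rec["ks_stat"] = float(ks.statistic)
                    rec["ks_p"] = float(ks.pvalue)
            records.append(rec)
    return pd.DataFrame.from_records(records), control_like_label


def silhouette_scan(matrix: ScreenMatrix, k_range: range) -> pd.DataFrame:
    """Mean silhouette score for each candidate k (guidance only)."""
    from sklearn.metrics import silhouette_score

    rows = []
    for k in k_range:
        labels, _ = ward_cluster(matrix, k)
        rows.append({"k": k, "silhouette": float(
            silhouette_score(matrix.data.values, labels.values))})
    return pd.DataFrame(rows)
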