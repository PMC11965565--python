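"""Circadian phenotype discovery: correlations, PCA, k-means, UMAP, mutations.

Integrates the per-cell-line circadian features (autocorrelation, wavelet,
multiresolution, decay readouts, reporter-averaged) with growth rates,
prunes redundancy via pairwise Pearson correlation, embeds with PCA and
UMAP, and clusters a three-parameter summary (period, phase-difference
variability, circadian band fraction) with k-means.  The elbow of the
within-cluster-dispersion curve (Kneedle, sensitivity 1) selects k, and
deterministic centroid rules map clusters onto the four circadian
phenotype labels: functional, weak, unstable, dysfunctional.

Mutation scoring assigns each variant a severity 1-3 (silent to
protein-truncating) over a circadian gene panel, aggregates per cell
line and per group, and exposes hierarchical clusterings of mutational
burden and expression tables.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from ._knee import find_knee
from .exceptions import ConfigurationError

PHENOTYPE_LABELS = ("functional", "weak", "unstable", "dysfunctional")
CLUSTER_FEATURES = ("period_h", "phase_diff_var", "circadian_band_pct")
STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


# ---------------------------------------------------------------- features

def minmax_scale(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise min-max scaling to [0, 1] (order-preserving)."""
    lo, hi = df.min(), df.max()
    span = (hi - lo).replace(0, 1.0)
    return (df - lo) / span


def correlation_matrix(ft: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p-values between feature columns.

    Zero-variance columns yield NaN entries (correlation undefined).
    """
    if len(ft) < 4:
        raise ConfigurationError("correlation analysis needs at least 4 rows")
    cols = ft.columns
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i:]:
            x, y = ft[a].to_numpy(float), ft[b].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            rr, pp = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_pct: np.ndarray


def pca_embed(ft_scaled: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """2-component PCA (exact full SVD) of a min-max scaled feature table."""
    if n_components > ft_scaled.shape[1]:
        raise ConfigurationError("more components requested than feature columns")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(ft_scaled.to_numpy(float))
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=ft_scaled.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=ft_scaled.columns, columns=comp_names),
        explained_pct=pca.explained_variance_ratio_ * 100.0,
    )


# ---------------------------------------------------------------- clustering

@dataclass
class PhenotypeAssignment:
    cluster_id: pd.Series
    labels: pd.Series
    k: int
    wcss: float
    silhouette: float
    wcss_by_k: Dict[int, float] = field(default_factory=dict)
    silhouette_by_k: Dict[int, float] = field(default_factory=dict)
    centroids: Optional[pd.DataFrame] = None


def label_clusters(centroids: pd.DataFrame) -> Dict[int, str]:
    """Deterministic centroid rules mapping clusters to phenotype labels.

    On (period, phase-difference variability, circadian band) centroids:
    functional = highest circadian band among clusters with at-or-below
    median variability; dysfunctional = (preferring above-median
    variability) the lowest-band, longest-period remaining cluster;
    unstable = remaining cluster with highest variability; weak = the
    rest.  Depends only on centroid geometry, so the mapping is invariant
    to cluster index permutations.  Non-4 cluster counts fall back to
    generic ``cluster_i`` names beyond the first four rules.
    """
    per, var, band = (centroids[c] for c in CLUSTER_FEATURES)
    remaining = list(centroids.index)
    mapping: Dict[int, str] = {}

    med_var = float(var.median())
    low_var = [c for c in remaining if var[c] <= med_var]
    functional = max(low_var or remaining, key=lambda c: band[c])
    mapping[functional] = "functional"
    remaining.remove(functional)

    if remaining:
        high_var = [c for c in remaining if var[c] > med_var]
        pool = high_var or remaining
        # lowest band; break ties toward the longest period
        dysfunctional = min(pool, key=lambda c: (band[c], -per[c]))
        mapping[dysfunctional] = "dysfunctional"
        remaining.remove(dysfunctional)
    if remaining:
        unstable = max(remaining, key=lambda c: var[c])
        mapping[unstable] = "unstable"
        remaining.remove(unstable)
    if remaining:
        mapping[remaining.pop(0)] = "weak"
    for extra in remaining:
        mapping[extra] = f"cluster_{extra}"
    return mapping


def select_k_and_cluster(
    features: pd.DataFrame,
    k_range: Iterable[int] = range(2, 8),
    seed: int = 0,
    sensitivity: float = 1.0,
    n_init: int = 10,
) -> PhenotypeAssignment:
    """K-means over a k range with elbow-based model selection.

    Expects the three min-max-scalable clustering features (period,
    phase-difference variability, circadian band fraction).  The knee of
    the within-cluster dispersion curve picks k (falling back to the
    best-silhouette k when no knee exists); the chosen clustering is
    labelled with the deterministic centroid rules.
    """
    missing = [c for c in CLUSTER_FEATURES if c not in features.columns]
    if missing:
        raise ConfigurationError(f"clustering features missing: {missing}")
    X = minmax_scale(features[list(CLUSTER_FEATURES)]).to_numpy(float)
    ks = [k for k in k_range if k < len(features)]
    if not ks:
        raise ConfigurationError("fewer rows than the smallest cluster count")
    fits, wcss_by_k, sil_by_k = {}, {}, {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
        fits[k] = km
        wcss_by_k[k] = float(km.inertia_)
        sil_by_k[k] = float(silhouette_score(X, labels)) if len(set(labels)) > 1 else np.nan

    # anchor the dispersion curve at k=1 (total scatter) so a two-cluster
    # structure still produces a detectable elbow
    wcss1 = float(((X - X.mean(axis=0)) ** 2).sum())
    knee = find_knee(
        [1] + ks, [wcss1] + [wcss_by_k[k] for k in ks], sensitivity=sensitivity
    )
    if knee is not None and int(knee) == 1:
        knee = None
    k_opt = int(knee) if knee is not None else max(sil_by_k, key=lambda k: sil_by_k[k])
    km = fits[k_opt]
    cluster_id = pd.Series(km.predict(X), index=features.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, columns=list(CLUSTER_FEATURES))
    # un-scale centroids back to feature units for interpretable rules
    lo = features[list(CLUSTER_FEATURES)].min()
    hi = features[list(CLUSTER_FEATURES)].max()
    centroids = centroids * (hi - lo).replace(0, 1.0).values + lo.values
    mapping = label_clusters(centroids)
    return PhenotypeAssignment(
        cluster_id=cluster_id,
        labels=cluster_id.map(mapping).rename("phenotype"),
        k=k_opt,
        wcss=wcss_by_k[k_opt],
        silhouette=sil_by_k[k_opt],
        wcss_by_k=wcss_by_k,
        silhouette_by_k=sil_by_k,
        centroids=centroids,
    )


def umap_embed(
    table: pd.DataFrame,
    n_neighbors: int = 3,
    n_components: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded UMAP embedding of a feature or expression table."""
    if len(table) < n_neighbors + 1:
        raise ConfigurationError("UMAP needs at least n_neighbors + 1 rows")
    import umap  # deferred: numba compilation is slow to import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=n_neighbors, n_components=n_components, random_state=seed
        )
        emb = reducer.fit_transform(table.to_numpy(float))
    cols = [f"UMAP{i + 1}" for i in range(n_components)]
    return pd.DataFrame(emb, index=table.index, columns=cols)


def neighbor_preservation(original: pd.DataFrame, embedded: pd.DataFrame, k: int = 3) -> float:
    """Fraction of k-nearest-neighbour relations preserved by an embedding."""
    from sklearn.neighbors import NearestNeighbors

    def knn(df):
        nn = NearestNeighbors(n_neighbors=k + 1).fit(df.to_numpy(float))
        _, idx = nn.kneighbors(df.to_numpy(float))
        return [set(row[1:]) for row in idx]

    a, b = knn(original), knn(embedded)
    return float(np.mean([len(x & y) / k for x, y in zip(a, b)]))


# ---------------------------------------------------------------- mutations

def default_severity_map() -> Dict[str, int]:
    """Variant-class severity map (1 silent .. 3 protein-truncating)."""
    text = importlib.resources.files("circapheno.data").joinpath(
        "variant_severity.yaml"
    ).read_text()
    return yaml.safe_load(text)


def default_core_clock_genes() -> list:
    """Default 16-gene core-clock panel (standard TTFL components)."""
    text = importlib.resources.files("circapheno.data").joinpath(
        "core_clock_genes.txt"
    ).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


@dataclass
class MutationScore:
    per_line: pd.Series
    composition: pd.DataFrame      # lines x variant class -> count
    severity_map: Dict[str, int]
    burden_linkage: Optional[np.ndarray] = None

    def group_scores(self, groups: Mapping[str, str]) -> pd.Series:
        """Mean per-line score within each group (phenotype or subtype)."""
        g = pd.Series(groups)
        aligned = self.per_line.reindex(g.index).fillna(0.0)
        return aligned.groupby(g).mean().rename("group_score")


def score_mutations(
    mutations: pd.DataFrame,
    gene_panel: Sequence[str],
    severity_map: Optional[Dict[str, int]] = None,
    per_line: str = "sum",
    strict: bool = False,
    cell_lines: Optional[Sequence[str]] = None,
) -> MutationScore:
    """Severity-score circadian-gene mutations per cell line.

    ``mutations`` needs columns ``cell_line, gene, variant_class``.  Each
    panel mutation contributes its severity (1-3); the per-line score is
    the sum (default) or mean of severities.  Unknown variant classes
    raise in strict mode, otherwise fall back to severity 2 with a
    warning.  Lines are hierarchically clustered on their per-gene burden
    (capped at 2) with Hamming distance and single linkage.
    """
    sev = severity_map if severity_map is not None else default_severity_map()
    if per_line not in ("sum", "mean"):
        raise ConfigurationError("per_line must be 'sum' or 'mean'")
    panel = set(gene_panel)
    sub = mutations[mutations["gene"].isin(panel)].copy()

    def severity_of(cls: str) -> int:
        key = str(cls).strip().lower()
        if key in sev:
            return int(sev[key])
        if strict:
            raise ConfigurationError(f"unknown variant class: {cls!r}")
        warnings.warn(f"unknown variant class {cls!r}; scoring as severity 2")
        return 2

    sub["severity"] = [severity_of(c) for c in sub["variant_class"]]
    lines = list(cell_lines) if cell_lines is not None else sorted(mutations["cell_line"].unique())
    agg = sub.groupby("cell_line")["severity"].agg(per_line)
    per_line_scores = agg.reindex(lines).fillna(0.0).rename("mutation_score")
    composition = (
        sub.groupby(["cell_line", "variant_class"]).size().unstack(fill_value=0)
        .reindex(lines).fillna(0).astype(int)
    )

    burden = (
        sub.groupby(["cell_line", "gene"]).size().unstack(fill_value=0)
        .reindex(index=lines, columns=sorted(panel)).fillna(0).clip(upper=2)
    )
    link = None
    if len(lines) > 1:
        link = linkage(pdist(burden.to_numpy(), metric="hamming"), method="single")
    return MutationScore(per_line_scores, composition, sev, link)


def cluster_table(
    table: pd.DataFrame, metric: str = "euclidean", method: str = "complete"
) -> Tuple[np.ndarray, np.ndarray]:
    """Row/column linkages for a clustered-heatmap export (e.g. expression)."""
    row = linkage(pdist(table.to_numpy(float), metric=metric), method=method)
    col = linkage(pdist(table.to_numpy(float).T, metric=metric), method=method)
    return row, col
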