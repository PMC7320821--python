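"""Metabolite-side computations.

Internal-standard normalization of feature intensities, ppm-window matching
of neutral masses against a reference compound table, PCA of tissue metabolite
profiles, and Spearman-based hierarchical clustering of mass-features.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from ._cluster import linkage_matrix
from ._utils import spearman_rows
from .io import MetaboliteMatrix

__all__ = [
    "CompoundReference",
    "MatchResult",
    "REFERENCE_COMPOUNDS",
    "normalize_by_standard",
    "ppm_match",
    "pca_scores",
    "metabolite_clusters",
    "InternalStandardNormalizer",
    "MetaboliteCorrelationClusterer",
]


@dataclasses.dataclass(frozen=True)
class CompoundReference:
    """A reference compound: name, monoisotopic neutral mass (Da), class."""

    name: str
    neutral_mass: float
    compound_class: str

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError(f"{self.name}: neutral mass must be positive")


#: Compounds typical of Cornus tissues, with monoisotopic masses computed
#: from their molecular formulae.  Used for ppm-window annotation examples
#: and as the mass pool for the synthetic generator.
REFERENCE_COMPOUNDS: tuple[CompoundReference, ...] = (
    CompoundReference("loganin", 390.152602, "iridoid"),            # C17H26O10
    CompoundReference("morroniside", 406.147517, "iridoid"),        # C17H26O11
    CompoundReference("sweroside", 358.126382, "iridoid"),          # C16H22O9
    CompoundReference("loganic acid", 376.136947, "iridoid"),       # C16H24O10
    CompoundReference("cornuside", 542.163555, "iridoid"),          # C24H30O14
    CompoundReference("ursolic acid", 456.360345, "triterpenoid"),  # C30H48O3
    CompoundReference("oleanolic acid", 456.360345, "triterpenoid"),
    CompoundReference("gallic acid", 170.021523, "gallotannin"),    # C7H6O5
    CompoundReference("1-O-galloyl-glucose", 332.074347, "gallotannin"),  # C13H16O10
    CompoundReference("tellimagrandin I", 786.091242, "gallotannin"),     # C34H26O22
    CompoundReference("chlorogenic acid", 354.095082, "phenylpropanoid"),  # C16H18O9
    CompoundReference("quercetin", 302.042653, "other"),            # C15H10O7
)


@dataclasses.dataclass(frozen=True)
class MatchResult:
    feature_id: str | None
    compound: str
    mass_error_ppm: float
    accepted: bool


def normalize_by_standard(mm: MetaboliteMatrix, standard_feature_id: str) -> MetaboliteMatrix:
    """Divide every feature's intensity by the internal standard's intensity
    in the same tissue.

    The standard must be present with strictly positive intensity in every
    tissue; its own row becomes all ones.  Within-tissue ratios between
    non-standard features are preserved.
    """
    if standard_feature_id not in mm.intensities.index:
        raise ValueError(f"internal standard {standard_feature_id!r} not found")
    std = mm.intensities.loc[standard_feature_id]
    if (std <= 0).any():
        bad = list(std.index[std <= 0])
        raise ValueError(
            f"internal standard {standard_feature_id!r} non-positive in tissues {bad}"
        )
    normalized = mm.intensities.div(std, axis=1)
    return MetaboliteMatrix(intensities=normalized, metadata=mm.metadata.copy())


class InternalStandardNormalizer(BaseEstimator, TransformerMixin):
    """Estimator-style wrapper around internal-standard normalization.

    Parameters
    ----------
    standard_feature_id : str
        Feature id of the spiked internal standard (e.g. lidocaine).
    """

    def __init__(self, standard_feature_id: str = "lidocaine"):
        self.standard_feature_id = standard_feature_id

    def fit(self, X: MetaboliteMatrix, y=None):
        if self.standard_feature_id not in X.intensities.index:
            raise ValueError(f"internal standard {self.standard_feature_id!r} not found")
        self.standard_profile_ = X.intensities.loc[self.standard_feature_id].copy()
        return self

    def transform(self, X: MetaboliteMatrix) -> MetaboliteMatrix:
        return normalize_by_standard(X, self.standard_feature_id)


def ppm_match(
    feature_mass: float,
    refs: Iterable[CompoundReference],
    tol_ppm: float = 10.0,
    feature_id: str | None = None,
) -> list[MatchResult]:
    """Match one neutral mass against a reference table within a ppm window.

    The mass error is ``(feature - reference) / reference * 1e6`` — always
    relative to the reference mass — and a match is accepted when its
    absolute error is at most ``tol_ppm`` (inclusive, two-sided).  All
    references are evaluated; results are sorted by absolute error.
    """
    if feature_mass <= 0:
        raise ValueError("feature mass must be positive")
    results = []
    for ref in refs:
        err = (feature_mass - ref.neutral_mass) / ref.neutral_mass * 1e6
        results.append(
            MatchResult(
                feature_id=feature_id,
                compound=ref.name,
                mass_error_ppm=err,
                accepted=abs(err) <= tol_ppm,
            )
        )
    results.sort(key=lambda r: (abs(r.mass_error_ppm), r.compound))
    return results


def pca_scores(
    mm: MetaboliteMatrix | pd.DataFrame, n_components: int = 2, log: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of the tissues in metabolite space.

    Tissues are the observations (columns of the intensity matrix become PCA
    samples); features are centred.  The sign of each component is fixed so
    that its largest-magnitude loading is positive.  Returns (scores
    DataFrame tissues x components, explained-variance fractions).
    """
    intensities = mm.intensities if isinstance(mm, MetaboliteMatrix) else mm
    X = intensities.to_numpy(dtype=float).T  # tissues x features
    if log:
        X = np.log1p(X)
    n_tissues = X.shape[0]
    if n_components > n_tissues:
        raise ValueError(
            f"requested {n_components} components from {n_tissues} tissues"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for k in range(n_components):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1
    score_df = pd.DataFrame(
        scores,
        index=intensities.columns,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return score_df, pca.explained_variance_ratio_.copy()


class MetaboliteCorrelationClusterer(BaseEstimator):
    """Hierarchical clustering of mass-features on Spearman correlation.

    Features are clustered with the given linkage on distance ``1 - rho``
    (rank correlation across tissues).  Constant features have undefined
    correlations; they are excluded with a warning and labelled ``-1``.

    Parameters
    ----------
    n_clusters : int, default 4
        Number of flat clusters to cut from the dendrogram.
    linkage : {"average", "complete", "single"}
        Agglomeration rule.

    Attributes
    ----------
    labels_ : pandas.Series
        Cluster label per feature (1..n_clusters; -1 for excluded features).
    correlation_ : pandas.DataFrame
        Feature-feature Spearman matrix for the retained features.
    linkage_ : numpy.ndarray
        scipy linkage matrix over the retained features.
    excluded_features_ : list
        Features dropped because of constant profiles.
    """

    def __init__(self, n_clusters: int = 4, linkage: str = "average"):
        self.n_clusters = n_clusters
        self.linkage = linkage

    def fit(self, X: MetaboliteMatrix | pd.DataFrame, y=None):
        intensities = X.intensities if isinstance(X, MetaboliteMatrix) else X
        values = intensities.to_numpy(dtype=float)
        constant = values.std(axis=1) == 0
        if constant.any():
            self.excluded_features_ = list(intensities.index[constant])
            warnings.warn(
                f"excluding constant feature(s) from clustering: "
                f"{self.excluded_features_}",
                stacklevel=2,
            )
        else:
            self.excluded_features_ = []
        kept = intensities.index[~constant]
        if len(kept) < self.n_clusters:
            raise ValueError(
                f"{len(kept)} usable features for {self.n_clusters} clusters"
            )
        corr = spearman_rows(values[~constant])
        self.correlation_ = pd.DataFrame(corr, index=kept, columns=kept)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist[np.abs(dist) < 1e-12] = 0.0
        self.linkage_ = linkage_matrix(dist, method=self.linkage)
        flat = hierarchy.fcluster(self.linkage_, t=self.n_clusters, criterion="maxclust")
        labels = pd.Series(-1, index=intensities.index, name="cluster", dtype=int)
        labels.loc[kept] = flat
        self.labels_ = labels
        return self

    def fit_predict(self, X, y=None) -> pd.Series:
        return self.fit(X).labels_


def metabolite_clusters(
    mm: MetaboliteMatrix | pd.DataFrame, n_clusters: int = 4, linkage: str = "average"
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster mass-features; returns (labels, Spearman matrix)."""
    est = MetaboliteCorrelationClusterer(n_clusters=n_clusters, linkage=linkage).fit(mm)
    return est.labels_, est.correlation_
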