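"""Assignment of annotated transcripts to a biosynthetic pathway by
co-expression clustering.

Transcripts pre-annotated (by homology) as enzymes of a pathway are clustered
hierarchically on rank-correlation distance across tissues.  Walking the
dendrogram cut heights from low to high, the smallest cluster whose members
jointly cover every enzyme class of the pathway is selected as the candidate
gene set — the operational form of "a single co-expressed cluster
representing all known enzymes".
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator

from ._cluster import linkage_matrix
from ._utils import spearman_rows

__all__ = [
    "PathwayDefinition",
    "CandidateAssignment",
    "IRIDOID_PATHWAY",
    "TRITERPENOID_PATHWAY",
    "GALLOTANNIN_PATHWAY",
    "spearman_matrix",
    "cluster_transcripts",
    "select_pathway_cluster",
    "candidate_expression_report",
    "PathwayClusterSelector",
]


@dataclasses.dataclass(frozen=True)
class PathwayDefinition:
    """A named pathway with its ordered enzyme-class labels."""

    name: str
    enzyme_classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.enzyme_classes:
            raise ValueError("a pathway needs at least one enzyme class")
        if len(set(self.enzyme_classes)) != len(self.enzyme_classes):
            raise ValueError("enzyme-class labels must be unique")


#: The ten enzymes of the iridoid pathway, geranyl diphosphate synthase
#: through secologanin synthase.
IRIDOID_PATHWAY = PathwayDefinition(
    "iridoid",
    ("GPPS", "GES", "G10H", "8HGO", "IS", "IO", "7DLGT", "7DLH", "LAMT", "SLS"),
)
#: Eight enzymes of triterpenoid biosynthesis (mevalonate-route skeleton
#: enzymes through amyrin synthesis/oxidation).
TRITERPENOID_PATHWAY = PathwayDefinition(
    "triterpenoid", ("FPPS", "SQS", "SQE", "CBS", "LS", "CAS", "AS", "AO")
)
#: Five enzymes of gallotannin biosynthesis (shikimate-route entry enzymes
#: plus galloylation steps).
GALLOTANNIN_PATHWAY = PathwayDefinition(
    "gallotannin", ("DAHPS", "DHQS", "DHQ/SDH", "GGT", "GALT")
)


def spearman_matrix(
    em: pd.DataFrame, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Gene-gene tie-corrected Spearman correlation across tissues.

    Constant-expression genes (rank correlation undefined) are excluded from
    the result with a warning.  Requesting a gene absent from the matrix is
    an error.
    """
    if em.shape[1] < 3:
        raise ValueError("co-expression needs at least three tissues")
    if genes is not None:
        missing = [g for g in genes if g not in em.index]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing}")
        em = em.loc[list(genes)]
    values = em.to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"excluding constant-expression gene(s): {list(em.index[constant])}",
            stacklevel=2,
        )
        em = em.loc[~constant]
        values = values[~constant]
    corr = spearman_rows(values)
    return pd.DataFrame(corr, index=em.index, columns=em.index)


def cluster_transcripts(corr: pd.DataFrame, method: str = "average") -> np.ndarray:
    """Agglomerate transcripts on distance ``1 - rho``.

    Returns a scipy-compatible linkage matrix whose leaves are the rows of
    ``corr`` in order.  Rank-correlation distances on few tissues are
    discrete, so exact merge ties are routine; they are resolved
    deterministically by the smallest leaf index (see ``_cluster``), making
    the dendrogram independent of pool ordering.
    """
    if corr.isna().any().any():
        raise ValueError("correlation matrix contains missing entries")
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist[np.abs(dist) < 1e-12] = 0.0
    return linkage_matrix(dist, method=method)


@dataclasses.dataclass(frozen=True)
class CandidateAssignment:
    """The selected co-expressed cluster for one pathway."""

    pathway: str
    members: tuple[str, ...]
    classes_covered: tuple[str, ...]
    height: float
    member_classes: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        covered = set()
        for classes in self.member_classes.values():
            covered.update(classes)
        if not set(self.classes_covered) <= covered:
            raise ValueError("classes_covered inconsistent with member annotations")


def _partitions(linkage: np.ndarray, n_leaves: int):
    """Yield (cut_height, list-of-clusters-as-leaf-index-tuples) walking the
    dendrogram cut heights from low to high, starting below the first merge."""
    yield 0.0, [(i,) for i in range(n_leaves)]
    heights = np.unique(linkage[:, 2]) if linkage.size else []
    for h in heights:
        flat = hierarchy.fcluster(linkage, t=h, criterion="distance")
        clusters: dict[int, list[int]] = {}
        for leaf, lab in enumerate(flat):
            clusters.setdefault(lab, []).append(leaf)
        yield float(h), [tuple(v) for v in clusters.values()]


def select_pathway_cluster(
    linkage: np.ndarray,
    gene_ids: Sequence[str],
    annotation: pd.DataFrame,
    pathway: PathwayDefinition,
    max_cut_height: float | None = 0.25,
) -> CandidateAssignment | None:
    """Pick the smallest co-expressed dendrogram cluster covering every
    enzyme class.

    Cuts of the dendrogram are examined from low to high (each distinct
    merge height plus the all-singleton cut below the first merge).  Among
    clusters whose members' enzyme-class annotations jointly include every
    class of the pathway, the one with fewest members wins; ties go to the
    lower cut height and then to lexicographic member order.

    ``max_cut_height`` caps the cuts considered: the selected cluster must
    cohere at distance ``1 - rho`` at most the cap, i.e. mean within-cluster
    Spearman correlation at least ``1 - max_cut_height`` (0.75 by default).
    Without a cap, a chance chain of mutually uncorrelated genes that
    happens to cover all classes could be "selected" at a cut near height 1,
    where cluster membership carries no co-expression evidence; the cap
    keeps the rule faithful to its target, a highly co-expressed cluster.
    Pass ``None`` to search all heights.

    Returns ``None`` when no eligible cut produces a covering cluster.
    """
    gene_ids = list(gene_ids)
    needed = set(pathway.enzyme_classes)
    gene_classes = {
        g: tuple(lbl for lbl in annotation.at[g, "enzyme_class"] if lbl in needed)
        if g in annotation.index
        else ()
        for g in gene_ids
    }
    best: tuple | None = None
    for height, clusters in _partitions(linkage, len(gene_ids)):
        if max_cut_height is not None and height > max_cut_height:
            continue
        for leaf_idxs in clusters:
            covered = set()
            for i in leaf_idxs:
                covered.update(gene_classes[gene_ids[i]])
            if covered >= needed:
                members = tuple(sorted(gene_ids[i] for i in leaf_idxs))
                key = (len(members), height, members)
                if best is None or key < best[0]:
                    best = (key, members, height)
    if best is None:
        return None
    _, members, height = best
    return CandidateAssignment(
        pathway=pathway.name,
        members=members,
        classes_covered=tuple(
            c for c in pathway.enzyme_classes
            if any(c in gene_classes[m] for m in members)
        ),
        height=max(height, 0.0),
        member_classes={m: gene_classes[m] for m in members},
    )


class PathwayClusterSelector(BaseEstimator):
    """Estimator interface for pathway assignment by co-expression.

    Parameters
    ----------
    pathway : PathwayDefinition
        The enzyme classes that must all be represented in the selected
        cluster.
    linkage_method : {"average", "complete", "single"}, default "average"
        Agglomeration rule on distance 1 - rho.
    max_cut_height : float or None, default 0.25
        Highest dendrogram cut considered when selecting the covering
        cluster (None searches all heights); see
        :func:`select_pathway_cluster`.

    Attributes
    ----------
    assignment_ : CandidateAssignment or None
        The selected cluster (None if no cut covers all classes).
    members_ : tuple of str
        Convenience view of the selected transcript ids (empty if none).
    correlation_ : pandas.DataFrame
        Gene-gene Spearman matrix of the annotated pool.
    linkage_ : numpy.ndarray
        scipy linkage matrix over the pool.
    """

    def __init__(
        self,
        pathway: PathwayDefinition = IRIDOID_PATHWAY,
        linkage_method: str = "average",
        max_cut_height: float | None = 0.25,
    ):
        self.pathway = pathway
        self.linkage_method = linkage_method
        self.max_cut_height = max_cut_height

    def fit(self, X: pd.DataFrame, y=None, *, annotation: pd.DataFrame):
        """Fit on the expression matrix of the annotated candidate pool.

        ``X`` is genes x tissues; only genes carrying at least one of the
        pathway's enzyme-class labels in ``annotation`` enter the clustering.
        """
        needed = set(self.pathway.enzyme_classes)
        pool = [
            g
            for g in X.index
            if g in annotation.index
            and any(lbl in needed for lbl in annotation.at[g, "enzyme_class"])
        ]
        if not pool:
            raise ValueError("no transcripts annotated with the pathway's enzyme classes")
        self.correlation_ = spearman_matrix(X, pool)
        self.linkage_ = cluster_transcripts(self.correlation_, method=self.linkage_method)
        self.assignment_ = select_pathway_cluster(
            self.linkage_,
            list(self.correlation_.index),
            annotation,
            self.pathway,
            max_cut_height=self.max_cut_height,
        )
        self.members_ = self.assignment_.members if self.assignment_ else ()
        return self


def candidate_expression_report(
    assignment: CandidateAssignment, em: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-transcript FPKM table for the selected cluster plus tissue means.

    Rows are ordered by the pathway's enzyme-class order (a transcript sorts
    under its first covered class), then transcript id; a ``enzyme_class``
    column records the labels.
    """
    class_order = {c: k for k, c in enumerate(assignment.classes_covered)}

    def sort_key(gene: str):
        classes = assignment.member_classes.get(gene, ())
        first = min((class_order.get(c, len(class_order)) for c in classes), default=len(class_order))
        return (first, gene)

    members = sorted(assignment.members, key=sort_key)
    report = em.loc[members].copy()
    report.insert(
        0, "enzyme_class", [";".join(assignment.member_classes.get(g, ())) for g in members]
    )
    tissue_means = em.loc[list(assignment.members)].mean(axis=0)
    tissue_means.name = "mean_fpkm"
    return report, tissue_means
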