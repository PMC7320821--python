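"""Metabolome-guided prioritization of cytochrome P450 candidates.

The funnel has three stages.  CYP-annotated transcripts are first filtered on
length and expression (>= 500 bp and FPKM >= 5 in at least one tissue by
default).  Survivors are correlated (Spearman, across tissues) against the
intensity profiles of a metabolite class of interest; a transcript enters
tier 1 when its squared correlation with at least one class member exceeds
the threshold (R^2 > 0.85).  Tier-1 transcripts are then correlated against
the genes previously assigned to the pathway; those linked — at the same
threshold — to at least half of the pathway genes (rounded up) form tier 2,
the prioritized candidates.  The resulting gene-metabolite and gene-gene
edges are exportable as a Cytoscape-compatible SIF edge list.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import spearman_cross
from .io import MetaboliteMatrix

__all__ = [
    "IntegrationParams",
    "Edge",
    "CorrelationNetwork",
    "PrioritizedCandidates",
    "filter_candidates",
    "gene_metabolite_edges",
    "pathway_link_edges",
    "export_network",
    "read_network",
    "CypPrioritizer",
]


@dataclasses.dataclass(frozen=True)
class IntegrationParams:
    """Thresholds of the prioritization funnel.

    ``corr_threshold_r2`` is compared against squared Spearman rho (strict
    inequality).  With ``r2_mode="abs_rho"`` the absolute rho itself is
    compared instead, for sensitivity analysis.  ``inclusive`` controls
    whether the length/FPKM filters use >= (default) or strict >.
    ``positive_only`` (default) keeps only positively correlated edges:
    candidates participating in a pathway should co-accumulate with its
    metabolites and co-express with its genes, and at seven tissues a
    sign-blind threshold admits chance anti-correlated profiles.  Set it
    False for a sign-blind sensitivity analysis.
    """

    min_length_bp: int = 500
    min_fpkm: float = 5.0
    corr_threshold_r2: float = 0.85
    pathway_link_fraction: float = 0.5
    correlation_kind: str = "spearman"
    r2_mode: str = "rho_squared"
    inclusive: bool = True
    positive_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.corr_threshold_r2 <= 1:
            raise ValueError("corr_threshold_r2 must be in (0, 1]")
        if not 0 < self.pathway_link_fraction <= 1:
            raise ValueError("pathway_link_fraction must be in (0, 1]")
        if self.r2_mode not in ("rho_squared", "abs_rho"):
            raise ValueError("r2_mode must be 'rho_squared' or 'abs_rho'")

    def passes_threshold(self, rho: float) -> bool:
        if self.positive_only and rho <= 0:
            return False
        stat = rho * rho if self.r2_mode == "rho_squared" else abs(rho)
        return stat > self.corr_threshold_r2


@dataclasses.dataclass(frozen=True)
class Edge:
    source: str
    target: str
    rho: float
    kind: str  # "gene-metabolite" | "gene-pathway_gene"

    @property
    def rho2(self) -> float:
        return self.rho * self.rho


@dataclasses.dataclass
class CorrelationNetwork:
    """Typed nodes plus weighted correlation edges."""

    nodes: dict[str, str]  # id -> "gene" | "metabolite" | "pathway_gene"
    edges: list[Edge]

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValueError(f"edge {e.source}->{e.target} has unknown endpoint")
            if abs(e.rho) > 1 + 1e-12:
                raise ValueError(f"|rho| > 1 on edge {e.source}->{e.target}")


@dataclasses.dataclass(frozen=True)
class PrioritizedCandidates:
    tier1: tuple[str, ...]
    tier2: tuple[str, ...]
    link_counts: dict[str, int]
    required_links: int


def filter_candidates(
    annotation: pd.DataFrame, em: pd.DataFrame, params: IntegrationParams | None = None
) -> list[str]:
    """CYP-flagged transcripts passing the length and expression filters.

    A transcript qualifies when it is annotated as a CYP, its length meets
    ``min_length_bp`` and its maximum FPKM over tissues meets ``min_fpkm``
    (>= by default).  Annotated transcripts absent from the expression matrix
    are excluded with a warning.
    """
    params = params or IntegrationParams()
    cyps = annotation.index[annotation["is_cyp"]]
    missing = [g for g in cyps if g not in em.index]
    if missing:
        warnings.warn(
            f"{len(missing)} CYP transcript(s) absent from expression matrix; excluded",
            stacklevel=2,
        )
    present = [g for g in cyps if g in em.index]
    out = []
    for g in present:
        length = annotation.at[g, "length_bp"]
        peak = em.loc[g].max()
        if params.inclusive:
            ok = length >= params.min_length_bp and peak >= params.min_fpkm
        else:
            ok = length > params.min_length_bp and peak > params.min_fpkm
        if ok:
            out.append(g)
    return out


def _pairwise_edges(
    row_ids: Sequence[str],
    row_values: np.ndarray,
    col_ids: Sequence[str],
    col_values: np.ndarray,
    params: IntegrationParams,
    kind: str,
) -> list[Edge]:
    corr = spearman_cross(row_values, col_values)
    if np.isnan(corr).any():
        warnings.warn(
            "constant profile(s) encountered; affected pairs skipped", stacklevel=3
        )
    edges = []
    for i, g in enumerate(row_ids):
        for j, m in enumerate(col_ids):
            rho = corr[i, j]
            if not np.isnan(rho) and params.passes_threshold(rho):
                edges.append(Edge(source=g, target=m, rho=float(rho), kind=kind))
    return edges


def gene_metabolite_edges(
    genes: Sequence[str],
    em: pd.DataFrame,
    mm: MetaboliteMatrix,
    metabolite_class: str,
    params: IntegrationParams | None = None,
) -> tuple[list[Edge], list[str]]:
    """Correlate candidate genes against all metabolites of one class.

    Returns the surviving edges plus tier 1: genes keeping at least one edge.
    Expression and metabolite matrices must share at least three tissues
    (matched by column name).
    """
    params = params or IntegrationParams()
    genes = list(genes)
    shared = [t for t in em.columns if t in set(mm.intensities.columns)]
    if len(shared) < 3:
        raise ValueError("need at least three shared tissues for correlation")
    features = mm.features_of_class(metabolite_class)
    if not genes or not features:
        return [], []
    edges = _pairwise_edges(
        genes,
        em.loc[genes, shared].to_numpy(dtype=float),
        features,
        mm.intensities.loc[features, shared].to_numpy(dtype=float),
        params,
        "gene-metabolite",
    )
    tier1 = sorted({e.source for e in edges}, key=genes.index)
    return edges, tier1


def pathway_link_edges(
    tier1: Sequence[str],
    pathway_genes: Sequence[str],
    em: pd.DataFrame,
    params: IntegrationParams | None = None,
) -> tuple[list[Edge], PrioritizedCandidates]:
    """Correlate tier-1 genes against the assigned pathway genes.

    Edges are kept at the same threshold as the metabolite step; tier 2
    collects tier-1 genes linked to at least ``ceil(fraction * n_pathway)``
    pathway genes.  An empty tier 1 yields an empty (not erroneous) result.
    """
    params = params or IntegrationParams()
    tier1 = list(tier1)
    pathway_genes = list(pathway_genes)
    if not pathway_genes:
        raise ValueError("pathway gene set is empty")
    required = math.ceil(params.pathway_link_fraction * len(pathway_genes))
    if not tier1:
        return [], PrioritizedCandidates((), (), {}, required)
    edges = _pairwise_edges(
        tier1,
        em.loc[tier1].to_numpy(dtype=float),
        pathway_genes,
        em.loc[pathway_genes].to_numpy(dtype=float),
        params,
        "gene-pathway_gene",
    )
    counts = {g: 0 for g in tier1}
    for e in edges:
        counts[e.source] += 1
    tier2 = tuple(g for g in tier1 if counts[g] >= required)
    return edges, PrioritizedCandidates(tuple(tier1), tier2, counts, required)


# ---------------------------------------------------------------------------
# SIF export

_INTERACTION = {"gene-metabolite": "gm", "gene-pathway_gene": "gp"}
_INTERACTION_REV = {v: k for k, v in _INTERACTION.items()}


def export_network(net: CorrelationNetwork, prefix) -> tuple[Path, Path]:
    """Write the network as ``<prefix>.sif`` plus ``<prefix>.attrs.tsv``.

    The SIF file holds ``source<TAB>interaction<TAB>target`` lines; the
    attribute table carries edge rho/rho^2/kind and, below the edges, the
    node types.  ``read_network`` reverses the export exactly.
    """
    prefix = Path(prefix)
    sif_path = prefix.with_suffix(".sif")
    attr_path = prefix.with_suffix(".attrs.tsv")
    with open(sif_path, "w") as fh:
        for e in net.edges:
            fh.write(f"{e.source}\t{_INTERACTION[e.kind]}\t{e.target}\n")
    with open(attr_path, "w") as fh:
        fh.write("record\tid1\tid2\trho\trho2\tkind\n")
        for e in net.edges:
            fh.write(
                f"edge\t{e.source}\t{e.target}\t{e.rho:.12g}\t{e.rho2:.12g}\t{e.kind}\n"
            )
        for node, ntype in sorted(net.nodes.items()):
            fh.write(f"node\t{node}\t\t\t\t{ntype}\n")
    return sif_path, attr_path


def read_network(prefix) -> CorrelationNetwork:
    """Read a network written by :func:`export_network`."""
    prefix = Path(prefix)
    attr_path = prefix.with_suffix(".attrs.tsv")
    nodes: dict[str, str] = {}
    edges: list[Edge] = []
    with open(attr_path) as fh:
        header = fh.readline()
        if not header.startswith("record\t"):
            raise ValueError(f"{attr_path}: unrecognized attribute header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "edge":
                edges.append(
                    Edge(source=parts[1], target=parts[2], rho=float(parts[3]), kind=parts[5])
                )
            elif parts[0] == "node":
                nodes[parts[1]] = parts[5]
    return CorrelationNetwork(nodes=nodes, edges=edges)


class CypPrioritizer(BaseEstimator):
    """End-to-end CYP prioritization as a fit-shaped estimator.

    Parameters mirror :class:`IntegrationParams`; ``metabolite_class`` names
    the metadata class whose features drive tier 1.

    Attributes
    ----------
    candidates_ : list of str
        CYPs passing the length/FPKM filter.
    tier1_ : tuple of str
        Candidates correlated with >=1 class metabolite above threshold.
    tier2_ : tuple of str
        Tier-1 genes linked to >= ceil(fraction x n_pathway) pathway genes.
    link_counts_ : dict
        Pathway-gene link count per tier-1 gene.
    network_ : CorrelationNetwork
        All surviving edges with typed nodes, ready for export.
    """

    def __init__(
        self,
        metabolite_class: str = "iridoid",
        min_length_bp: int = 500,
        min_fpkm: float = 5.0,
        corr_threshold_r2: float = 0.85,
        pathway_link_fraction: float = 0.5,
        r2_mode: str = "rho_squared",
        inclusive: bool = True,
        positive_only: bool = True,
    ):
        self.metabolite_class = metabolite_class
        self.min_length_bp = min_length_bp
        self.min_fpkm = min_fpkm
        self.corr_threshold_r2 = corr_threshold_r2
        self.pathway_link_fraction = pathway_link_fraction
        self.r2_mode = r2_mode
        self.inclusive = inclusive
        self.positive_only = positive_only

    def _params(self) -> IntegrationParams:
        return IntegrationParams(
            min_length_bp=self.min_length_bp,
            min_fpkm=self.min_fpkm,
            corr_threshold_r2=self.corr_threshold_r2,
            pathway_link_fraction=self.pathway_link_fraction,
            r2_mode=self.r2_mode,
            inclusive=self.inclusive,
            positive_only=self.positive_only,
        )

    def fit(
        self,
        X: pd.DataFrame,
        y=None,
        *,
        annotation: pd.DataFrame,
        metabolites: MetaboliteMatrix,
        pathway_genes: Sequence[str],
    ):
        """Run the funnel on an expression matrix ``X`` (genes x tissues)."""
        params = self._params()
        self.candidates_ = filter_candidates(annotation, X, params)
        gm_edges, tier1 = gene_metabolite_edges(
            self.candidates_, X, metabolites, self.metabolite_class, params
        )
        gp_edges, prioritized = pathway_link_edges(tier1, pathway_genes, X, params)
        self.tier1_ = prioritized.tier1
        self.tier2_ = prioritized.tier2
        self.link_counts_ = prioritized.link_counts
        self.required_links_ = prioritized.required_links
        nodes: dict[str, str] = {g: "gene" for g in tier1}
        for e in gm_edges:
            nodes.setdefault(e.target, "metabolite")
        for g in pathway_genes:
            nodes[g] = "pathway_gene"
        kept_gm = [e for e in gm_edges if e.source in set(tier1)]
        self.network_ = CorrelationNetwork(nodes=nodes, edges=kept_gm + gp_edges)
        assert set(self.tier2_) <= set(self.tier1_) <= set(self.candidates_)
        return self
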