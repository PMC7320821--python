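"""CYP prioritization funnel: filtering, correlation edges, tiers, export."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from omicforge import simulate
from omicforge.integrate import (
    CorrelationNetwork,
    CypPrioritizer,
    Edge,
    IntegrationParams,
    export_network,
    filter_candidates,
    gene_metabolite_edges,
    pathway_link_edges,
    read_network,
)
from omicforge.io import MetaboliteMatrix
from omicforge.pathway import PathwayClusterSelector, IRIDOID_PATHWAY

TISSUES = [f"t{j}" for j in range(7)]


def _annot(entries):
    """entries: {gene: (length, is_cyp)}"""
    return pd.DataFrame(
        {
            "length_bp": [v[0] for v in entries.values()],
            "enzyme_class": [() for _ in entries],
            "is_cyp": [v[1] for v in entries.values()],
        },
        index=pd.Index(entries.keys(), name="transcript_id"),
    )


def _mm(values, ids):
    intensities = pd.DataFrame(values, index=ids, columns=TISSUES)
    meta = pd.DataFrame(
        {"neutral_mass": 400.0, "compound_class": "iridoid", "name": ""},
        index=intensities.index,
    )
    return MetaboliteMatrix(intensities=intensities, metadata=meta)


class TestFilterCandidates:
    def test_inclusive_boundaries_retained(self):
        em = pd.DataFrame([[5.0] + [0.1] * 6], index=["g1"], columns=TISSUES)
        annot = _annot({"g1": (500, True)})
        assert filter_candidates(annot, em) == ["g1"]

    def test_strict_mode_drops_boundary(self):
        em = pd.DataFrame([[5.0] + [0.1] * 6], index=["g1"], columns=TISSUES)
        annot = _annot({"g1": (500, True)})
        assert filter_candidates(annot, em, IntegrationParams(inclusive=False)) == []

    def test_non_cyp_excluded_regardless(self):
        em = pd.DataFrame([[100.0] * 7], index=["g1"], columns=TISSUES)
        annot = _annot({"g1": (10000, False)})
        assert filter_candidates(annot, em) == []

    def test_missing_from_expression_warns(self):
        em = pd.DataFrame([[10.0] * 7], index=["g1"], columns=TISSUES)
        annot = _annot({"g1": (800, True), "g2": (800, True)})
        with pytest.warns(UserWarning, match="absent"):
            out = filter_candidates(annot, em)
        assert out == ["g1"]

    def test_matches_direct_enumeration_on_large_pool(self, rng):
        # pool of 822 CYP-flagged transcripts with varied lengths and peaks
        n = 822
        ids = [f"cyp{i}" for i in range(n)]
        lengths = rng.integers(200, 2000, size=n)
        em = pd.DataFrame(
            np.exp(rng.normal(1.0, 1.2, size=(n, 7))), index=ids, columns=TISSUES
        )
        annot = _annot({g: (int(L), True) for g, L in zip(ids, lengths)})
        got = filter_candidates(annot, em)
        expected = [
            g
            for g, L in zip(ids, lengths)
            if L >= 500 and em.loc[g].max() >= 5.0
        ]
        assert got == expected
        assert 0 < len(got) < n


class TestGeneMetaboliteEdges:
    def test_identical_profile_kept(self):
        profile = np.arange(1.0, 8.0)
        em = pd.DataFrame([profile], index=["g"], columns=TISSUES)
        mm = _mm([profile * 3], ["m"])
        edges, tier1 = gene_metabolite_edges(["g"], em, mm, "iridoid")
        assert tier1 == ["g"]
        assert edges[0].rho == pytest.approx(1.0) and edges[0].rho2 > 0.85

    def test_single_adjacent_swap_retained_two_swaps_decided_by_rank_formula(self):
        base = np.arange(1.0, 8.0)
        one_swap = base[[1, 0, 2, 3, 4, 5, 6]]
        two_swaps = base[[1, 0, 3, 2, 4, 5, 6]]
        em = pd.DataFrame([base], index=["g"], columns=TISSUES)
        # rank-distance formula: rho = 1 - 6*sum(d^2)/(n(n^2-1)); n=7 -> /336
        rho_one = 1 - 6 * 2 / 336
        rho_two = 1 - 6 * 4 / 336
        assert rho_one == pytest.approx(0.9642857142857143)
        mm = _mm([one_swap, two_swaps], ["m1", "m2"])
        edges, tier1 = gene_metabolite_edges(["g"], em, mm, "iridoid")
        kept = {e.target: e.rho for e in edges}
        assert kept["m1"] == pytest.approx(rho_one)
        # two adjacent swaps: rho^2 = 0.9286^2 = 0.862 > 0.85 -> still kept
        assert kept["m2"] == pytest.approx(rho_two)
        assert rho_two**2 > 0.85

    def test_three_swaps_rejected(self):
        base = np.arange(1.0, 8.0)
        three = base[[1, 0, 3, 2, 5, 4, 6]]
        em = pd.DataFrame([base], index=["g"], columns=TISSUES)
        mm = _mm([three], ["m"])
        edges, tier1 = gene_metabolite_edges(["g"], em, mm, "iridoid")
        rho = 1 - 6 * 6 / 336
        assert rho**2 < 0.85 and edges == [] and tier1 == []

    def test_planted_tier1_recovery(self):
        config = simulate.default_config(seed=21, noise_sd=0.1, n_contigs=0)
        em, truth = simulate.generate_expression(config)
        annot = simulate.generate_annotation(config)
        mm, _ = simulate.generate_metabolites(config)
        genes = filter_candidates(annot, em)
        edges, tier1 = gene_metabolite_edges(genes, em, mm, "iridoid")
        planted = set(truth.linked_cyps["iridoid"])
        got = set(tier1)
        assert len(got & planted) / len(planted) >= 0.85  # recall
        assert len(got & planted) / max(len(got), 1) >= 0.5  # modest precision pre-tier2

    def test_insufficient_shared_tissues(self):
        em = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        mm = _mm([np.arange(7.0)], ["m"])
        with pytest.raises(ValueError, match="shared tissues"):
            gene_metabolite_edges(["g"], em, mm, "iridoid")


class TestPathwayLinkEdges:
    def test_required_links_is_ceiling(self):
        em = pd.DataFrame(
            np.exp(np.random.default_rng(0).normal(size=(32, 7))),
            index=[f"p{i}" for i in range(31)] + ["g"],
            columns=TISSUES,
        )
        _, prio = pathway_link_edges(["g"], [f"p{i}" for i in range(31)], em)
        assert prio.required_links == math.ceil(0.5 * 31) == 16

    def test_perfectly_correlated_gene_fully_linked(self):
        profile = np.arange(1.0, 8.0)
        ids = [f"p{i}" for i in range(5)] + ["g"]
        em = pd.DataFrame([profile * (i + 1) for i in range(6)], index=ids, columns=TISSUES)
        edges, prio = pathway_link_edges(["g"], ids[:5], em)
        assert prio.tier2 == ("g",)
        assert prio.link_counts["g"] == 5

    def test_empty_tier1_is_empty_result(self, rng):
        em = pd.DataFrame(np.exp(rng.normal(size=(3, 7))), index=list("abc"), columns=TISSUES)
        edges, prio = pathway_link_edges([], ["a", "b"], em)
        assert edges == [] and prio.tier2 == ()

    def test_tier2_subset_tier1(self, rng):
        em = pd.DataFrame(
            np.exp(rng.normal(size=(20, 7))), index=[f"x{i}" for i in range(20)], columns=TISSUES
        )
        _, prio = pathway_link_edges([f"x{i}" for i in range(5)], [f"x{i}" for i in range(5, 20)], em)
        assert set(prio.tier2) <= set(prio.tier1)


class TestThresholdMonotonicity:
    def test_raising_r2_never_adds_edges(self, rng):
        em = pd.DataFrame(
            np.exp(rng.normal(size=(10, 7))), index=[f"g{i}" for i in range(10)], columns=TISSUES
        )
        mm = _mm(np.exp(rng.normal(size=(6, 7))), [f"m{i}" for i in range(6)])
        genes = list(em.index)
        loose, _ = gene_metabolite_edges(genes, em, mm, "iridoid", IntegrationParams(corr_threshold_r2=0.3))
        tight, _ = gene_metabolite_edges(genes, em, mm, "iridoid", IntegrationParams(corr_threshold_r2=0.7))
        key = lambda es: {(e.source, e.target) for e in es}
        assert key(tight) <= key(loose)

    def test_raising_fraction_never_enlarges_tier2(self, rng):
        profile = np.arange(1.0, 8.0)
        ids = [f"p{i}" for i in range(6)] + ["g1", "g2"]
        rows = [profile + rng.normal(0, 0.4, 7) for _ in range(8)]
        em = pd.DataFrame(np.exp(np.vstack(rows)), index=ids, columns=TISSUES)
        tiers = []
        for frac in (0.25, 0.5, 0.75, 1.0):
            _, prio = pathway_link_edges(
                ["g1", "g2"], ids[:6], em, IntegrationParams(pathway_link_fraction=frac)
            )
            tiers.append(set(prio.tier2))
        for small, big in zip(tiers[1:], tiers):
            assert small <= big

    def test_abs_rho_mode_is_looser_at_same_threshold(self, rng):
        em = pd.DataFrame(
            np.exp(rng.normal(size=(8, 7))), index=[f"g{i}" for i in range(8)], columns=TISSUES
        )
        mm = _mm(np.exp(rng.normal(size=(5, 7))), [f"m{i}" for i in range(5)])
        genes = list(em.index)
        sq, _ = gene_metabolite_edges(genes, em, mm, "iridoid", IntegrationParams(r2_mode="rho_squared"))
        ab, _ = gene_metabolite_edges(genes, em, mm, "iridoid", IntegrationParams(r2_mode="abs_rho"))
        key = lambda es: {(e.source, e.target) for e in es}
        assert key(sq) <= key(ab)


class TestNetworkExport:
    def test_empty_network_round_trip(self, tmp_path):
        net = CorrelationNetwork(nodes={}, edges=[])
        export_network(net, tmp_path / "net")
        back = read_network(tmp_path / "net")
        assert back.nodes == {} and back.edges == []

    def test_toy_network_round_trip(self, tmp_path):
        nodes = {"g1": "gene", "m1": "metabolite", "p1": "pathway_gene"}
        edges = [
            Edge("g1", "m1", 0.96, "gene-metabolite"),
            Edge("g1", "p1", -0.93, "gene-pathway_gene"),
        ]
        net = CorrelationNetwork(nodes=nodes, edges=edges)
        sif, attrs = export_network(net, tmp_path / "net")
        assert sif.read_text().splitlines()[0] == "g1\tgm\tm1"
        back = read_network(tmp_path / "net")
        assert back.nodes == nodes
        assert [(e.source, e.target, e.kind) for e in back.edges] == [
            (e.source, e.target, e.kind) for e in edges
        ]
        assert all(abs(a.rho - b.rho) < 1e-12 for a, b in zip(back.edges, edges))

    def test_large_random_round_trip(self, tmp_path, rng):
        nodes = {f"n{i}": ("gene" if i % 2 else "metabolite") for i in range(200)}
        ids = list(nodes)
        edges = [
            Edge(ids[int(rng.integers(200))], ids[int(rng.integers(200))],
                 float(rng.uniform(-1, 1)), "gene-metabolite")
            for _ in range(1000)
        ]
        net = CorrelationNetwork(nodes=nodes, edges=edges)
        export_network(net, tmp_path / "net")
        back = read_network(tmp_path / "net")
        assert len(back.edges) == 1000
        assert all(
            a.source == b.source and a.target == b.target and abs(a.rho - b.rho) < 1e-12
            for a, b in zip(back.edges, edges)
        )

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError, match="unknown endpoint"):
            CorrelationNetwork(nodes={"a": "gene"}, edges=[Edge("a", "b", 0.9, "gene-metabolite")])


class TestCypPrioritizerEndToEnd:
    def test_planted_pipeline_recovery(self):
        config = simulate.default_config(seed=33, n_contigs=0)
        em, truth = simulate.generate_expression(config)
        annot = simulate.generate_annotation(config)
        mm, _ = simulate.generate_metabolites(config)
        selector = PathwayClusterSelector(pathway=IRIDOID_PATHWAY).fit(em, annotation=annot)
        prio = CypPrioritizer().fit(
            em, annotation=annot, metabolites=mm, pathway_genes=list(selector.members_)
        )
        planted = set(truth.linked_cyps["iridoid"])
        got = set(prio.tier2_)
        assert len(got & planted) / len(planted) >= 0.85
        assert len(got & planted) / max(len(got), 1) >= 0.85
        assert set(prio.tier2_) <= set(prio.tier1_) <= set(prio.candidates_)

    def test_estimator_params_round_trip(self):
        est = CypPrioritizer(corr_threshold_r2=0.7)
        assert est.get_params()["corr_threshold_r2"] == 0.7
        est.set_params(min_fpkm=2.0)
        assert est._params().min_fpkm == 2.0
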