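"""Synthetic tissue-omics data with known ground truth.

Generates every input the pipeline consumes — an FPKM expression matrix, a
metabolite intensity matrix with mass/class metadata, a transcript annotation
table and contig sequences with planted microsatellites — with the
statistical structure the analysis assumes: co-expressed pathway modules
whose member genes share a tissue profile, metabolite classes tied to those
modules, decoy genes that share enzyme-class annotations but not expression,
planted "true" CYPs riding a module's profile among independent decoy CYPs,
and SSR motifs embedded at recorded coordinates in otherwise repeat-free
flanks.

The noise model is additive Gaussian on log intensities (log-normal
multiplicative noise).  Identical configurations (including the seed)
reproduce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import MetaboliteMatrix
from .metabolites import REFERENCE_COMPOUNDS, CompoundReference
from .pathway import (
    GALLOTANNIN_PATHWAY,
    IRIDOID_PATHWAY,
    TRITERPENOID_PATHWAY,
)
from .ssr import SSRParams, find_ssrs

__all__ = [
    "PlantedModule",
    "SynthConfig",
    "TruthBundle",
    "TISSUE_PRESETS",
    "default_modules",
    "default_config",
    "generate_expression",
    "generate_annotation",
    "generate_metabolites",
    "generate_contigs",
    "generate_dataset",
]

TISSUES = (
    "young_leaf",
    "mature_leaf",
    "young_stem",
    "mature_stem",
    "inflorescence",
    "pericarp",
    "seed",
)

#: Log-FPKM tissue profiles used by the default planted modules.  Values are
#: spaced ~0.6 log-units apart so tissue rank orders are well defined at the
#: default noise level (fold range across tissues roughly 40x, typical for
#: tissue-specific specialized metabolism).
TISSUE_PRESETS: dict[str, tuple[float, ...]] = {
    # young stem highest, inflorescence/pericarp next (iridoid-like trend)
    "young-stem-high": (1.8, 1.2, 4.2, 0.6, 3.6, 3.0, 2.4),
    # young stem then inflorescence, low in seed/leaf/pericarp (triterpenoid-like)
    "stem-inflorescence-high": (1.2, 0.6, 4.2, 2.4, 3.6, 1.8, 3.0),
    # young leaf then mature leaf and inflorescence (gallotannin-like)
    "leaf-high": (4.2, 3.6, 2.4, 0.6, 3.0, 1.2, 1.8),
    # seed-dominated accumulation
    "seed-high": (1.2, 0.6, 2.4, 1.8, 3.0, 3.6, 4.2),
}


@dataclasses.dataclass(frozen=True)
class PlantedModule:
    """A co-expressed pathway module planted in the synthetic data."""

    pathway_name: str
    enzyme_classes: tuple[str, ...]
    genes_per_class: int
    tissue_profile: tuple[float, ...]
    linked_metabolite_class: str | None = None
    n_linked_cyps: int = 0

    def __post_init__(self) -> None:
        if self.genes_per_class < 1:
            raise ValueError("each enzyme class needs at least one gene")
        if not self.enzyme_classes:
            raise ValueError("module needs at least one enzyme class")

    @property
    def n_genes(self) -> int:
        return self.genes_per_class * len(self.enzyme_classes)


def default_modules() -> tuple[PlantedModule, ...]:
    """Three modules mirroring the studied pathways: iridoids (10 enzyme
    classes, metabolite-linked, with planted true CYPs), triterpenoids (8)
    and gallotannins (5)."""
    return (
        PlantedModule(
            pathway_name=IRIDOID_PATHWAY.name,
            enzyme_classes=IRIDOID_PATHWAY.enzyme_classes,
            genes_per_class=3,
            tissue_profile=TISSUE_PRESETS["young-stem-high"],
            linked_metabolite_class="iridoid",
            n_linked_cyps=7,
        ),
        PlantedModule(
            pathway_name=TRITERPENOID_PATHWAY.name,
            enzyme_classes=TRITERPENOID_PATHWAY.enzyme_classes,
            genes_per_class=3,
            tissue_profile=TISSUE_PRESETS["stem-inflorescence-high"],
            linked_metabolite_class="triterpenoid",
        ),
        PlantedModule(
            pathway_name=GALLOTANNIN_PATHWAY.name,
            enzyme_classes=GALLOTANNIN_PATHWAY.enzyme_classes,
            genes_per_class=3,
            tissue_profile=TISSUE_PRESETS["leaf-high"],
            linked_metabolite_class="gallotannin",
        ),
    )


_DEFAULT_SSRS = (("A", 12), ("AG", 8), ("AAG", 6), ("ACGT", 5), ("AACGT", 5), ("AACGTC", 5))


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Full description of one synthetic dataset."""

    n_tissues: int = 7
    n_background_genes: int = 300
    modules: tuple[PlantedModule, ...] = dataclasses.field(default_factory=default_modules)
    n_decoys_per_class: int = 2
    n_metabolites_per_class: int = 15
    n_unlinked_metabolites: int = 30
    noise_sd: float = 0.15
    n_decoy_cyps: int = 200
    n_contigs: int = 100
    contig_length_range: tuple[int, int] = (300, 3000)
    planted_ssrs: tuple[tuple[str, int], ...] = _DEFAULT_SSRS
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for field in (
            "n_background_genes",
            "n_decoys_per_class",
            "n_metabolites_per_class",
            "n_unlinked_metabolites",
            "n_decoy_cyps",
            "n_contigs",
        ):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        for module in self.modules:
            if len(module.tissue_profile) != self.n_tissues:
                raise ValueError(
                    f"module {module.pathway_name!r}: tissue_profile length "
                    f"{len(module.tissue_profile)} != n_tissues {self.n_tissues}"
                )
        lo, hi = self.contig_length_range
        if lo < 50 or hi < lo:
            raise ValueError("contig_length_range must satisfy 50 <= lo <= hi")
        for motif, count in self.planted_ssrs:
            if not set(motif) <= set("ACGT"):
                raise ValueError(f"planted SSR motif {motif!r} has non-ACGT characters")
            if len(motif) * count > lo:
                raise ValueError(f"planted SSR {motif}x{count} exceeds minimum contig length")

    @property
    def tissue_ids(self) -> list[str]:
        if self.n_tissues == len(TISSUES):
            return list(TISSUES)
        return [f"tissue_{i + 1}" for i in range(self.n_tissues)]


def default_config(seed: int = 0, **overrides) -> SynthConfig:
    """The default study-shaped configuration with a chosen seed."""
    return dataclasses.replace(SynthConfig(seed=seed), **overrides)


@dataclasses.dataclass
class TruthBundle:
    """Ground truth for every planted entity."""

    module_genes: dict[str, tuple[str, ...]] = dataclasses.field(default_factory=dict)
    linked_cyps: dict[str, tuple[str, ...]] = dataclasses.field(default_factory=dict)
    decoy_genes: tuple[str, ...] = ()
    metabolite_classes: dict[str, str] = dataclasses.field(default_factory=dict)
    linked_metabolites: dict[str, tuple[str, ...]] = dataclasses.field(default_factory=dict)
    ssr_truth: list[dict] = dataclasses.field(default_factory=list)


# ---------------------------------------------------------------------------
# gene plan (deterministic naming shared by expression and annotation)


@dataclasses.dataclass(frozen=True)
class _GenePlan:
    gene_id: str
    classes: tuple[str, ...]
    is_cyp: bool
    module: PlantedModule | None  # None => independent profile
    role: str  # "module" | "linked_cyp" | "decoy" | "decoy_cyp" | "background"


def _gene_plan(config: SynthConfig) -> list[_GenePlan]:
    plan: list[_GenePlan] = []
    for module in config.modules:
        for cls in module.enzyme_classes:
            for j in range(module.genes_per_class):
                safe_cls = cls.replace("/", "-")
                plan.append(
                    _GenePlan(f"{module.pathway_name}_{safe_cls}_{j + 1}", (cls,), False, module, "module")
                )
        for j in range(module.n_linked_cyps):
            plan.append(
                _GenePlan(f"{module.pathway_name}_CYP_{j + 1}", (), True, module, "linked_cyp")
            )
    for module in config.modules:
        for cls in module.enzyme_classes:
            for j in range(config.n_decoys_per_class):
                safe_cls = cls.replace("/", "-")
                plan.append(
                    _GenePlan(f"decoy_{module.pathway_name}_{safe_cls}_{j + 1}", (cls,), False, None, "decoy")
                )
    for j in range(config.n_decoy_cyps):
        plan.append(_GenePlan(f"decoy_CYP_{j + 1}", (), True, None, "decoy_cyp"))
    for j in range(config.n_background_genes):
        plan.append(_GenePlan(f"bg_{j + 1}", (), False, None, "background"))
    return plan


def _independent_profile(rng: np.random.Generator, n_tissues: int) -> np.ndarray:
    # own mean log level plus per-tissue spread comparable to module profiles
    return rng.normal(loc=rng.uniform(0.5, 3.5), scale=1.2, size=n_tissues)


def generate_expression(config: SynthConfig) -> tuple[pd.DataFrame, TruthBundle]:
    """Simulate the FPKM matrix (genes x tissues) plus ground truth.

    Module genes (and planted CYPs) follow ``exp(profile + N(0, noise_sd^2))``;
    decoys and background genes each draw an independent tissue profile.
    Values are clipped at zero after optional dropout.
    """
    rng = np.random.default_rng([config.seed, 1])
    plan = _gene_plan(config)
    n_t = config.n_tissues
    rows = np.empty((len(plan), n_t))
    for i, g in enumerate(plan):
        base = (
            np.asarray(g.module.tissue_profile)
            if g.module is not None
            else _independent_profile(rng, n_t)
        )
        rows[i] = np.exp(base + rng.normal(0.0, config.noise_sd, size=n_t))
    if config.dropout_rate > 0:
        rows[rng.random(rows.shape) < config.dropout_rate] = 0.0
    np.clip(rows, 0.0, None, out=rows)
    em = pd.DataFrame(
        rows,
        index=pd.Index([g.gene_id for g in plan], name="gene_id"),
        columns=config.tissue_ids,
    )
    truth = TruthBundle(
        module_genes={
            m.pathway_name: tuple(g.gene_id for g in plan if g.module is m and g.role == "module")
            for m in config.modules
        },
        linked_cyps={
            m.pathway_name: tuple(
                g.gene_id for g in plan if g.module is m and g.role == "linked_cyp"
            )
            for m in config.modules
        },
        decoy_genes=tuple(g.gene_id for g in plan if g.role in ("decoy", "decoy_cyp")),
    )
    return em, truth


def generate_annotation(config: SynthConfig) -> pd.DataFrame:
    """Annotation table consistent with the gene plan.

    Planted module genes and linked CYPs get lengths passing the integration
    filter; decoy CYPs draw lengths from 200-2500 bp so some fail it.
    """
    rng = np.random.default_rng([config.seed, 4])
    plan = _gene_plan(config)
    lengths = []
    for g in plan:
        if g.role in ("module", "linked_cyp", "decoy"):
            lengths.append(int(rng.integers(600, 2500)))
        else:
            lengths.append(int(rng.integers(200, 2500)))
    return pd.DataFrame(
        {
            "length_bp": lengths,
            "enzyme_class": [g.classes for g in plan],
            "is_cyp": [g.is_cyp for g in plan],
        },
        index=pd.Index([g.gene_id for g in plan], name="transcript_id"),
    )


def generate_metabolites(
    config: SynthConfig, refs: Sequence[CompoundReference] = REFERENCE_COMPOUNDS
) -> tuple[MetaboliteMatrix, TruthBundle]:
    """Simulate metabolite features (rows) x tissues with mass metadata.

    Features linked to a module share its tissue profile plus independent
    log-normal noise; unlinked features draw independent profiles.  Each
    feature's neutral mass sits within a few ppm of a reference compound of
    its class (unlinked features use masses near arbitrary references), so
    ppm-window annotation is exercised realistically.
    """
    rng = np.random.default_rng([config.seed, 2])
    linked_classes = {
        m.linked_metabolite_class: m for m in config.modules if m.linked_metabolite_class
    }
    for cls in linked_classes:
        if not any(r.compound_class == cls for r in refs):
            refs = tuple(refs) + (CompoundReference(f"synthetic_{cls}", 400.0 + 7 * len(cls), cls),)
    feature_ids: list[str] = []
    profiles: list[np.ndarray] = []
    masses: list[float] = []
    classes: list[str] = []
    names: list[str] = []
    truth = TruthBundle()
    n_t = config.n_tissues
    for cls, module in linked_classes.items():
        class_refs = [r for r in refs if r.compound_class == cls]
        ids = []
        for j in range(config.n_metabolites_per_class):
            fid = f"{cls}_feat_{j + 1}"
            ref = class_refs[j % len(class_refs)]
            ppm_offset = rng.uniform(-5.0, 5.0)
            feature_ids.append(fid)
            ids.append(fid)
            profiles.append(
                np.exp(np.asarray(module.tissue_profile) + rng.normal(0, config.noise_sd, n_t))
            )
            masses.append(ref.neutral_mass * (1.0 + ppm_offset * 1e-6))
            classes.append(cls)
            names.append(ref.name)
            truth.metabolite_classes[fid] = cls
        truth.linked_metabolites[cls] = tuple(ids)
    for j in range(config.n_unlinked_metabolites):
        fid = f"unlinked_feat_{j + 1}"
        ref = refs[int(rng.integers(len(refs)))]
        feature_ids.append(fid)
        profiles.append(np.exp(_independent_profile(rng, n_t) + rng.normal(0, config.noise_sd, n_t)))
        masses.append(ref.neutral_mass * (1.0 + rng.uniform(-5.0, 5.0) * 1e-6))
        classes.append("other")
        names.append("")
        truth.metabolite_classes[fid] = "other"
    intensities = pd.DataFrame(
        np.vstack(profiles) if profiles else np.empty((0, n_t)),
        index=pd.Index(feature_ids, name="feature_id"),
        columns=config.tissue_ids,
    )
    metadata = pd.DataFrame(
        {"neutral_mass": masses, "compound_class": classes, "name": names},
        index=intensities.index,
    )
    return MetaboliteMatrix(intensities=intensities, metadata=metadata), truth


def _random_clean_flank(
    rng: np.random.Generator, length: int, params: SSRParams
) -> str:
    """Random sequence verified free of qualifying SSRs by the scanner."""
    bases = np.array(list("ACGT"))
    for _ in range(200):
        seq = "".join(rng.choice(bases, size=length))
        if not find_ssrs("flank", seq, params):
            return seq
    raise RuntimeError("could not generate an SSR-free flank")  # pragma: no cover


def generate_contigs(
    config: SynthConfig, params: SSRParams | None = None
) -> tuple[list[SeqRecord], TruthBundle]:
    """Simulate contigs with planted microsatellites at known coordinates.

    The planted SSR specs are cycled over the first ``len(planted_ssrs)``-fold
    of contigs; remaining contigs carry no SSR.  Flanks are random sequence
    re-screened by the scanner so that each planted repeat is the only
    qualifying SSR on its contig, and every contig (with or without a plant)
    is verified against the scanner before being emitted.
    """
    params = params or SSRParams()
    rng = np.random.default_rng([config.seed, 3])
    lo, hi = config.contig_length_range
    records: list[SeqRecord] = []
    truth = TruthBundle()
    specs = list(config.planted_ssrs)
    for i in range(config.n_contigs):
        length = int(rng.integers(lo, hi + 1))
        seq_id = f"contig_{i + 1}"
        if specs and i < (config.n_contigs // 2) * 2 and i % 2 == 0:
            motif, count = specs[(i // 2) % len(specs)]
            insert = motif * count
            for _ in range(100):
                pos = int(rng.integers(1, length - len(insert)))  # 0-based insert offset
                left = _random_clean_flank(rng, pos, params)
                right = _random_clean_flank(rng, length - pos - len(insert), params)
                seq = left + insert + right
                found = find_ssrs(seq_id, seq, params)
                if (
                    len(found) == 1
                    and found[0].motif == motif
                    and found[0].repeat_count == count
                    and found[0].start_bp == pos + 1
                ):
                    break
            else:  # pragma: no cover
                raise RuntimeError(f"failed to plant {motif}x{count} cleanly")
            truth.ssr_truth.append(
                {
                    "seq_id": seq_id,
                    "motif": motif,
                    "repeat_count": count,
                    "start_bp": pos + 1,
                    "end_bp": pos + len(insert),
                }
            )
        else:
            seq = _random_clean_flank(rng, length, params)
        records.append(SeqRecord(Seq(seq), id=seq_id, description=""))
    return records, truth


def generate_dataset(config: SynthConfig):
    """Generate every pipeline input at once.

    Returns ``(expression, annotation, metabolites, contigs, truth)`` where
    ``truth`` merges the per-generator truth bundles.
    """
    em, truth_e = generate_expression(config)
    annotation = generate_annotation(config)
    mm, truth_m = generate_metabolites(config)
    contigs, truth_c = generate_contigs(config)
    truth = TruthBundle(
        module_genes=truth_e.module_genes,
        linked_cyps=truth_e.linked_cyps,
        decoy_genes=truth_e.decoy_genes,
        metabolite_classes=truth_m.metabolite_classes,
        linked_metabolites=truth_m.linked_metabolites,
        ssr_truth=truth_c.ssr_truth,
    )
    return em, annotation, mm, contigs, truth
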