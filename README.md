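# omicforge

Tissue multi-omics analytics for plant specialized metabolism, built around
the workflow used to mine candidate biosynthesis genes in *Cornus
officinalis* (Japanese cornelian cherry): tissue-resolved transcriptome and
metabolome profiles are integrated by rank correlation to assign transcripts
to biosynthetic pathways and to prioritize cytochrome P450 (CYP) candidates
for specialized-metabolite pathways such as iridoids, triterpenoids and
gallotannins.

The package is for computational biologists who have (or simulate) a
genes × tissues FPKM matrix, a mass-feature × tissues metabolite matrix and
a homology-based transcript annotation, and want a tested, deterministic
implementation of the downstream analytics:

- **Pathway assignment by co-expression.** Transcripts annotated as enzymes
  of a pathway are clustered (average linkage on distance 1 − ρ, Spearman
  across tissues). Walking the dendrogram cuts from low to high, the
  smallest co-expressed cluster whose members jointly cover *every* enzyme
  class of the pathway is selected as the candidate gene set.
- **Metabolome-guided CYP prioritization.** CYP-annotated transcripts are
  filtered (length ≥ 500 bp, FPKM ≥ 5 in ≥ 1 tissue), then correlated
  against the metabolites of a class: tier 1 keeps genes with Spearman
  ρ² > 0.85 against ≥ 1 class metabolite; tier 2 keeps tier-1 genes linked
  at the same threshold to at least ⌈50%⌉ of the assigned pathway genes.
  Edges export as Cytoscape-compatible SIF.
- **Resource computations.** Contig statistics (N50, length-threshold
  counts), BUSCO-summary arithmetic, expression-presence accounting
  (shared / tissue-exclusive transcripts), MISA-style microsatellite (SSR)
  scanning with compound grouping and summary tables, internal-standard
  normalization, 10-ppm-window compound annotation, metabolite PCA and
  correlation clustering, and a longest-Met-ORF six-frame translator.
- **Synthetic data with ground truth.** A generator plants co-expressed
  pathway modules, linked metabolite classes, pathway-linked CYPs among
  decoys, and SSR motifs at known coordinates, so every stage is benchmarked
  against planted truth without any external download.

Core quantities, in the field's notation: Spearman ρ is the Pearson
correlation of average ranks across the *n* = 7 tissues; the integration
threshold is ρ² > 0.85 (i.e. |ρ| > 0.922, positive by default). N50 is the
length *L* such that contigs ≥ *L* cover ≥ half of the assembled bases. The
ppm mass error of a feature against a reference compound is
(m_obs − m_ref)/m_ref × 10⁶, accepted within ±10 ppm.

## Worked example

```python
from omicforge import simulate, assembly
from omicforge.pathway import IRIDOID_PATHWAY, PathwayClusterSelector
from omicforge.integrate import CypPrioritizer

config = simulate.default_config(seed=1)
expr, annot, metab, contigs, truth = simulate.generate_dataset(config)

stats = assembly.contig_stats([len(r.seq) for r in contigs])
print(f"contigs: {stats.n_contigs}, N50 = {stats.n50_bp} bp, mean = {stats.mean_bp} bp")

selector = PathwayClusterSelector(pathway=IRIDOID_PATHWAY).fit(expr, annotation=annot)
a = selector.assignment_
print(f"iridoid cluster: {len(a.members)} transcripts covering "
      f"{len(a.classes_covered)}/10 enzyme classes at height {a.height:.3f}")

prio = CypPrioritizer(metabolite_class="iridoid").fit(
    expr, annotation=annot, metabolites=metab, pathway_genes=list(selector.members_))
print(f"CYP funnel: {len(prio.candidates_)} filtered -> {len(prio.tier1_)} tier 1 "
      f"-> {len(prio.tier2_)} tier 2 (>= {prio.required_links_} pathway links)")
recovered = set(prio.tier2_) & set(truth.linked_cyps["iridoid"])
print(f"recovered {len(recovered)}/7 planted pathway-linked CYPs")
```

prints

```
contigs: 100, N50 = 2127 bp, mean = 1662 bp
iridoid cluster: 30 transcripts covering 10/10 enzyme classes at height 0.000
CYP funnel: 178 filtered -> 7 tier 1 -> 7 tier 2 (>= 15 pathway links)
recovered 7/7 planted pathway-linked CYPs
```

The simulated dataset plants one co-expressed module per pathway (30 iridoid
transcripts across the 10 enzyme classes GPPS…SLS), 15 iridoid mass-features
riding the same tissue profile, and 7 pathway-linked CYPs among 200 decoy
CYPs. The selector returns exactly the planted module (height 0 means its
members correlate perfectly at rank level), and the prioritization funnel
narrows 178 length/FPKM-filtered CYPs to the 7 planted ones.

The same steps are available from the shell:

```bash
omicforge simulate --seed 1 --outdir data/
omicforge assembly-stats data/contigs.fasta
omicforge ssr-scan data/contigs.fasta --out data/ssrs.tsv
omicforge pathway-assign data/expression.tsv data/annotation.tsv --pathway iridoid
omicforge integrate data/expression.tsv data/annotation.tsv \
    data/metabolites.tsv data/metabolite_meta.tsv --outdir data/integration
```

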