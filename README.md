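# symbiopsi

Comparative pseudogenization analysis for group-structured genome
cohorts, built around the contrast between free-living and symbiotic
dinoflagellate lineages (Suessiales: the free-living *Effrenium*-like
group `Ev` and outgroup `Po` versus the symbiotic `S1` and `S2` groups).

For genome-evolution researchers asking whether a symbiotic lifestyle
leaves a measurable footprint in genomes, the package provides a tested,
desk-scale implementation of:

- **Pseudogene calling** — each predicted protein is searched against
  the six reading frames of its *gene-masked* genome; matched regions
  with ≥ 75% amino-acid identity are pseudogene fragments, and
  co-oriented fragments < 1 kb apart are chained into one pseudogene.
- **The pseudogenization statistic Ψ** — for a homologous protein set
  *S* and taxon group *G*,

  Ψ(S, G) = n_pseudo(S, G) / n_genes(S, G),

  the ratio of pseudogene calls attributed to *S* over *G*'s taxa to the
  putatively functional proteins of *S* in *G*'s taxa.  Per set, groups
  are compared with a two-sided Fisher exact test on
  [[n_pseudo_a, n_genes_a], [n_pseudo_b, n_genes_b]]; a set is called
  directional (e.g. Ψ_S1 > Ψ_Ev) when p < 0.05.
- **Gene-structure and composition contrasts** — per-gene length, intron
  number/lengths, exon/intron fractions, region-wise GC, with exact or
  tie-corrected Wilcoxon rank-sum group comparisons.
- **Core k-mers** — canonical 23-mers shared by every genome in the
  cohort, and the fraction of them lying in repeat-annotated regions.
- **Lineage set accounting** — upset-style exclusive combination counts
  of homolog presence across groups, and per-node descendant counts on a
  species tree.
- **A synthetic cohort generator** — group-structured genomes with
  planted decayed pseudogene copies, group-specific intron/GC parameters
  and a shared repeat library, so the whole pipeline is testable with
  known truth and no downloads.

Orthogroups can be ingested from OrthoFinder `Orthogroups.tsv` files; a
simple built-in clusterer covers desk-scale cohorts.

## Worked example

Simulate the default cohort (8 taxa in 4 groups, 200 kb genomes, 150
gene families with a 2× higher pseudogene rate in the symbiotic groups),
call pseudogenes in one genome, and compare Ψ between groups:

```python
from symbiopsi import (
    CohortConfig, CallerConfig, StatConfig, simulate_cohort,
    call_pseudogenes, compute_psi, compare_psi, summarize_directions,
)
from symbiopsi.homology import assign_calls, cluster_proteins

cohort = simulate_cohort(CohortConfig(seed=1))
calls = [
    c
    for taxon in cohort.genomes
    for c in call_pseudogenes(
        cohort.proteomes[taxon], cohort.genomes[taxon],
        cohort.annotations[taxon], CallerConfig(), taxon=taxon,
    )
]
print(len(calls), "pseudogene calls")

table = cluster_proteins(cohort.proteomes)
records = compute_psi(assign_calls(calls, table), table, cohort.groups)
comps = compare_psi(records, "S1+S2", "Ev", StatConfig())
print(summarize_directions(comps))
```

Output:

```
1454 pseudogene calls
{('S1+S2', 'Ev'): {'a_gt_b': 0, 'b_gt_a': 0, 'none': 150}}
```

1454 loci are called across the eight genomes (99.5% of the cleanly
planted copies — realized amino-acid identity ≥ 0.85 — are recovered).
On this deliberately dense desk-scale cohort the < 1 kb chaining rule
merges many adjacent planted loci, which flattens the *called* per-set
counts; feeding the planted per-set counts through the same statistics
recovers the planted asymmetry (sets with significantly higher Ψ in the
symbiotic groups, none in the free-living direction).  See
`docs/methods.md` for why density matters and what the tests do and do
not show.

The same pipeline is available from the shell:

```sh
symbiopsi simulate --seed 1 --out cohort/
symbiopsi pseudogenes --genome cohort/Ev_1.genome.fasta \
    --gff cohort/Ev_1.gff3 --proteins cohort/Ev_1.proteins.fasta \
    --taxon Ev_1 --out Ev_1.pseudogenes.gff3
symbiopsi run --config pipeline.yaml   # full multi-stage run + manifest
```

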