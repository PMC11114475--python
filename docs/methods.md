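# Methods

## Scope and model system

`symbiopsi` implements the comparative-genomics core of a pseudogenization
study in a Suessiales-like cohort: taxa are partitioned into four groups —
the free-living *Effrenium*-like `Ev`, the earlier-branching largely
symbiotic `S1`, the later-branching symbiotic `S2`, and the free-living
outgroup `Po` — and the package quantifies, per group, pseudogene load
(the Ψ statistic), gene structure and composition (intron lengths and
density, region-wise GC), lineage-specific homolog-set sharing, and
cross-taxon core k-mer content.

## Pseudogene identification

Pseudogenes are called operationally, as translated-homology relics in
non-genic sequence:

1. **Masking.** Every annotated gene span (exons and introns) is replaced
   by `N`.  Fragments therefore can never arise inside genes.
2. **Translated search.** Each predicted protein is searched against all
   six reading frames of the masked genome (tBLASTn-style).  The kernel
   is seed-and-extend: exact 4-residue protein words anchor candidate
   loci; candidates within one protein length on a compatible diagonal
   band are grouped and re-aligned with a local Smith–Waterman over a
   padded window (BLOSUM62; a gap of length L costs 11 + L).  Windowed
   exact DP replaces the x-drop heuristic extension of large-scale search
   tools, which is unnecessary at the window sizes involved; the test
   suite shows the kernel equivalent to exhaustive translated
   Smith–Waterman on small instances.
3. **Fragment filters.** A match is kept when its amino-acid identity is
   ≥ 75% and its query span is ≥ 20 residues.  Identity is, by default,
   identical residue pairs over *all* alignment columns, gap columns
   included; the BLAST `pident` convention (gap columns excluded) is
   available via `identity_includes_gaps=False`.  The 20-residue floor
   suppresses spurious micro-hits; no e-value cutoff is applied, keeping
   the procedure identity-threshold-driven.  Overlapping same-frame
   fragments of one query are resolved to the highest score.
4. **Chaining.** Per scaffold and strand, fragments strictly less than
   1000 bp apart (measured end-to-start; touching or overlapping
   fragments always merge) are chained into one pseudogene call — the
   unique maximal chaining, equivalent to transitive closure.  Chains may
   mix fragments from different query proteins (a pseudogene is a locus,
   not a per-query hit) and may change reading frame between fragments
   (pseudogenes accumulate frameshifts), but never strand.
5. **Gene-aware splitting.** The distance rule alone can link fragments
   lying on either side of a masked gene.  A pseudogene call spanning an
   intact annotated gene is not a meaningful locus, so `call_pseudogenes`
   splits chains whose internal gap crosses a gene span
   (`CallerConfig.split_at_genes`, default on).  `chain_fragments` itself
   remains purely distance-based.

A call's representative query is its highest-scoring fragment's protein
(ties broken by query id), which also determines the call's homologous
set.

## The Ψ statistic

For homologous set *S* and group *G*, Ψ(S, G) = (pseudogene calls
attributed to *S* across *G*'s taxa) / (proteins of *S* in *G*'s taxa);
counts are pooled over the group's taxa because Ψ is a property of the
set, not of a taxon.  Ψ is undefined when the group holds no proteins of
the set; such sets are skipped in comparisons and logged.

Per set, two groups are compared by a two-sided Fisher exact test on
`[[n_pseudo_a, n_genes_a], [n_pseudo_b, n_genes_b]]` — chosen because it
is exact and count-native at the small per-set counts involved; a
conditional binomial ratio test is available as an alternative.  A set is
directional only when p < α (default 0.05) *and* the Ψ values differ.
Merged labels (`S1+S2`) pool counts before testing, which is equivalent
to testing a merged group directly.  No multiple-testing correction is
applied by default, matching per-set reporting at a fixed α; a
Benjamini–Hochberg option exists behind `StatConfig(fdr=True)`.

## Gene structure, composition, and rank-sum comparisons

Gene length is the genomic span (gene models are UTR-less, as typical for
dinoflagellate gene predictions); introns are the gaps between
consecutive exons; GC excludes ambiguity codes from numerator and
denominator, so the GC of a concatenation is the length-weighted mean of
its parts.  Group-level means pool genes within a group (not means of
per-taxon means): the pooled quantity is the primary one.

Group comparisons use the two-sided Wilcoxon rank-sum test: the exact
null distribution when both samples have n ≤ 12 and the pooled sample is
tie-free, otherwise the normal approximation with tie and continuity
correction; the method used is recorded per result, and degenerate input
(all values identical) yields p = 1 flagged `degenerate`.

The intron position profile maps intron midpoints to the normalized
5′→3′ axis of their gene (strand-aware) and bins them into quintiles, to
probe the 5′-bias signature expected under transposon-driven intron
expansion.

## Core k-mers

k-mers (default k = 23) are 2-bit packed into `uint64` (valid for
k ≤ 31) and stored as sorted unique arrays; windows containing `N` are
skipped, and each k-mer is canonicalized to the lexicographic minimum of
itself and its reverse complement (a flag disables canonicalization).
The core set is the intersection across all genomes.  A core k-mer
counts as "in repeats" for a genome when at least one of its occurrences
there overlaps a repeat interval by ≥ 1 bp (occurrence-based, matching
the per-taxon "in repetitive regions" summary); the per-occurrence
alternative is a flag.

## Homologous sets

Orthogroup tables in the OrthoFinder `Orthogroups.tsv` dialect are
ingested directly for real data.  The built-in stand-in clusterer is
single-linkage over pairwise local alignments (BLOSUM62, 11/1 gaps) with
identity ≥ 0.4 over aligned columns, coverage ≥ 0.5 of the shorter
protein, and alignment score ≥ 75.  The score floor plays the role
e-value cutoffs play in orthology tools: short chance windows between
unrelated proteins can reach 40% identity but score far below genuine
homolog alignments (Karlin–Altschul expectations put chance scores below
~50 at these sequence lengths, while within-family alignments score in
the hundreds).  Clustering is order-invariant by construction.

## The synthetic cohort

The generator emulates the comparative design of the target system, not
its scale.
Defaults (all overridable):

| parameter | Ev | S1 | S2 | Po | rationale |
|---|---|---|---|---|---|
| taxa per group | 2 | 2 | 2 | 2 | desk scale |
| genome length (bp) | 200 000 | 200 000 | 200 000 | 200 000 | desk scale |
| GC target | 0.51 | 0.51 | 0.46 | 0.46 | mirrors the measured genome-GC contrast (≈51% vs ≈46%) |
| intron length mean (bp) | 100 | 40 | 55 | 85 | preserves the ordering Ev > Po > S2 > S1 and the ≈2.5× Ev/S1 contrast at ~10× reduced absolute scale |
| introns per gene mean | 3.0 | 2.4 | 2.4 | 1.8 | density ordering Ev > S1 = S2 > Po, scaled from ≈18/14/14 |
| pseudogene rate (per gene) | 0.6 | 1.2 | 1.2 | 0.6 | 2× symbiotic/free-living contrast at genome-wide pseudogene-to-gene ratios within the observed ≈0.55–2.0 range |

Each of 150 gene families has two copies per taxon (gene duplication is
pervasive in these genomes); family ancestral proteins (40–60 residues)
are shared across taxa, and per-taxon copies diverge by 3% amino-acid
substitution plus independent codon choice.  Codon choice, intron bodies
and intergenic sequence are biased toward the group GC target (introns
carry GT…AG ends).  The per-set gene count (4 per group, 8 pooled) and
the 2× rate contrast were fixed by a prospective power calculation:
Fisher's exact test on per-set counts has essentially no power with 2
genes per side, while 4 genes per group yield a reliably positive median
directional excess across seeds.

Pseudogenes are modeled as duplication-then-decay — a copy of an extant
CDS receives per-site substitutions, an optional premature stop, optional
truncation to a contiguous 60–95% segment, and Poisson-distributed
frameshift indels — inserted into intergenic space, because the caller
detects pseudogenes by translated similarity of non-genic sequence.
Indels are kept ≥ 60 nt from segment ends and from each other so that
the in-frame pieces between them stay individually alignable; realized
amino-acid identity (fraction of retained codons with unchanged
translation, measured before indels) is recorded per copy as the
recovery oracle.  A library of repeat elements (5 × 600 bp, 2 copies per
genome) is planted identically in every genome, making its k-mers core
by construction.

Features are packed in random order onto 4 scaffolds with ≥ 30 bp random
intergenic gaps; infeasible packing raises an error carrying the sizes.
All randomness derives from one seed, with per-taxon substreams keyed by
a stable hash of the taxon name, so adding a taxon leaves the others
byte-identical.

### What the generator does not emulate

Realistic repeat taxonomy (LINE vs other classes), introner elements,
mRNA editing, assembly fragmentation/contamination, and — importantly —
genomic sparsity.  A 200 kb genome carrying ~600 features is about four
orders of magnitude denser than real 1–2 Gbp dinoflagellate genomes.  One
visible consequence: the < 1 kb chaining rule frequently merges adjacent
planted pseudogene loci, more so in the high-rate symbiotic groups, so
*called* per-set counts understate the planted contrast at desk scale.
The recovery tests therefore score recall by locus overlap, and the Ψ
calibration/power tests drive the statistical pipeline with the planted
per-set counts; `scripts/acceptance.py` reports both the caller-based
and the planted-count Ψ asymmetries, suffixed `_called` and `_planted`.
Passing tests demonstrate correctness of the machinery under these
conditions, not end-to-end effect sizes on gigabase genomes.

## Numerical and procedural choices

- Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
  is converted only at the I/O boundary.  Multi-isoform genes collapse to
  the longest-CDS mRNA (genes, not transcripts, are counted).
- The chaining boundary is strict: a 999 bp gap merges, 1000 bp splits.
- Representative-query ties break by lexicographic protein id; clusterer
  set ids follow each component's smallest member id — all outputs are
  deterministic given inputs and seed.
- Fisher p-values come from `scipy.stats.fisher_exact`; the suite checks
  them against exact integer hypergeometric enumeration (exhaustively
  for small tables, by randomized sweep up to margins of 60).  Exact
  Wilcoxon p-values are checked against full permutation enumeration for
  n ≤ 8 per side.
- The alignment kernel is checked against an independent Smith–Waterman
  (Gotoh) oracle with its own traceback on random ≤ 4 kb instances; the
  comparison allows coordinate shifts of ≤ 2 codons for equal-score
  alignment ties.
- Problem sizes in the test suite and acceptance script (200 kb genomes,
  8 taxa, 150 families; 20-seed calibration runs; 60 oracle instances)
  are the package's desk-scale defaults, chosen to keep a full run in
  minutes on one CPU.

## Known limitations

- The stand-in clusterer is O(n²) with a k-mer prefilter: fine for
  thousands of proteins, not for the ~800 k of a full-scale run — ingest
  real OrthoFinder output there.
- Pseudogene mechanism (processed vs duplicated), Ka/Ks, repeat
  pre-filtering, and GO enrichment are out of scope.
- How pseudogene calls are attributed to homologous sets and which
  per-set significance test to use are genuinely open choices; the
  representative-query rule and the Fisher test are this package's
  documented decisions.  Absolute significant-set counts from other
  implementations of the same fragment/chaining rules therefore need not
  be comparable — the direction of the asymmetry is the robust quantity.
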