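"""Group-structured multi-taxon genome cohorts with known ground truth.

The generator emulates the comparative design of a Suessiales-like study
cohort: taxa fall into four groups (free-living ``Ev`` and ``Po``,
symbiotic ``S1`` and ``S2``) whose genomes differ in GC content, intron
length and density, and in the rate at which decayed pseudogene copies of
gene-family members accumulate in intergenic space.  A small library of
repeat elements is planted identically in every genome so that cross-taxon
core k-mers exist by construction.

Pseudogenes are modeled as duplication-then-decay: a copy of an extant CDS
is mutated (substitutions, optional premature stop, truncation, frameshift
indels) and inserted into intergenic sequence, because the downstream
caller detects pseudogenes by translated similarity of non-genic sequence
to extant proteins.

All randomness flows from one integer seed; per-taxon substreams are
derived by stable hashing of taxon names, so adding a taxon does not
perturb the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io_formats import (
    GeneModel,
    GroupAssignment,
    Interval,
    OrthoGroupTable,
    SequenceRecord,
    write_bed,
    write_fasta,
    write_gff3,
    write_group_assignment,
    write_orthogroups,
)

_NT = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
_AA_TO_CODONS: Dict[str, List[str]] = {}
for codon, aa in _STANDARD.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_TO_CODONS.values():
    codons.sort()
_AMINO_ACIDS = sorted(_AA_TO_CODONS)
_STOP_CODONS = sorted(_STANDARD.stop_codons)
_CODON_TO_AA = dict(_STANDARD.forward_table)
_CODON_TO_AA.update({c: "*" for c in _STOP_CODONS})


@dataclass(frozen=True)
class DecayParams:
    """How a duplicated gene copy is degraded into a pseudogene.

    substitution_rate
        Per-nucleotide substitution probability.
    frameshift_rate
        Expected number of frame-disrupting indels per copy (Poisson).
    truncation_fraction
        Probability that a copy is truncated to a contiguous sub-segment.
    premature_stop_rate
        Probability that one internal codon is replaced by a stop.
    """

    substitution_rate: float = 0.04
    frameshift_rate: float = 0.4
    truncation_fraction: float = 0.3
    premature_stop_rate: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "substitution_rate",
            "truncation_fraction",
            "premature_stop_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frameshift_rate < 0:
            raise ValueError("frameshift_rate must be >= 0")


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    Per-group maps must share the same label set.  Defaults describe a
    desk-scale cohort (2 taxa per group, 200 kb genomes, 150 gene families
    with two copies per family per taxon) whose group contrasts mirror the
    study system: higher GC and longer/denser introns in the free-living
    ``Ev``, and a 2x higher pseudogene rate in the symbiotic ``S1``/``S2``.
    """

    taxa_per_group: Dict[str, int] = field(
        default_factory=lambda: {"Ev": 2, "S1": 2, "S2": 2, "Po": 2}
    )
    n_families: int = 150
    genes_per_family_per_taxon: int = 2
    genome_length: int = 200_000
    n_scaffolds: int = 4
    gc_target: Dict[str, float] = field(
        default_factory=lambda: {"Ev": 0.51, "S1": 0.51, "S2": 0.46, "Po": 0.46}
    )
    intron_length_mean: Dict[str, float] = field(
        default_factory=lambda: {"Ev": 100.0, "S1": 40.0, "S2": 55.0, "Po": 85.0}
    )
    introns_per_gene_mean: Dict[str, float] = field(
        default_factory=lambda: {"Ev": 3.0, "S1": 2.4, "S2": 2.4, "Po": 1.8}
    )
    pseudogene_rate: Dict[str, float] = field(
        default_factory=lambda: {"Ev": 0.6, "S1": 1.2, "S2": 1.2, "Po": 0.6}
    )
    decay: DecayParams = field(default_factory=DecayParams)
    repeat_library_size: int = 5
    repeat_length: int = 600
    repeat_copies_per_genome: int = 2
    k_shared_repeat: int = 23
    cds_codons_range: Tuple[int, int] = (40, 60)
    aa_divergence: float = 0.03
    min_intron_length: int = 20
    min_intergenic_gap: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        labels = set(self.taxa_per_group)
        for name in (
            "gc_target",
            "intron_length_mean",
            "introns_per_gene_mean",
            "pseudogene_rate",
        ):
            m = getattr(self, name)
            if set(m) != labels:
                raise ValueError(
                    f"{name} labels {sorted(m)} != group labels {sorted(labels)}"
                )
        for label, gc in self.gc_target.items():
            if not 0.0 < gc < 1.0:
                raise ValueError(f"gc_target[{label}] must be in (0, 1)")
        for label, r in self.pseudogene_rate.items():
            if r < 0:
                raise ValueError(f"pseudogene_rate[{label}] must be >= 0")
        if not 1 <= self.k_shared_repeat <= 31:
            raise ValueError("k_shared_repeat must be in [1, 31]")

    @property
    def taxa(self) -> List[str]:
        return [
            f"{label}_{i + 1}"
            for label in self.taxa_per_group
            for i in range(self.taxa_per_group[label])
        ]

    def group_of(self, taxon: str) -> str:
        return taxon.rsplit("_", 1)[0]

    def group_assignment(self) -> GroupAssignment:
        return GroupAssignment({t: self.group_of(t) for t in self.taxa})


@dataclass
class PlantedPseudogene:
    taxon: str
    location: Interval
    family_id: str
    source_protein: str
    realized_identity: float
    truncated: bool
    n_frameshifts: int


@dataclass
class SyntheticTruth:
    """What was planted where: the oracle for recovery tests."""

    planted_pseudogenes: List[PlantedPseudogene]
    family_membership: Dict[str, str]  # protein id -> family id
    repeat_intervals: Dict[str, List[Interval]]  # taxon -> placed repeats
    group_effects: CohortConfig


@dataclass
class Cohort:
    genomes: Dict[str, List[SequenceRecord]]
    annotations: Dict[str, List[GeneModel]]
    proteomes: Dict[str, List[SequenceRecord]]
    truth: SyntheticTruth
    groups: GroupAssignment
    config: CohortConfig

    def family_table(self) -> OrthoGroupTable:
        """True family membership as an orthogroup table."""
        prot_taxon = {
            rec.id: taxon
            for taxon, recs in self.proteomes.items()
            for rec in recs
        }
        sets: Dict[str, Dict[str, List[str]]] = {}
        for prot, fam in self.truth.family_membership.items():
            taxon = prot_taxon[prot]
            sets.setdefault(fam, {t: [] for t in self.genomes})[taxon].append(prot)
        ordered = {fam: sets[fam] for fam in sorted(sets)}
        return OrthoGroupTable(ordered)


# ---------------------------------------------------------------------------
# sequence-level helpers


def _taxon_rng(seed: int, taxon: str) -> np.random.Generator:
    h = int.from_bytes(hashlib.sha256(taxon.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, h & 0x7FFFFFFF]))


def _stream_rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, tag]))


def random_nt(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_NT[rng.choice(4, size=length, p=p)])


def random_protein(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_AMINO_ACIDS), size=n_codons - 1)
    return "M" + "".join(_AMINO_ACIDS[i] for i in body)


def _codon_weights(gc: float) -> Dict[str, Tuple[List[str], np.ndarray]]:
    out = {}
    for aa, codons in _AA_TO_CODONS.items():
        w = np.array(
            [gc ** sum(c in "GC" for c in cod) * (1 - gc) ** sum(c in "AT" for c in cod)
             for cod in codons]
        )
        out[aa] = (codons, np.cumsum(w / w.sum()))
    return out


def back_translate(protein: str, gc: float, rng: np.random.Generator) -> str:
    """Choose synonymous codons with GC-content biased toward ``gc``."""
    weights = _codon_weights(gc)
    u = rng.random(len(protein))
    parts = []
    for aa, ui in zip(protein, u):
        codons, cum = weights[aa]
        parts.append(codons[int(np.searchsorted(cum, ui))])
    return "".join(parts)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(seq: str) -> str:
    return str(Seq(seq).translate())


# ---------------------------------------------------------------------------
# decay


def decay_sequence(
    cds: SequenceRecord, params: DecayParams, rng: np.random.Generator
) -> SequenceRecord:
    """Degrade a CDS copy into a pseudogene sequence.

    Applies, in order: per-site substitutions, an optional premature stop
    codon, optional truncation to a contiguous segment, and frame-shifting
    indels.  Indels are kept >= 60 nt from the ends and from each other so
    that the in-frame segments between them stay individually alignable.

    The realized amino-acid identity to the source -- the fraction of
    retained codons whose translation is unchanged, measured before indels
    -- is recorded in the output description.
    """
    seq = list(cds.seq)
    n_codons = len(seq) // 3
    if n_codons * 3 != len(seq):
        raise ValueError("CDS length must be divisible by 3")

    # substitutions
    hits = np.flatnonzero(rng.random(len(seq)) < params.substitution_rate)
    for pos in hits:
        alts = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alts[rng.integers(3)]

    # premature stop
    if n_codons >= 8 and rng.random() < params.premature_stop_rate:
        ci = int(rng.integers(n_codons // 4, 3 * n_codons // 4))
        stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
        seq[3 * ci : 3 * ci + 3] = list(stop)

    # per-codon amino-acid preservation, relative to the source
    mutated = "".join(seq)
    same = np.array(
        [
            _CODON_TO_AA[cds.seq[3 * i : 3 * i + 3]]
            == _CODON_TO_AA[mutated[3 * i : 3 * i + 3]]
            for i in range(n_codons)
        ]
    )

    # truncation to a contiguous run of codons
    truncated = rng.random() < params.truncation_fraction
    if truncated:
        keep = max(1, int(round(n_codons * rng.uniform(0.6, 0.95))))
        keep = min(keep, n_codons - 1) if n_codons > 1 else n_codons
        start = int(rng.integers(0, n_codons - keep + 1))
        seq = seq[3 * start : 3 * (start + keep)]
        same = same[start : start + keep]
    identity = float(same.mean()) if len(same) else 0.0

    # frameshift indels, spaced so inter-indel segments remain alignable
    n_shift = int(rng.poisson(params.frameshift_rate))
    margin = 60
    positions: List[int] = []
    for _ in range(n_shift):
        lo, hi = margin, len(seq) - margin
        candidates = [
            p for p in range(lo, hi)
            if all(abs(p - q) >= margin for q in positions)
        ]
        if not candidates:
            break
        positions.append(int(rng.choice(candidates)))
    for pos in sorted(positions, reverse=True):
        width = int(rng.integers(1, 3))  # 1 or 2 nt: always frame-breaking
        if rng.random() < 0.5:
            del seq[pos : pos + width]
        else:
            ins = [_NT[rng.integers(4)] for _ in range(width)]
            seq[pos:pos] = ins

    return SequenceRecord(
        id=f"{cds.id}_decayed",
        seq="".join(seq),
        moltype="nt",
        description=(
            f"identity={identity:.4f} source={cds.id} "
            f"truncated={int(truncated)} frameshifts={len(positions)}"
        ),
    )


def _parse_decay(description: str) -> Tuple[float, bool, int]:
    kv = dict(tok.split("=", 1) for tok in description.split() if "=" in tok)
    return float(kv["identity"]), bool(int(kv["truncated"])), int(kv["frameshifts"])


# ---------------------------------------------------------------------------
# cohort assembly


def _build_gene(
    cds_seq: str,
    rng: np.random.Generator,
    introns_mean: float,
    intron_len_mean: float,
    min_intron: int,
    gc: float,
) -> Tuple[str, List[Tuple[int, int]]]:
    """Interleave a CDS with introns; returns (region seq, relative exons)."""
    n_introns = int(rng.poisson(introns_mean))
    max_cuts = max(0, (len(cds_seq) - 10) // 20)
    n_introns = min(n_introns, max_cuts)
    cuts: List[int] = []
    if n_introns:
        candidates = np.arange(10, len(cds_seq) - 9)
        for _ in range(n_introns):
            ok = [c for c in candidates if all(abs(c - x) >= 10 for x in cuts)]
            if not ok:
                break
            cuts.append(int(rng.choice(ok)))
        cuts.sort()
    pieces = []
    prev = 0
    for c in cuts:
        pieces.append(cds_seq[prev:c])
        prev = c
    pieces.append(cds_seq[prev:])

    region_parts: List[str] = []
    exons: List[Tuple[int, int]] = []
    offset = 0
    for i, piece in enumerate(pieces):
        region_parts.append(piece)
        exons.append((offset, offset + len(piece)))
        offset += len(piece)
        if i < len(pieces) - 1:
            mean_extra = max(1.0, intron_len_mean - min_intron)
            ilen = min_intron + int(rng.geometric(1.0 / mean_extra))
            intron = "GT" + random_nt(rng, ilen - 4, gc) + "AG"
            region_parts.append(intron)
            offset += ilen
    return "".join(region_parts), exons


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate genomes, annotations, proteomes and truth for one cohort.

    Deterministic under ``config.seed``.  Raises ``ValueError`` when the
    requested features cannot be packed into ``genome_length`` (with the
    offending sizes in the message).
    """
    # shared, taxon-independent material
    fam_rng = _stream_rng(config.seed, 101)
    lo, hi = config.cds_codons_range
    family_lengths = fam_rng.integers(lo, hi + 1, size=config.n_families)
    family_proteins = [
        random_protein(fam_rng, int(n)) for n in family_lengths
    ]
    rep_rng = _stream_rng(config.seed, 202)
    repeat_library = [
        SequenceRecord(f"REP{i:02d}", random_nt(rep_rng, config.repeat_length, 0.5))
        for i in range(config.repeat_library_size)
    ]

    genomes: Dict[str, List[SequenceRecord]] = {}
    annotations: Dict[str, List[GeneModel]] = {}
    proteomes: Dict[str, List[SequenceRecord]] = {}
    planted: List[PlantedPseudogene] = []
    family_membership: Dict[str, str] = {}
    repeat_intervals: Dict[str, List[Interval]] = {}

    for taxon in config.taxa:
        label = config.group_of(taxon)
        rng = _taxon_rng(config.seed, taxon)
        gc = config.gc_target[label]

        # genes: per family, per copy
        features: List[Tuple[str, dict]] = []  # (kind, payload)
        taxon_proteins: List[SequenceRecord] = []
        gene_cds: Dict[str, str] = {}
        for fi, ancestral in enumerate(family_proteins):
            fam_id = f"F{fi:04d}"
            for copy in range(config.genes_per_family_per_taxon):
                prot = list(ancestral)
                n_mut = rng.binomial(len(prot), config.aa_divergence)
                for pos in rng.choice(len(prot), size=n_mut, replace=False):
                    prot[pos] = _AMINO_ACIDS[rng.integers(len(_AMINO_ACIDS))]
                prot_seq = "".join(prot)
                gene_id = f"{taxon}_g{fi:04d}_{copy + 1}"
                cds_seq = back_translate(prot_seq, gc, rng)
                region, exons = _build_gene(
                    cds_seq,
                    rng,
                    config.introns_per_gene_mean[label],
                    config.intron_length_mean[label],
                    config.min_intron_length,
                    gc,
                )
                strand = "+" if rng.random() < 0.5 else "-"
                features.append(
                    (
                        "gene",
                        dict(
                            gene_id=gene_id,
                            seq=region if strand == "+" else reverse_complement(region),
                            exons=exons,
                            region_len=len(region),
                            strand=strand,
                        ),
                    )
                )
                taxon_proteins.append(
                    SequenceRecord(gene_id, prot_seq, "aa", f"family={fam_id}")
                )
                family_membership[gene_id] = fam_id
                gene_cds[gene_id] = cds_seq

        # pseudogenes: decayed copies of this taxon's own genes
        rate = config.pseudogene_rate[label]
        for prot_rec in taxon_proteins:
            gene_id = prot_rec.id
            fam_id = family_membership[gene_id]
            for k in range(int(rng.poisson(rate))):
                source = SequenceRecord(gene_id, gene_cds[gene_id], "nt")
                decayed = decay_sequence(source, config.decay, rng)
                identity, trunc, nshift = _parse_decay(decayed.description)
                strand = "+" if rng.random() < 0.5 else "-"
                seq = decayed.seq if strand == "+" else reverse_complement(decayed.seq)
                features.append(
                    (
                        "pseudogene",
                        dict(
                            seq=seq,
                            strand=strand,
                            family_id=fam_id,
                            source=gene_id,
                            identity=identity,
                            truncated=trunc,
                            n_frameshifts=nshift,
                        ),
                    )
                )

        # shared repeats (identical across taxa)
        for rep in repeat_library:
            for _ in range(config.repeat_copies_per_genome):
                features.append(("repeat", dict(seq=rep.seq, rep_id=rep.id)))

        # packing
        total_feat = sum(len(f[1]["seq"]) for f in features)
        n_gaps = len(features) + config.n_scaffolds
        spare = config.genome_length - total_feat - n_gaps * config.min_intergenic_gap
        if spare < 0:
            raise ValueError(
                f"{taxon}: cannot pack {len(features)} features "
                f"({total_feat} bp) plus {n_gaps} gaps of >= "
                f"{config.min_intergenic_gap} bp into genome_length="
                f"{config.genome_length}; deficit {-spare} bp"
            )
        order = rng.permutation(len(features))
        extra = rng.multinomial(spare, np.full(n_gaps, 1.0 / n_gaps))
        gap_lengths = extra + config.min_intergenic_gap

        per_scaffold = int(np.ceil(len(features) / config.n_scaffolds))
        scaffolds: List[SequenceRecord] = []
        models: List[GeneModel] = []
        reps_here: List[Interval] = []
        gi = 0
        for si in range(config.n_scaffolds):
            name = f"{taxon}_scf{si + 1}"
            chunk = order[si * per_scaffold : (si + 1) * per_scaffold]
            parts: List[str] = []
            pos = 0
            for idx in chunk:
                gap = int(gap_lengths[gi])
                gi += 1
                parts.append(random_nt(rng, gap, gc))
                pos += gap
                kind, payload = features[idx]
                seq = payload["seq"]
                if kind == "gene":
                    rl = payload["region_len"]
                    if payload["strand"] == "+":
                        abs_exons = [
                            Interval(name, pos + s, pos + e, payload["strand"])
                            for s, e in payload["exons"]
                        ]
                    else:
                        abs_exons = [
                            Interval(name, pos + rl - e, pos + rl - s, payload["strand"])
                            for s, e in payload["exons"]
                        ]
                    models.append(
                        GeneModel(
                            gene_id=payload["gene_id"],
                            taxon=taxon,
                            scaffold=name,
                            strand=payload["strand"],
                            exons=abs_exons,
                            cds=list(abs_exons),
                        )
                    )
                elif kind == "pseudogene":
                    planted.append(
                        PlantedPseudogene(
                            taxon=taxon,
                            location=Interval(
                                name, pos, pos + len(seq), payload["strand"]
                            ),
                            family_id=payload["family_id"],
                            source_protein=payload["source"],
                            realized_identity=payload["identity"],
                            truncated=payload["truncated"],
                            n_frameshifts=payload["n_frameshifts"],
                        )
                    )
                else:
                    reps_here.append(Interval(name, pos, pos + len(seq), "."))
                parts.append(seq)
                pos += len(seq)
            gap = int(gap_lengths[gi])
            gi += 1
            parts.append(random_nt(rng, gap, gc))
            scaffolds.append(SequenceRecord(name, "".join(parts), "nt"))

        genomes[taxon] = scaffolds
        annotations[taxon] = sorted(
            models, key=lambda m: (m.scaffold, m.span.start)
        )
        proteomes[taxon] = taxon_proteins
        repeat_intervals[taxon] = reps_here

    truth = SyntheticTruth(
        planted_pseudogenes=planted,
        family_membership=family_membership,
        repeat_intervals=repeat_intervals,
        group_effects=config,
    )
    return Cohort(
        genomes=genomes,
        annotations=annotations,
        proteomes=proteomes,
        truth=truth,
        groups=config.group_assignment(),
        config=config,
    )


# ---------------------------------------------------------------------------
# species tree and on-disk layout


_GROUP_ORDER = ["Po", "S1", "Ev", "S2"]  # outgroup first, Ev sister to S2


def make_species_tree(groups: GroupAssignment) -> str:
    """Newick topology nesting groups as (Po,(S1,(Ev,S2))), taxa as leaves."""
    order = [g for g in _GROUP_ORDER if g in groups.labels]
    order += [g for g in groups.labels if g not in order]

    def clade(label: str) -> str:
        taxa = groups.taxa_of(label)
        return taxa[0] if len(taxa) == 1 else "(" + ",".join(taxa) + ")"

    tree = clade(order[-1])
    for label in reversed(order[:-1]):
        tree = f"({clade(label)},{tree})"
    return tree + ";"


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort as per-taxon FASTA/GFF3/BED plus cohort tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for taxon in cohort.genomes:
        write_fasta(cohort.genomes[taxon], outdir / f"{taxon}.genome.fasta")
        write_gff3(cohort.annotations[taxon], outdir / f"{taxon}.gff3")
        write_fasta(cohort.proteomes[taxon], outdir / f"{taxon}.proteins.fasta")
        write_bed(
            cohort.truth.repeat_intervals[taxon], outdir / f"{taxon}.repeats.bed"
        )
    write_group_assignment(cohort.groups, outdir / "groups.tsv")
    with open(outdir / "tree.nwk", "w") as fh:
        fh.write(make_species_tree(cohort.groups) + "\n")
    write_orthogroups(cohort.family_table(), outdir / "families.tsv")
    with open(outdir / "truth_pseudogenes.tsv", "w") as fh:
        fh.write(
            "taxon\tscaffold\tstart\tend\tstrand\tfamily\tsource_protein\t"
            "identity\ttruncated\tn_frameshifts\n"
        )
        for p in cohort.truth.planted_pseudogenes:
            fh.write(
                f"{p.taxon}\t{p.location.scaffold}\t{p.location.start}\t"
                f"{p.location.end}\t{p.location.strand}\t{p.family_id}\t"
                f"{p.source_protein}\t{p.realized_identity:.4f}\t"
                f"{int(p.truncated)}\t{p.n_frameshifts}\n"
            )
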