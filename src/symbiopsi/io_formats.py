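"""Readers and writers for the external formats the pipeline touches.

Every coordinate held in memory is 0-based half-open on the forward strand
of its scaffold; GFF3 (1-based inclusive) is converted at this boundary and
nowhere else.  BED input is already 0-based half-open and is kept as-is.

FASTA ids are tokenized at the first whitespace, matching the id convention
of proteome files and orthogroup tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import dendropy
import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence.

    ``moltype`` is ``"nt"`` (alphabet ACGTN) or ``"aa"`` (20 amino acids
    plus X and *).  Sequences are stored uppercase.
    """

    id: str
    seq: str
    moltype: str = "nt"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        self.seq = self.seq.upper()
        if not self.seq:
            raise FormatError(f"sequence {self.id!r} is empty")
        alphabet = NT_ALPHABET if self.moltype == "nt" else AA_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"outside the {self.moltype} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open 0-based genomic interval, strand in {+, -, .}."""

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise FormatError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """Exon/CDS structure of one gene on a scaffold, strand-aware.

    ``exons`` are sorted, non-overlapping forward-strand intervals; introns
    are the gaps between consecutive exons.  The gene span is
    ``[exons[0].start, exons[-1].end)`` regardless of strand.
    """

    gene_id: str
    taxon: str
    scaffold: str
    strand: str
    exons: List[Interval]
    cds: List[Interval]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")

    @property
    def span(self) -> Interval:
        return Interval(
            self.scaffold, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def gene_length(self) -> int:
        return self.span.length

    @property
    def introns(self) -> List[Interval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(Interval(self.scaffold, a.end, b.start, self.strand))
        return out

    def spliced_cds(self, scaffold_seq: str) -> str:
        """Concatenated CDS sequence in coding (5'->3') orientation."""
        parts = [scaffold_seq[iv.start : iv.end] for iv in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class OrthoGroupTable:
    """Homologous protein sets: set_id -> taxon -> list of protein ids."""

    sets: Dict[str, Dict[str, List[str]]]

    def __post_init__(self) -> None:
        seen: Dict[str, str] = {}
        for set_id, by_taxon in self.sets.items():
            for taxon, prots in by_taxon.items():
                for p in prots:
                    if p in seen and seen[p] != set_id:
                        raise FormatError(
                            f"protein {p!r} appears in sets "
                            f"{seen[p]!r} and {set_id!r}"
                        )
                    seen[p] = set_id

    @property
    def taxa(self) -> List[str]:
        names: List[str] = []
        for by_taxon in self.sets.values():
            for t in by_taxon:
                if t not in names:
                    names.append(t)
        return names

    def protein_to_set(self) -> Dict[str, str]:
        out: Dict[str, str] = {}
        for set_id, by_taxon in self.sets.items():
            for prots in by_taxon.values():
                for p in prots:
                    out[p] = set_id
        return out

    def protein_to_taxon(self) -> Dict[str, str]:
        out: Dict[str, str] = {}
        for by_taxon in self.sets.values():
            for taxon, prots in by_taxon.items():
                for p in prots:
                    out[p] = taxon
        return out


@dataclass
class GroupAssignment:
    """Taxon -> group label (e.g. Ev, S1, S2, Po)."""

    groups: Dict[str, str]

    def label(self, taxon: str) -> str:
        try:
            return self.groups[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} has no group label") from None

    def taxa_of(self, label: str) -> List[str]:
        return [t for t, g in self.groups.items() if g == label]

    @property
    def labels(self) -> List[str]:
        out: List[str] = []
        for g in self.groups.values():
            if g not in out:
                out.append(g)
        return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, moltype: str = "nt") -> List[SequenceRecord]:
    """Read a FASTA file into validated records (order preserved).

    Headers are tokenized at the first whitespace for the id.  Duplicate
    ids and empty sequences are hard errors.
    """
    records: List[SequenceRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip()
        records.append(SequenceRecord(rec.id, str(rec.seq), moltype, desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models


def _scaffold_lengths(genome: Sequence[SequenceRecord]) -> Dict[str, int]:
    return {rec.id: len(rec.seq) for rec in genome}


def read_gff3(path, genome: Sequence[SequenceRecord], taxon: str = "") -> List[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon/CDS linked by ID/Parent).

    GFF3 1-based inclusive coordinates become 0-based half-open.  One model
    per gene: multi-mRNA genes keep the longest-CDS isoform.  Genes whose
    CDS falls outside their exons are dropped with a logged warning; exons
    outside scaffold bounds are a hard error.
    """
    lengths = _scaffold_lengths(genome)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: List[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        best: Optional[GeneModel] = None
        best_cds_len = -1
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            mrnas = [gene]  # allow exon/CDS directly under gene
        for mrna in mrnas:
            exons = []
            cds = []
            for feat in db.children(mrna, featuretype=("exon", "CDS")):
                if feat.end < feat.start:
                    raise FormatError(
                        f"{feat.featuretype} with end < start in gene {gene.id}"
                    )
                iv = Interval(feat.seqid, feat.start - 1, feat.end, feat.strand)
                if feat.seqid not in lengths:
                    raise FormatError(
                        f"gene {gene.id}: unknown scaffold {feat.seqid!r}"
                    )
                if iv.end > lengths[feat.seqid]:
                    raise FormatError(
                        f"gene {gene.id}: feature {iv.start}-{iv.end} outside "
                        f"scaffold {feat.seqid} (length {lengths[feat.seqid]})"
                    )
                (exons if feat.featuretype == "exon" else cds).append(iv)
            if not exons:
                continue
            exons.sort(key=lambda iv: iv.start)
            if not _cds_within_exons(cds, exons):
                logger.warning(
                    "gene %s: CDS not contained in exons; gene dropped", gene.id
                )
                continue
            cds_len = sum(iv.length for iv in cds)
            if cds_len > best_cds_len:
                best_cds_len = cds_len
                best = GeneModel(
                    gene_id=gene.id,
                    taxon=taxon,
                    scaffold=gene.seqid,
                    strand=gene.strand,
                    exons=exons,
                    cds=cds,
                )
        if best is not None:
            models.append(best)
    return models


def _cds_within_exons(cds: List[Interval], exons: List[Interval]) -> bool:
    for c in cds:
        if not any(e.start <= c.start and c.end <= e.end for e in exons):
            return False
    return True


def write_gff3(models: Iterable[GeneModel], path, source: str = "symbiopsi") -> None:
    """Write gene models as gene/mRNA/exon/CDS rows (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span
            attrs = f"ID={m.gene_id}"
            fh.write(
                f"{m.scaffold}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{m.gene_id}.t1"
            fh.write(
                f"{m.scaffold}\t{source}\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
                f"{m.strand}\t.\tID={mrna_id};Parent={m.gene_id}\n"
            )
            for i, iv in enumerate(m.exons, 1):
                fh.write(
                    f"{m.scaffold}\t{source}\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{m.strand}\t.\tID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            for i, iv in enumerate(m.cds, 1):
                fh.write(
                    f"{m.scaffold}\t{source}\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{m.strand}\t0\tID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# Pseudogene call GFF3 (written by the caller, read back for round trips)


def write_gff3_calls(calls, path, source: str = "symbiopsi") -> None:
    """Write pseudogene calls as ``pseudogene`` features with
    ``pseudogenic_region`` fragment children (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for call in calls:
            loc = call.location
            fh.write(
                f"{loc.scaffold}\t{source}\tpseudogene\t{loc.start + 1}\t{loc.end}"
                f"\t.\t{call.strand}\t.\tID={call.call_id};"
                f"representative={call.representative_query}\n"
            )
            for i, frag in enumerate(call.fragments, 1):
                fh.write(
                    f"{loc.scaffold}\t{source}\tpseudogenic_region\t"
                    f"{frag.location.start + 1}\t{frag.location.end}\t"
                    f"{frag.score:g}\t{call.strand}\t.\t"
                    f"ID={call.call_id}.f{i};Parent={call.call_id};"
                    f"query={frag.query_protein};frame={frag.frame};"
                    f"identity={frag.identity:.6f};"
                    f"query_span={frag.query_span[0]}-{frag.query_span[1]}\n"
                )


def read_gff3_calls(path):
    """Read pseudogene calls written by :func:`write_gff3_calls`."""
    from .pseudogene_caller import PseudogeneCall, PseudogeneFragment

    calls = []
    frags_by_parent: Dict[str, list] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"malformed GFF3 row in {path}: {line!r}")
            rows.append(cols)
    for cols in rows:
        attrs = dict(
            kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
        )
        if cols[2] == "pseudogenic_region":
            qs, qe = attrs["query_span"].split("-")
            frag = PseudogeneFragment(
                query_protein=attrs["query"],
                location=Interval(cols[0], int(cols[3]) - 1, int(cols[4]), cols[6]),
                frame=int(attrs["frame"]),
                identity=float(attrs["identity"]),
                score=float(cols[5]),
                query_span=(int(qs), int(qe)),
            )
            frags_by_parent.setdefault(attrs["Parent"], []).append(frag)
    for cols in rows:
        if cols[2] != "pseudogene":
            continue
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
        call_id = attrs["ID"]
        calls.append(
            PseudogeneCall(
                call_id=call_id,
                location=Interval(cols[0], int(cols[3]) - 1, int(cols[4]), cols[6]),
                strand=cols[6],
                fragments=sorted(
                    frags_by_parent.get(call_id, []),
                    key=lambda f: (f.location.start, f.location.end),
                ),
                representative_query=attrs["representative"],
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Orthogroup tables (OrthoFinder Orthogroups.tsv dialect)


def read_orthogroups(path) -> OrthoGroupTable:
    """Parse a tab-separated orthogroup table.

    First column is the set id; remaining columns are taxa (named in the
    header); cells hold comma-separated protein ids (empty cell = none).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: orthogroup table needs >= 2 columns")
        taxa = header[1:]
        sets: Dict[str, Dict[str, List[str]]] = {}
        for line in fh:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            set_id = cells[0]
            if set_id in sets:
                raise FormatError(f"duplicate set id {set_id!r}")
            row: Dict[str, List[str]] = {}
            for taxon, cell in zip(taxa, cells[1:]):
                row[taxon] = [p.strip() for p in cell.split(",") if p.strip()]
            for taxon in taxa[len(cells) - 1 :]:
                row[taxon] = []
            sets[set_id] = row
    return OrthoGroupTable(sets)


def write_orthogroups(table: OrthoGroupTable, path) -> None:
    taxa = table.taxa
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(taxa) + "\n")
        for set_id in table.sets:
            cells = [
                ", ".join(table.sets[set_id].get(t, [])) for t in taxa
            ]
            fh.write(set_id + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# BED, newick, group tables


def read_bed(path) -> List[Interval]:
    """Read BED (0-based half-open, kept as-is); strand from column 6."""
    out: List[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"BED row with < 3 columns: {line!r}")
            strand = cols[5] if len(cols) >= 6 and cols[5] in "+-" else "."
            out.append(Interval(cols[0], int(cols[1]), int(cols[2]), strand))
    return out


def write_bed(intervals: Iterable[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\n")


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def check_tree_taxa(tree: dendropy.Tree, groups: GroupAssignment) -> None:
    """Every leaf label must be a known taxon; offenders are listed."""
    known = set(groups.groups)
    offenders = [
        leaf.taxon.label for leaf in tree.leaf_node_iter()
        if leaf.taxon is not None and leaf.taxon.label not in known
    ]
    if offenders:
        raise FormatError(
            f"tree leaves not in group assignment: {sorted(offenders)}"
        )


def read_group_assignment(path) -> GroupAssignment:
    """Two-column TSV: taxon <tab> group label."""
    groups: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"group table row with < 2 columns: {line!r}")
            if cols[0].lower() in ("taxon", "sample"):
                continue
            groups[cols[0]] = cols[1]
    if not groups:
        raise FormatError(f"{path}: empty group assignment")
    return GroupAssignment(groups)


def write_group_assignment(groups: GroupAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tgroup\n")
        for taxon, label in groups.groups.items():
            fh.write(f"{taxon}\t{label}\n")
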