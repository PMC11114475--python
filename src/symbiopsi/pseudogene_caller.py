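"""Pseudogene identification by translated homology in gene-masked genomes.

The procedure mirrors protein-vs-genome (tBLASTn-style) searching: every
annotated gene span (exons and introns) is hard-masked, each predicted
protein is searched against all six reading frames of the remaining
sequence, matched regions with >= 75% amino-acid identity are retained as
pseudogene fragments, and fragments on the same scaffold and strand that
lie < 1 kb apart are chained into a single pseudogene call.

The search kernel is seed-and-extend: exact ``seed_word_length``-mer
protein words anchor candidate loci, which are then re-aligned with a
local Smith-Waterman (BLOSUM62, affine gaps; a gap of length L costs
``gap_open + L * gap_extend``).  Identity is, by default, the fraction of
identical amino-acid pairs over all alignment columns, gap columns
included; the BLAST ``pident`` convention (gap columns excluded) is
available via ``identity_includes_gaps=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import GeneModel, Interval, SequenceRecord

_MASK_CHAR = "N"


@dataclass(frozen=True)
class CallerConfig:
    """Tunable parameters of the pseudogene caller.

    ``min_identity`` and ``max_chain_gap`` are the two defining rules
    (fragments at >= 75% identity; chained when < 1000 bp apart, strictly);
    the remainder are search-kernel choices: exact-word seed length,
    a length floor to suppress spurious micro-hits, and the scoring scheme
    (tBLASTn-default BLOSUM62 with affine 11/1 gaps).
    """

    min_identity: float = 0.75
    max_chain_gap: int = 1000
    seed_word_length: int = 4
    min_fragment_aa: int = 20
    scoring: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    identity_includes_gaps: bool = True
    split_at_genes: bool = True
    band_aa: int = 16  # diagonal tolerance when clustering seed hits
    window_margin_aa: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        if self.max_chain_gap < 0:
            raise ValueError("max_chain_gap must be >= 0")


@dataclass(frozen=True)
class PseudogeneFragment:
    """One translated-homology match in masked genomic sequence."""

    query_protein: str
    location: Interval
    frame: int  # 0,1,2 on the fragment's strand
    identity: float
    score: float
    query_span: Tuple[int, int]  # [aa_start, aa_end) on the query


@dataclass
class PseudogeneCall:
    """A chained, co-oriented set of fragments treated as one pseudogene."""

    call_id: str
    location: Interval
    strand: str
    fragments: List[PseudogeneFragment]
    representative_query: str
    taxon: str = ""

    @property
    def best_identity(self) -> float:
        return max(f.identity for f in self.fragments)


# ---------------------------------------------------------------------------
# masking


def mask_genes(
    genome: Sequence[SequenceRecord], models: Sequence[GeneModel]
) -> List[SequenceRecord]:
    """Replace every base inside any gene span (exons + introns) with N.

    Lengths are unchanged; overlapping genes mask their union once.
    """
    by_scaffold: Dict[str, List[GeneModel]] = {}
    names = {rec.id for rec in genome}
    for m in models:
        if m.scaffold not in names:
            raise ValueError(f"gene {m.gene_id} on unknown scaffold {m.scaffold}")
        by_scaffold.setdefault(m.scaffold, []).append(m)
    out: List[SequenceRecord] = []
    for rec in genome:
        spans = [m.span for m in by_scaffold.get(rec.id, [])]
        if not spans:
            out.append(SequenceRecord(rec.id, rec.seq, rec.moltype, rec.description))
            continue
        arr = np.frombuffer(rec.seq.encode(), dtype="S1").copy()
        for sp in spans:
            arr[sp.start : sp.end] = _MASK_CHAR.encode()
        out.append(
            SequenceRecord(rec.id, arr.tobytes().decode(), rec.moltype, rec.description)
        )
    return out


# ---------------------------------------------------------------------------
# six-frame translation with coordinate mapping


@dataclass(frozen=True)
class Frame:
    """One reading frame of one scaffold.

    ``aa[i]`` covers, on the forward strand of the scaffold,
    ``[frame + 3i, frame + 3i + 3)`` when ``strand == '+'`` and
    ``[L - frame - 3i - 3, L - frame - 3i)`` when ``strand == '-'``
    (``frame`` counted on the reverse-complement).
    """

    scaffold: str
    scaffold_length: int
    strand: str
    frame: int
    aa: str

    def genomic_interval(self, aa_start: int, aa_end: int) -> Interval:
        if self.strand == "+":
            return Interval(
                self.scaffold,
                self.frame + 3 * aa_start,
                self.frame + 3 * aa_end,
                "+",
            )
        return Interval(
            self.scaffold,
            self.scaffold_length - self.frame - 3 * aa_end,
            self.scaffold_length - self.frame - 3 * aa_start,
            "-",
        )


def six_frame_translations(rec: SequenceRecord) -> List[Frame]:
    frames: List[Frame] = []
    fwd = rec.seq
    rev = str(Seq(fwd).reverse_complement())
    for strand, seq in (("+", fwd), ("-", rev)):
        for f in range(3):
            usable = (len(seq) - f) // 3
            if usable <= 0:
                continue
            aa = str(Seq(seq[f : f + 3 * usable]).translate())
            frames.append(Frame(rec.id, len(rec.seq), strand, f, aa))
    return frames


# ---------------------------------------------------------------------------
# seed index and alignment


def _make_aligner(cfg: CallerConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(cfg.scoring)
    # BLAST convention: a gap of length L costs gap_open + L * gap_extend
    aligner.open_gap_score = -(cfg.gap_open + cfg.gap_extend)
    aligner.extend_gap_score = -cfg.gap_extend
    return aligner


class GenomeIndex:
    """Seed-word index over the six-frame translation of a masked genome.

    Built once per genome and shared by every query protein.
    """

    def __init__(self, masked_genome: Sequence[SequenceRecord], cfg: CallerConfig):
        self.cfg = cfg
        self.frames: List[Frame] = []
        for rec in masked_genome:
            self.frames.extend(six_frame_translations(rec))
        w = cfg.seed_word_length
        self._index: List[Dict[str, List[int]]] = []
        for fr in self.frames:
            d: Dict[str, List[int]] = {}
            aa = fr.aa
            for i in range(len(aa) - w + 1):
                word = aa[i : i + w]
                if "X" in word or "*" in word:
                    continue
                d.setdefault(word, []).append(i)
            self._index.append(d)

    def seed_hits(self, protein: str) -> Dict[int, List[Tuple[int, int]]]:
        """Frame index -> list of (query_pos, subject_pos) exact word hits."""
        w = self.cfg.seed_word_length
        hits: Dict[int, List[Tuple[int, int]]] = {}
        words = [(q, protein[q : q + w]) for q in range(len(protein) - w + 1)]
        for fi, d in enumerate(self._index):
            lst = []
            for q, word in words:
                for s in d.get(word, ()):
                    lst.append((q, s))
            if lst:
                hits[fi] = lst
        return hits


def _cluster_seeds(
    hits: List[Tuple[int, int]], protein_len: int, band: int
) -> List[Tuple[int, int]]:
    """Group seed hits into candidate subject windows.

    Hits are clustered when they fall in a compatible diagonal band and
    within one protein length of each other on the subject; each cluster
    yields a (min_subject, max_subject) anchor range.
    """
    # sort by diagonal then subject position
    items = sorted(((s - q, q, s) for q, s in hits))
    clusters: List[List[Tuple[int, int, int]]] = []
    for item in items:
        placed = False
        for cl in clusters:
            d0 = cl[-1][0]
            if abs(item[0] - d0) <= band and abs(item[2] - cl[-1][2]) <= protein_len:
                cl.append(item)
                placed = True
                break
        if not placed:
            clusters.append([item])
    # merge clusters whose subject ranges are close (split diagonals of one locus)
    ranges = sorted(
        (min(s for _, _, s in cl), max(s for _, _, s in cl)) for cl in clusters
    )
    merged: List[Tuple[int, int]] = []
    for lo, hi in ranges:
        if merged and lo - merged[-1][1] <= protein_len:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _alignment_stats(aln, include_gaps: bool) -> Tuple[float, int, int, int, int]:
    """(identity, sub_start, sub_end, q_start, q_end) for a local alignment."""
    sub_blocks, q_blocks = aln.aligned
    counts = aln.counts()
    columns = counts.identities + counts.mismatches
    if include_gaps:
        columns += counts.gaps
    identity = counts.identities / columns if columns else 0.0
    return (
        identity,
        int(sub_blocks[0][0]),
        int(sub_blocks[-1][1]),
        int(q_blocks[0][0]),
        int(q_blocks[-1][1]),
    )


def find_fragments(
    protein: SequenceRecord,
    masked_genome,
    cfg: CallerConfig,
) -> List[PseudogeneFragment]:
    """Locate >= ``min_identity`` translated matches of one protein.

    ``masked_genome`` may be a list of masked scaffolds or a prebuilt
    :class:`GenomeIndex`.  Overlapping same-frame fragments for the query
    are resolved to the highest-scoring one.
    """
    index = (
        masked_genome
        if isinstance(masked_genome, GenomeIndex)
        else GenomeIndex(masked_genome, cfg)
    )
    aligner = _make_aligner(cfg)
    fragments: List[PseudogeneFragment] = []
    pseq = protein.seq
    for fi, hits in index.seed_hits(pseq).items():
        fr = index.frames[fi]
        found: List[Tuple[float, int, int, int, int, float]] = []
        for lo, hi in _cluster_seeds(hits, len(pseq), cfg.band_aa):
            wlo = max(0, lo - len(pseq) - cfg.window_margin_aa)
            whi = min(len(fr.aa), hi + len(pseq) + cfg.window_margin_aa)
            window = fr.aa[wlo:whi]
            alns = aligner.align(window, pseq)
            if len(alns) == 0 or alns[0].score <= 0:
                continue
            aln = alns[0]
            identity, sa, sb, qa, qb = _alignment_stats(
                aln, cfg.identity_includes_gaps
            )
            found.append((aln.score, wlo + sa, wlo + sb, qa, qb, identity))
        # resolve overlapping candidates (same query, same frame): best score
        found.sort(key=lambda t: (-t[0], t[1]))
        kept: List[Tuple[float, int, int, int, int, float]] = []
        for cand in found:
            if any(not (cand[2] <= k[1] or k[2] <= cand[1]) for k in kept):
                continue
            kept.append(cand)
        for score, sa, sb, qa, qb, identity in kept:
            if identity < cfg.min_identity:
                continue
            if qb - qa < cfg.min_fragment_aa:
                continue
            fragments.append(
                PseudogeneFragment(
                    query_protein=protein.id,
                    location=fr.genomic_interval(sa, sb),
                    frame=fr.frame,
                    identity=identity,
                    score=float(score),
                    query_span=(qa, qb),
                )
            )
    fragments.sort(key=lambda f: (f.location.scaffold, f.location.start, f.location.end))
    return fragments


# ---------------------------------------------------------------------------
# chaining


def chain_fragments(
    fragments: Sequence[PseudogeneFragment], cfg: CallerConfig
) -> List[PseudogeneCall]:
    """Chain co-oriented fragments < ``max_chain_gap`` bp apart.

    Per (scaffold, strand): fragments are sorted by start and linked while
    the gap to the running end is strictly below the threshold (touching
    or overlapping fragments always merge).  The result is the unique
    maximal chaining; fragments from different query proteins may share a
    call, whose representative is the highest-scoring member (ties broken
    by query id).
    """
    groups: Dict[Tuple[str, str], List[PseudogeneFragment]] = {}
    for f in fragments:
        groups.setdefault((f.location.scaffold, f.location.strand), []).append(f)
    calls: List[PseudogeneCall] = []
    for (scaffold, strand), frags in sorted(groups.items()):
        frags = sorted(frags, key=lambda f: (f.location.start, f.location.end))
        run: List[PseudogeneFragment] = []
        run_end = -(10**18)
        for f in frags:
            if run and f.location.start - run_end >= cfg.max_chain_gap:
                calls.append(_make_call(run, scaffold, strand))
                run = []
            run.append(f)
            run_end = max(run_end, f.location.end)
        if run:
            calls.append(_make_call(run, scaffold, strand))
    calls.sort(key=lambda c: (c.location.scaffold, c.location.start))
    for i, c in enumerate(calls, 1):
        c.call_id = f"pg{i:06d}"
    return calls


def _make_call(
    frags: List[PseudogeneFragment], scaffold: str, strand: str
) -> PseudogeneCall:
    start = min(f.location.start for f in frags)
    end = max(f.location.end for f in frags)
    rep = min(frags, key=lambda f: (-f.score, f.query_protein))
    return PseudogeneCall(
        call_id="",
        location=Interval(scaffold, start, end, strand),
        strand=strand,
        fragments=list(frags),
        representative_query=rep.query_protein,
    )


# ---------------------------------------------------------------------------
# full per-taxon procedure


def call_pseudogenes(
    proteome: Sequence[SequenceRecord],
    genome: Sequence[SequenceRecord],
    models: Sequence[GeneModel],
    cfg: Optional[CallerConfig] = None,
    taxon: str = "",
) -> List[PseudogeneCall]:
    """Mask -> per-protein fragment search -> pooled chaining.

    Calls are sorted by scaffold then start and are deterministic given
    the inputs and configuration.
    """
    cfg = cfg or CallerConfig()
    masked = mask_genes(genome, models)
    index = GenomeIndex(masked, cfg)
    fragments: List[PseudogeneFragment] = []
    for protein in proteome:
        fragments.extend(find_fragments(protein, index, cfg))
    calls = chain_fragments(fragments, cfg)
    if cfg.split_at_genes:
        calls = _split_calls_at_genes(calls, models, cfg)
    for c in calls:
        c.taxon = taxon
    return calls


def _split_calls_at_genes(
    calls: List[PseudogeneCall],
    models: Sequence[GeneModel],
    cfg: CallerConfig,
) -> List[PseudogeneCall]:
    """Break chains whose internal gaps cross an annotated gene span.

    The distance rule alone can link fragments on either side of a masked
    gene; a pseudogene spanning an intact gene is not a meaningful locus,
    so such chains are split at the gene.  Fragments themselves never
    overlap gene spans (they cannot align into masked sequence).
    """
    spans: Dict[str, List[Tuple[int, int]]] = {}
    for m in models:
        sp = m.span
        spans.setdefault(m.scaffold, []).append((sp.start, sp.end))
    for lst in spans.values():
        lst.sort()

    def gap_crosses_gene(scaffold: str, lo: int, hi: int) -> bool:
        if lo >= hi:
            return False
        for s, e in spans.get(scaffold, ()):
            if s < hi and lo < e:
                return True
            if s >= hi:
                break
        return False

    out: List[PseudogeneCall] = []
    for call in calls:
        frags = sorted(
            call.fragments, key=lambda f: (f.location.start, f.location.end)
        )
        run: List[PseudogeneFragment] = [frags[0]]
        run_end = frags[0].location.end
        for f in frags[1:]:
            if gap_crosses_gene(call.location.scaffold, run_end, f.location.start):
                out.append(_make_call(run, call.location.scaffold, call.strand))
                run = []
                run_end = -(10**18)
            run.append(f)
            run_end = max(run_end, f.location.end)
        out.append(_make_call(run, call.location.scaffold, call.strand))
    out.sort(key=lambda c: (c.location.scaffold, c.location.start))
    for i, c in enumerate(out, 1):
        c.call_id = f"pg{i:06d}"
    return out
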