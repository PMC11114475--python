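"""Homologous protein sets and the attribution of pseudogene calls to them.

Sets are either ingested from an OrthoFinder-style table
(:func:`symbiopsi.io_formats.read_orthogroups`) or built by
:func:`cluster_proteins`, a deliberately simple stand-in: single-linkage
connected components over pairwise local-alignment similarity.  It gives
OrthoFinder-like granularity on desk-scale cohorts; full-scale analyses
should ingest real orthogroup output instead.

A pseudogene call inherits the set of its representative query (the
highest-scoring fragment's protein) -- the simplest deterministic rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import OrthoGroupTable, SequenceRecord
from .pseudogene_caller import PseudogeneCall


@dataclass
class SetAssignment:
    """call_id -> set_id mapping plus the taxon of each assigned call."""

    assigned: Dict[str, str]
    taxon_of: Dict[str, str]
    unassigned: List[str] = field(default_factory=list)


def _kmer_set(seq: str, k: int = 4) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def cluster_proteins(
    proteomes: Mapping[str, Sequence[SequenceRecord]],
    min_identity: float = 0.4,
    min_coverage: float = 0.5,
    min_score: float = 75.0,
) -> OrthoGroupTable:
    """Single-linkage clustering of proteins into homologous sets.

    An edge joins two proteins when their local alignment (BLOSUM62,
    affine 11/1 gaps) has amino-acid identity >= ``min_identity`` over the
    aligned columns, covers >= ``min_coverage`` of the shorter protein,
    and scores >= ``min_score``.  The score floor plays the role BLAST
    e-value cutoffs play in orthology tools: it rejects short chance
    windows that can reach 40% identity between unrelated sequences.
    A shared-4-mer prefilter skips clearly unrelated pairs.  Clustering is
    invariant to input order: ids are sorted before union, and set ids are
    assigned in order of each component's smallest member id.
    """
    records: List[Tuple[str, str, str]] = []  # (protein_id, taxon, seq)
    for taxon in proteomes:
        for rec in proteomes[taxon]:
            records.append((rec.id, taxon, rec.seq))
    if len(records) < 2:
        raise ValueError("cluster_proteins needs >= 2 proteins")
    records.sort(key=lambda r: r[0])

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1

    kmers = [_kmer_set(seq) for _, _, seq in records]
    graph = nx.Graph()
    graph.add_nodes_from(pid for pid, _, _ in records)
    for i in range(len(records)):
        pid_i, _, seq_i = records[i]
        for j in range(i + 1, len(records)):
            pid_j, _, seq_j = records[j]
            shorter = min(len(seq_i), len(seq_j))
            # prefilter: a >= min_identity alignment over >= min_coverage of
            # the shorter sequence implies shared exact 4-mers
            if len(kmers[i] & kmers[j]) < max(1, int(0.02 * shorter)):
                continue
            alns = aligner.align(seq_i, seq_j)
            if len(alns) == 0 or alns[0].score < min_score:
                continue
            aln = alns[0]
            counts = aln.counts()
            columns = counts.identities + counts.mismatches + counts.gaps
            if columns == 0:
                continue
            identity = counts.identities / columns
            blocks_i, blocks_j = aln.aligned
            cov_i = (blocks_i[-1][1] - blocks_i[0][0]) / len(seq_i)
            cov_j = (blocks_j[-1][1] - blocks_j[0][0]) / len(seq_j)
            coverage = cov_i if len(seq_i) <= len(seq_j) else cov_j
            if identity >= min_identity and coverage >= min_coverage:
                graph.add_edge(pid_i, pid_j)

    taxon_of = {pid: taxon for pid, taxon, _ in records}
    taxa = list(proteomes)
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(graph)),
        key=lambda c: c[0],
    )
    sets: Dict[str, Dict[str, List[str]]] = {}
    for idx, comp in enumerate(components):
        set_id = f"HG{idx:06d}"
        row: Dict[str, List[str]] = {t: [] for t in taxa}
        for pid in comp:
            row[taxon_of[pid]].append(pid)
        sets[set_id] = row
    return OrthoGroupTable(sets)


def assign_calls(
    calls: Sequence[PseudogeneCall], table: OrthoGroupTable
) -> SetAssignment:
    """Attribute each call to the set of its representative query.

    Calls whose representative protein belongs to no set are listed as
    unassigned and excluded from downstream Psi computation.
    """
    prot_to_set = table.protein_to_set()
    assigned: Dict[str, str] = {}
    taxon_of: Dict[str, str] = {}
    unassigned: List[str] = []
    for call in calls:
        set_id = prot_to_set.get(call.representative_query)
        if set_id is None:
            unassigned.append(call.call_id)
            continue
        assigned[call.call_id] = set_id
        taxon_of[call.call_id] = call.taxon
    return SetAssignment(assigned=assigned, taxon_of=taxon_of, unassigned=unassigned)
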