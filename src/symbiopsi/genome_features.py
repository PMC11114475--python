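"""Gene-structure and composition statistics with rank-sum group tests.

Per gene: genomic span length, intron count and lengths, exon/intron
fractions of the span, and GC of the concatenated CDS and introns.  Gene
length is the genomic span (UTR-less models assumed, as in dinoflagellate
gene predictions).  GC excludes N and other ambiguity codes from both
numerator and denominator.  Group comparisons use the two-sided Wilcoxon
rank-sum (Mann-Whitney) test: exact when both sides have n <= 12 and
there are no ties, otherwise the normal approximation with tie and
continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .io_formats import GeneModel, GroupAssignment, SequenceRecord


@dataclass(frozen=True)
class GeneFeatureRow:
    taxon: str
    gene_id: str
    gene_length: int
    n_introns: int
    intron_lengths: Tuple[int, ...]
    exon_fraction: float
    intron_fraction: float
    cds_gc: float
    intron_gc: float


@dataclass(frozen=True)
class GcSummary:
    taxon: str
    genome_gc: float
    cds_gc: float
    intron_gc: float


def gc_content(seq) -> float:
    """(G+C)/(A+C+G+T); ambiguity codes excluded.  NaN for all-N input."""
    s = seq.seq if isinstance(seq, SequenceRecord) else str(seq).upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return math.nan
    return gc / (gc + at)


def feature_table(
    models: Sequence[GeneModel], genome: Sequence[SequenceRecord]
) -> List[GeneFeatureRow]:
    seqs = {rec.id: rec.seq for rec in genome}
    rows: List[GeneFeatureRow] = []
    for m in models:
        scaffold = seqs[m.scaffold]
        introns = m.introns
        ilens = tuple(iv.length for iv in introns)
        exon_len = sum(iv.length for iv in m.exons)
        glen = m.gene_length
        cds_seq = "".join(scaffold[iv.start : iv.end] for iv in m.cds)
        intron_seq = "".join(scaffold[iv.start : iv.end] for iv in introns)
        rows.append(
            GeneFeatureRow(
                taxon=m.taxon,
                gene_id=m.gene_id,
                gene_length=glen,
                n_introns=len(introns),
                intron_lengths=ilens,
                exon_fraction=exon_len / glen,
                intron_fraction=sum(ilens) / glen,
                cds_gc=gc_content(cds_seq),
                intron_gc=gc_content(intron_seq) if intron_seq else math.nan,
            )
        )
    return rows


def gc_summary(
    genome: Sequence[SequenceRecord],
    models: Sequence[GeneModel],
    taxon: str = "",
) -> GcSummary:
    """Region GC over the whole genome, concatenated CDS, and introns."""
    seqs = {rec.id: rec.seq for rec in genome}
    genome_seq = "".join(seqs.values())
    cds_parts: List[str] = []
    intron_parts: List[str] = []
    for m in models:
        scaffold = seqs[m.scaffold]
        cds_parts.extend(scaffold[iv.start : iv.end] for iv in m.cds)
        intron_parts.extend(scaffold[iv.start : iv.end] for iv in m.introns)
    return GcSummary(
        taxon=taxon or (models[0].taxon if models else ""),
        genome_gc=gc_content(genome_seq),
        cds_gc=gc_content("".join(cds_parts)),
        intron_gc=gc_content("".join(intron_parts)),
    )


def intron_position_profile(
    models: Sequence[GeneModel], n_bins: int = 5
) -> np.ndarray:
    """Histogram of intron midpoints along the normalized 5'->3' gene axis.

    Midpoints are mapped onto the coding strand (so bin 0 is always the
    5' end), then binned into ``n_bins`` equal slices of the gene span.
    """
    counts = np.zeros(n_bins, dtype=int)
    for m in models:
        span = m.span
        if span.length == 0:
            continue
        for iv in m.introns:
            mid = (iv.start + iv.end) / 2
            rel = (mid - span.start) / span.length
            if m.strand == "-":
                rel = 1.0 - rel
            b = min(int(rel * n_bins), n_bins - 1)
            counts[b] += 1
    return counts


@dataclass(frozen=True)
class FeatureComparison:
    group_a: str
    group_b: str
    feature: str
    p_value: float
    n_a: int
    n_b: int
    method: str  # exact | asymptotic | degenerate


_SCALAR_FEATURES = {
    "gene_length": lambda r: [float(r.gene_length)],
    "n_introns": lambda r: [float(r.n_introns)],
    "intron_length": lambda r: [float(x) for x in r.intron_lengths],
    "exon_fraction": lambda r: [r.exon_fraction],
    "intron_fraction": lambda r: [r.intron_fraction],
    "cds_gc": lambda r: [r.cds_gc],
    "intron_gc": lambda r: [r.intron_gc],
}


def _values(
    rows: Sequence[GeneFeatureRow], taxa: Sequence[str], feature: str
) -> np.ndarray:
    extract = _SCALAR_FEATURES[feature]
    vals = [
        v
        for r in rows
        if r.taxon in taxa
        for v in extract(r)
        if not math.isnan(v)
    ]
    return np.asarray(vals, dtype=float)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> Tuple[float, str]:
    """Two-sided Mann-Whitney p-value with the method-selection rule.

    Exact null distribution when both n <= 12 and the pooled sample has no
    ties; otherwise normal approximation with tie and continuity
    correction.  All-identical pooled values give p = 1 (flagged
    ``degenerate``).
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0, "degenerate"
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= 12 and len(y) <= 12 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.pvalue), "exact"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue), "asymptotic"


def compare_feature(
    groups: GroupAssignment,
    rows: Sequence[GeneFeatureRow],
    feature: str,
) -> List[FeatureComparison]:
    """Pairwise two-sided rank-sum tests of one feature between groups.

    Values are pooled over genes (and over introns, for ``intron_length``)
    within each group.
    """
    if feature not in _SCALAR_FEATURES:
        raise ValueError(
            f"unknown feature {feature!r}; choose from {sorted(_SCALAR_FEATURES)}"
        )
    out: List[FeatureComparison] = []
    for a, b in combinations(groups.labels, 2):
        x = _values(rows, groups.taxa_of(a), feature)
        y = _values(rows, groups.taxa_of(b), feature)
        if len(x) == 0 or len(y) == 0:
            continue
        p, method = rank_sum_test(x, y)
        out.append(
            FeatureComparison(
                group_a=a,
                group_b=b,
                feature=feature,
                p_value=p,
                n_a=len(x),
                n_b=len(y),
                method=method,
            )
        )
    return out


def group_means(
    groups: GroupAssignment,
    rows: Sequence[GeneFeatureRow],
    feature: str,
) -> Dict[str, float]:
    """Mean of a feature pooled over genes within each group."""
    out: Dict[str, float] = {}
    for label in groups.labels:
        vals = _values(rows, groups.taxa_of(label), feature)
        out[label] = float(vals.mean()) if len(vals) else math.nan
    return out
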