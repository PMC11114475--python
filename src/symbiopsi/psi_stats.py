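"""The pseudogenization statistic Psi and its between-group comparisons.

For a homologous protein set S and a taxon group G, Psi(S, G) is the ratio
of pseudogene calls attributed to S across G's taxa to the number of
(putatively functional) proteins of S in G's taxa.  Psi is undefined when
the group has no proteins in the set.  Per set, two groups are compared
with a two-sided Fisher exact test on the 2x2 table
``[[n_pseudo_a, n_genes_a], [n_pseudo_b, n_genes_b]]`` (count-native and
exact at small counts; a conditional binomial ratio test is available as
an alternative).  A set is called directional when p < alpha and the Psi
values differ; merged group labels (e.g. S1+S2) pool counts before
testing.  No multiple-testing correction is applied by default; a
Benjamini-Hochberg option exists behind ``fdr=True``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .homology import SetAssignment
from .io_formats import GroupAssignment, OrthoGroupTable

logger = logging.getLogger(__name__)

Labels = Union[str, Sequence[str]]


@dataclass(frozen=True)
class StatConfig:
    alpha: float = 0.05
    test: str = "fisher_2x2"  # or "binomial_ratio"
    fdr: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.test not in ("fisher_2x2", "binomial_ratio"):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass(frozen=True)
class PsiRecord:
    set_id: str
    group: str
    n_pseudo: int
    n_genes: int

    @property
    def psi(self) -> float:
        """n_pseudo / n_genes; NaN when undefined (no genes in group)."""
        return self.n_pseudo / self.n_genes if self.n_genes else math.nan


@dataclass(frozen=True)
class PsiComparison:
    set_id: str
    group_a: str
    group_b: str
    direction: str  # a_gt_b | b_gt_a | none
    p_value: float
    n_pseudo_a: int
    n_genes_a: int
    n_pseudo_b: int
    n_genes_b: int


def compute_psi(
    assignment: SetAssignment,
    table: OrthoGroupTable,
    groups: GroupAssignment,
) -> List[PsiRecord]:
    """Per-set, per-group pseudogene and gene counts (pooled over taxa).

    Counts are pooled across a group's taxa -- not averaged per taxon --
    because Psi is defined on the set.  Every taxon holding proteins or
    calls must carry a group label.
    """
    labels = groups.labels
    counts: Dict[Tuple[str, str], List[int]] = {}
    for set_id, by_taxon in table.sets.items():
        for taxon, prots in by_taxon.items():
            label = groups.label(taxon)  # KeyError -> unlabeled taxon
            key = (set_id, label)
            counts.setdefault(key, [0, 0])[1] += len(prots)
    for call_id, set_id in assignment.assigned.items():
        taxon = assignment.taxon_of[call_id]
        label = groups.label(taxon)
        counts.setdefault((set_id, label), [0, 0])[0] += 1
    records = []
    for set_id in table.sets:
        for label in labels:
            n_pseudo, n_genes = counts.get((set_id, label), (0, 0))
            records.append(PsiRecord(set_id, label, n_pseudo, n_genes))
    return records


def _pool(
    records: Sequence[PsiRecord], set_id: str, labels: Sequence[str]
) -> Optional[Tuple[int, int]]:
    n_pseudo = n_genes = 0
    for r in records:
        if r.set_id == set_id and r.group in labels:
            n_pseudo += r.n_pseudo
            n_genes += r.n_genes
    return (n_pseudo, n_genes)


def _as_labels(side: Labels) -> List[str]:
    if isinstance(side, str):
        return side.split("+")
    return list(side)


def _p_value(table: List[List[int]], test: str) -> float:
    (pa, ga), (pb, gb) = table
    if test == "fisher_2x2":
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    total = pa + pb
    if total == 0:
        return 1.0
    expected = ga / (ga + gb)
    return float(stats.binomtest(pa, total, expected).pvalue)


def compare_psi(
    records: Sequence[PsiRecord],
    a: Labels,
    b: Labels,
    cfg: Optional[StatConfig] = None,
) -> List[PsiComparison]:
    """Per-set comparison of Psi between two (possibly merged) groups.

    Sets where either side has undefined Psi (no genes) are skipped and
    logged.  Direction is decided by comparing the Psi ratios, and only
    claimed when the test's p-value is below ``cfg.alpha`` (after optional
    Benjamini-Hochberg adjustment across the tested sets).
    """
    cfg = cfg or StatConfig()
    labels_a, labels_b = _as_labels(a), _as_labels(b)
    name_a, name_b = "+".join(labels_a), "+".join(labels_b)
    set_ids = sorted({r.set_id for r in records})
    rows: List[Tuple[str, int, int, int, int, float]] = []
    n_skipped = 0
    for set_id in set_ids:
        pa, ga = _pool(records, set_id, labels_a)
        pb, gb = _pool(records, set_id, labels_b)
        if ga == 0 or gb == 0:
            n_skipped += 1
            continue
        p = _p_value([[pa, ga], [pb, gb]], cfg.test)
        rows.append((set_id, pa, ga, pb, gb, p))
    if n_skipped:
        logger.info(
            "compare_psi(%s vs %s): skipped %d sets with undefined Psi",
            name_a, name_b, n_skipped,
        )
    pvals = np.array([row[5] for row in rows])
    effective = (
        stats.false_discovery_control(pvals) if (cfg.fdr and len(pvals)) else pvals
    )
    out: List[PsiComparison] = []
    for (set_id, pa, ga, pb, gb, p), p_eff in zip(rows, effective):
        psi_a, psi_b = pa / ga, pb / gb
        if p_eff < cfg.alpha and psi_a > psi_b:
            direction = "a_gt_b"
        elif p_eff < cfg.alpha and psi_b > psi_a:
            direction = "b_gt_a"
        else:
            direction = "none"
        out.append(
            PsiComparison(
                set_id=set_id,
                group_a=name_a,
                group_b=name_b,
                direction=direction,
                p_value=float(p),
                n_pseudo_a=pa,
                n_genes_a=ga,
                n_pseudo_b=pb,
                n_genes_b=gb,
            )
        )
    return out


def summarize_directions(
    comparisons: Sequence[PsiComparison],
) -> Dict[Tuple[str, str], Dict[str, int]]:
    """Per (group_a, group_b) pair: counts of a_gt_b / b_gt_a / none.

    The three counts sum to the number of tested sets for that pair.
    """
    out: Dict[Tuple[str, str], Dict[str, int]] = {}
    for c in comparisons:
        key = (c.group_a, c.group_b)
        tally = out.setdefault(key, {"a_gt_b": 0, "b_gt_a": 0, "none": 0})
        tally[c.direction] += 1
    return out
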