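"""Presence/absence accounting of homologous sets across groups and trees.

Two complementary summaries:

* combination counts (upset semantics): each set is counted exactly once,
  under the exact combination of groups in which it has >= 1 member;
* per-node descendant counts on a species tree: for every internal node,
  the number of sets present in >= 1 descendant taxon (monotone toward
  the root), and for every tip the number of sets exclusive to that taxon.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Optional, Tuple

import dendropy
import pandas as pd

from .io_formats import FormatError, GroupAssignment, OrthoGroupTable


def presence_matrix(
    table: OrthoGroupTable, groups: Optional[GroupAssignment] = None
) -> pd.DataFrame:
    """Boolean set x column matrix; columns are group labels, or taxa when
    ``groups`` is None.  Rows with no presence anywhere are excluded."""
    taxa = table.taxa
    if groups is not None:
        for t in taxa:
            groups.label(t)  # raises on unlabeled taxon
        columns = groups.labels
    else:
        columns = taxa
    rows = {}
    for set_id, by_taxon in table.sets.items():
        row = dict.fromkeys(columns, False)
        for taxon, prots in by_taxon.items():
            if prots:
                col = groups.label(taxon) if groups is not None else taxon
                row[col] = True
        if any(row.values()):
            rows[set_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(columns))
    return df.astype(bool)


def combination_counts(matrix: pd.DataFrame) -> Dict[FrozenSet[str], int]:
    """Upset-style exclusive combination counts; values sum to n rows."""
    out: Dict[FrozenSet[str], int] = {}
    cols = list(matrix.columns)
    for _, row in matrix.iterrows():
        combo = frozenset(c for c in cols if row[c])
        out[combo] = out.get(combo, 0) + 1
    return out


def node_descendant_counts(
    tree: dendropy.Tree, matrix: pd.DataFrame
) -> Tuple[Dict[str, int], Dict[str, int]]:
    """Counts of sets present under each node, and exclusive to each tip.

    ``matrix`` must be at taxon resolution with every tree leaf as a
    column.  Internal nodes count sets present in >= 1 descendant leaf
    (regardless of presence elsewhere); tips count sets present in that
    leaf and in no other leaf.  Internal nodes are keyed by their label
    when present, else ``node<postorder index>``.
    """
    leaf_labels = [
        leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None
    ]
    missing = [l for l in leaf_labels if l not in matrix.columns]
    if missing:
        raise FormatError(f"tree leaves missing from matrix: {sorted(missing)}")

    node_counts: Dict[str, int] = {}
    tip_exclusive: Dict[str, int] = {}
    present = {l: matrix[l].to_numpy() for l in leaf_labels}
    row_sums = matrix[leaf_labels].sum(axis=1).to_numpy()

    for i, node in enumerate(tree.postorder_node_iter()):
        if node.is_leaf():
            if node.taxon is None:
                continue
            label = node.taxon.label
            exclusive = int((present[label] & (row_sums == 1)).sum())
            tip_exclusive[label] = exclusive
            node_counts[label] = int(present[label].sum())
        else:
            leaves = [
                l.taxon.label for l in node.leaf_iter() if l.taxon is not None
            ]
            any_present = present[leaves[0]].copy()
            for l in leaves[1:]:
                any_present |= present[l]
            label = node.label if node.label else f"node{i}"
            node_counts[label] = int(any_present.sum())
    return node_counts, tip_exclusive
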