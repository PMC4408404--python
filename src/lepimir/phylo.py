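"""Phylogenetic placement of miRNA families.

Maps a family x species presence/absence matrix onto a rooted species tree
under a single-gain (Dollo-style) assumption: each family arises once, at
the most recent common ancestor of the species carrying it.  That node is
the *latest possible node of origin* -- with unobserved losses the true
origin can only be the assigned node or one of its ancestors, so the
assignment is a lower bound on family age.  Per-node gain counts and
implied lineage-specific losses are tabulated from the same assignment.

Trees are dendropy objects throughout; matrices are pandas DataFrames with
families as rows, species as columns and cells coded 0 (absent),
1 (genomic evidence only) or 2 (small-RNA sequencing evidence).
"""

from __future__ import annotations

import io

import dendropy
import pandas as pd

ABSENT, PRESENT_GENOMIC, PRESENT_SEQUENCED = 0, 1, 2


class TreeError(ValueError):
    pass


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick tree; duplicate leaves or malformed input raise.

    A basal polytomy is rejected as an unrooted tree: origin assignment is
    undefined without a root.
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise TreeError(f"newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate leaf labels: {dupes}")
    if len(tree.seed_node.child_nodes()) > 2:
        raise TreeError("tree root is a polytomy; an explicitly rooted "
                        "binary root is required")
    tree.is_rooted = True
    ensure_node_labels(tree)
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def ensure_node_labels(tree: dendropy.Tree) -> None:
    """Give every node a stable label (leaf taxon label, or node_i)."""
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            if node.taxon is not None:
                node.label = node.taxon.label
        elif node.taxon is not None and node.taxon.label:
            node.label = node.taxon.label
        elif not node.label:
            node.label = f"node_{counter}"
        counter += 1


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def read_presence_matrix(path_or_buffer) -> pd.DataFrame:
    """Read a families x species TSV with 0/1/2 presence codes."""
    if isinstance(path_or_buffer, str) and "\t" in path_or_buffer:
        path_or_buffer = io.StringIO(path_or_buffer)
    df = pd.read_csv(path_or_buffer, sep="\t", index_col=0)
    return validate_matrix(df)


def validate_matrix(df: pd.DataFrame) -> pd.DataFrame:
    df = df.astype(int)
    if not df.isin([ABSENT, PRESENT_GENOMIC, PRESENT_SEQUENCED]).all().all():
        raise ValueError("matrix cells must be 0 (absent), 1 (genomic) or "
                         "2 (sequenced)")
    empty = df.index[(df > 0).sum(axis=1) == 0]
    if len(empty):
        raise ValueError(f"families with no present species: {list(empty)}")
    return df


def assign_origin(tree: dendropy.Tree, presence_row) -> dendropy.Node:
    """Latest possible node of origin: the MRCA of all present species.

    ``presence_row`` is a mapping/Series of species -> presence code; any
    nonzero code counts as present.  For a single present species the
    origin is that leaf's own branch.  Present species missing from the
    tree raise a labelling error naming the species.
    """
    present = [sp for sp, v in dict(presence_row).items() if int(v) > 0]
    if not present:
        raise ValueError("presence row has no present species")
    known = set(leaf_labels(tree))
    missing = sorted(set(present) - known)
    if missing:
        raise KeyError(f"present species not in tree: {missing}")
    if len(present) == 1:
        return tree.find_node_with_taxon_label(present[0])
    return tree.mrca(taxon_labels=present)


def tabulate_gains(tree: dendropy.Tree, matrix: pd.DataFrame) -> pd.Series:
    """Per-node counts of family origins; counts sum to the number of rows."""
    matrix = validate_matrix(matrix)
    counts: dict[str, int] = {n.label: 0 for n in tree.preorder_node_iter()}
    origins = {}
    for family, row in matrix.iterrows():
        node = assign_origin(tree, row)
        origins[family] = node.label
        counts[node.label] += 1
    series = pd.Series(counts, name="gains")
    series.attrs["origins"] = origins
    return series


def infer_losses(tree: dendropy.Tree, presence_row, origin: dendropy.Node):
    """Leaves under the origin scored absent: implied lineage-specific losses.

    Every loss call rests on absence from an assembly rather than positive
    evidence, so each is flagged ``genome-completeness-limited``.
    """
    row = dict(presence_row)
    losses = []
    for leaf in origin.leaf_iter():
        label = leaf.taxon.label
        if int(row.get(label, ABSENT)) == ABSENT:
            losses.append({"species": label, "flag": "genome-completeness-limited"})
    return losses


def placement_report(tree: dendropy.Tree, matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-family origin node and implied losses as a tidy table."""
    matrix = validate_matrix(matrix)
    rows = []
    for family, row in matrix.iterrows():
        origin = assign_origin(tree, row)
        losses = infer_losses(tree, row, origin)
        rows.append({
            "family": family,
            "origin_node": origin.label,
            "n_present": int((row > 0).sum()),
            "n_losses": len(losses),
            "lost_species": ",".join(l["species"] for l in losses),
        })
    return pd.DataFrame(rows).set_index("family")
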