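"""Efflux-pump family selection, distances, neighbor joining, clade calls.

The procedure mirrors how an ortholog group of RND efflux-pump
inner-membrane subunits is delimited across a genome collection:

1. select the protein family by its functional tag (COG0841 by default);
2. score all pairs by global alignment (BLOSUM50, affine gaps) and convert
   scores to a dissimilarity ``d_ij = 1 - S_ij / min(S_ii, S_jj)``;
3. build a neighbor-joining tree from the dissimilarity matrix;
4. root the tree at the midpoint of its longest leaf-to-leaf path;
5. the clade is every leaf descending from the most recent common
   ancestor (MRCA) of the anchor leaves (the functionally tested genes);
6. summarize per-taxon prevalence and per-genome copy number.

The dissimilarity is 0 for identical sequences and scale-free; it can
exceed 1 for very dissimilar pairs and is deliberately not clipped.
Neighbor joining breaks Q-criterion ties by the lexicographically smallest
cluster-id pair and truncates negative branch lengths to zero, so the
whole pipeline is deterministic and order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "CladeReport",
    "select_family",
    "pairwise_distance",
    "neighbor_joining",
    "midpoint_root",
    "mrca_clade",
    "prevalence_summary",
    "call_clade",
]


def select_family(annotations: pd.DataFrame, tag: str = "COG0841") -> pd.DataFrame:
    """All and only proteins carrying the functional tag.

    ``annotations`` needs columns ``seq_id`` and ``tag`` (plus any
    metadata, carried through).  An empty result is an error.
    """
    hits = annotations[annotations["tag"] == tag].copy()
    if len(hits) == 0:
        raise ValueError(f"no proteins carry tag {tag!r}")
    return hits


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def pairwise_distance(
    sequences: dict,
    matrix: str = "BLOSUM50",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> DistanceMatrix:
    """Alignment-score dissimilarity matrix over a set of proteins.

    Global dynamic-programming alignment with affine gaps gives a score
    ``S_ij``; the dissimilarity is ``1 - S_ij / min(S_ii, S_jj)`` with a
    zero diagonal.
    """
    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    for sid in ids:
        if len(sequences[sid]) == 0:
            raise ValueError(f"empty sequence: {sid}")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    self_scores = {sid: aligner.score(sequences[sid], sequences[sid]) for sid in ids}
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s_ij = aligner.score(sequences[ids[i]], sequences[ids[j]])
            denom = min(self_scores[ids[i]], self_scores[ids[j]])
            d[i, j] = d[j, i] = 1.0 - s_ij / denom
    return DistanceMatrix(d, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a dissimilarity matrix.

    Standard agglomeration minimizing the Q criterion.  Ties are broken by
    the lexicographically smallest pair of cluster ids (a cluster is named
    after its smallest leaf), and negative branch lengths are truncated to
    zero.  Exactly additive inputs are reproduced by tree path lengths.
    The returned tree is unrooted (trifurcating root).
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm[1], dm[0]) if isinstance(dm, tuple) else DistanceMatrix(dm)
    data = np.array(dm.data, dtype=float)
    if np.isnan(data).any():
        raise ValueError("distance matrix contains NaN")
    n = data.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    nodes = [TreeNode(name=str(i)) for i in dm.ids]
    names = [str(i) for i in dm.ids]  # tie-break key: smallest leaf in cluster
    D = data

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((names[i], names[j]))), (i, j))
            for i, j in cand
            if i < j
        )
        i, j = best[1]
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        d_new = 0.5 * (D[i, :] + D[j, :] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], d_new[keep][None, :]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        new_name = min(names[i], names[j])
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [new_name]

    # resolve the final three clusters with the three-point formulas
    (a, b, c) = (0, 1, 2)
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = max(float(length), 0.0)
    return TreeNode(children=nodes)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root an unrooted tree at the midpoint of its longest leaf-to-leaf path."""
    tree = tree.copy()
    total = sum(n.length or 0.0 for n in tree.traverse() if n.length)
    if total == 0:
        warnings.warn("tree has zero total length; rooting at an arbitrary node")
        return tree
    tips = list(tree.tips())
    if len(tips) == 2:  # degenerate: place the root halfway between the pair
        d = tips[0].distance(tips[1])
        return TreeNode(
            children=[
                TreeNode(name=tips[0].name, length=d / 2.0),
                TreeNode(name=tips[1].name, length=d / 2.0),
            ]
        )
    return tree.root_at_midpoint()


def mrca_clade(rooted: TreeNode, anchors: list) -> list:
    """Leaves descending from the MRCA of the anchor leaves."""
    if not anchors:
        raise ValueError("need at least one anchor")
    leaf_names = {t.name for t in rooted.tips()}
    unknown = [a for a in anchors if a not in leaf_names]
    if unknown:
        raise ValueError(f"anchors not in tree: {unknown}")
    if len(anchors) == 1:
        return [anchors[0]]
    mrca = rooted.lca(anchors)
    if mrca.is_tip():
        return [mrca.name]
    return sorted(t.name for t in mrca.tips())


@dataclass
class CladeReport:
    """An anchor-defined clade with prevalence and copy-number summaries."""

    name: str
    anchors: list
    members: list
    copy_number: pd.Series  # per genome, 0 included
    prevalence: pd.Series  # per taxonomic class, fraction of genomes with >=1
    tree: TreeNode | None = None


def prevalence_summary(
    members: list,
    metadata: pd.DataFrame,
    classes: list | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Per-class prevalence and per-genome copy number of clade members.

    ``metadata`` needs columns ``seq_id``, ``genome_id`` and ``class``.
    Prevalence is the fraction of genomes in each class encoding at least
    one member; copy number counts members per genome over all genomes.
    When an explicit ``classes`` list is given, classes with no genomes in
    the metadata are omitted with a warning.
    """
    missing = set(members) - set(metadata["seq_id"])
    if missing:
        raise ValueError(f"members lack metadata: {sorted(missing)[:5]}")
    genome_class = metadata.drop_duplicates("genome_id").set_index("genome_id")["class"]
    member_meta = metadata[metadata["seq_id"].isin(members)]
    copies = member_meta.groupby("genome_id").size()
    copy_number = copies.reindex(genome_class.index, fill_value=0)
    copy_number.name = "copy_number"
    prevalence = (copy_number > 0).groupby(genome_class).mean()
    prevalence.name = "prevalence"
    if classes is not None:
        absent = [c for c in classes if c not in set(genome_class)]
        if absent:
            warnings.warn(f"classes with no genomes omitted: {absent}")
        prevalence = prevalence.reindex([c for c in classes if c not in absent])
    return prevalence, copy_number


def call_clade(
    sequences: dict,
    metadata: pd.DataFrame,
    anchors: list | None = None,
    name: str = "clade",
    matrix: str = "BLOSUM50",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> CladeReport:
    """Run the whole procedure: distances -> NJ -> midpoint -> MRCA -> summary."""
    if anchors is None:
        anchors = list(metadata.loc[metadata["is_anchor"], "seq_id"])
    dm = pairwise_distance(sequences, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)
    tree = midpoint_root(neighbor_joining(dm))
    members = mrca_clade(tree, anchors)
    prevalence, copy_number = prevalence_summary(members, metadata)
    return CladeReport(
        name=name,
        anchors=list(anchors),
        members=members,
        copy_number=copy_number,
        prevalence=prevalence,
        tree=tree,
    )
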