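"""Neighbor-joining trees and the >50% monophyly discrimination rule.

Trees are built from K2P distance matrices with the Saitou-Nei
agglomeration (scikit-bio's implementation) and treated as unrooted: a
"monophyletic group" is one side of a bipartition induced by an edge.  A
species is discriminated at a locus when strictly more than a threshold
fraction (default one half) of its individuals form such a pure side.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .barcode_stats import K2PDistanceMatrix

DEFAULT_DISCRIMINATION_THRESHOLD = 0.5


@dataclass
class PhyloTree:
    """An unrooted NJ tree plus a record of negative-length clamping."""

    tree: TreeNode
    clamped: bool

    def leaf_names(self) -> set[str]:
        return {tip.name for tip in self.tree.tips()}

    def newick(self) -> str:
        return str(self.tree)


class SaturatedPairError(ValueError):
    """The distance matrix carries saturated pairs; exclude them first."""


def nj(dm: K2PDistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a K2P matrix.

    Negative branch-length estimates (possible on non-additive matrices)
    are clamped to zero with the deficit moved to the adjacent branch; the
    ``clamped`` flag records whether that happened.
    """
    if len(dm) < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    if dm.any_saturated():
        bad = [
            (dm.sequence_ids[i], dm.sequence_ids[j])
            for i, j in zip(*np.nonzero(np.triu(dm.saturated, k=1)))
        ]
        raise SaturatedPairError(
            f"{len(bad)} saturated pair(s), e.g. {bad[0]}; exclude the "
            "affected sequences before tree building"
        )
    skbio_dm = DistanceMatrix(dm.values, ids=dm.sequence_ids)
    raw = _skbio_nj(skbio_dm, neg_as_zero=False)
    clamped = any(
        node.length is not None and node.length < 0 for node in raw.traverse()
    )
    tree = _skbio_nj(skbio_dm, neg_as_zero=True) if clamped else raw
    return PhyloTree(tree, clamped)


def _tip_sets(tree: TreeNode) -> list[frozenset[str]]:
    """Tip-name sets of every subtree (each induces one bipartition side)."""
    sets: list[frozenset[str]] = []
    cache: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_tip():
            cache[id(node)] = frozenset([node.name])
        else:
            cache[id(node)] = frozenset().union(
                *(cache[id(child)] for child in node.children)
            )
        sets.append(cache[id(node)])
    return sets


def monophyly_fraction(tree: PhyloTree | TreeNode, group: Iterable[str]) -> float:
    """Largest fraction of ``group`` forming a pure bipartition side.

    The tree is unrooted: each edge splits the leaves in two, and a side
    counts only if every leaf on it belongs to the group.  Returns 1.0 when
    the group is exactly one side (in particular when it is all leaves).
    """
    node = tree.tree if isinstance(tree, PhyloTree) else tree
    group = frozenset(group)
    if not group:
        raise ValueError("group must be non-empty")
    leaves = frozenset(tip.name for tip in node.tips())
    if not group <= leaves:
        raise ValueError(f"group members not in tree: {sorted(group - leaves)}")
    if group == leaves:
        return 1.0
    best = 0
    for side in _tip_sets(node):
        for candidate in (side, leaves - side):
            if candidate and candidate <= group and len(candidate) > best:
                best = len(candidate)
    return best / len(group)


def discriminated(
    tree: PhyloTree | TreeNode,
    group: Iterable[str],
    threshold: float = DEFAULT_DISCRIMINATION_THRESHOLD,
) -> bool:
    """Strict rule: the group is discriminated iff its monophyly fraction
    exceeds (not merely reaches) the threshold."""
    return monophyly_fraction(tree, group) > threshold


def path_length_matrix(tree: PhyloTree | TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path lengths; used for additivity and invariance checks."""
    node = tree.tree if isinstance(tree, PhyloTree) else tree
    tips = sorted(tip.name for tip in node.tips())
    n = len(tips)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = node.find(tips[i]).distance(node.find(tips[j]))
        out[i, j] = out[j, i] = d
    return tips, out


def bootstrap_support(
    matrix,
    groups: dict[str, set[str]],
    n_replicates: int = 0,
    seed: Optional[int] = None,
    deletion_policy: str = "pairwise",
) -> dict[str, float]:
    """Column-resampling bootstrap for group monophyly (optional; default
    zero replicates returns an empty report).

    Resamples alignment columns with replacement, rebuilds the NJ tree and
    reports, per named group, the fraction of replicates in which the group
    was strictly discriminated.
    """
    from .barcode_stats import k2p_matrix
    from .seqio import AlignedLocusMatrix, SeqEntry

    if n_replicates <= 0:
        return {}
    rng = np.random.default_rng(seed)
    hits = {name: 0 for name in groups}
    columns = np.arange(matrix.length)
    for _ in range(n_replicates):
        chosen = rng.choice(columns, size=matrix.length, replace=True)
        records = [
            SeqEntry(r.sequence_id, r.sample_id,
                     "".join(r.residues[c] for c in chosen),
                     r.clone_id, r.species_label)
            for r in matrix.records
        ]
        resampled = AlignedLocusMatrix(matrix.locus_id, records)
        try:
            tree = nj(k2p_matrix(resampled, deletion_policy))
        except (ValueError, SaturatedPairError):
            continue
        for name, members in groups.items():
            if discriminated(tree, members):
                hits[name] += 1
    return {name: count / n_replicates for name, count in hits.items()}
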