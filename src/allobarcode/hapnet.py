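"""Haplotype collapsing and parsimony-style network construction.

Identical aligned sequences are collapsed into haplotypes (gaps count as a
fifth character state) and connected into a minimum-spanning network: pairs
are linked in increasing mutational-step order, every alternative connection
of equal minimal length is retained (producing the loops typical of nuclear
loci), and a connection limit caps the number of steps an edge chain may
span, leaving more divergent haplogroups in separate components.  Multi-step
connections are materialised as chains of anonymous inferred intermediates
so every edge of the final graph is a single mutational step.

The statistical-parsimony probability recursion that would derive the limit
from a 95% confidence level is deliberately not recomputed; the limit is a
direct parameter (default 30 steps, the conventional cap for loci of this
length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import networkx as nx

from .seqio import AlignedLocusMatrix, AMBIG_CODE, encode_residues

DEFAULT_CONNECTION_LIMIT = 30

AmbiguityPolicy = Literal["strict", "keep"]


@dataclass
class Haplotype:
    """A distinct aligned sequence variant and the sequences that share it."""

    haplotype_id: str
    residues: str
    members: list[str]
    group: Optional[str] = None     # A-type / B-type / mixed

    def __len__(self) -> int:
        return len(self.residues)


def collapse_haplotypes(
    matrix: AlignedLocusMatrix, ambiguity_policy: AmbiguityPolicy = "strict"
) -> list[Haplotype]:
    """Collapse identical sequences into haplotypes (h1, h2, ... by first
    appearance).

    Under the default ``strict`` policy sequences carrying IUPAC ambiguity
    codes are excluded with a warning, mirroring the usual practice of
    dropping ambiguous reads before network construction; ``keep`` retains
    them, treating each ambiguity code as a literal state.
    """
    haps: dict[str, Haplotype] = {}
    excluded = []
    for rec in matrix.records:
        if ambiguity_policy == "strict":
            if (encode_residues(rec.residues) == AMBIG_CODE).any():
                excluded.append(rec.sequence_id)
                continue
        elif ambiguity_policy != "keep":
            raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
        hap = haps.get(rec.residues)
        if hap is None:
            hap = Haplotype(f"h{len(haps) + 1}", rec.residues, [])
            haps[rec.residues] = hap
        hap.members.append(rec.sequence_id)
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} ambiguous sequence(s) from haplotype "
            f"collapsing: {', '.join(excluded[:5])}"
            + ("..." if len(excluded) > 5 else "")
        )
    return list(haps.values())


def tag_haplotypes(
    haps: Iterable[Haplotype], labels: Mapping[str, str]
) -> None:
    """Assign each haplotype's group tag from its members' labels in place."""
    for hap in haps:
        groups = {labels[m] for m in hap.members if m in labels}
        if not groups:
            hap.group = None
        elif len(groups) == 1:
            hap.group = next(iter(groups))
        else:
            hap.group = "mixed"


def hap_steps(h1, h2) -> int:
    """Mutational steps between two haplotypes: Hamming distance over the
    five-state alphabet {A, C, G, T, -}."""
    s1 = h1.residues if isinstance(h1, Haplotype) else h1
    s2 = h2.residues if isinstance(h2, Haplotype) else h2
    if len(s1) != len(s2):
        raise ValueError("haplotypes differ in length")
    a = encode_residues(s1)
    b = encode_residues(s2)
    return int((a != b).sum())


@dataclass
class HaplotypeNetwork:
    """Unit-step haplotype graph with anonymous inferred intermediates.

    ``graph`` nodes carry an ``observed`` attribute; every edge is exactly
    one step.  ``connections`` lists the direct haplotype-to-haplotype links
    retained (with their step counts) before intermediate insertion, and
    ``components`` partitions the observed haplotypes.
    """

    graph: nx.Graph
    connection_limit: int
    connections: list[tuple[str, str, int]]
    components: list[set[str]]
    haplotypes: dict[str, Haplotype] = field(default_factory=dict)

    @property
    def n_observed(self) -> int:
        return sum(1 for _, obs in self.graph.nodes(data="observed") if obs)

    @property
    def n_inferred(self) -> int:
        return sum(1 for _, obs in self.graph.nodes(data="observed") if not obs)


def build_network(
    haps: Sequence[Haplotype],
    connection_limit: int = DEFAULT_CONNECTION_LIMIT,
) -> HaplotypeNetwork:
    """Minimum-spanning haplotype network with equal-length ties retained.

    Candidate pairs are processed in increasing step order; at each step
    level, every pair whose endpoints lie in different components *as of the
    previous level* is connected (so alternative minimal connections form
    loops), then components are merged.  Pairs needing more than
    ``connection_limit`` steps are never connected.
    """
    if not haps:
        raise ValueError("need at least one haplotype")
    graph = nx.Graph()
    for hap in haps:
        graph.add_node(hap.haplotype_id, observed=True,
                       n_members=len(hap.members), group=hap.group)

    pairs = []
    for i, h1 in enumerate(haps):
        for h2 in haps[i + 1:]:
            steps = hap_steps(h1, h2)
            pairs.append((steps, h1.haplotype_id, h2.haplotype_id))
    pairs.sort()

    parent = {h.haplotype_id: h.haplotype_id for h in haps}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    connections = []
    n_inferred = 0
    level_start = 0
    while level_start < len(pairs):
        steps = pairs[level_start][0]
        level_end = level_start
        while level_end < len(pairs) and pairs[level_end][0] == steps:
            level_end += 1
        if steps > connection_limit:
            break
        level = pairs[level_start:level_end]
        # admit edges against the component structure of the previous level
        admitted = [
            (a, b) for _, a, b in level
            if steps > 0 and find(a) != find(b)
        ]
        for a, b in admitted:
            connections.append((a, b, steps))
            if steps == 1:
                graph.add_edge(a, b)
            else:
                chain = [a]
                for _ in range(steps - 1):
                    n_inferred += 1
                    node = f"m{n_inferred}"
                    graph.add_node(node, observed=False)
                    chain.append(node)
                chain.append(b)
                for u, v in zip(chain, chain[1:]):
                    graph.add_edge(u, v)
        for a, b in admitted:
            parent[find(a)] = find(b)
        level_start = level_end

    roots: dict[str, set[str]] = {}
    for hap in haps:
        roots.setdefault(find(hap.haplotype_id), set()).add(hap.haplotype_id)
    components = sorted(roots.values(), key=lambda c: sorted(c)[0])
    return HaplotypeNetwork(
        graph, connection_limit, connections, components,
        {h.haplotype_id: h for h in haps},
    )


def intercluster_steps(
    haps: Sequence[Haplotype],
    group_a_members: Iterable[str],
    group_b_members: Iterable[str],
) -> int:
    """Minimum steps between any A-group and any B-group haplotype.

    A haplotype belongs to a group when any of its member sequences is in
    the group's id set.  This is the uncapped separation of the two
    haplogroups, reported independently of the network's connection limit.
    """
    set_a = set(group_a_members)
    set_b = set(group_b_members)
    haps_a = [h for h in haps if set(h.members) & set_a]
    haps_b = [h for h in haps if set(h.members) & set_b]
    if not haps_a or not haps_b:
        raise ValueError("both haplogroups must be non-empty")
    return min(hap_steps(h1, h2) for h1 in haps_a for h2 in haps_b)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_edge_list(network: HaplotypeNetwork, path) -> None:
    """Tab-separated edge list: node, node, steps(=1), inferred flags."""
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tsteps\tnode1_inferred\tnode2_inferred\n")
        for u, v in sorted(network.graph.edges()):
            iu = not network.graph.nodes[u]["observed"]
            iv = not network.graph.nodes[v]["observed"]
            fh.write(f"{u}\t{v}\t1\t{int(iu)}\t{int(iv)}\n")


def write_graphml(network: HaplotypeNetwork, path) -> None:
    graph = network.graph.copy()
    for _, data in graph.nodes(data=True):
        if data.get("group") is None:
            data.pop("group", None)
    nx.write_graphml(graph, path)


def write_membership_table(
    haps: Sequence[Haplotype], path, locus_id: str = ""
) -> None:
    """Per-sequence haplotype membership, mirroring a survey call table."""
    with open(path, "w") as fh:
        fh.write("sequence_id\thaplotype_id\tgroup\tlocus\n")
        for hap in haps:
            for member in hap.members:
                fh.write(f"{member}\t{hap.haplotype_id}\t"
                         f"{hap.group or ''}\t{locus_id}\n")
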