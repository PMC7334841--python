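"""mtDNA haplotype collapsing, distance matrices, and haplotype networks.

Works on pre-aligned mitochondrial sequences.  Columns containing a gap or
ambiguous base in any sequence are removed first (complete deletion, the
convention of alignment-polymorphism software); identical sequences over
the remaining columns collapse into haplotypes.  The network is the union
of all minimum spanning trees over haplotype Hamming distances — the
epsilon = 0 backbone of a median-joining network without added median
(Steiner) vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .genotype_io import ValidationError

_AMBIGUOUS = frozenset("-N")


@dataclass
class Alignment:
    """Equal-length aligned nucleotide sequences with unique identifiers."""

    ids: list[str]
    seqs: list[str]
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValidationError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate sequence identifiers")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValidationError("aligned sequences must have equal length")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0


@dataclass
class Haplotype:
    index: int
    sequence: str
    members: list[str]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeNetwork:
    haplotypes: list[Haplotype]
    graph: nx.Graph  # nodes: haplotype indices; edge attr "mutations"

    def edges(self) -> list[tuple[int, int, int]]:
        return [
            (u, v, int(d["mutations"])) for u, v, d in self.graph.edges(data=True)
        ]


def read_alignment(path: str, popmap: dict[str, str] | None = None) -> Alignment:
    """Read an aligned FASTA file."""
    from Bio import SeqIO

    ids, seqs = [], []
    for rec in SeqIO.parse(path, "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise ValidationError(f"{path}: no sequences found")
    return Alignment(ids=ids, seqs=seqs, populations=popmap or {})


def _retained_columns(aln: Alignment) -> list[int]:
    cols = []
    for j in range(aln.length):
        if all(s[j] not in _AMBIGUOUS for s in aln.seqs):
            cols.append(j)
    return cols


def collapse_haplotypes(aln: Alignment) -> list[Haplotype]:
    """Collapse identical sequences (over complete-deletion columns) into
    haplotypes, numbered by first occurrence."""
    if not aln.seqs:
        raise ValidationError("empty alignment")
    cols = _retained_columns(aln)
    if not cols:
        raise ValidationError("no columns remain after removing gap/N columns")
    haps: dict[str, Haplotype] = {}
    for sid, seq in zip(aln.ids, aln.seqs):
        key = "".join(seq[j] for j in cols)
        if key not in haps:
            haps[key] = Haplotype(index=len(haps), sequence=key, members=[])
        haps[key].members.append(sid)
    return list(haps.values())


def pairwise_differences(haplotypes: list[Haplotype]) -> np.ndarray:
    """Symmetric Hamming-distance matrix over collapsed haplotype sequences."""
    if len(haplotypes) < 2:
        raise ValidationError("need >= 2 haplotypes for a distance matrix")
    n = len(haplotypes)
    mat = np.zeros((n, n), dtype=np.int64)
    arrs = [np.frombuffer(h.sequence.encode(), dtype=np.uint8) for h in haplotypes]
    for i in range(n):
        for j in range(i + 1, n):
            d = int((arrs[i] != arrs[j]).sum())
            mat[i, j] = mat[j, i] = d
    return mat


def minimum_spanning_network(
    haplotypes: list[Haplotype], distances: np.ndarray
) -> HaplotypeNetwork:
    """Union of all minimum spanning trees over the haplotype distances.

    Kruskal with rank-grouped tie retention: edges are processed in weight
    groups; every edge in a group that joins two components formed by
    strictly lighter edges is kept (it belongs to at least one MST), and
    only then are the components merged.
    """
    n = len(haplotypes)
    if distances.shape != (n, n):
        raise ValidationError("distance matrix shape mismatch")
    g = nx.Graph()
    for h in haplotypes:
        g.add_node(h.index, count=h.count, members=list(h.members))
    if n == 1:
        return HaplotypeNetwork(haplotypes=haplotypes, graph=g)

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = sorted(
        ((int(distances[i, j]), i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: e[0],
    )
    i = 0
    while i < len(edges):
        w = edges[i][0]
        group = []
        while i < len(edges) and edges[i][0] == w:
            group.append(edges[i])
            i += 1
        keep = [
            (w_, u, v) for (w_, u, v) in group if find(u) != find(v)
        ]
        for w_, u, v in keep:
            g.add_edge(u, v, mutations=w_)
        for _, u, v in keep:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
    roots = {find(x) for x in range(n)}
    if len(roots) > 1:
        raise ValidationError("distance matrix is disconnected (zero-weight islands)")
    return HaplotypeNetwork(haplotypes=haplotypes, graph=g)


def alignment_pi(
    aln: Alignment, populations: dict[str, str] | None = None
) -> tuple[float, dict[str, float | None]]:
    """Per-site nucleotide diversity of an alignment: mean pairwise Hamming
    distance over all sequence pairs, divided by the retained column count.

    Returns (overall pi, per-population pi); groups of one sequence get None.
    """
    if len(aln.seqs) < 2:
        raise ValidationError("alignment pi needs >= 2 sequences")
    cols = _retained_columns(aln)
    if not cols:
        raise ValidationError("no columns remain after removing gap/N columns")
    trimmed = {
        sid: np.frombuffer(
            "".join(seq[j] for j in cols).encode(), dtype=np.uint8
        )
        for sid, seq in zip(aln.ids, aln.seqs)
    }

    def mean_pi(ids: list[str]) -> float:
        total = 0
        n_pairs = 0
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                total += int((trimmed[ids[a]] != trimmed[ids[b]]).sum())
                n_pairs += 1
        return total / n_pairs / len(cols)

    overall = mean_pi(aln.ids)
    pops = populations if populations is not None else aln.populations
    per_pop: dict[str, float | None] = {}
    if pops:
        groups: dict[str, list[str]] = {}
        for sid in aln.ids:
            if sid in pops:
                groups.setdefault(pops[sid], []).append(sid)
        for pop, ids in groups.items():
            per_pop[pop] = mean_pi(ids) if len(ids) >= 2 else None
    return overall, per_pop
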