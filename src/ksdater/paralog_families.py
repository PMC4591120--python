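"""Paralog pair filtering, single-linkage gene families, and node-Ks values.

All-by-all nucleotide hits are filtered at the duplicate-pair cutoffs
(E-value <= 1e-5, identity >= 40%, alignment length >= 150 bp), reciprocal
hits are merged, and connected components of the resulting pair graph form
gene families.  Each family is decomposed by agglomerative single-linkage
clustering of its pairwise Ks matrix into m-1 node values — one Ks per
internal node — so a family of m co-duplicated genes contributes m-1 data
points to the age distribution instead of m(m-1)/2 correlated pairs.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seq_io import HitRecord

EVALUE_MAX = 1e-5
PIDENT_MIN = 40.0
ALNLEN_MIN = 150

#: finite sentinel used for clustering pairs whose Ks estimation failed
_BIG = 1e9


@dataclasses.dataclass(frozen=True)
class ParalogPair:
    id_a: str
    id_b: str
    evalue: float
    pident: float
    aln_len: int

    def __post_init__(self):
        if self.id_a >= self.id_b:
            raise ValueError("ParalogPair requires id_a < id_b")


@dataclasses.dataclass
class GeneFamily:
    family_id: int
    members: tuple[str, ...]
    #: unordered member pair -> Ks (math.inf when estimation failed)
    pair_ks: dict[frozenset, float] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class NodeKs:
    family_id: int
    node_index: int
    ks: float
    ka: float | None
    left_members: tuple[str, ...]
    right_members: tuple[str, ...]


def filter_pairs(
    hits: Iterable[HitRecord],
    evalue_max: float = EVALUE_MAX,
    pident_min: float = PIDENT_MIN,
    alnlen_min: int = ALNLEN_MIN,
) -> list[ParalogPair]:
    """Duplicate-pair candidates from all-by-all hits.

    Self-hits are dropped; thresholds are inclusive at their stated values;
    A->B and B->A rows are merged keeping the row with the smaller E-value.
    """
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        if h.qid == h.sid:
            continue
        if h.evalue > evalue_max or h.pident < pident_min or h.aln_len < alnlen_min:
            continue
        key = (h.qid, h.sid) if h.qid < h.sid else (h.sid, h.qid)
        cur = best.get(key)
        if cur is None or (h.evalue, -h.bitscore) < (cur.evalue, -cur.bitscore):
            best[key] = h
    return [
        ParalogPair(id_a=a, id_b=b, evalue=h.evalue, pident=h.pident,
                    aln_len=h.aln_len)
        for (a, b), h in sorted(best.items())
    ]


def single_linkage_families(pairs: Iterable[ParalogPair]) -> list[GeneFamily]:
    """Connected components of the pair graph, ids assigned in order of the
    smallest member id."""
    graph = nx.Graph()
    for p in pairs:
        graph.add_edge(p.id_a, p.id_b)
    comps = sorted(
        (tuple(sorted(c)) for c in nx.connected_components(graph)),
        key=lambda members: members[0],
    )
    return [GeneFamily(family_id=i + 1, members=m) for i, m in enumerate(comps)]


def node_ks(
    family: GeneFamily,
    summary: str = "median",
    pair_ka: Mapping[frozenset, float] | None = None,
) -> list[NodeKs]:
    """Single-linkage node-Ks decomposition of one family.

    The family's pairwise Ks matrix (missing/failed pairs at +inf) is
    clustered by single linkage; each of the m-1 merges contributes one Ks:
    the ``summary`` statistic (median, min or mean) of all cross-cluster
    pairwise Ks at that merge.  Node values equal to 0 are removed.
    """
    if summary not in ("median", "min", "mean"):
        raise ValueError(f"unknown node summary {summary!r}")
    members = list(family.members)
    m = len(members)
    usable = {mem for pair in family.pair_ks
              for mem in pair if math.isfinite(family.pair_ks[pair])}
    if m < 2 or len(usable) < 2:
        return []
    idx = {name: i for i, name in enumerate(members)}

    dist = np.full((m, m), math.inf)
    np.fill_diagonal(dist, 0.0)
    for pair, ks in family.pair_ks.items():
        a, b = sorted(pair)
        dist[idx[a], idx[b]] = dist[idx[b], idx[a]] = ks

    finite = np.where(np.isfinite(dist), dist, _BIG)
    Z = linkage(squareform(finite, checks=False), method="single")

    summarize = {"median": np.median, "min": np.min, "mean": np.mean}[summary]
    clusters: dict[int, list[int]] = {i: [i] for i in range(m)}
    out: list[NodeKs] = []
    for node_i, (left, right, _height, _count) in enumerate(Z, start=1):
        li, ri = clusters.pop(int(left)), clusters.pop(int(right))
        cross = np.array([dist[i, j] for i in li for j in ri])
        ks_val = float(summarize(cross))
        ka_val = None
        if pair_ka is not None:
            kas = [pair_ka.get(frozenset((members[i], members[j])))
                   for i in li for j in ri]
            kas = [k for k in kas if k is not None and math.isfinite(k)]
            if kas:
                ka_val = float(summarize(np.array(kas)))
        out.append(
            NodeKs(
                family_id=family.family_id,
                node_index=node_i,
                ks=ks_val,
                ka=ka_val,
                left_members=tuple(members[i] for i in sorted(li)),
                right_members=tuple(members[j] for j in sorted(ri)),
            )
        )
        clusters[m + node_i - 1] = li + ri
    return [n for n in out if n.ks != 0.0]


def age_distribution(
    nodes: Iterable[NodeKs],
    ks_max: float = 2.0,
) -> list[float]:
    """Node Ks values entering the age distribution: 0 < ks < ks_max and
    finite (failed estimates excluded)."""
    return [n.ks for n in nodes
            if math.isfinite(n.ks) and 0.0 < n.ks < ks_max]


def family_node_ks(
    families: Sequence[GeneFamily],
    summary: str = "median",
) -> list[NodeKs]:
    out: list[NodeKs] = []
    for fam in families:
        out.extend(node_ks(fam, summary=summary))
    return out
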