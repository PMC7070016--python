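"""Clustering of retained hits into communities and hit groups.

A single horizontal transfer of one functional TE can yield thousands of
cross-clade hits, because the transferred copy keeps transposing within the
recipient genomes and is inherited through speciations.  Hits are therefore
reduced to *hit groups*, each representing one (direct or indirect)
transfer between two clades, in two iterations:

1. within each pair of young clades (crown age < 40 My), hits are connected
   when they satisfy **criterion 1** — the TE copies the two hits involve
   show higher sequence identity within at least one clade than between
   clades, the signature of post-transfer diversification inside a
   recipient clade — and communities of hits are delineated on that graph
   by greedy modularity maximization;
2. communities (possibly involving different species) are connected when
   ≥5% of their cross-community hit pairs pass criterion 1 (or when their
   copy sets are non-overlapping fragments of one element: no nucleotide
   homology and <100 bp of shared protein-anchored region), **and** they
   satisfy **criterion 2** — each community's average TE Ks must be at
   least the core-gene Ks quantile of every host speciation the common
   transfer would have to predate, so that "one transfer before the
   speciations" is chronologically possible.  Hit groups are then read off
   the community graph by complete-linkage agglomeration, which guarantees
   every pair of communities inside a group passes both criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from httscan.htt_filter import CoreKsLookup
from httscan.kaks import TECopy
from httscan.treespace import CladePartition, SpeciesTree

__all__ = [
    "IdentityTable",
    "HitCommunity",
    "HitGroup",
    "precluster",
    "criterion1_hits",
    "build_communities",
    "criterion1_communities",
    "criterion2_communities",
    "hit_groups",
    "cluster_pipeline",
]


class IdentityTable:
    """Symmetric copy-pair percent identities (best alignment >= 100 bp)."""

    def __init__(self, table: pd.DataFrame):
        self._pid: dict[tuple[str, str], float] = {}
        if len(table):
            for c1, c2, pid in zip(table["copy1"], table["copy2"],
                                   table["pid"]):
                key = (c1, c2) if c1 <= c2 else (c2, c1)
                prev = self._pid.get(key)
                if prev is None or pid > prev:
                    self._pid[key] = float(pid)

    def get(self, c1: str, c2: str) -> float | None:
        """Best identity between two copies; 100 for a copy with itself;
        None when no alignment was reported."""
        if c1 == c2:
            return 100.0
        key = (c1, c2) if c1 <= c2 else (c2, c1)
        return self._pid.get(key)

    def has_homology(self, set_a, set_b) -> bool:
        """True if any copy pair across the two sets shares an alignment
        (a copy present in both sets counts)."""
        set_a, set_b = set(set_a), set(set_b)
        if set_a & set_b:
            return True
        return any(
            self.get(a, b) is not None for a in set_a for b in set_b
        )


@dataclass(frozen=True)
class HitCommunity:
    community_id: int
    superfamily: str
    clade_pair: tuple[int, int]
    hit_ids: tuple[int, ...]
    copies_a: frozenset[str]
    copies_b: frozenset[str]
    species_a: frozenset[str]
    species_b: frozenset[str]
    mean_ks: float
    mean_pid: float


@dataclass
class HitGroup:
    group_id: int
    superfamily: str
    te_class: str
    community_ids: tuple[int, ...]
    hit_ids: tuple[int, ...]
    copies_a: frozenset[str]
    copies_b: frozenset[str]
    species_a: frozenset[str]
    species_b: frozenset[str]
    ks_values: np.ndarray
    hit_pids: np.ndarray  # member hit percent identities (cross-clade)
    theta: float  # Ks threshold in force when the member hits were selected
    retrieved_a: frozenset[str] = field(default_factory=frozenset)
    retrieved_b: frozenset[str] = field(default_factory=frozenset)

    @property
    def species(self) -> frozenset[str]:
        return self.species_a | self.species_b


# ---------------------------------------------------------------------------
# pre-clustering


def precluster(hits: pd.DataFrame, max_hits_per_pair: int = 200) -> pd.DataFrame:
    """Single-linkage clusters of hits sharing a TE copy, capped.

    Returns the hits with a ``precluster`` column, thinned to at most
    ``max_hits_per_pair`` hits per cluster per species pair, preferring
    hits covering the longest protein-coding regions (largest ``n_codons``,
    ties by score then stable id).
    """
    if hits.empty:
        out = hits.copy()
        out["precluster"] = pd.Series(dtype=int)
        return out
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for q, s in zip(hits["qseqid"], hits["sseqid"]):
        parent.setdefault(q, q)
        parent.setdefault(s, s)
        union(q, s)
    roots = sorted({find(c) for c in parent})
    root_ids = {r: i for i, r in enumerate(roots)}
    out = hits.copy()
    out["precluster"] = [root_ids[find(q)] for q in out["qseqid"]]

    pair_key = [tuple(sorted(t))
                for t in zip(out["q_species"], out["s_species"])]
    out["_pair"] = pair_key
    out = (
        out.sort_values(["n_codons", "bitscore"], ascending=False,
                        kind="mergesort")
        .groupby(["precluster", "_pair"], group_keys=False, sort=False)
        .head(max_hits_per_pair)
    )
    return out.drop(columns="_pair").sort_index()


# ---------------------------------------------------------------------------
# criterion 1 (identity structure)


def criterion1_hits(h1, h2, idt: IdentityTable) -> bool:
    """Can two hits derive from a single transfer?  True iff, in at least
    one clade, the identity between the two hits' copies in that clade
    exceeds the between-clade identity, taken as ``min(h1.pid, h2.pid)``.

    ``h1``/``h2`` carry ``copy_a, copy_b, pid`` with sides already aligned
    to the same clade pair.  Copy pairs without a reported alignment
    contribute no within-clade link.
    """
    ref = min(h1.pid, h2.pid)
    for c1, c2 in ((h1.copy_a, h2.copy_a), (h1.copy_b, h2.copy_b)):
        within = idt.get(c1, c2)
        if within is not None and within > ref:
            return True
    return False


@dataclass(frozen=True)
class _HitView:
    """One hit with its copies oriented to a (clade_a, clade_b) pair."""

    hit_id: int
    copy_a: str
    copy_b: str
    species_a: str
    species_b: str
    pid: float
    ks: float


def _hit_views(hits: pd.DataFrame, partition: CladePartition) -> list[_HitView]:
    views = []
    for row in hits.itertuples():
        ca, cb = partition.clade_of(row.q_species), partition.clade_of(row.s_species)
        if ca <= cb:
            views.append(_HitView(row.Index, row.qseqid, row.sseqid,
                                  row.q_species, row.s_species,
                                  row.pident, row.ks))
        else:
            views.append(_HitView(row.Index, row.sseqid, row.qseqid,
                                  row.s_species, row.q_species,
                                  row.pident, row.ks))
    return views


def build_communities(
    hits: pd.DataFrame,
    idt: IdentityTable,
    partition: CladePartition,
    start_id: int = 0,
) -> list[HitCommunity]:
    """Delineate hit communities within one (superfamily, clade-pair) set.

    Hits are nodes; criterion-1 passes are edges; communities maximize
    modularity by greedy agglomeration (isolated hits become singleton
    communities).  Node order is the stable hit id, making the partition
    deterministic.
    """
    if hits.empty:
        return []
    sf = hits["q_superfamily"].iloc[0]
    views = _hit_views(hits, partition)
    clade_pair = tuple(sorted((
        partition.clade_of(views[0].species_a),
        partition.clade_of(views[0].species_b),
    )))
    graph = nx.Graph()
    graph.add_nodes_from(v.hit_id for v in views)
    for i, v1 in enumerate(views):
        for v2 in views[i + 1 :]:
            if criterion1_hits(v1, v2, idt):
                graph.add_edge(v1.hit_id, v2.hit_id)
    membership: list[set[int]] = []
    for component in sorted(nx.connected_components(graph), key=min):
        sub = graph.subgraph(component)
        if sub.number_of_edges() == 0 or sub.number_of_nodes() <= 2:
            membership.append(set(component))
            continue
        comms = nx.community.greedy_modularity_communities(sub)
        membership.extend(sorted((set(c) for c in comms), key=min))
    view_by_id = {v.hit_id: v for v in views}
    communities = []
    for k, members in enumerate(membership):
        ids = tuple(sorted(members))
        vs = [view_by_id[h] for h in ids]
        ks_vals = [v.ks for v in vs if np.isfinite(v.ks)]
        communities.append(HitCommunity(
            community_id=start_id + k,
            superfamily=sf,
            clade_pair=clade_pair,
            hit_ids=ids,
            copies_a=frozenset(v.copy_a for v in vs),
            copies_b=frozenset(v.copy_b for v in vs),
            species_a=frozenset(v.species_a for v in vs),
            species_b=frozenset(v.species_b for v in vs),
            mean_ks=float(np.mean(ks_vals)) if ks_vals else float("nan"),
            mean_pid=float(np.mean([v.pid for v in vs])),
        ))
    return communities


# ---------------------------------------------------------------------------
# criterion 1 and 2 between communities


def shared_protein_region(copies_a, copies_b,
                          copy_index: dict[str, TECopy]) -> int:
    """Length (nt) of protein-anchored region shared by two copy sets,
    measured on the anchor proteins' own coordinates."""

    def anchored(copy_ids):
        intervals: dict[str, list[tuple[int, int]]] = {}
        for cid in copy_ids:
            for seg in copy_index[cid].frame_segments:
                intervals.setdefault(seg.protein_family, []).append(
                    (seg.protein_start, seg.protein_start + seg.end - seg.start)
                )
        return intervals

    def merged(intervals):
        out = []
        for start, end in sorted(intervals):
            if out and start <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], end))
            else:
                out.append((start, end))
        return out

    ia, ib = anchored(copies_a), anchored(copies_b)
    total = 0
    for prot in set(ia) & set(ib):
        ma, mb = merged(ia[prot]), merged(ib[prot])
        for a0, a1 in ma:
            for b0, b1 in mb:
                total += max(0, min(a1, b1) - max(a0, b0))
    return total


def criterion1_communities(
    c1: HitCommunity,
    c2: HitCommunity,
    idt: IdentityTable,
    hits: pd.DataFrame,
    partition: CladePartition,
    copy_index: dict[str, TECopy] | None = None,
    min_pass_fraction: float = 0.05,
    min_protein_overlap: int = 100,
    swap: bool = False,
) -> bool:
    """Criterion 1 between two communities: passed by at least
    ``min_pass_fraction`` of all cross-community hit pairs; if the two copy
    sets share no nucleotide homology at all and less than
    ``min_protein_overlap`` bp of anchored protein region, they are taken
    as non-overlapping fragments of one element and the criterion passes.
    ``swap`` aligns c2's sides to c1's when their clade pairs are oriented
    oppositely.
    """
    v1 = [v for v in _hit_views(hits.loc[list(c1.hit_ids)], partition)]
    v2 = [v for v in _hit_views(hits.loc[list(c2.hit_ids)], partition)]
    if swap:
        v2 = [
            _HitView(v.hit_id, v.copy_b, v.copy_a, v.species_b, v.species_a,
                     v.pid, v.ks)
            for v in v2
        ]
    total = len(v1) * len(v2)
    n_pass = sum(
        criterion1_hits(a, b, idt) for a in v1 for b in v2
    )
    if total and n_pass / total >= min_pass_fraction:
        return True
    all1 = c1.copies_a | c1.copies_b
    all2 = c2.copies_a | c2.copies_b
    if not idt.has_homology(all1, all2):
        if copy_index is None:
            return False
        if shared_protein_region(all1, all2, copy_index) < min_protein_overlap:
            return True
    return False


def orient_communities(c1: HitCommunity, c2: HitCommunity,
                       tree: SpeciesTree) -> bool | None:
    """Side mapping under which the two communities could share a transfer.

    Returns False (c2 unswapped), True (c2's sides swapped), or None when
    no mapping yields two host lineages each containing one side of both
    communities and excluding the other — in which case no single transfer
    can explain both.
    """
    for swap in (False, True):
        a2, b2 = (c2.species_b, c2.species_a) if swap else (
            c2.species_a, c2.species_b)
        ua = c1.species_a | a2
        ub = c1.species_b | b2
        if ua & ub:
            continue
        min_cross = min(
            tree.divergence_my(x, y) for x in ua for y in ub
        )
        if tree.crown_age(ua) < min_cross and tree.crown_age(ub) < min_cross:
            return swap
    return None


def criterion2_communities(
    c1: HitCommunity,
    c2: HitCommunity,
    core: CoreKsLookup,
    quantile: float = 0.005,
    swap: bool = False,
) -> bool:
    """Criterion 2: a common transfer must predate every within-side
    speciation separating the species the two communities involve.

    For each side where the species sets differ, both communities' mean
    hit Ks must reach the core-gene Ks quantile of the deepest divergence
    between one side's species and the other's; sides with identical
    species sets are vacuously compatible.
    """
    a2, b2 = (c2.species_b, c2.species_a) if swap else (
        c2.species_a, c2.species_b)
    for s1, s2 in ((c1.species_a, a2), (c1.species_b, b2)):
        if s1 == s2:
            continue
        qmax = 0.0
        for x in sorted(s1):
            for y in sorted(s2):
                if x == y:
                    continue
                qmax = max(qmax, core.quantile(x, y, quantile))
        if not (c1.mean_ks >= qmax and c2.mean_ks >= qmax):
            return False
    return True


# ---------------------------------------------------------------------------
# complete-linkage hit groups


def hit_groups(
    communities: list[HitCommunity],
    passes: dict[tuple[int, int], bool],
    affinity: dict[tuple[int, int], float] | None = None,
) -> list[list[HitCommunity]]:
    """Complete-linkage agglomeration on the community pass graph.

    ``passes[(i, j)]`` (i < j, community ids) marks pairs passing both
    criteria; two clusters merge only if every cross pair passes.  Merges
    proceed by decreasing mean affinity (mean community pair ``mean_pid``
    unless given), ties broken by lowest community id, so the partition is
    deterministic.
    """
    comms = {c.community_id: c for c in communities}
    if affinity is None:
        affinity = {
            (i, j): (comms[i].mean_pid + comms[j].mean_pid) / 2.0
            for (i, j), ok in passes.items() if ok
        }
    clusters: list[list[int]] = [[c.community_id] for c in
                                 sorted(communities,
                                        key=lambda c: c.community_id)]

    def pair_ok(i: int, j: int) -> bool:
        key = (i, j) if i < j else (j, i)
        return passes.get(key, False)

    def linkage(ca: list[int], cb: list[int]) -> float | None:
        vals = []
        for i in ca:
            for j in cb:
                if not pair_ok(i, j):
                    return None
                key = (i, j) if i < j else (j, i)
                vals.append(affinity.get(key, 0.0))
        return float(np.mean(vals)) if vals else None

    while True:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                score = linkage(clusters[x], clusters[y])
                if score is None:
                    continue
                key = (-score, clusters[x][0], clusters[y][0])
                if best is None or key < best[0]:
                    best = (key, x, y)
        if best is None:
            break
        _, x, y = best
        clusters[x] = sorted(clusters[x] + clusters[y])
        del clusters[y]
    return [[comms[i] for i in cl] for cl in clusters]


# ---------------------------------------------------------------------------
# orchestration over a filtered hit table


def cluster_pipeline(
    hits: pd.DataFrame,
    identities: pd.DataFrame,
    core: CoreKsLookup,
    tree: SpeciesTree,
    copy_index: dict[str, TECopy] | None = None,
    theta_by_hit: pd.Series | None = None,
    young_clade_age: float = 40.0,
    max_hits_per_pair: int = 200,
    min_pass_fraction: float = 0.05,
    min_protein_overlap: int = 100,
    quantile: float = 0.005,
    ks_cap: float = 0.5,
) -> tuple[list[HitCommunity], list[HitGroup], pd.DataFrame]:
    """Filtered hits -> communities -> hit groups.

    Returns (communities, groups, hits-after-precluster).  ``theta_by_hit``
    records the Ks threshold each hit was selected under; a group's theta
    is the loosest threshold among its member hits.
    """
    partition = tree.clades_younger_than(young_clade_age)
    idt = IdentityTable(identities)
    hits = precluster(hits, max_hits_per_pair)

    communities: list[HitCommunity] = []
    keys = []
    for row in hits.itertuples():
        cp = tuple(sorted((partition.clade_of(row.q_species),
                           partition.clade_of(row.s_species))))
        keys.append((row.q_superfamily, cp))
    hits = hits.assign(_key=pd.Series(keys, index=hits.index))
    for _key, sub in sorted(hits.groupby("_key", sort=False),
                            key=lambda kv: str(kv[0])):
        communities.extend(
            build_communities(sub.drop(columns="_key"), idt, partition,
                              start_id=len(communities))
        )
    hits = hits.drop(columns="_key")

    by_sf: dict[str, list[HitCommunity]] = {}
    for c in communities:
        by_sf.setdefault(c.superfamily, []).append(c)
    groups: list[HitGroup] = []
    te_class_of = {}
    if copy_index:
        te_class_of = {cid: te.te_class for cid, te in copy_index.items()}
    for sf in sorted(by_sf):
        cs = by_sf[sf]
        passes: dict[tuple[int, int], bool] = {}
        swaps: dict[tuple[int, int], bool] = {}
        for i, c1 in enumerate(cs):
            for c2 in cs[i + 1 :]:
                key = (c1.community_id, c2.community_id)
                swap = orient_communities(c1, c2, tree)
                if swap is None:
                    passes[key] = False
                    continue
                ok = criterion1_communities(
                    c1, c2, idt, hits, partition, copy_index,
                    min_pass_fraction, min_protein_overlap, swap,
                ) and criterion2_communities(c1, c2, core, quantile, swap)
                passes[key] = ok
                swaps[key] = swap
        for members in hit_groups(cs, passes):
            anchor = members[0]
            sp_a, sp_b = set(anchor.species_a), set(anchor.species_b)
            cp_a, cp_b = set(anchor.copies_a), set(anchor.copies_b)
            hit_ids: list[int] = list(anchor.hit_ids)
            for c in members[1:]:
                key = (min(anchor.community_id, c.community_id),
                       max(anchor.community_id, c.community_id))
                swap = swaps.get(key, False)
                a_sp, b_sp = (c.species_b, c.species_a) if swap else (
                    c.species_a, c.species_b)
                a_cp, b_cp = (c.copies_b, c.copies_a) if swap else (
                    c.copies_a, c.copies_b)
                sp_a |= a_sp
                sp_b |= b_sp
                cp_a |= a_cp
                cp_b |= b_cp
                hit_ids.extend(c.hit_ids)
            hit_ids = sorted(set(hit_ids))
            sub = hits.loc[hit_ids]
            ks_vals = sub["ks"].to_numpy(dtype=float)
            ks_vals = ks_vals[np.isfinite(ks_vals)]
            if theta_by_hit is not None:
                theta = float(theta_by_hit.loc[hit_ids].max())
            else:
                theta = ks_cap
            groups.append(HitGroup(
                group_id=len(groups),
                superfamily=sf,
                te_class=te_class_of.get(next(iter(cp_a)), ""),
                community_ids=tuple(c.community_id for c in members),
                hit_ids=tuple(hit_ids),
                copies_a=frozenset(cp_a),
                copies_b=frozenset(cp_b),
                species_a=frozenset(sp_a),
                species_b=frozenset(sp_b),
                ks_values=ks_vals,
                hit_pids=sub["pident"].to_numpy(dtype=float),
                theta=theta,
            ))
    return communities, groups, hits
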