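"""Counting independent transfer events from evaluated hit groups.

Two hit groups always witness at least two transfers, but similar TEs in
distantly related hosts need not have moved directly between them: each
clade may have acquired the element independently from third parties
("indirect transfer").  The minimal number of independent events is
estimated by a greedy explanatory-transfer procedure:

* a copy of the focal group (clade A side) is *explained* by another group
  when that group involves a clade C equal to, nested in, or encompassing
  clade A, and the copy resembles some clade-C copy of that group more
  than it resembles at least one of its own cross-clade partners;
* *requirement 1*: every species involved in the focal group has at least
  one explained copy, and at least two distinct explanatory groups appear
  among the explanations;
* explanatory groups whose removal would break requirement 1 are flagged
  *required* and can never themselves be explained away later;
* groups are processed by increasing reliability score — the lower of the
  two per-clade sums of each copy's best hit identity, so that weakly
  attested groups are candidates for removal first — and an explained
  group leaves the pool of potential explanations.

Groups still unexplained at the end are the independent transfer events.
The procedure is a greedy upper-bound heuristic, not an exact set-cover
minimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from httscan.htt_cluster import HitGroup, IdentityTable

__all__ = [
    "TransferEvent",
    "SimilarityIndex",
    "reliability",
    "copy_explained",
    "count_independent",
    "representative_pair",
]


class SimilarityIndex:
    """Best available percent identity between any two copies, pooled over
    hit tables and identity tables."""

    def __init__(self, hits: pd.DataFrame | None = None,
                 idt: IdentityTable | None = None):
        self._pid: dict[tuple[str, str], float] = dict(
            idt._pid) if idt is not None else {}
        if hits is not None and len(hits):
            for q, s, pid in zip(hits["qseqid"], hits["sseqid"],
                                 hits["pident"]):
                key = (q, s) if q <= s else (s, q)
                prev = self._pid.get(key)
                if prev is None or pid > prev:
                    self._pid[key] = float(pid)

    def get(self, c1: str, c2: str) -> float | None:
        if c1 == c2:
            return 100.0
        key = (c1, c2) if c1 <= c2 else (c2, c1)
        return self._pid.get(key)


@dataclass
class TransferEvent:
    group_id: int
    independent: bool
    reliability: float
    explained_by: frozenset[int]
    required_for: frozenset[int]
    representative_pair: tuple[str, str]
    superfamily: str
    te_class: str


@dataclass
class _GroupView:
    """Per-group data the counting procedure needs."""

    group: HitGroup
    species_of: dict[str, str]  # copy -> species (hit copies only)
    best_pid: dict[str, float]  # copy -> best member-hit pID
    weakest_cross: dict[str, float]  # copy -> min pID to the other clade
    partners: dict[str, str] = field(default_factory=dict)


def _views(groups: list[HitGroup], hits: pd.DataFrame,
           species_of_copy: dict[str, str]) -> dict[int, _GroupView]:
    views = {}
    for g in groups:
        best: dict[str, float] = {}
        weakest: dict[str, float] = {}
        for hid in g.hit_ids:
            row = hits.loc[hid]
            pid = float(row["pident"])
            for cid in (row["qseqid"], row["sseqid"]):
                if pid > best.get(cid, -1.0):
                    best[cid] = pid
                if pid < weakest.get(cid, 101.0):
                    weakest[cid] = pid
        views[g.group_id] = _GroupView(
            group=g,
            species_of={c: species_of_copy[c]
                        for c in (g.copies_a | g.copies_b)},
            best_pid=best,
            weakest_cross=weakest,
        )
    return views


def reliability(group: HitGroup, hits: pd.DataFrame) -> float:
    """Lower of the two per-clade sums of each copy's best hit pID."""
    best: dict[str, float] = {}
    for hid in group.hit_ids:
        row = hits.loc[hid]
        pid = float(row["pident"])
        for cid in (row["qseqid"], row["sseqid"]):
            if pid > best.get(cid, -1.0):
                best[cid] = pid
    sum_a = sum(best.get(c, 0.0) for c in group.copies_a)
    sum_b = sum(best.get(c, 0.0) for c in group.copies_b)
    return min(sum_a, sum_b)


def copy_explained(
    copy_id: str,
    own_clade: frozenset[str],
    weakest_cross_pid: float,
    candidate: HitGroup,
    sim: SimilarityIndex,
) -> bool:
    """Could this copy have entered its host via ``candidate`` instead?

    True iff one of the candidate's clades (clade C) is the same as,
    nested in, or encompassing the copy's clade, and the copy is more
    similar to some clade-C copy of the candidate (retrieved copies
    included) than to at least one of its own cross-clade partners.
    """
    for side_species, side_copies in (
        (candidate.species_a, candidate.copies_a | candidate.retrieved_a),
        (candidate.species_b, candidate.copies_b | candidate.retrieved_b),
    ):
        if not (side_species <= own_clade or own_clade <= side_species):
            continue
        for other in side_copies:
            if other == copy_id:
                continue
            pid = sim.get(copy_id, other)
            if pid is not None and pid > weakest_cross_pid:
                return True
    return False


def _explanations(
    focal: _GroupView, pool: list[HitGroup], sim: SimilarityIndex
) -> dict[str, set[int]]:
    """Per-species sets of candidate group ids explaining >= 1 copy."""
    g = focal.group
    per_species: dict[str, set[int]] = {}
    for side_copies, side_species in ((g.copies_a, g.species_a),
                                      (g.copies_b, g.species_b)):
        for cid in sorted(side_copies):
            species = focal.species_of[cid]
            weakest = focal.weakest_cross.get(cid)
            if weakest is None:
                continue
            for cand in pool:
                if cand.group_id == g.group_id:
                    continue
                if copy_explained(cid, side_species, weakest, cand, sim):
                    per_species.setdefault(species, set()).add(cand.group_id)
    return per_species


def _requirement1(per_species: dict[str, set[int]],
                  species: frozenset[str]) -> bool:
    if not all(per_species.get(sp) for sp in species):
        return False
    used = set().union(*per_species.values()) if per_species else set()
    return len(used) >= 2


def count_independent(
    groups: list[HitGroup],
    hits: pd.DataFrame,
    species_of_copy: dict[str, str],
    sim: SimilarityIndex,
    descending: bool = False,
) -> list[TransferEvent]:
    """Greedy explanatory-transfer reduction; see the module docstring.

    Groups are processed by increasing reliability (ties by group id); an
    explained group leaves the explanatory pool; groups flagged required by
    an earlier focal group are never explained.  ``descending`` reverses
    the processing order (a sensitivity probe, not the standard
    procedure).
    """
    views = _views(groups, hits, species_of_copy)
    order = sorted(groups,
                   key=lambda g: (reliability(g, hits), g.group_id),
                   reverse=descending)
    pool: dict[int, HitGroup] = {g.group_id: g for g in groups}
    required: dict[int, set[int]] = {}  # group -> focal groups needing it
    explained_by: dict[int, frozenset[int]] = {}

    for focal in order:
        view = views[focal.group_id]
        candidates = [pool[i] for i in sorted(pool) if i != focal.group_id]
        per_species = _explanations(view, candidates, sim)
        species = frozenset(view.species_of.values())
        if not _requirement1(per_species, species):
            continue
        used = sorted(set().union(*per_species.values()))
        for cand_id in used:
            reduced = {
                sp: ids - {cand_id} for sp, ids in per_species.items()
            }
            if not _requirement1(reduced, species):
                required.setdefault(cand_id, set()).add(focal.group_id)
        if focal.group_id in required:
            continue  # required to explain an earlier group; keep it
        explained_by[focal.group_id] = frozenset(used)
        del pool[focal.group_id]

    events = []
    for g in sorted(groups, key=lambda g: g.group_id):
        events.append(TransferEvent(
            group_id=g.group_id,
            independent=g.group_id not in explained_by,
            reliability=reliability(g, hits),
            explained_by=explained_by.get(g.group_id, frozenset()),
            required_for=frozenset(required.get(g.group_id, set())),
            representative_pair=representative_pair(g, hits),
            superfamily=g.superfamily,
            te_class=g.te_class,
        ))
    return events


def representative_pair(group: HitGroup, hits: pd.DataFrame) -> tuple[str, str]:
    """Species pair of the member hit with the highest identity (ties by
    stable hit id); clade-A species first."""
    best = None
    for hid in group.hit_ids:
        row = hits.loc[hid]
        key = (-float(row["pident"]), hid)
        if best is None or key < best[0]:
            q_sp, s_sp = row["q_species"], row["s_species"]
            if q_sp in group.species_a:
                pair = (q_sp, s_sp)
            else:
                pair = (s_sp, q_sp)
            best = (key, pair)
    if best is None:
        raise ValueError(f"group {group.group_id} has no member hits")
    return best[1]
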