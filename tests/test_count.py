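import itertools

import numpy as np
import pandas as pd
import pytest

from httscan.htt_cluster import HitGroup, IdentityTable
from httscan.htt_count import (
    SimilarityIndex,
    copy_explained,
    count_independent,
    reliability,
    representative_pair,
)
from tests.oracles import count_independent_oracle


def build_instance(spec):
    """Build (groups, hits, species_of_copy, sim) plus the pre-digested
    oracle form from a compact description.

    ``spec``: list of dicts with keys ``copies_a``/``copies_b`` mapping
    copy -> species, ``hits``: list of (copy_a, copy_b, pid), and shared
    ``extra_sims``: dict of unordered copy pair -> pid.
    """
    rows = []
    groups = []
    species_of = {}
    hit_id = 0
    for gid, g in enumerate(spec["groups"]):
        ids = []
        for ca, cb, pid in g["hits"]:
            rows.append({
                "qseqid": ca, "sseqid": cb, "pident": pid,
                "q_species": g["copies_a"][ca], "s_species": g["copies_b"][cb],
            })
            ids.append(hit_id)
            hit_id += 1
        species_of.update(g["copies_a"])
        species_of.update(g["copies_b"])
        groups.append(HitGroup(
            group_id=gid, superfamily="SF", te_class="DNA_transposon",
            community_ids=(gid,), hit_ids=tuple(ids),
            copies_a=frozenset(g["copies_a"]),
            copies_b=frozenset(g["copies_b"]),
            species_a=frozenset(g["copies_a"].values()),
            species_b=frozenset(g["copies_b"].values()),
            ks_values=np.array([0.1]), hit_pids=np.array([90.0]),
            theta=0.5,
        ))
    hits = pd.DataFrame(rows)
    idt_rows = [("SF", a, b, pid)
                for (a, b), pid in spec.get("extra_sims", {}).items()]
    idt = IdentityTable(pd.DataFrame(
        idt_rows, columns=["superfamily", "copy1", "copy2", "pid"]))
    sim = SimilarityIndex(hits, idt)
    return groups, hits, species_of, sim


def digest_for_oracle(groups, hits, species_of, sim):
    """Re-derive the oracle's pre-digested instance independently of the
    implementation's internals (only raw tables are used)."""
    out = {}
    for g in groups:
        copies = {}
        for side_copies, side_species in ((g.copies_a, g.species_a),
                                          (g.copies_b, g.species_b)):
            for cid in side_copies:
                mine = hits[(hits.qseqid == cid) | (hits.sseqid == cid)]
                mine = mine[mine.index.isin(g.hit_ids)]
                if mine.empty:
                    continue
                copies[cid] = (side_species, float(mine.pident.min()),
                               species_of[cid])
        out[g.group_id] = {
            "copies": copies,
            "clades": (g.species_a, g.species_b),
            "side_copies": (set(g.copies_a), set(g.copies_b)),
            "sims": {tuple(sorted((a, b))): sim.get(a, b)
                     for a in species_of for b in species_of if a < b
                     if sim.get(a, b) is not None},
        }
    return out


def simple_group(gid, a_species, b_species, pid=90.0, tag=None):
    tag = tag or f"g{gid}"
    copies_a = {f"{tag}a{i}_{sp}": sp for i, sp in enumerate(a_species)}
    copies_b = {f"{tag}b{i}_{sp}": sp for i, sp in enumerate(b_species)}
    hits = [(ca, cb, pid) for ca in copies_a for cb in copies_b]
    return {"copies_a": copies_a, "copies_b": copies_b, "hits": hits}


class TestReliability:
    def test_min_of_per_clade_best_pid_sums(self):
        spec = {"groups": [{
            "copies_a": {"a1": "s1", "a2": "s1"},
            "copies_b": {"b1": "s2"},
            "hits": [("a1", "b1", 90.0), ("a2", "b1", 80.0)],
        }]}
        groups, hits, _, _ = build_instance(spec)
        # clade A sums best pids 90 + 80 = 170; clade B has one copy at 90
        assert reliability(groups[0], hits) == pytest.approx(90.0)

    def test_monotone_in_added_copies(self):
        base = {"groups": [simple_group(0, ["s1"], ["s2"])]}
        bigger = {"groups": [simple_group(0, ["s1", "s1"], ["s2"])]}
        g1, h1, _, _ = build_instance(base)
        g2, h2, _, _ = build_instance(bigger)
        assert reliability(g2[0], h2) >= reliability(g1[0], h1)


class TestCopyExplained:
    def _candidate(self, species_a, copies_a, species_b=("z",)):
        return HitGroup(
            group_id=1, superfamily="SF", te_class="DNA_transposon",
            community_ids=(1,), hit_ids=(),
            copies_a=frozenset(copies_a),
            copies_b=frozenset({f"zz{i}" for i in range(len(species_b))}),
            species_a=frozenset(species_a), species_b=frozenset(species_b),
            ks_values=np.array([0.1]), hit_pids=np.array([90.0]), theta=0.5,
        )

    def _sim(self, entries):
        rows = [("SF", a, b, pid) for (a, b), pid in entries.items()]
        return SimilarityIndex(None, IdentityTable(pd.DataFrame(
            rows, columns=["superfamily", "copy1", "copy2", "pid"])))

    def test_same_clade_and_higher_similarity(self):
        cand = self._candidate({"s1"}, {"c1"})
        sim = self._sim({("a1", "c1"): 95.0})
        assert copy_explained("a1", frozenset({"s1"}), 90.0, cand, sim)

    def test_disjoint_clade_never_explains(self):
        cand = self._candidate({"s9"}, {"c1"})
        sim = self._sim({("a1", "c1"): 99.0})
        assert not copy_explained("a1", frozenset({"s1"}), 90.0, cand, sim)

    def test_similarity_not_above_weakest_partner(self):
        cand = self._candidate({"s1"}, {"c1"})
        sim = self._sim({("a1", "c1"): 90.0})
        assert not copy_explained("a1", frozenset({"s1"}), 92.0, cand, sim)

    def test_nested_clades_allowed_both_ways(self):
        sim = self._sim({("a1", "c1"): 95.0})
        nested = self._candidate({"s1"}, {"c1"})
        enclosing = self._candidate({"s1", "s3"}, {"c1"})
        assert copy_explained("a1", frozenset({"s1", "s3"}), 90.0, nested,
                              sim)
        assert copy_explained("a1", frozenset({"s1"}), 90.0, enclosing, sim)


class TestCountIndependent:
    def test_single_group_is_independent(self):
        spec = {"groups": [simple_group(0, ["s1"], ["s2"])]}
        events = count_independent(*build_instance(spec))
        assert [e.independent for e in events] == [True]

    def test_two_groups_cannot_explain_each_other(self):
        # each would need two distinct explanatory transfers
        spec = {"groups": [
            simple_group(0, ["s1"], ["s2"]),
            simple_group(1, ["s1"], ["s3"]),
        ], "extra_sims": {}}
        groups, hits, species_of, sim = build_instance(spec)
        events = count_independent(groups, hits, species_of, sim)
        assert all(e.independent for e in events)

    def test_weak_group_explained_by_two_strong_ones(self):
        # group 2's copies match groups 0 and 1 better than their own
        # cross-clade partners
        spec = {"groups": [
            simple_group(0, ["s1"], ["s9"], pid=95.0),
            simple_group(1, ["s2"], ["s9"], pid=95.0),
            {"copies_a": {"xa_s1": "s1"}, "copies_b": {"xb_s2": "s2"},
             "hits": [("xa_s1", "xb_s2", 80.0)]},
        ], "extra_sims": {
            ("xa_s1", "g0a0_s1"): 92.0,   # matches group 0's clade copies
            ("xb_s2", "g1a0_s2"): 91.0,   # matches group 1's clade copies
        }}
        groups, hits, species_of, sim = build_instance(spec)
        events = count_independent(groups, hits, species_of, sim)
        flags = {e.group_id: e.independent for e in events}
        assert flags == {0: True, 1: True, 2: False}
        assert {e.group_id: sorted(e.explained_by)
                for e in events}[2] == [0, 1]

    def test_representative_pair_is_best_hit(self):
        spec = {"groups": [{
            "copies_a": {"a1": "s1", "a2": "s3"},
            "copies_b": {"b1": "s2"},
            "hits": [("a1", "b1", 91.0), ("a2", "b1", 95.0),
                     ("a1", "b1", 88.0)],
        }]}
        groups, hits, _, _ = build_instance(spec)
        assert representative_pair(groups[0], hits) == ("s3", "s2")


class TestOracleAgreement:
    def random_instance(self, rng, n_groups):
        species_pool = [f"s{i}" for i in range(4)]
        groups = []
        for gid in range(n_groups):
            n_a = int(rng.integers(1, 4))
            n_b = int(rng.integers(1, 4))
            sp_a = [species_pool[rng.integers(2)] for _ in range(n_a)]
            sp_b = [species_pool[2 + rng.integers(2)] for _ in range(n_b)]
            g = simple_group(gid, sp_a, sp_b,
                             pid=float(rng.uniform(76, 96)))
            groups.append(g)
        # random cross-group similarities
        all_copies = [c for g in groups
                      for c in list(g["copies_a"]) + list(g["copies_b"])]
        extra = {}
        for _ in range(n_groups * 6):
            a, b = rng.choice(all_copies, size=2, replace=False)
            extra[tuple(sorted((a, b)))] = float(rng.uniform(70, 100))
        return {"groups": groups, "extra_sims": extra}

    def test_matches_literal_procedure_on_small_instances(self, rng):
        for trial in range(40):
            n_groups = int(rng.integers(2, 7))
            spec = self.random_instance(rng, n_groups)
            groups, hits, species_of, sim = build_instance(spec)
            events = count_independent(groups, hits, species_of, sim)
            impl_explained = {e.group_id for e in events if not e.independent}
            digest = digest_for_oracle(groups, hits, species_of, sim)
            order = [e.group_id for e in
                     sorted(events, key=lambda e: (e.reliability,
                                                   e.group_id))]
            oracle_explained = count_independent_oracle(digest, order)
            assert impl_explained == oracle_explained

    def test_count_close_to_best_over_all_orders(self, rng):
        for trial in range(12):
            n_groups = int(rng.integers(3, 6))
            spec = self.random_instance(rng, n_groups)
            groups, hits, species_of, sim = build_instance(spec)
            events = count_independent(groups, hits, species_of, sim)
            impl_count = sum(e.independent for e in events)
            digest = digest_for_oracle(groups, hits, species_of, sim)
            best = min(
                n_groups - len(count_independent_oracle(digest, list(order)))
                for order in itertools.permutations(range(n_groups))
            )
            # the procedure is greedy, not optimal
            assert best <= impl_count <= best + 1

    def test_reverse_order_changes_counts_moderately(self, rng):
        counts_f, counts_r = 0, 0
        for trial in range(15):
            spec = self.random_instance(rng, 5)
            groups, hits, species_of, sim = build_instance(spec)
            fwd = count_independent(groups, hits, species_of, sim)
            rev = count_independent(groups, hits, species_of, sim,
                                    descending=True)
            counts_f += sum(e.independent for e in fwd)
            counts_r += sum(e.independent for e in rev)
        assert abs(counts_f - counts_r) <= 0.15 * max(counts_f, counts_r)
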