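import pandas as pd

from httscan.htt_cluster import (
    IdentityTable,
    criterion1_hits,
    hit_groups,
    precluster,
    shared_protein_region,
)
from httscan.kaks import FrameSegment, TECopy


class _H:
    def __init__(self, copy_a, copy_b, pid):
        self.copy_a, self.copy_b, self.pid = copy_a, copy_b, pid


def idt(rows):
    return IdentityTable(pd.DataFrame(rows, columns=["superfamily", "copy1",
                                                     "copy2", "pid"]))


class TestCriterion1Hits:
    def test_within_clade_identity_above_reference_passes(self):
        table = idt([("SF", "A1", "A2", 95.0)])
        assert criterion1_hits(_H("A1", "B1", 90), _H("A2", "B2", 90), table)

    def test_no_side_above_reference_fails(self):
        table = idt([("SF", "A1", "A2", 85.0), ("SF", "B1", "B2", 84.0)])
        assert not criterion1_hits(_H("A1", "B1", 90), _H("A2", "B2", 90),
                                   table)

    def test_hit_with_itself_passes_via_shared_copies(self):
        h = _H("A1", "B1", 90)
        assert criterion1_hits(h, h, idt([]))

    def test_missing_identity_contributes_no_link(self):
        assert not criterion1_hits(_H("A1", "B1", 90), _H("A2", "B2", 90),
                                   idt([]))

    def test_reference_is_the_weaker_hit(self):
        table = idt([("SF", "A1", "A2", 88.0)])
        # min(pid) = 85 < 88 -> pass even though one hit is at 95
        assert criterion1_hits(_H("A1", "B1", 95), _H("A2", "B2", 85), table)


class TestPrecluster:
    def _hits(self, rows):
        return pd.DataFrame(
            rows, columns=["qseqid", "sseqid", "q_species", "s_species",
                           "n_codons", "bitscore"],
        )

    def test_shared_copy_links_hits(self):
        out = precluster(self._hits([
            ("A", "B", "s1", "s2", 100, 500),
            ("A", "C", "s1", "s2", 100, 500),
            ("D", "E", "s1", "s2", 100, 500),
        ]))
        assert out.precluster.iloc[0] == out.precluster.iloc[1]
        assert out.precluster.iloc[0] != out.precluster.iloc[2]

    def test_cap_prefers_longest_coding_regions(self):
        rows = [(f"A{i}", "B", "s1", "s2", i, 500.0) for i in range(250)]
        out = precluster(self._hits(rows), max_hits_per_pair=200)
        assert len(out) == 200
        assert out.n_codons.min() == 50  # the 200 largest survive

    def test_no_shared_copies_every_hit_isolated(self):
        out = precluster(self._hits([
            ("A", "B", "s1", "s2", 100, 500),
            ("C", "D", "s1", "s2", 100, 500),
        ]))
        assert out.precluster.nunique() == 2


class TestSharedProteinRegion:
    def _copy(self, cid, segs):
        return TECopy(cid, "sp", "SF", "DNA_transposon", "A" * 1200, segs)

    def test_full_overlap(self):
        idx = {
            "a": self._copy("a", [FrameSegment(0, 600, 0, "pol", 0)]),
            "b": self._copy("b", [FrameSegment(0, 600, 0, "pol", 0)]),
        }
        assert shared_protein_region({"a"}, {"b"}, idx) == 600

    def test_disjoint_fragments_share_nothing(self):
        idx = {
            "a": self._copy("a", [FrameSegment(0, 600, 0, "pol", 0)]),
            "b": self._copy("b", [FrameSegment(0, 600, 0, "pol", 600)]),
        }
        assert shared_protein_region({"a"}, {"b"}, idx) == 0

    def test_different_proteins_share_nothing(self):
        idx = {
            "a": self._copy("a", [FrameSegment(0, 600, 0, "pol", 0)]),
            "b": self._copy("b", [FrameSegment(0, 600, 0, "gag", 0)]),
        }
        assert shared_protein_region({"a"}, {"b"}, idx) == 0


class TestCriterion1Communities:
    def _setup(self, n1, n2, n_pass, protein_starts=(0, 0)):
        """Two communities with a controlled number of passing cross
        pairs: passing pairs share clade-A copies with a recorded
        within-clade identity above the hit pIDs."""
        from httscan.htt_cluster import HitCommunity, criterion1_communities
        from httscan.treespace import parse_timetree

        tree = parse_timetree("((s1:10,s1b:10):150,(s2:10,s2b:10):150);")
        partition = tree.clades_younger_than(40)
        rows = []
        idt_rows = []
        hit_id = 0
        copies = {}

        def add_copy(cid, species, pstart):
            copies[cid] = TECopy(cid, species, "SF", "DNA_transposon",
                                 "A" * 1200,
                                 [FrameSegment(0, 600, 0, "pol", pstart)])

        for comm, (n, pstart) in enumerate(((n1, protein_starts[0]),
                                            (n2, protein_starts[1]))):
            for i in range(n):
                ca, cb = f"c{comm}a{i}", f"c{comm}b{i}"
                add_copy(ca, "s1", pstart)
                add_copy(cb, "s2", pstart)
                rows.append({"qseqid": ca, "sseqid": cb, "q_species": "s1",
                             "s_species": "s2", "q_superfamily": "SF",
                             "pident": 85.0, "ks": 0.1})
                hit_id += 1
        # exactly n_pass cross pairs get a strong within-clade link
        count = 0
        for i in range(n1):
            for j in range(n2):
                if count < n_pass:
                    idt_rows.append(("SF", f"c0a{i}", f"c1a{j}", 95.0))
                    count += 1
        hits = pd.DataFrame(rows)
        idt = IdentityTable(pd.DataFrame(
            idt_rows, columns=["superfamily", "copy1", "copy2", "pid"]))
        comms = []
        for comm, n in enumerate((n1, n2)):
            ids = tuple(range(comm * n1, comm * n1 + n))
            comms.append(HitCommunity(
                comm, "SF", (0, 1), ids,
                frozenset(f"c{comm}a{i}" for i in range(n)),
                frozenset(f"c{comm}b{i}" for i in range(n)),
                frozenset({"s1"}), frozenset({"s2"}), 0.1, 85.0))
        hits.index = range(len(hits))
        return comms, idt, hits, partition, copies, criterion1_communities

    def test_five_percent_boundary_is_inclusive(self):
        comms, idt, hits, part, copies, crit = self._setup(10, 10, 5)
        assert crit(comms[0], comms[1], idt, hits, part, copies)

    def test_below_five_percent_fails(self):
        comms, idt, hits, part, copies, crit = self._setup(10, 10, 4)
        assert not crit(comms[0], comms[1], idt, hits, part, copies)

    def test_disjoint_fragments_pass_via_fallback(self):
        # no within- or cross-community homology at all, and the two copy
        # sets anchor disjoint protein regions: fragmentation fallback
        comms, idt, hits, part, copies, crit = self._setup(
            3, 3, 0, protein_starts=(0, 600))
        assert crit(comms[0], comms[1], idt, hits, part, copies)

    def test_disjoint_copy_sets_with_shared_protein_fail(self):
        comms, idt, hits, part, copies, crit = self._setup(
            3, 3, 0, protein_starts=(0, 0))
        assert not crit(comms[0], comms[1], idt, hits, part, copies)


class TestCompleteLinkage:
    def _comm(self, cid, pid=90.0):
        from httscan.htt_cluster import HitCommunity

        return HitCommunity(cid, "SF", (0, 1), (cid,), frozenset({f"a{cid}"}),
                            frozenset({f"b{cid}"}), frozenset({"s1"}),
                            frozenset({"s2"}), 0.1, pid)

    def test_all_pairs_passing_gives_one_group(self):
        comms = [self._comm(i) for i in range(3)]
        passes = {(i, j): True for i in range(3) for j in range(i + 1, 3)}
        groups = hit_groups(comms, passes)
        assert len(groups) == 1 and len(groups[0]) == 3

    def test_chain_without_closure_splits(self):
        comms = [self._comm(i) for i in range(3)]
        passes = {(0, 1): True, (1, 2): True, (0, 2): False}
        groups = hit_groups(comms, passes)
        sizes = sorted(len(g) for g in groups)
        assert sizes == [1, 2]

    def test_no_passing_pairs_keeps_singletons(self):
        comms = [self._comm(i) for i in range(4)]
        groups = hit_groups(comms, {})
        assert len(groups) == 4

    def test_deterministic_partition(self):
        comms = [self._comm(i, pid=80 + i) for i in range(5)]
        passes = {(0, 1): True, (1, 2): True, (2, 3): True, (0, 2): True,
                  (1, 3): False, (0, 3): False, (0, 4): False, (1, 4): True,
                  (2, 4): False, (3, 4): False}
        g1 = [[c.community_id for c in g] for g in hit_groups(comms, passes)]
        g2 = [[c.community_id for c in g] for g in hit_groups(comms, passes)]
        assert g1 == g2


class TestClusterEndToEnd:
    def test_planted_events_give_distinct_superfamily_groups(
            self, two_event_result):
        groups = two_event_result.groups
        assert {g.superfamily for g in groups} >= {"Tc1_Mariner", "LINE1"}
        # sides are species sets from the two deep sides of the tree
        for g in groups:
            sides = [{s[0] for s in g.species_a}, {s[0] for s in g.species_b}]
            assert sides[0] in ({"F"}, {"T"}) and sides[1] in ({"F"}, {"T"})
            assert sides[0] != sides[1]

    def test_complete_linkage_audit(self, two_event_dataset,
                                    two_event_result):
        """Every community pair inside every emitted group passes both
        criteria when re-checked exhaustively."""
        from httscan.htt_cluster import (
            criterion1_communities,
            criterion2_communities,
            orient_communities,
        )
        from httscan.htt_filter import CoreKsLookup

        res = two_event_result
        ds = two_event_dataset
        core = CoreKsLookup(ds.core_ks, ds.tree)
        table = IdentityTable(ds.identities)
        partition = ds.tree.clades_younger_than(40)
        comms = {c.community_id: c for c in res.communities}
        hits = res.retained
        for g in res.groups:
            for i, ci in enumerate(g.community_ids):
                for cj in g.community_ids[i + 1:]:
                    c1, c2 = comms[ci], comms[cj]
                    swap = orient_communities(c1, c2, ds.tree)
                    assert swap is not None
                    assert criterion1_communities(
                        c1, c2, table, hits, partition, ds.copies, swap=swap)
                    assert criterion2_communities(c1, c2, core, swap=swap)
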