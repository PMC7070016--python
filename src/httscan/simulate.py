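"""Forward simulator of core-gene and TE evolution along a dated species tree.

The simulator is first-class, tested code: it produces every input the
transfer-detection pipeline consumes — TE copies with coding-frame
annotations, core-gene synonymous divergences per species pair, TE-TE
similarity hits in BLAST tabular form, within-clade identity tables — plus
ground-truth records for every planted horizontal transfer, so that each
pipeline stage can be verified end to end without external data.

Model
-----
Sequences evolve by a per-site proposal/rejection codon process: point
mutations are proposed uniformly over the three alternative bases at a total
rate of ``mu_s`` per site per year; proposals creating stop codons are always
rejected and non-synonymous proposals are rejected with probability
``1 - omega``.  Under this process the expected pairwise synonymous
divergence of two lineages split ``t`` years ago is ``2 * mu_s * t`` (on
Li's synonymous-site scale) and the realized Ka/Ks approaches ``omega``.
The default ``mu_s`` of 3.1e-9 substitutions per synonymous site per year is
the neutral vertebrate rate the divergence filters are calibrated against.

TE families evolve gaplessly (substitutions only), so homologous coordinates
stay exact and hit emission reduces to positional comparison; different
families of a superfamily share a protein anchor but no nucleotide homology.
Copies duplicate by transposition bursts (duplicating a randomly chosen
active copy in the lineage), are inherited through speciations, and may be
copied across lineages by planted horizontal transfer events, after which
the transferred copy amplifies in the recipient lineage.  A per-copy
lognormal rate multiplier (off by default) introduces rate heterogeneity,
which is how slow-evolving vertical tails — the motivation for the
Ks-truncation filter — are produced on demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from httscan.kaks import (
    _AA,
    _BASES,
    _codon_index,
    _li93_indices,
    FrameSegment,
    STOP_CODONS,
    TECopy,
)
from httscan.treespace import SpeciesTree, parse_timetree

__all__ = [
    "SuperfamilyConfig",
    "HTTEventConfig",
    "SimulationConfig",
    "TruthRecord",
    "SyntheticDataset",
    "evolve_codon_sequence",
    "random_coding_sequence",
    "simulate_dataset",
    "emit_hit_table",
    "write_dataset",
    "DEFAULT_TREE_NEWICK",
]

MY = 1e6  # years per million years

#: Two sides that diverged 450 My ago, each split 90 My ago into two young
#: clades of three species (crown ages 15 My).  Only cross-side species
#: pairs are older than 120 My, so transfer can only be called between the
#: two sides; the 40-My partition yields four three-species clades.
DEFAULT_TREE_NEWICK = (
    "(((F1:15,F2:15,F3:15):75,(F4:15,F5:15,F6:15):75):360,"
    "((T1:15,T2:15,T3:15):75,(T4:15,T5:15,T6:15):75):360);"
)

_OTHER = {b: [o for o in _BASES if o != b] for b in _BASES}

#: Nucleotide-search detectability horizon: copy pairs below this percent
#: identity are treated as sharing no reportable alignment.
IDENTITY_DETECTION_PID = 70.0


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SuperfamilyConfig:
    """One TE superfamily: class label and target Ka/Ks while active."""

    name: str
    te_class: str  # "retrotransposon" | "DNA_transposon"
    omega: float
    n_families: int = 1

    def __post_init__(self):
        if self.te_class not in ("retrotransposon", "DNA_transposon"):
            raise ValueError(f"unknown TE class {self.te_class!r}")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


@dataclass(frozen=True)
class HTTEventConfig:
    """A planted horizontal transfer.

    ``donor`` and ``recipient`` name extant species; the transfer happens at
    ``time_my`` (My before present) on the branch of each species' root path
    spanning that age.  The transferred copy founds an active lineage that
    transposes ``n_amplify`` times immediately and keeps transposing at
    ``amplify_rate`` per My in every descendant recipient lineage, giving
    the star-like within-clade divergence structure and the sustained
    young-copy cohort of a real TE invasion.
    """

    event_id: str
    donor: str
    recipient: str
    time_my: float
    superfamily: str
    family: str | None = None  # default: first family of the superfamily
    n_amplify: int = 15  # immediate post-transfer transpositions
    amplify_rate: float = 2.5  # ongoing transpositions of the transferred
    #                            lineage per recipient lineage per My


@dataclass
class SimulationConfig:
    newick: str = DEFAULT_TREE_NEWICK
    n_core_genes: int = 500
    core_gene_length: int = 600
    mu_s: float = 3.1e-9
    coding_length: int = 400  # codons per TE copy (transposase-scale ORF)
    superfamilies: list[SuperfamilyConfig] = field(
        default_factory=lambda: [
            SuperfamilyConfig("Tc1_Mariner", "DNA_transposon", 1.0),
            SuperfamilyConfig("LINE1", "retrotransposon", 0.2),
        ]
    )
    ancestral_copies: int = 2
    burst_rate: float = 0.3  # transpositions per lineage per My per family
    htt_events: list[HTTEventConfig] = field(default_factory=list)
    # Turnover: non-master copies deactivate (stop transposing, evolve
    # neutrally) after ~10 My on average; once inert they are eventually
    # deleted or fragmented beyond annotation (~25 My), and their
    # protein-anchored reading frames survive only a few My of neutral
    # drift before frameshifts destroy them, so old relics stay alignable
    # at the DNA level but are useless for codon-level rate estimation.
    # Each genome thus keeps a young, mutually similar cohort per family
    # (master-lineage dynamics) plus a thin layer of frame-dead relics, as
    # real TE annotations do.  Set the rates to 0 (and the frame horizon
    # to infinity) for immortal, always-active, full-frame copies.
    deactivation_rate: float = 0.1  # per copy per My; deactivated -> omega 1
    max_active_my: float = 15.0  # hard cap on a copy's active span
    loss_rate: float = 0.04  # per inert copy per My
    frame_max_inert_my: float = 6.0  # inert age beyond which frames are lost
    rate_lognorm_sd: float = 0.0  # per-copy lognormal rate multiplier sd
    seed: int = 0

    def __post_init__(self):
        if self.mu_s <= 0:
            raise ValueError("mu_s must be > 0")
        if self.core_gene_length < 600:
            raise ValueError("core_gene_length must be >= 600 bp")
        if self.core_gene_length % 3:
            raise ValueError("core_gene_length must be a codon multiple")


@dataclass(frozen=True)
class TruthRecord:
    event_id: str
    donor: str
    recipient: str
    time_my: float
    superfamily: str
    family: str
    recipient_copies: tuple[str, ...]
    donor_copies: tuple[str, ...]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    tree: SpeciesTree
    copies: dict[str, TECopy]
    copies_meta: pd.DataFrame
    core_ks: pd.DataFrame  # gene, species_a, species_b, ks, aln_len
    hits: pd.DataFrame
    identities: pd.DataFrame  # superfamily, copy1, copy2, pid
    truth: list[TruthRecord]


# ---------------------------------------------------------------------------
# sequence evolution


def random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """Uniform random stop-free codon sequence."""
    non_stop = sorted(set(_AA) - STOP_CODONS)
    idx = rng.integers(0, len(non_stop), size=n_codons)
    return "".join(non_stop[i] for i in idx)


def evolve_codon_sequence(
    parent_seq: str,
    t: float,
    mu_s: float,
    omega: float,
    rng: np.random.Generator,
) -> str:
    """Evolve a codon sequence for ``t`` years under the proposal process.

    Proposals arrive at rate ``mu_s`` per site per year (uniform over the
    three alternative bases); stop-creating proposals are rejected,
    non-synonymous ones accepted with probability ``omega``.
    """
    L = len(parent_seq)
    if L % 3:
        raise ValueError("sequence length must be a multiple of 3")
    if t < 0:
        raise ValueError("t must be >= 0")
    for i in range(0, L, 3):
        if parent_seq[i : i + 3] in STOP_CODONS:
            raise ValueError(f"stop codon at position {i}")
    n_events = rng.poisson(mu_s * t * L)
    if n_events == 0:
        return parent_seq
    arr = list(parent_seq)
    positions = rng.integers(0, L, size=n_events)
    alt_picks = rng.integers(0, 3, size=n_events)
    accept_draws = rng.random(size=n_events)
    aa = _AA
    for pos, pick, u in zip(positions, alt_picks, accept_draws):
        pos = int(pos)
        cur = arr[pos]
        alt = _OTHER[cur][pick]
        cs = pos - pos % 3
        off = pos - cs
        codon = arr[cs] + arr[cs + 1] + arr[cs + 2]
        new = codon[:off] + alt + codon[off + 1 :]
        if new in STOP_CODONS:
            continue
        if aa[new] != aa[codon] and u >= omega:
            continue
        arr[pos] = alt
    return "".join(arr)


# ---------------------------------------------------------------------------
# tree scaffolding for the sweep


class _Node:
    __slots__ = ("idx", "age", "parent", "children", "label")

    def __init__(self, idx, age, parent, label):
        self.idx = idx
        self.age = age
        self.parent = parent
        self.children: list[int] = []
        self.label = label


def _node_table(tree: SpeciesTree) -> list[_Node]:
    nodes: list[_Node] = []
    index: dict[object, int] = {}
    for dnode in tree._tree.preorder_node_iter():
        parent = index.get(dnode.parent_node)
        label = dnode.taxon.label if dnode.is_leaf() else None
        node = _Node(len(nodes), tree._age[dnode], parent, label)
        index[dnode] = node.idx
        if parent is not None:
            nodes[parent].children.append(node.idx)
        nodes.append(node)
    return nodes


def _edge_at_age(nodes: list[_Node], tip_idx: int, age: float) -> int:
    """Index of the node whose parent edge spans ``age`` on the tip's root
    path (edge interval is [node.age, parent.age))."""
    cur = tip_idx
    while True:
        node = nodes[cur]
        if node.parent is None:
            raise ValueError(f"age {age} My is at or above the root")
        if node.age <= age < nodes[node.parent].age:
            return cur
        cur = node.parent


# ---------------------------------------------------------------------------
# TE sweep


class _SimCopy:
    __slots__ = ("seq", "active", "master", "active_left_my", "inert_my",
                 "rate_mult", "origin_event", "family", "serial")

    def __init__(self, seq, active, master, active_left_my, inert_my,
                 rate_mult, origin_event, family, serial):
        self.seq = seq
        self.active = active
        self.master = master  # master copies never deactivate or decay
        self.active_left_my = active_left_my  # remaining active span
        self.inert_my = inert_my  # My spent inactive (drives frame decay)
        self.rate_mult = rate_mult
        self.origin_event = origin_event
        self.family = family
        self.serial = serial


class _TESim:
    """Event sweep for one superfamily over the whole tree.

    Lineage states (copy lists) live on edges, keyed by the edge's child
    node; a global age-ordered event queue interleaves speciations,
    transposition bursts, planted transfers and their amplifications, so a
    transfer can read the donor lineage's state at exactly the transfer age.
    """

    def __init__(self, cfg: SimulationConfig, sf: SuperfamilyConfig,
                 nodes: list[_Node], rng: np.random.Generator):
        self.cfg = cfg
        self.sf = sf
        self.nodes = nodes
        self.rng = rng
        self.next_serial = 0
        self.tip_copies: dict[str, list[_SimCopy]] = {}

    def _new_rate_mult(self) -> float:
        if self.cfg.rate_lognorm_sd <= 0:
            return 1.0
        sd = self.cfg.rate_lognorm_sd
        # mean-one lognormal, clamped to a 10-fold band: synonymous rates
        # across lineages vary severalfold, not without bound
        mult = float(np.exp(self.rng.normal(-0.5 * sd * sd, sd)))
        return min(max(mult, 0.1), 10.0)

    def _active_span(self) -> float:
        cfg = self.cfg
        if cfg.deactivation_rate <= 0:
            return float("inf")
        span = self.rng.exponential(1.0 / cfg.deactivation_rate)
        return min(span, cfg.max_active_my)

    def _spawn(self, seq, family, origin_event,
               master: bool = False) -> _SimCopy:
        copy = _SimCopy(seq, True, master, self._active_span(), 0.0,
                        self._new_rate_mult(), origin_event, family,
                        self.next_serial)
        self.next_serial += 1
        return copy

    def _inherit(self, c: _SimCopy) -> _SimCopy:
        copy = _SimCopy(c.seq, c.active, c.master, c.active_left_my,
                        c.inert_my, c.rate_mult, c.origin_event, c.family,
                        self.next_serial)
        self.next_serial += 1
        return copy

    def _evolve_copy(self, copy: _SimCopy, dt_my: float) -> bool:
        """Evolve one copy through ``dt_my``; False when the copy is lost
        (decayed below annotation detectability) during the interval.
        Master copies neither deactivate nor decay.  Each non-master copy
        carries a pre-drawn remaining active span (exponential, hard-
        capped); loss waiting times are exponential, so piecewise sampling
        is exact."""
        cfg, rng = self.cfg, self.rng
        mu = cfg.mu_s * copy.rate_mult
        while dt_my > 0:
            if copy.master:
                copy.seq = evolve_codon_sequence(copy.seq, dt_my * MY, mu,
                                                 self.sf.omega, rng)
                return True
            if copy.active:
                if copy.active_left_my < dt_my:
                    t_deact = copy.active_left_my
                    copy.seq = evolve_codon_sequence(
                        copy.seq, t_deact * MY, mu, self.sf.omega, rng)
                    copy.active = False
                    copy.active_left_my = 0.0
                    dt_my -= t_deact
                    continue
                copy.active_left_my -= dt_my
                copy.seq = evolve_codon_sequence(copy.seq, dt_my * MY, mu,
                                                 self.sf.omega, rng)
                return True
            if cfg.loss_rate > 0:
                t_loss = rng.exponential(1.0 / cfg.loss_rate)
                if t_loss < dt_my:
                    return False
            copy.inert_my += dt_my
            copy.seq = evolve_codon_sequence(copy.seq, dt_my * MY, mu,
                                             1.0, rng)
            return True
        return True

    def run(self, htt_events: list[HTTEventConfig]) -> None:
        cfg, nodes, rng = self.cfg, self.nodes, self.rng
        root = nodes[0]
        families = [f"{self.sf.name}.f{i}" for i in range(self.sf.n_families)]
        state: dict[int, tuple[float, list[_SimCopy]]] = {}
        root_copies = []
        for fam in families:
            ancestral = random_coding_sequence(cfg.coding_length, rng)
            for k in range(cfg.ancestral_copies):
                root_copies.append(self._spawn(ancestral, fam, None,
                                               master=(k == 0)))
        state[root.idx] = (root.age, root_copies)

        # (age, priority, tiebreak, kind, payload), processed by decreasing
        # age.  An edge spans [node.age, parent.age); an event falling
        # exactly on a node's age still belongs to the edge above it, so
        # same-age bursts/transfers precede the speciation.
        events: list[tuple[float, int, int, str, object]] = []
        tick = 0
        for node in nodes:
            if node.children:
                events.append((node.age, 2, tick, "speciation", node.idx))
                tick += 1
        for node in nodes:
            if node.parent is None:
                continue
            span = nodes[node.parent].age - node.age
            for fam in families:
                n_bursts = rng.poisson(cfg.burst_rate * span)
                times = nodes[node.parent].age - rng.random(n_bursts) * span
                for t_burst in times:
                    events.append((float(t_burst), 1, tick, "burst",
                                   (node.idx, fam)))
                    tick += 1
        tip_index = {n.label: n.idx for n in nodes if n.label}
        for ev in htt_events:
            donor_edge = _edge_at_age(nodes, tip_index[ev.donor], ev.time_my)
            recip_edge = _edge_at_age(nodes, tip_index[ev.recipient],
                                      ev.time_my)
            events.append((ev.time_my, 1, tick, "htt",
                           (ev, donor_edge, recip_edge)))
            tick += 1
            bot = nodes[recip_edge].age
            amp_times = list(bot + rng.random(ev.n_amplify)
                             * (ev.time_my - bot))
            # ongoing transposition of the transferred lineage in the
            # recipient branch and all its descendants
            stack = [recip_edge]
            while stack:
                edge = stack.pop()
                top = min(ev.time_my, nodes[nodes[edge].parent].age)
                span = top - nodes[edge].age
                if span > 0:
                    n_amp = rng.poisson(ev.amplify_rate * span)
                    times = nodes[edge].age + rng.random(n_amp) * span
                    if edge == recip_edge:
                        amp_times.extend(float(t) for t in times)
                    else:
                        for t_amp in times:
                            events.append((float(t_amp), 1, tick, "amplify",
                                           (edge, ev.event_id)))
                            tick += 1
                stack.extend(nodes[edge].children)
            for t_amp in amp_times:
                events.append((float(t_amp), 1, tick, "amplify",
                               (recip_edge, ev.event_id)))
                tick += 1
        events.sort(key=lambda e: (-e[0], e[1], e[2]))

        def advance(node_idx: int, to_age: float) -> list[_SimCopy]:
            cur_age, copies = state[node_idx]
            if cur_age > to_age:
                copies = [c for c in copies
                          if self._evolve_copy(c, cur_age - to_age)]
                state[node_idx] = (to_age, copies)
            return copies

        for age, _prio, _tick, kind, payload in events:
            if kind == "speciation":
                node = nodes[payload]
                copies = advance(node.idx, age)
                del state[node.idx]
                for child in node.children:
                    state[child] = (age, [self._inherit(c) for c in copies])
            elif kind == "burst":
                node_idx, fam = payload
                if node_idx not in state:
                    continue  # burst sampled at an age outside the edge span
                copies = advance(node_idx, age)
                # master-gene dynamics: new insertions are copies of the
                # family's replicating master lineage, so within-genome
                # divergence is star-like around the master
                pool = [c for c in copies if c.master and c.family == fam
                        and c.origin_event is None]
                if not pool:
                    pool = [c for c in copies
                            if c.active and c.family == fam]
                if not pool:
                    continue
                src = pool[int(rng.integers(len(pool)))]
                copies.append(self._spawn(src.seq, src.family,
                                          src.origin_event))
            elif kind == "htt":
                ev, donor_edge, recip_edge = payload
                donor_copies = advance(donor_edge, age)
                recip_copies = advance(recip_edge, age)
                fam = ev.family or families[0]
                pool = [c for c in donor_copies
                        if c.active and c.family == fam]
                if not pool:
                    raise ValueError(
                        f"event {ev.event_id}: no active {fam} copy in the "
                        f"donor lineage at {age} My"
                    )
                # the master copy — the family's functional, replicating
                # lineage — is what invades; it founds an active master
                # lineage in the recipient genome
                masters = [c for c in pool if c.master]
                src = masters[0] if masters else pool[int(rng.integers(len(pool)))]
                recip_copies.append(self._spawn(src.seq, src.family,
                                                ev.event_id, master=True))
            elif kind == "amplify":
                recip_edge, event_id = payload
                copies = advance(recip_edge, age)
                pool = [c for c in copies
                        if c.master and c.origin_event == event_id]
                if not pool:
                    pool = [c for c in copies
                            if c.active and c.origin_event == event_id]
                if not pool:
                    continue
                src = pool[int(rng.integers(len(pool)))]
                copies.append(self._spawn(src.seq, src.family, event_id))

        for node in nodes:
            if node.label is not None and node.idx in state:
                self.tip_copies[node.label] = advance(node.idx, 0.0)


# ---------------------------------------------------------------------------
# dataset assembly


def _codon_indices(seq: str) -> np.ndarray:
    return np.array([_codon_index(seq[i : i + 3])
                     for i in range(0, len(seq), 3)])


def _simulate_core_ks(cfg: SimulationConfig, tree: SpeciesTree,
                      nodes: list[_Node],
                      rng: np.random.Generator) -> pd.DataFrame:
    n_codons = cfg.core_gene_length // 3
    tips = tree.tips
    records = []
    for g in range(cfg.n_core_genes):
        gene = f"gene{g:04d}"
        seqs: dict[int, str] = {0: random_coding_sequence(n_codons, rng)}
        tip_seqs: dict[str, np.ndarray] = {}
        for node in nodes:
            if node.parent is not None:
                span = nodes[node.parent].age - node.age
                seqs[node.idx] = evolve_codon_sequence(
                    seqs[node.parent], span * MY, cfg.mu_s, 1.0, rng
                )
            if node.label is not None:
                tip_seqs[node.label] = _codon_indices(seqs[node.idx])
        for i, a in enumerate(tips):
            for b in tips[i + 1 :]:
                res = _li93_indices(tip_seqs[a], tip_seqs[b])
                # saturated or out-of-range estimates carry no usable
                # signal beyond "very divergent"
                ks = res.ks if (not res.saturated and res.ks >= 0) else math.inf
                records.append((gene, a, b, ks, cfg.core_gene_length))
    return pd.DataFrame(
        records, columns=["gene", "species_a", "species_b", "ks", "aln_len"]
    )


def _frame_for(cfg: SimulationConfig, c: _SimCopy,
               superfamily: str) -> list[FrameSegment]:
    """Protein-anchored frame of a copy: full-length while the copy has
    spent at most ``frame_max_inert_my`` inert, absent beyond that
    (frameshift accumulation destroys the anchor while the DNA itself
    stays alignable)."""
    if c.inert_my > cfg.frame_max_inert_my:
        return []
    return [FrameSegment(0, 3 * cfg.coding_length, 0,
                         protein_family=f"{superfamily}#pol",
                         protein_start=0)]


def _finalize_copies(cfg: SimulationConfig, sims: list[_TESim]):
    copies: dict[str, TECopy] = {}
    meta_rows = []
    for sim in sims:
        sf = sim.sf
        for species in sorted(sim.tip_copies):
            for k, c in enumerate(sorted(sim.tip_copies[species],
                                         key=lambda c: c.serial)):
                copy_id = f"{species}|{c.family}|{k}"
                copies[copy_id] = TECopy(
                    copy_id=copy_id,
                    species=species,
                    superfamily=sf.name,
                    te_class=sf.te_class,
                    sequence=c.seq,
                    frame_segments=_frame_for(cfg, c, sf.name),
                )
                meta_rows.append(
                    (copy_id, species, sf.name, sf.te_class, c.family,
                     len(c.seq), c.origin_event or "")
                )
    meta = pd.DataFrame(
        meta_rows,
        columns=["copy_id", "species", "superfamily", "te_class", "family",
                 "length", "origin_event"],
    )
    return copies, meta


def _pairwise_pid(seq_a: np.ndarray, seq_b: np.ndarray):
    matches = int((seq_a == seq_b).sum())
    n = len(seq_a)
    return 100.0 * matches / n, matches, n - matches


def _nt_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def emit_hit_table(
    ds: SyntheticDataset,
    min_len: int = 300,
    min_pid: float = 75.0,
    min_score: float = 200.0,
    search_age: float = 40.0,
) -> pd.DataFrame:
    """Best reciprocal positional hits between same-family copies.

    Mimics the reciprocal-search convention: for every ordered pair of
    species belonging to different clades younger than ``search_age`` My,
    each query copy reports its best-scoring alignment per target species.
    Alignments are positional over the shared family coordinates (the
    simulator evolves families gaplessly); score is ``2*matches -
    3*mismatches``, the default nucleotide-search match/mismatch weights.
    Hits shorter than ``min_len``, below ``min_pid`` percent identity or
    ``min_score``, or crossing superfamilies are not reported.  Coordinates
    in the returned table are 0-based half-open.
    """
    partition = ds.tree.clades_younger_than(search_age)
    arrays = {cid: _nt_array(te.sequence) for cid, te in ds.copies.items()}
    by_species_family: dict[str, dict[str, list[str]]] = {}
    for row in ds.copies_meta.itertuples(index=False):
        by_species_family.setdefault(row.species, {}).setdefault(
            row.family, []
        ).append(row.copy_id)
    rows = []
    species = sorted(by_species_family)
    for q_sp in species:
        for t_sp in species:
            if q_sp == t_sp:
                continue
            if partition.clade_of(q_sp) == partition.clade_of(t_sp):
                continue
            for fam, q_copies in sorted(by_species_family[q_sp].items()):
                t_copies = by_species_family[t_sp].get(fam, [])
                if not t_copies:
                    continue
                for qid in q_copies:
                    qa = arrays[qid]
                    best = None
                    for tid in t_copies:
                        pid, matches, mism = _pairwise_pid(qa, arrays[tid])
                        score = 2.0 * matches - 3.0 * mism
                        key = (score, tid)
                        if best is None or key > best[0]:
                            best = (key, tid, pid, mism, score)
                    _, tid, pid, mism, score = best
                    length = len(qa)
                    if (length >= min_len and pid >= min_pid
                            and score >= min_score):
                        rows.append(
                            (qid, tid, pid, length, mism, 0, 0, length,
                             0, length, 0.0, score)
                        )
    return pd.DataFrame(
        rows,
        columns=["qseqid", "sseqid", "pident", "length", "mismatch",
                 "gapopen", "qstart", "qend", "sstart", "send", "evalue",
                 "bitscore"],
    )


def _emit_identities(copies: dict[str, TECopy], meta: pd.DataFrame,
                     min_len: int = 100) -> pd.DataFrame:
    """All-vs-all pairwise identities per superfamily (same family only;
    unrelated families share no alignment).  Pairs below the detectability
    horizon are absent, mimicking a nucleotide search's loss of signal."""
    arrays = {cid: _nt_array(te.sequence) for cid, te in copies.items()}
    rows = []
    groups: dict[str, list[str]] = {}
    sf_of: dict[str, str] = {}
    for row in meta.itertuples(index=False):
        groups.setdefault(row.family, []).append(row.copy_id)
        sf_of[row.copy_id] = row.superfamily
    for _fam, ids in sorted(groups.items()):
        for i, cid1 in enumerate(ids):
            if len(arrays[cid1]) < min_len:
                continue
            for cid2 in ids[i + 1 :]:
                pid, _, _ = _pairwise_pid(arrays[cid1], arrays[cid2])
                if pid >= IDENTITY_DETECTION_PID:
                    rows.append((sf_of[cid1], cid1, cid2, pid))
    return pd.DataFrame(rows,
                        columns=["superfamily", "copy1", "copy2", "pid"])


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Run the full simulation; byte-identical outputs given ``cfg.seed``."""
    tree = parse_timetree(cfg.newick)
    nodes = _node_table(tree)
    tip_labels = {n.label for n in nodes if n.label}
    sf_names = {sf.name for sf in cfg.superfamilies}
    problems = []
    for ev in cfg.htt_events:
        if ev.donor not in tip_labels or ev.recipient not in tip_labels:
            problems.append(f"{ev.event_id}: unknown donor/recipient species")
            continue
        if ev.superfamily not in sf_names:
            problems.append(f"{ev.event_id}: unknown superfamily")
            continue
        div = tree.divergence_my(ev.donor, ev.recipient)
        if not (0 < ev.time_my < div):
            problems.append(
                f"{ev.event_id}: time {ev.time_my} My outside the open "
                f"interval (0, {div}) of donor/recipient divergence"
            )
    if problems:
        raise ValueError("invalid htt_events: " + "; ".join(problems))

    seeds = np.random.SeedSequence(cfg.seed).spawn(1 + len(cfg.superfamilies))
    rng_core = np.random.default_rng(seeds[0])
    sims = []
    for i, sf in enumerate(cfg.superfamilies):
        sim = _TESim(cfg, sf, nodes, np.random.default_rng(seeds[1 + i]))
        sim.run([ev for ev in cfg.htt_events if ev.superfamily == sf.name])
        sims.append(sim)

    copies, meta = _finalize_copies(cfg, sims)
    core_ks = _simulate_core_ks(cfg, tree, nodes, rng_core)
    identities = _emit_identities(copies, meta)

    truth = []
    origin_of = dict(zip(meta.copy_id, meta.origin_event))
    tip_index = {n.label: n.idx for n in nodes if n.label}
    for ev in cfg.htt_events:
        fam = ev.family or f"{ev.superfamily}.f0"
        recip = tuple(sorted(cid for cid, org in origin_of.items()
                             if org == ev.event_id))
        # donor clade: the tips descending from the donor branch
        donor_edge = _edge_at_age(nodes, tip_index[ev.donor], ev.time_my)
        donor_tips = set()
        stack = [donor_edge]
        while stack:
            node = nodes[stack.pop()]
            if node.label is not None:
                donor_tips.add(node.label)
            stack.extend(node.children)
        donor_side = tuple(sorted(
            row.copy_id
            for row in meta.itertuples(index=False)
            if row.family == fam and not row.origin_event
            and row.species in donor_tips
        ))
        truth.append(
            TruthRecord(ev.event_id, ev.donor, ev.recipient, ev.time_my,
                        ev.superfamily, fam, recip, donor_side)
        )

    ds = SyntheticDataset(
        config=cfg,
        tree=tree,
        copies=copies,
        copies_meta=meta,
        core_ks=core_ks,
        hits=pd.DataFrame(),
        identities=identities,
        truth=truth,
    )
    ds.hits = emit_hit_table(ds)
    return ds


# ---------------------------------------------------------------------------
# plain-text emission


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write the dataset as FASTA / TSV / Newick under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "copies.fasta", "w") as fa:
        for cid in sorted(ds.copies):
            fa.write(f">{cid}\n{ds.copies[cid].sequence}\n")
    ds.copies_meta.to_csv(outdir / "copies_meta.tsv", sep="\t", index=False)
    frame_rows = [
        (cid, seg.start, seg.end, seg.phase, seg.protein_family,
         seg.protein_start)
        for cid in sorted(ds.copies)
        for seg in ds.copies[cid].frame_segments
    ]
    pd.DataFrame(frame_rows, columns=["copy_id", "start", "end", "phase",
                                      "protein_family", "protein_start"]
                 ).to_csv(outdir / "frames.tsv", sep="\t", index=False)
    ds.core_ks.to_csv(outdir / "core_ks.tsv", sep="\t", index=False)
    hits = ds.hits.copy()
    # BLAST outfmt-6 dialect: 1-based inclusive start coordinates
    for col in ("qstart", "sstart"):
        hits[col] = hits[col] + 1
    hits.to_csv(outdir / "hits.tsv", sep="\t", index=False, header=False)
    ds.identities.to_csv(outdir / "identities.tsv", sep="\t", index=False)
    (outdir / "tree.nwk").write_text(ds.config.newick + "\n")
    pd.DataFrame([t.__dict__ for t in ds.truth]).to_csv(
        outdir / "truth.tsv", sep="\t", index=False
    )
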