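"""Pairwise Ka/Ks on degraded TE coding regions (Li 1993).

TE copies accumulate frame-disrupting damage, so protein-coding codon pairs
are reconstructed from a nucleotide alignment plus per-copy protein-anchored
frame annotations (:func:`codon_project`), and synonymous (Ks) and
non-synonymous (Ka) distances are then estimated on the retained codons by
Li's degeneracy-class method (:func:`li93`):

* every codon site is classified as nondegenerate (0-fold), twofold, or
  fourfold degenerate from the standard genetic code (by the number of
  synonymous alternatives at the site; 1 or 2 synonymous alternatives count
  as twofold, per Li's convention);
* transitional and transversional difference proportions ``Pi``, ``Qi`` are
  tallied per class, averaging site classes over the two codons and
  weighting multi-substitution pathways within a codon equally (pathways
  through stop codons are excluded when at least one stop-free pathway
  exists);
* Kimura-type corrections ``Ai = 1/2 ln(1/(1-2Pi-Qi)) - 1/4 ln(1/(1-2Qi))``
  and ``Bi = 1/2 ln(1/(1-2Qi))`` give
  ``Ks = (L2*A2 + L4*A4)/(L2+L4) + B4`` and
  ``Ka = A0 + (L0*B0 + L2*B2)/(L0+L2)``.

The Ks standard deviation is a delta-method propagation of the multinomial
sampling variance of the per-class ``(Pi, Qi)`` proportions; it is consumed
only by the downstream divergence filter.  Saturated pairs (any required
logarithm undefined) are flagged and treated downstream as failing the
``Ks < 0.5`` filter.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "TECopy",
    "FrameSegment",
    "CodonPairAlignment",
    "KaKsResult",
    "codon_project",
    "li93",
    "batch_kaks",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_PURINES = {"A", "G"}


def _codon_index(codon: str) -> int:
    return (
        16 * _BASE_INDEX[codon[0]] + 4 * _BASE_INDEX[codon[1]] + _BASE_INDEX[codon[2]]
    )


def _index_codon(idx: int) -> str:
    return _BASES[idx // 16] + _BASES[(idx // 4) % 4] + _BASES[idx % 4]


def _translation_table() -> dict[str, str]:
    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return {c.replace("U", "T"): aa for c, aa in table.items()}


_AA = _translation_table()
STOP_CODONS = frozenset(c for c, aa in _AA.items() if aa == "*")


def _is_transition(b1: str, b2: str) -> bool:
    return b1 != b2 and (b1 in _PURINES) == (b2 in _PURINES)


def _site_class(codon: str, pos: int) -> int:
    """0, 1, 2 for non-, two-, four-fold degenerate (stops excluded)."""
    n_syn = 0
    for alt in _BASES:
        if alt == codon[pos]:
            continue
        mutant = codon[:pos] + alt + codon[pos + 1 :]
        if _AA[mutant] == _AA[codon]:
            n_syn += 1
    if n_syn == 0:
        return 0
    if n_syn == 3:
        return 2
    return 1


def _build_tables():
    """Per-codon site classes and per-codon-pair difference tables.

    Returns (valid, site_L, ts, tv): ``site_L[c, k]`` is the number of sites
    of class k in codon c; ``ts[c1, c2, k]`` / ``tv[c1, c2, k]`` are the
    transitional / transversional difference counts between the codon pair
    attributed to class k (site classes averaged over the two codons
    flanking each substitution step, pathways weighted equally).
    """
    valid = np.zeros(64, dtype=bool)
    site_cls = np.zeros((64, 3), dtype=np.int8)
    for idx in range(64):
        codon = _index_codon(idx)
        if codon in STOP_CODONS:
            continue
        valid[idx] = True
        for pos in range(3):
            site_cls[idx, pos] = _site_class(codon, pos)
    site_L = np.zeros((64, 3))
    for idx in range(64):
        if valid[idx]:
            for pos in range(3):
                site_L[idx, site_cls[idx, pos]] += 1.0

    ts = np.zeros((64, 64, 3))
    tv = np.zeros((64, 64, 3))
    for i1 in range(64):
        if not valid[i1]:
            continue
        c1 = _index_codon(i1)
        for i2 in range(64):
            if not valid[i2] or i1 == i2:
                continue
            c2 = _index_codon(i2)
            diff_pos = [p for p in range(3) if c1[p] != c2[p]]
            pathways = []
            for order in itertools.permutations(diff_pos):
                steps = []
                cur = c1
                ok = True
                for p in order:
                    nxt = cur[:p] + c2[p] + cur[p + 1 :]
                    if nxt in STOP_CODONS:
                        ok = False
                        break
                    steps.append((cur, nxt, p))
                    cur = nxt
                if ok:
                    pathways.append(steps)
            if not pathways:  # all pathways blocked by stops: allow them all
                for order in itertools.permutations(diff_pos):
                    steps = []
                    cur = c1
                    for p in order:
                        nxt = cur[:p] + c2[p] + cur[p + 1 :]
                        steps.append((cur, nxt, p))
                        cur = nxt
                    pathways.append(steps)
            w = 1.0 / len(pathways)
            for steps in pathways:
                for cur, nxt, p in steps:
                    k_cur = _site_class(cur, p) if cur not in STOP_CODONS else None
                    k_nxt = _site_class(nxt, p) if nxt not in STOP_CODONS else None
                    classes = [k for k in (k_cur, k_nxt) if k is not None]
                    target = ts if _is_transition(cur[p], nxt[p]) else tv
                    for k in classes:
                        target[i1, i2, k] += w * (1.0 / len(classes))
    return valid, site_L, ts, tv


_VALID, _SITE_L, _TS, _TV = _build_tables()


@dataclass(frozen=True)
class FrameSegment:
    """Protein-anchored coding region of a copy, 0-based half-open.

    ``phase`` is the within-codon position (0, 1, 2) of the segment's first
    base; ``protein_family`` records the anchoring protein and
    ``protein_start`` the nucleotide-scale coordinate of the segment's first
    base on that protein, so that shared anchored regions between copies can
    be measured even when the copies themselves share no alignment.
    """

    start: int
    end: int
    phase: int
    protein_family: str = ""
    protein_start: int = 0

    def __post_init__(self):
        if not (0 <= self.phase <= 2):
            raise ValueError("codon phase must be 0, 1 or 2")
        if self.end <= self.start:
            raise ValueError("empty frame segment")


@dataclass
class TECopy:
    """A TE copy: sequence plus species, superfamily and frame annotation."""

    copy_id: str
    species: str
    superfamily: str
    te_class: str
    sequence: str
    frame_segments: list[FrameSegment] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        segs = sorted(self.frame_segments, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"copy {self.copy_id}: overlapping frame segments "
                    f"({prev.start},{prev.end}) and ({cur.start},{cur.end})"
                )
        if segs and segs[-1].end > len(self.sequence):
            raise ValueError(f"copy {self.copy_id}: frame segment out of bounds")
        self.frame_segments = segs

    def phase_at(self, pos: int) -> int | None:
        """Within-codon position of base ``pos``, or None outside frames."""
        for seg in self.frame_segments:
            if seg.start <= pos < seg.end:
                return (pos - seg.start + seg.phase) % 3
        return None


@dataclass(frozen=True)
class CodonPairAlignment:
    """Gap-free, stop-free list of aligned codon pairs."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon lists must have equal length")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ks_sd: float
    n_codons: int
    L: tuple[float, float, float]  # (L0, L2, L4)
    P: tuple[float, float, float]
    Q: tuple[float, float, float]
    A: tuple[float, float, float]
    B: tuple[float, float, float]
    saturated: bool

    @property
    def ka_ks(self) -> float:
        if not math.isfinite(self.ka) or not math.isfinite(self.ks) or self.ks == 0:
            return math.nan
        return self.ka / self.ks


def codon_project(
    copy_a: TECopy,
    copy_b: TECopy,
    aligned_a: str,
    aligned_b: str,
    start_a: int = 0,
    start_b: int = 0,
) -> CodonPairAlignment:
    """Project a pairwise nucleotide alignment onto shared codon frames.

    ``aligned_a`` / ``aligned_b`` are equal-length gapped strings ('-' for
    gaps); ``start_a`` / ``start_b`` give the copy coordinate of the first
    aligned base.  A codon pair is retained iff its three alignment columns
    are gap-free, unambiguous (ACGT only), contiguous in both copies, fall
    inside annotated frame segments of both copies, agree in within-codon
    phase at every column, and neither codon is a stop.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    pos_a, pos_b = start_a, start_b
    columns = []  # (base_a, base_b, coord_a, coord_b, phase) or None
    for ca, cb in zip(aligned_a.upper(), aligned_b.upper()):
        if ca == "-" and cb == "-":
            continue
        if ca == "-":
            pos_b += 1
            columns.append(None)
            continue
        if cb == "-":
            pos_a += 1
            columns.append(None)
            continue
        pa = copy_a.phase_at(pos_a)
        pb = copy_b.phase_at(pos_b)
        if ca in _BASES and cb in _BASES and pa is not None and pa == pb:
            columns.append((ca, cb, pos_a, pos_b, pa))
        else:
            columns.append(None)
        pos_a += 1
        pos_b += 1

    codons_a: list[str] = []
    codons_b: list[str] = []
    buf: list[tuple[str, str, int, int, int]] = []
    for col in columns:
        if col is None:
            buf = []
            continue
        if col[4] == 0:
            buf = [col]
            continue
        if buf and col[4] == len(buf) and col[2] == buf[-1][2] + 1 and col[3] == buf[-1][3] + 1:
            buf.append(col)
            if len(buf) == 3:
                ca = "".join(c[0] for c in buf)
                cb = "".join(c[1] for c in buf)
                if ca not in STOP_CODONS and cb not in STOP_CODONS:
                    codons_a.append(ca)
                    codons_b.append(cb)
                buf = []
        else:
            buf = []
    return CodonPairAlignment(tuple(codons_a), tuple(codons_b))


def _correction_terms(P: float, Q: float) -> tuple[float, float, bool]:
    """(A, B, saturated) for one degeneracy class."""
    argA = 1.0 - 2.0 * P - Q
    argB = 1.0 - 2.0 * Q
    if argA <= 0.0 or argB <= 0.0:
        return math.nan, math.nan, True
    A = 0.5 * math.log(1.0 / argA) - 0.25 * math.log(1.0 / argB)
    B = 0.5 * math.log(1.0 / argB)
    return A, B, False


def li93(cp: CodonPairAlignment) -> KaKsResult:
    """Li (1993) Ka, Ks and delta-method Ks standard deviation."""
    if cp.n_codons == 0:
        raise ValueError("li93 is undefined on an empty codon alignment")
    ia = np.array([_codon_index(c) for c in cp.codons_a])
    ib = np.array([_codon_index(c) for c in cp.codons_b])
    return _li93_indices(ia, ib)


def _li93_indices(ia: np.ndarray, ib: np.ndarray) -> KaKsResult:
    """Fast path on arrays of codon indices (16*b0 + 4*b1 + b2, ACGT order)."""
    n = len(ia)
    if not (_VALID[ia].all() and _VALID[ib].all()):
        raise ValueError("stop codon in codon pair alignment")
    L = 0.5 * (_SITE_L[ia].sum(axis=0) + _SITE_L[ib].sum(axis=0))
    ts = _TS[ia, ib].sum(axis=0)
    tv = _TV[ia, ib].sum(axis=0)

    P = np.where(L > 0, ts / np.where(L > 0, L, 1.0), 0.0)
    Q = np.where(L > 0, tv / np.where(L > 0, L, 1.0), 0.0)
    A = np.zeros(3)
    B = np.zeros(3)
    saturated = False
    for k in range(3):
        if L[k] > 0:
            A[k], B[k], sat = _correction_terms(P[k], Q[k])
            saturated = saturated or sat
    L0, L2, L4 = L
    if saturated:
        ka = ks = ks_sd = math.nan
    else:
        ks = (L2 * A[1] + L4 * A[2]) / (L2 + L4) + B[2] if (L2 + L4) > 0 else math.nan
        ka = A[0] + (L0 * B[0] + L2 * B[1]) / (L0 + L2) if (L0 + L2) > 0 else math.nan
        ks_sd = _ks_sd(L, P, Q) if (L2 + L4) > 0 else math.nan
    return KaKsResult(
        ka=float(ka),
        ks=float(ks),
        ks_sd=float(ks_sd),
        n_codons=n,
        L=tuple(float(x) for x in L),
        P=tuple(float(x) for x in P),
        Q=tuple(float(x) for x in Q),
        A=tuple(float(x) for x in A),
        B=tuple(float(x) for x in B),
        saturated=bool(saturated),
    )


def _ks_sd(L, P, Q) -> float:
    """Delta-method variance of Ks in the (P2, Q2, P4, Q4) proportions.

    Per class, (ts, tv) counts over L sites are treated as multinomial:
    Var(P) = P(1-P)/L, Var(Q) = Q(1-Q)/L, Cov(P, Q) = -PQ/L; classes are
    independent (disjoint site sets).
    """
    L0, L2, L4 = L
    var = 0.0
    for k, (dKdP, dKdQ) in _ks_gradients(L, P, Q).items():
        Lk = L[k]
        if Lk <= 0:
            continue
        vP = P[k] * (1 - P[k]) / Lk
        vQ = Q[k] * (1 - Q[k]) / Lk
        cPQ = -P[k] * Q[k] / Lk
        var += dKdP**2 * vP + dKdQ**2 * vQ + 2 * dKdP * dKdQ * cPQ
    return math.sqrt(max(var, 0.0))


def _ks_gradients(L, P, Q):
    """d Ks / d(Pk, Qk) for the twofold (k=1) and fourfold (k=2) classes."""
    L0, L2, L4 = L
    denom = L2 + L4
    grads = {}
    if denom <= 0:
        return grads
    for k, weight in ((1, L2 / denom), (2, L4 / denom)):
        a = 1.0 / (1.0 - 2.0 * P[k] - Q[k])
        b = 1.0 / (1.0 - 2.0 * Q[k])
        dA_dP = a
        dA_dQ = 0.5 * a - 0.5 * b
        dP = weight * dA_dP
        dQ = weight * dA_dQ
        if k == 2:  # + B4 term
            dQ += b
        grads[k] = (dP, dQ)
    return grads


# -- batch interface ----------------------------------------------------------

_ALIGNER = PairwiseAligner(
    mode="global", match_score=2, mismatch_score=-3, open_gap_score=-5,
    extend_gap_score=-2,
)


def batch_kaks(
    hits: pd.DataFrame,
    copies: dict[str, TECopy],
) -> pd.DataFrame:
    """Annotate a hit table with Ka, Ks, Ks_sd and n_codons.

    ``hits`` must carry ``qseqid, sseqid, qstart, qend, sstart, send``
    (0-based half-open copy coordinates).  Hit regions of equal length are
    paired positionally; unequal regions are globally re-aligned first.
    Hits whose region yields no projectable codon carry ``n_codons = 0``
    and NaN rates.
    """
    out = hits.copy()
    ka = np.full(len(out), np.nan)
    ks = np.full(len(out), np.nan)
    ks_sd = np.full(len(out), np.nan)
    ncod = np.zeros(len(out), dtype=int)
    sat = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        try:
            ca = copies[row.qseqid]
            cb = copies[row.sseqid]
        except KeyError as exc:
            raise KeyError(f"hit {row.qseqid}/{row.sseqid}: missing copy {exc}") from None
        sa = ca.sequence[row.qstart : row.qend]
        sb = cb.sequence[row.sstart : row.send]
        if len(sa) == len(sb):
            aligned_a, aligned_b = sa, sb
        else:
            aln = _ALIGNER.align(sa, sb)[0]
            aligned_a, aligned_b = str(aln[0]), str(aln[1])
        cp = codon_project(ca, cb, aligned_a, aligned_b, row.qstart, row.sstart)
        ncod[i] = cp.n_codons
        if cp.n_codons:
            res = li93(cp)
            ka[i], ks[i], ks_sd[i], sat[i] = res.ka, res.ks, res.ks_sd, res.saturated
    out["ka"] = ka
    out["ks"] = ks
    out["ks_sd"] = ks_sd
    out["n_codons"] = ncod
    out["saturated"] = sat
    return out
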