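"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles — its own genetic-code
table, its own site classification, plain-float arithmetic — so that it
shares no code with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

# hand-typed standard genetic code (DNA codons)
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOPS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}
PURINES = {"A", "G"}


def site_degeneracy_class(codon: str, pos: int) -> int:
    """0 = nondegenerate, 1 = twofold (1-2 synonymous alternatives),
    2 = fourfold."""
    syn = 0
    for base in "ACGT":
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1:]
        if GENETIC_CODE[alt] == GENETIC_CODE[codon]:
            syn += 1
    return {0: 0, 1: 1, 2: 1, 3: 2}[syn]


def is_transition(b1: str, b2: str) -> bool:
    return b1 != b2 and ((b1 in PURINES) == (b2 in PURINES))


def pair_counts(c1: str, c2: str):
    """(L, ts, tv) per degeneracy class for one codon pair, averaging site
    classes over the two codons flanking each substitution step, weighting
    stop-free pathways equally (all pathways when none is stop-free)."""
    L = [0.0, 0.0, 0.0]
    for pos in range(3):
        L[site_degeneracy_class(c1, pos)] += 0.5
        L[site_degeneracy_class(c2, pos)] += 0.5
    ts = [0.0, 0.0, 0.0]
    tv = [0.0, 0.0, 0.0]
    diffs = [p for p in range(3) if c1[p] != c2[p]]
    if not diffs:
        return L, ts, tv
    paths = []
    for order in itertools.permutations(diffs):
        steps = []
        cur = c1
        blocked = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in STOPS:
                blocked = True
                break
            steps.append((cur, nxt, p))
            cur = nxt
        if not blocked:
            paths.append(steps)
    if not paths:
        for order in itertools.permutations(diffs):
            steps = []
            cur = c1
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1:]
                steps.append((cur, nxt, p))
                cur = nxt
            paths.append(steps)
    w = 1.0 / len(paths)
    for steps in paths:
        for cur, nxt, p in steps:
            classes = []
            if cur not in STOPS:
                classes.append(site_degeneracy_class(cur, p))
            if nxt not in STOPS:
                classes.append(site_degeneracy_class(nxt, p))
            bucket = ts if is_transition(cur[p], nxt[p]) else tv
            for k in classes:
                bucket[k] += w / len(classes)
    return L, ts, tv


def li93_oracle(codons_a, codons_b):
    """Brute-force Li (1993) Ka, Ks and delta-method Ks sd.

    Returns a dict with keys ka, ks, ks_sd, saturated.
    """
    assert len(codons_a) == len(codons_b) and codons_a
    L = [0.0, 0.0, 0.0]
    ts = [0.0, 0.0, 0.0]
    tv = [0.0, 0.0, 0.0]
    for c1, c2 in zip(codons_a, codons_b):
        dL, dts, dtv = pair_counts(c1, c2)
        for k in range(3):
            L[k] += dL[k]
            ts[k] += dts[k]
            tv[k] += dtv[k]
    P = [ts[k] / L[k] if L[k] > 0 else 0.0 for k in range(3)]
    Q = [tv[k] / L[k] if L[k] > 0 else 0.0 for k in range(3)]
    A = [0.0, 0.0, 0.0]
    B = [0.0, 0.0, 0.0]
    saturated = False
    for k in range(3):
        if L[k] <= 0:
            continue
        a_arg = 1.0 - 2.0 * P[k] - Q[k]
        b_arg = 1.0 - 2.0 * Q[k]
        if a_arg <= 0 or b_arg <= 0:
            saturated = True
            continue
        A[k] = 0.5 * math.log(1.0 / a_arg) - 0.25 * math.log(1.0 / b_arg)
        B[k] = 0.5 * math.log(1.0 / b_arg)
    if saturated:
        return {"ka": math.nan, "ks": math.nan, "ks_sd": math.nan,
                "saturated": True}
    ks = (L[1] * A[1] + L[2] * A[2]) / (L[1] + L[2]) + B[2]
    ka = A[0] + (L[0] * B[0] + L[1] * B[1]) / (L[0] + L[1])
    # delta-method variance of Ks over the per-class (P, Q) multinomials
    var = 0.0
    denom = L[1] + L[2]
    for k in (1, 2):
        if L[k] <= 0:
            continue
        a = 1.0 / (1.0 - 2.0 * P[k] - Q[k])
        b = 1.0 / (1.0 - 2.0 * Q[k])
        dP = (L[k] / denom) * a
        dQ = (L[k] / denom) * (0.5 * a - 0.5 * b)
        if k == 2:
            dQ += b
        vP = P[k] * (1 - P[k]) / L[k]
        vQ = Q[k] * (1 - Q[k]) / L[k]
        cPQ = -P[k] * Q[k] / L[k]
        var += dP * dP * vP + dQ * dQ * vQ + 2 * dP * dQ * cPQ
    return {"ka": ka, "ks": ks, "ks_sd": math.sqrt(max(var, 0.0)),
            "saturated": False}


# ---------------------------------------------------------------------------
# explanatory-transfer counting oracle


def count_independent_oracle(groups, order):
    """Literal walk of the explanatory-transfer procedure.

    ``groups``: dict id -> {"species": {species: [copy, ...]} per side
    tuple, "copies": {copy: (clade_key, weakest_cross)}, "clades": (setA,
    setB), "copy_clade": {copy: frozenset}, "sims": {(c1, c2): pid}}
    given in pre-digested form (see the test that builds it); ``order``:
    processing order of group ids.  Returns the set of explained ids.
    """
    pool = set(groups)
    required = set()
    explained = set()
    for gid in order:
        g = groups[gid]
        per_species = {}
        used = set()
        for copy, (own_clade, weakest, species) in g["copies"].items():
            for cand_id in sorted(pool - {gid}):
                cand = groups[cand_id]
                for side in (0, 1):
                    cside = cand["clades"][side]
                    if not (cside <= own_clade or own_clade <= cside):
                        continue
                    side_copies = cand["side_copies"][side]
                    hit = False
                    for other in side_copies:
                        if other == copy:
                            continue
                        pid = g["sims"].get(tuple(sorted((copy, other))))
                        if pid is not None and pid > weakest:
                            hit = True
                            break
                    if hit:
                        per_species.setdefault(species, set()).add(cand_id)
                        used.add(cand_id)
        all_species = {spec for (_, _, spec) in g["copies"].values()}
        req1 = bool(all_species) and all(
            per_species.get(sp) for sp in all_species
        ) and len(used) >= 2
        if not req1:
            continue
        for cand_id in sorted(used):
            reduced_ok = all(
                (per_species.get(sp, set()) - {cand_id})
                for sp in all_species
            ) and len(used - {cand_id}) >= 2
            if not reduced_ok:
                required.add(cand_id)
        if gid in required:
            continue
        explained.add(gid)
        pool.discard(gid)
    return explained
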