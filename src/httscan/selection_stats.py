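"""Selection-regime contrasts on TE protein-coding regions.

Two Ka/Ks distributions are built per TE superfamily:

* **horizontally diverged pairs** — the retained cross-clade hits, whose
  divergence includes a transfer between host lineages; producing a
  functional transposition protein is a prerequisite for invading a new
  genome, so purifying selection (Ka/Ks < 1) is expected here for all TE
  types;
* **within-genome pairs** — copies from the same hit community and the
  same genome, whose divergence involves transposition only; purifying
  selection here indicates that transposition favors copies encoding
  functional proteins (cis-preference for retrotransposons), whereas
  trans-complemented elements such as DNA transposons may drift neutrally.

Each distribution is tested against neutrality (location 1) with a
one-sided Wilcoxon signed-rank test, the one-sample analogue of the
Mann-Whitney test; values exactly at 1 are dropped per the classical
procedure.  Ratios with Ks = 0 carry no usable signal and are excluded
with a logged count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from httscan.htt_cluster import HitCommunity
from httscan.kaks import TECopy, batch_kaks

__all__ = [
    "within_genome_pairs",
    "kaks_by_superfamily",
    "test_vs_neutral",
    "SelectionSummary",
    "selection_table",
]


@dataclass(frozen=True)
class SelectionSummary:
    superfamily: str
    context: str  # "horizontal" | "within_genome"
    n_pairs: int
    median_ka_ks: float
    p_value: float


def within_genome_pairs(
    communities: list[HitCommunity],
    copies: dict[str, TECopy],
    min_coding_bp: int = 300,
) -> pd.DataFrame:
    """Ka/Ks over copy pairs sharing a hit community and a genome.

    Pairs must align over at least ``min_coding_bp`` bp of projectable
    protein-coding region.  Returns a hit-table-like frame annotated by
    :func:`httscan.kaks.batch_kaks`.
    """
    rows = []
    seen: set[tuple[str, str]] = set()
    for comm in communities:
        by_species: dict[str, list[str]] = {}
        for cid in sorted(comm.copies_a | comm.copies_b):
            by_species.setdefault(copies[cid].species, []).append(cid)
        for _species, ids in sorted(by_species.items()):
            for i, c1 in enumerate(ids):
                for c2 in ids[i + 1 :]:
                    key = (c1, c2)
                    if key in seen:
                        continue
                    seen.add(key)
                    n = min(len(copies[c1].sequence),
                            len(copies[c2].sequence))
                    rows.append((c1, c2, comm.superfamily,
                                 copies[c1].te_class, 0, n, 0, n))
    if not rows:
        return pd.DataFrame(columns=["qseqid", "sseqid", "superfamily",
                                     "te_class", "qstart", "qend", "sstart",
                                     "send", "ka", "ks", "ks_sd",
                                     "n_codons", "saturated"])
    pairs = pd.DataFrame(rows, columns=["qseqid", "sseqid", "superfamily",
                                        "te_class", "qstart", "qend",
                                        "sstart", "send"])
    pairs = batch_kaks(pairs, copies)
    return pairs[3 * pairs["n_codons"] >= min_coding_bp].reset_index(drop=True)


def _usable_ratios(df: pd.DataFrame) -> np.ndarray:
    """Finite Ka/Ks values; pairs with Ks = 0 (no synonymous signal) and
    saturated pairs are excluded."""
    ka = df["ka"].to_numpy(dtype=float)
    ks = df["ks"].to_numpy(dtype=float)
    ok = np.isfinite(ka) & np.isfinite(ks) & (ks > 0)
    return ka[ok] / ks[ok]


def kaks_by_superfamily(
    ht_hits: pd.DataFrame,
    wg_pairs: pd.DataFrame,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-superfamily Ka/Ks value lists for the two divergence contexts.

    ``ht_hits`` must carry ``q_superfamily`` (retained hit table);
    ``wg_pairs`` carries ``superfamily`` (within-genome pair table).
    Superfamilies without usable values in either context are absent.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    if len(ht_hits):
        for sf, sub in ht_hits.groupby("q_superfamily"):
            vals = _usable_ratios(sub)
            if len(vals):
                out.setdefault(sf, {})["horizontal"] = vals
    if len(wg_pairs):
        for sf, sub in wg_pairs.groupby("superfamily"):
            vals = _usable_ratios(sub)
            if len(vals):
                out.setdefault(sf, {})["within_genome"] = vals
    return out


def test_vs_neutral(values, side: str = "less",
                    exact_max_n: int = 25) -> float:
    """One-sided Wilcoxon signed-rank test of Ka/Ks against 1.

    Values exactly equal to 1 are dropped (classical zero handling); the
    null is exact for up to ``exact_max_n`` non-zero differences and a
    normal approximation with continuity correction beyond.  All values at
    1 give p = 1 by convention.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no values to test")
    diffs = values - 1.0
    diffs = diffs[diffs != 0.0]
    if diffs.size == 0:
        return 1.0
    method = "exact" if (
        diffs.size <= exact_max_n and len(np.unique(np.abs(diffs))) == diffs.size
    ) else "approx"
    res = stats.wilcoxon(diffs, alternative=side, method=method,
                         correction=(method == "approx"))
    return float(res.pvalue)


def selection_table(
    distributions: dict[str, dict[str, np.ndarray]],
    alpha_side: str = "less",
) -> list[SelectionSummary]:
    """Run the neutrality test for every superfamily and context."""
    out = []
    for sf in sorted(distributions):
        for context in ("horizontal", "within_genome"):
            vals = distributions[sf].get(context)
            if vals is None or len(vals) == 0:
                continue
            out.append(SelectionSummary(
                superfamily=sf,
                context=context,
                n_pairs=int(len(vals)),
                median_ka_ks=float(np.median(vals)),
                p_value=test_vs_neutral(vals, side=alpha_side),
            ))
    return out
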