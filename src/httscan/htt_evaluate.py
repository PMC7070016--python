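"""Post-cluster hit-group evaluation.

Two failure modes survive the divergence filters and clustering:

* **contamination** — DNA from one genome assembled into another looks like
  an extremely recent transfer but involves very few copies; hit groups
  must therefore comprise at least five copies per clade (counting
  *retrieved* copies — copies of the member species attributable to the
  group but discarded earlier for workload reasons) and at least two
  per clade among the group's own hit copies;
* **vertical slow tails** — vertically inherited copy pairs that happened
  to diverge unusually slowly pass a Ks cutoff as the left tail of a larger
  vertical distribution; such groups are recognized by a Ks histogram that
  is visibly truncated at the selection threshold (modal class not
  dominating the rightmost class, or maximum Ks within 0.2 of the
  threshold) and removed.

Each check is a pure predicate on the group, so their order is irrelevant.
"""

from __future__ import annotations

import math

import numpy as np

from httscan.htt_cluster import HitGroup, IdentityTable

__all__ = [
    "retrieve_and_attribute",
    "copy_count_filter",
    "ks_histogram",
    "truncation_filter",
]


def retrieve_and_attribute(
    group: HitGroup,
    candidates_by_species: dict[str, list[str]],
    idt: IdentityTable,
) -> HitGroup:
    """Attribute unclustered copies of the member species to the group.

    A candidate copy joins clade A iff its mean identity to the group's
    clade-A copies (over reported alignments of at least 100 bp) is
    strictly higher than the group's mean cross-clade hit identity; same
    for clade B.  A copy passing on both sides joins the side it resembles
    more.  Candidates sharing no alignment with the group are ignored.
    """
    cross_mean = (
        float(np.mean(group.hit_pids)) if len(group.hit_pids)
        else float("nan")
    )
    in_group = group.copies_a | group.copies_b
    attributed: dict[str, list[str]] = {"a": [], "b": []}
    for species in sorted(group.species):
        for cid in sorted(candidates_by_species.get(species, [])):
            if cid in in_group:
                continue
            means = {}
            for side, side_copies in (("a", group.copies_a),
                                      ("b", group.copies_b)):
                pids = [idt.get(cid, other) for other in side_copies]
                pids = [p for p in pids if p is not None]
                if pids:
                    means[side] = float(np.mean(pids))
            passing = {s: m for s, m in means.items() if m > cross_mean}
            if passing:
                best = max(passing, key=lambda s: (passing[s], s == "a"))
                attributed[best].append(cid)
    group.retrieved_a = frozenset(attributed["a"])
    group.retrieved_b = frozenset(attributed["b"])
    return group


def copy_count_filter(group: HitGroup, min_incl_retrieved: int = 5,
                      min_excl_retrieved: int = 2) -> bool:
    """Anti-contamination copy counts: per clade, at least
    ``min_incl_retrieved`` copies counting retrieved ones and
    ``min_excl_retrieved`` among the group's own hit copies."""
    na, nb = len(group.copies_a), len(group.copies_b)
    return (
        na + len(group.retrieved_a) >= min_incl_retrieved
        and nb + len(group.retrieved_b) >= min_incl_retrieved
        and na >= min_excl_retrieved
        and nb >= min_excl_retrieved
    )


def _pretty_step(raw: float) -> float:
    """Nice class width: 1, 2 or 5 times a power of ten, nearest to raw."""
    if raw <= 0:
        return 1.0
    k = math.floor(math.log10(raw))
    best, best_err = None, None
    for c in (1.0, 2.0, 5.0, 10.0):
        step = c * 10.0**k
        err = abs(step - raw)
        if best is None or err < best_err:
            best, best_err = step, err
    return best


def ks_histogram(values) -> tuple[np.ndarray, np.ndarray]:
    """Histogram classes in the style of R's ``hist()`` defaults.

    The class count targets Sturges' rule (``ceil(log2(n)) + 1``) and
    boundaries fall on nice round numbers covering the range; intervals are
    right-closed with the lowest boundary included.  Returns
    ``(breaks, counts)``.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("ks_histogram requires at least one value")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return np.array([lo, hi]), np.array([values.size])
    n_classes = math.ceil(math.log2(values.size)) + 1
    step = _pretty_step((hi - lo) / n_classes)
    start = math.floor(lo / step) * step
    stop = math.ceil(hi / step) * step
    breaks = np.arange(start, stop + step / 2, step)
    if breaks[-1] < hi:
        breaks = np.append(breaks, breaks[-1] + step)
    # right-closed intervals, lowest bound included
    idx = np.searchsorted(breaks, values, side="left") - 1
    idx = np.clip(idx, 0, len(breaks) - 2)
    counts = np.bincount(idx, minlength=len(breaks) - 1)
    return breaks, counts


def truncation_filter(group: HitGroup, margin: float = 0.2,
                      min_modal_excess: int = 20) -> bool:
    """Anti-vertical Ks-shape check.

    Keep iff the modal Ks class (leftmost on ties) contains at least
    ``min_modal_excess`` more hits than the rightmost non-empty class, and
    the maximum Ks stays at least ``margin`` below the selection threshold
    recorded on the group.
    """
    ks = np.asarray(group.ks_values, dtype=float)
    ks = ks[np.isfinite(ks)]
    if ks.size == 0:
        return False
    _, counts = ks_histogram(ks)
    nonempty = np.nonzero(counts)[0]
    modal = int(counts.max())
    rightmost = int(counts[nonempty[-1]])
    if len(nonempty) == 1:
        # a single occupied class is its own rightmost class; the modal
        # excess requirement then cannot be met
        rightmost = modal
    if modal < rightmost + min_modal_excess:
        return False
    return float(ks.max()) <= group.theta - margin
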