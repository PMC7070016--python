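"""Selection of TE-TE hits whose divergence is incompatible with vertical
inheritance.

The vertical-divergence null for a species pair is the distribution of
core-gene (conserved single-copy ortholog) synonymous divergences between
the two sister clades descending from the pair's most recent common
ancestor.  A TE-TE hit survives when its synonymous divergence, plus twice
its standard deviation, lies below the 0.5% quantile of that null — i.e.
the TE pair is younger than (almost) any vertically inherited gene pair —
subject to the absolute guards ``Ks < 0.5`` and at least 100 projectable
codons.  Hits between species that diverged within the last 120 My are
excluded wholesale: at vertebrate rates, slow-evolving vertical copies
cannot be told apart from transfer at such short timescales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from httscan.treespace import CladePair, SpeciesTree

__all__ = [
    "KsDistribution",
    "CoreKsLookup",
    "build_core_ks",
    "ks_threshold",
    "retain_hits",
    "dedup_reciprocal",
    "exclude_young_pairs",
    "pid_prefilter",
    "ks_filter",
]


def _empirical_quantile(values: np.ndarray, q: float) -> float:
    """Linear interpolation between order statistics, tolerating +inf
    entries (saturated core Ks values sort to the top and only matter when
    the quantile falls among them)."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    pos = q * (n - 1)
    lo, hi = int(np.floor(pos)), int(np.ceil(pos))
    if not np.isfinite(values[hi]):
        if pos == lo and np.isfinite(values[lo]):
            return float(values[lo])
        return float("inf")
    return float(values[lo] + (pos - lo) * (values[hi] - values[lo]))


@dataclass(frozen=True)
class KsDistribution:
    """Empirical core-gene Ks distribution for one sister-clade pair."""

    pair_id: str
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.size == 0:
            raise ValueError(
                f"empty core Ks distribution for {self.pair_id}: "
                "downstream thresholds are undefined"
            )
        if (vals < 0).any():
            raise ValueError("negative Ks in core distribution")
        object.__setattr__(self, "values", np.sort(vals))

    def quantile(self, q: float) -> float:
        return _empirical_quantile(self.values, q)

    def __len__(self) -> int:
        return len(self.values)


def ks_threshold(dist: KsDistribution, quantile: float = 0.005,
                 ks_cap: float = 0.5) -> float:
    """Ks threshold: the smaller of ``ks_cap`` and the distribution's
    ``quantile`` (default the 0.5% quantile)."""
    return min(ks_cap, dist.quantile(quantile))


def build_core_ks(
    ortholog_ks: pd.DataFrame,
    pair: CladePair,
    tree: SpeciesTree,
    min_aln_len: int = 600,
    deep_pair_age: float = 250.0,
    subclade_age: float = 30.0,
) -> KsDistribution:
    """Core-gene Ks distribution for one sister-clade pair.

    ``ortholog_ks`` carries columns ``gene, species_a, species_b, ks,
    aln_len``.  Alignments shorter than ``min_aln_len`` are dropped; among
    alignments sharing a gene instance (a gene in a given species — the
    same gene in different species counts as different genes) only the
    longest is kept, greedily by decreasing length, to limit
    pseudo-replication.  For clade pairs older than ``deep_pair_age`` My,
    only one designated genome per sub-``subclade_age`` subclade is used on
    each side: the one contributing the most gene records.
    """
    df = ortholog_ks[ortholog_ks["aln_len"] >= min_aln_len]
    cross = (
        (df["species_a"].isin(pair.clade_a) & df["species_b"].isin(pair.clade_b))
        | (df["species_a"].isin(pair.clade_b) & df["species_b"].isin(pair.clade_a))
    )
    df = df[cross]

    if pair.mrca_age > deep_pair_age and len(df):
        partition = tree.clades_younger_than(subclade_age)
        counts = (
            pd.concat([df["species_a"], df["species_b"]])
            .value_counts()
            .to_dict()
        )
        keep_species = set()
        for side in (pair.clade_a, pair.clade_b):
            per_clade: dict[int, str] = {}
            for sp in sorted(side):
                cid = partition.clade_of(sp)
                best = per_clade.get(cid)
                if best is None or (counts.get(sp, 0), sp) > (
                    counts.get(best, 0), best
                ):
                    per_clade[cid] = sp
            keep_species.update(per_clade.values())
        df = df[df["species_a"].isin(keep_species)
                & df["species_b"].isin(keep_species)]

    # longest alignment per gene instance, greedy by decreasing length
    df = df.sort_values(["aln_len", "gene", "species_a", "species_b"],
                        ascending=[False, True, True, True])
    used: set[tuple[str, str]] = set()
    values = []
    for row in df.itertuples(index=False):
        ga, gb = (row.gene, row.species_a), (row.gene, row.species_b)
        if ga in used or gb in used:
            continue
        used.add(ga)
        used.add(gb)
        values.append(row.ks)
    pair_id = (
        "|".join(sorted(pair.clade_a)) + "--" + "|".join(sorted(pair.clade_b))
    )
    return KsDistribution(pair_id, np.asarray(values, dtype=float))


class CoreKsLookup:
    """Cache of sister-clade-pair Ks distributions keyed by species pair."""

    def __init__(self, ortholog_ks: pd.DataFrame, tree: SpeciesTree,
                 min_aln_len: int = 600, deep_pair_age: float = 250.0,
                 subclade_age: float = 30.0):
        self._ortholog_ks = ortholog_ks
        self._tree = tree
        self._min_aln_len = min_aln_len
        self._deep_pair_age = deep_pair_age
        self._subclade_age = subclade_age
        self._cache: dict = {}

    @property
    def tree(self) -> SpeciesTree:
        return self._tree

    def pair(self, sp1: str, sp2: str) -> CladePair:
        return self._tree.sister_clade_pair(sp1, sp2)

    def distribution(self, sp1: str, sp2: str) -> KsDistribution:
        pair = self.pair(sp1, sp2)
        key = pair.key()
        if key not in self._cache:
            self._cache[key] = build_core_ks(
                self._ortholog_ks, pair, self._tree,
                min_aln_len=self._min_aln_len,
                deep_pair_age=self._deep_pair_age,
                subclade_age=self._subclade_age,
            )
        return self._cache[key]

    def quantile(self, sp1: str, sp2: str, q: float = 0.005) -> float:
        return self.distribution(sp1, sp2).quantile(q)


# ---------------------------------------------------------------------------
# hit-level filters; each returns a keep-mask so the pipeline can record
# which rule discarded each hit


def retain_hits(hits: pd.DataFrame, min_len: int = 300,
                min_pid: float = 75.0, min_score: float = 200.0) -> pd.Series:
    """Similarity-search retention: alignment length >= ``min_len`` bp,
    percent identity >= ``min_pid``, score >= ``min_score``, and matching
    superfamilies (checked when ``q_superfamily``/``s_superfamily`` columns
    are present)."""
    keep = (
        (hits["length"] >= min_len)
        & (hits["pident"] >= min_pid)
        & (hits["bitscore"] >= min_score)
    )
    if "q_superfamily" in hits.columns and "s_superfamily" in hits.columns:
        keep &= hits["q_superfamily"] == hits["s_superfamily"]
    return keep


def dedup_reciprocal(hits: pd.DataFrame) -> pd.DataFrame:
    """Collapse reciprocal duplicates (the A->B and B->A best hits over the
    same unordered copy pair), keeping the higher-scoring record."""
    if hits.empty:
        return hits
    key = [tuple(sorted(t)) for t in zip(hits["qseqid"], hits["sseqid"])]
    out = hits.assign(_pairkey=key)
    out = out.sort_values(["bitscore", "qseqid", "sseqid"],
                          ascending=[False, True, True])
    out = out.drop_duplicates("_pairkey", keep="first")
    return out.drop(columns="_pairkey").sort_index()


def exclude_young_pairs(hits: pd.DataFrame, tree: SpeciesTree,
                        min_age: float = 120.0) -> pd.Series:
    """Keep only hits between species that diverged at least ``min_age`` My
    ago (a pair diverged exactly at the boundary is kept)."""
    species = pd.concat([hits["q_species"], hits["s_species"]]).unique()
    missing = sorted(sp for sp in species if sp not in tree)
    if missing:
        raise KeyError(f"species absent from tree: {missing}")
    div = np.array([
        tree.divergence_my(q, s)
        for q, s in zip(hits["q_species"], hits["s_species"])
    ]) if len(hits) else np.array([])
    return pd.Series(div >= min_age, index=hits.index, dtype=bool)


def pid_prefilter(hits: pd.DataFrame, quantiles: pd.Series) -> pd.Series:
    """Cheap pre-screen before Ka/Ks computation: keep a hit iff its global
    divergence proxy ``1 - pID/100`` does not exceed the core-gene Ks
    quantile for its species pair.  Purely an optimization — any hit kept
    here by mistake still faces :func:`ks_filter`."""
    return (1.0 - hits["pident"] / 100.0) <= quantiles


def ks_filter(hits: pd.DataFrame, quantiles: pd.Series,
              max_ks: float = 0.5, min_codons: int = 100) -> pd.Series:
    """Divergence filter: keep iff ``Ks + 2*Ks_sd <= quantile`` and
    ``Ks < max_ks`` and ``n_codons >= min_codons``.  Saturated or
    uncomputable rates fail."""
    if hits.empty:
        return pd.Series(dtype=bool, index=hits.index)
    ks = hits["ks"].to_numpy(dtype=float)
    sd = hits["ks_sd"].to_numpy(dtype=float)
    finite = np.isfinite(ks) & np.isfinite(sd)
    ks_safe = np.where(finite, ks, np.inf)
    sd_safe = np.where(finite, sd, 0.0)
    keep = (
        finite
        & (ks_safe + 2.0 * sd_safe <= quantiles.to_numpy(dtype=float))
        & (ks_safe < max_ks)
        & (hits["n_codons"].to_numpy() >= min_codons)
    )
    return pd.Series(keep, index=hits.index)
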