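"""Permutation nulls for the distribution of transfers across clades.

Each independent transfer is reduced to its representative species pair
(the pair of the highest-identity hit).  A null distribution of per-clade
transfer counts is generated by shuffling species identities among the
species involved in a unit's transfers — a bijection, so a species is
replaced by the same species in every pair, preserving per-species transfer
multiplicities — and rejecting permutations that would imply a transfer
between species diverged less than 120 My ago, which real data cannot
contain by construction.  Units are TE superfamilies; superfamilies with
few transfers are pooled per TE class, and very large units are split into
balanced subsets because legal permutations become too rare to sample.

The habitat test permutes aquatic/terrestrial labels across the tetrapod
species involved in transfers with ray-finned fishes (such permutations are
always legal) and compares the observed number of aquatic-tetrapod-fish
groups to the permuted distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from httscan.treespace import SpeciesTree

__all__ = [
    "PermutationSummary",
    "permute_species",
    "clade_count_test",
    "pool_and_subset",
    "habitat_permutation",
]

#: Rejection-sampling budget per unit before giving up.
MAX_PERMUTATION_DRAWS = 10_000_000


@dataclass(frozen=True)
class PermutationSummary:
    label: str
    observed: int
    null_mean: float
    null_q025: float
    null_q975: float
    verdict: str  # "below_all" | "above_all" | "within" | "outside_95"
    ratio: float  # observed / null mean (inf when the null mean is 0)


def _legal(pairs: list[tuple[str, str]], tree: SpeciesTree,
           min_age: float) -> bool:
    return all(tree.divergence_my(a, b) >= min_age for a, b in pairs)


def permute_species(
    pairs: list[tuple[str, str]],
    tree: SpeciesTree,
    n_perm: int = 1000,
    min_age: float = 120.0,
    seed: int | np.random.Generator = 0,
) -> list[list[tuple[str, str]]]:
    """Draw ``n_perm`` legal species permutations of the transfer pairs.

    Each permutation is a bijection on the species involved, applied
    consistently to every pair; draws implying any transfer between
    species diverged less than ``min_age`` My are rejected and redrawn.
    Raises ``RuntimeError`` when the rejection budget is exhausted (the
    unit should then be subset).
    """
    if not pairs:
        raise ValueError("no transfer pairs to permute")
    if not _legal(pairs, tree, min_age):
        raise ValueError("observed pairs violate the divergence rule")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    species = sorted({sp for pair in pairs for sp in pair})
    out: list[list[tuple[str, str]]] = []
    draws = 0
    while len(out) < n_perm:
        if draws >= MAX_PERMUTATION_DRAWS:
            raise RuntimeError(
                f"no {n_perm} legal permutations within "
                f"{MAX_PERMUTATION_DRAWS} draws ({len(out)} found); "
                "subset the transfers of this unit"
            )
        draws += 1
        perm = rng.permutation(len(species))
        mapping = {species[i]: species[perm[i]] for i in range(len(species))}
        permuted = [(mapping[a], mapping[b]) for a, b in pairs]
        if _legal(permuted, tree, min_age):
            out.append(permuted)
    return out


def clade_count_test(
    pairs: list[tuple[str, str]],
    clade_of: dict[str, str],
    permutations: list[list[tuple[str, str]]],
) -> list[PermutationSummary]:
    """Observed vs permuted per-clade transfer counts.

    A transfer counts for a clade when either of its representative species
    belongs to it (once, even if both do).  Verdicts: ``below_all`` /
    ``above_all`` when the observed count is outside every permutation
    (p < 1/n_perm one-sided), ``within`` when inside the central 95%,
    ``outside_95`` otherwise.
    """

    def counts(pair_list):
        tally: dict[str, int] = {}
        for a, b in pair_list:
            for clade in {clade_of[a], clade_of[b]}:
                tally[clade] = tally.get(clade, 0) + 1
        return tally

    observed = counts(pairs)
    labels = sorted(set(clade_of.values()))
    null = {lab: np.zeros(len(permutations)) for lab in labels}
    for k, perm in enumerate(permutations):
        tally = counts(perm)
        for lab in labels:
            null[lab][k] = tally.get(lab, 0)
    summaries = []
    for lab in labels:
        obs = observed.get(lab, 0)
        dist = null[lab]
        mean = float(dist.mean())
        q025, q975 = (float(np.quantile(dist, 0.025)),
                      float(np.quantile(dist, 0.975)))
        if obs > dist.max():
            verdict = "above_all"
        elif obs < dist.min():
            verdict = "below_all"
        elif q025 <= obs <= q975:
            verdict = "within"
        else:
            verdict = "outside_95"
        ratio = obs / mean if mean > 0 else float("inf")
        summaries.append(PermutationSummary(lab, obs, mean, q025, q975,
                                            verdict, ratio))
    return summaries


def pool_and_subset(
    transfers: pd.DataFrame,
    min_per_family: int = 20,
    max_for_perm: int = 120,
    seed: int | np.random.Generator = 0,
) -> dict[str, pd.DataFrame]:
    """Partition transfers into permutation units.

    ``transfers`` carries ``superfamily`` and ``te_class`` columns.
    Superfamilies with at least ``min_per_family`` transfers form their own
    unit; smaller ones are pooled per TE class (unit ``<class> (other)``).
    Units larger than ``max_for_perm`` are shuffled (seeded) and split into
    balanced contiguous subsets of at most ``max_for_perm``.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    units: dict[str, pd.DataFrame] = {}
    pooled: dict[str, list[pd.DataFrame]] = {}
    for sf, sub in sorted(transfers.groupby("superfamily")):
        if len(sub) >= min_per_family:
            units[sf] = sub
        else:
            pooled.setdefault(sub["te_class"].iloc[0], []).append(sub)
    for te_class, parts in sorted(pooled.items()):
        units[f"{te_class} (other)"] = pd.concat(parts)
    out: dict[str, pd.DataFrame] = {}
    for name, sub in units.items():
        if len(sub) <= max_for_perm:
            out[name] = sub
            continue
        n_chunks = math.ceil(len(sub) / max_for_perm)
        size = math.ceil(len(sub) / n_chunks)
        shuffled = sub.iloc[rng.permutation(len(sub))]
        for k in range(n_chunks):
            out[f"{name} [{k + 1}/{n_chunks}]"] = shuffled.iloc[
                k * size : (k + 1) * size
            ]
    return out


def habitat_permutation(
    pairs: list[tuple[str, str]],
    habitat: dict[str, str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PermutationSummary:
    """Aquatic-vs-terrestrial test for tetrapod-fish transfers.

    ``pairs`` are (tetrapod species, fish species) per hit group; habitat
    labels (``aquatic`` / ``terrestrial``, amphibious species labelled
    aquatic by the caller) are permuted across the involved tetrapod
    species.  The statistic is the number of groups whose tetrapod is
    aquatic; the verdict compares it to the central 95% of the null.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    tetrapods = sorted({t for t, _ in pairs})
    missing = [t for t in tetrapods if t not in habitat]
    if missing:
        raise KeyError(f"no habitat label for {missing}")

    def stat(lab: dict[str, str]) -> int:
        return sum(lab[t] == "aquatic" for t, _ in pairs)

    observed = stat(habitat)
    labels = [habitat[t] for t in tetrapods]
    null = np.zeros(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(len(tetrapods))
        shuffled = {tetrapods[i]: labels[perm[i]]
                    for i in range(len(tetrapods))}
        null[k] = stat(shuffled)
    mean = float(null.mean())
    q025, q975 = float(np.quantile(null, 0.025)), float(np.quantile(null, 0.975))
    if observed > null.max():
        verdict = "above_all"
    elif observed < null.min():
        verdict = "below_all"
    elif q025 <= observed <= q975:
        verdict = "within"
    else:
        verdict = "outside_95"
    ratio = observed / mean if mean > 0 else float("inf")
    return PermutationSummary("aquatic_tetrapod_fish", observed, mean,
                              q025, q975, verdict, ratio)
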