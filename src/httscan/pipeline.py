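"""End-to-end orchestration of the transfer-detection pipeline.

Every tunable threshold of the procedure lives in :class:`PipelineConfig`
(one field per threshold, with the standard value as default); stages
receive them from there, never from literals, so a run is fully described
by its config.  :func:`run_pipeline` executes

    hits -> basic retention -> reciprocal dedup -> young-pair exclusion
         -> Ka/Ks annotation -> divergence (Ks) filter
         -> pre-clustering -> communities -> hit groups
         -> retrieval + copy-count + truncation evaluation
         -> independent-event counting
         -> species permutations and selection-regime tests

and returns a :class:`PipelineResult` carrying every intermediate table
plus a manifest of per-stage record counts, the config and the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from httscan import htt_count, htt_evaluate, htt_filter, htt_permute
from httscan import selection_stats
from httscan.htt_cluster import (
    HitCommunity,
    HitGroup,
    IdentityTable,
    cluster_pipeline,
)
from httscan.kaks import FrameSegment, TECopy, batch_kaks
from httscan.simulate import SimulationConfig, SyntheticDataset
from httscan.treespace import SpeciesTree, parse_timetree

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_dataset"]


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the procedure, in one place.

    Ages are in My, lengths in bp, identities in percent.
    """

    young_clade_age: float = 40.0       # species collapse for searches/communities
    min_transfer_age: float = 120.0     # exclude hits between younger species
    subclade_age: float = 30.0          # one genome per subclade this young...
    deep_pair_age: float = 250.0        # ...for clade pairs older than this
    min_hit_length: int = 300
    min_hit_pid: float = 75.0
    min_hit_score: float = 200.0
    core_quantile: float = 0.005        # core-gene Ks null quantile
    max_te_ks: float = 0.5
    min_codons: int = 100
    min_core_aln_len: int = 600
    max_hits_per_pair: int = 200        # per pre-cluster per species pair
    criterion1_fraction: float = 0.05
    min_protein_overlap: int = 100
    min_identity_len: int = 100         # alignment floor for identity tables
    min_copies_incl_retrieved: int = 5
    min_copies_excl_retrieved: int = 2
    truncation_margin: float = 0.2
    truncation_excess: int = 20
    min_transfers_per_superfamily: int = 20
    max_transfers_per_unit: int = 120
    n_permutations: int = 1000
    min_wg_coding_bp: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.min_transfer_age <= 0:
            raise ValueError(
                "min_transfer_age must be positive: without a divergence "
                "floor, transfer cannot be told apart from vertical "
                "inheritance"
            )


@dataclass
class PipelineResult:
    config: PipelineConfig
    tree: SpeciesTree
    hits: pd.DataFrame              # all input hits with audit columns
    retained: pd.DataFrame          # hits surviving every filter, annotated
    communities: list[HitCommunity]
    groups: list[HitGroup]          # all clustered groups
    surviving_groups: list[HitGroup]
    group_audit: pd.DataFrame       # per-group evaluation decisions
    events: list[htt_count.TransferEvent]
    permutation_summaries: dict[str, list[htt_permute.PermutationSummary]]
    selection_summaries: list[selection_stats.SelectionSummary]
    manifest: dict

    @property
    def n_independent(self) -> int:
        return sum(e.independent for e in self.events)


def _join_meta(hits: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    cols = meta.set_index("copy_id")
    out = hits.copy()
    for prefix, key in (("q", "qseqid"), ("s", "sseqid")):
        joined = cols.reindex(out[key])
        missing = joined.index[joined["species"].isna()]
        if len(missing):
            raise KeyError(f"hits reference unknown copies: "
                           f"{sorted(set(missing))[:5]}")
        out[f"{prefix}_species"] = joined["species"].to_numpy()
        out[f"{prefix}_superfamily"] = joined["superfamily"].to_numpy()
    return out


def run_pipeline(
    ds: SyntheticDataset,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    run_permutations: bool = True,
    run_selection: bool = True,
) -> PipelineResult:
    """Run every stage on a dataset bundle (simulated or loaded)."""
    cfg = config or PipelineConfig()
    tree = ds.tree
    core = htt_filter.CoreKsLookup(
        ds.core_ks, tree,
        min_aln_len=cfg.min_core_aln_len,
        deep_pair_age=cfg.deep_pair_age,
        subclade_age=cfg.subclade_age,
    )

    hits = _join_meta(ds.hits, ds.copies_meta)
    hits["keep_basic"] = htt_filter.retain_hits(
        hits, cfg.min_hit_length, cfg.min_hit_pid, cfg.min_hit_score
    )
    deduped = htt_filter.dedup_reciprocal(hits[hits["keep_basic"]])
    hits["kept_dedup"] = hits.index.isin(deduped.index)
    stage = hits[hits["kept_dedup"]].copy()
    keep_age = htt_filter.exclude_young_pairs(stage, tree,
                                              cfg.min_transfer_age)
    hits["keep_age"] = False
    hits.loc[keep_age.index[keep_age], "keep_age"] = True
    stage = stage[keep_age]

    quantiles = pd.Series(
        [core.quantile(q, s, cfg.core_quantile)
         for q, s in zip(stage["q_species"], stage["s_species"])],
        index=stage.index, dtype=float,
    )
    keep_pre = htt_filter.pid_prefilter(stage, quantiles)
    hits["keep_prefilter"] = False
    hits.loc[keep_pre.index[keep_pre], "keep_prefilter"] = True
    stage = stage[keep_pre]
    quantiles = quantiles[keep_pre]

    stage = batch_kaks(stage, ds.copies)
    keep_ks = htt_filter.ks_filter(stage, quantiles, cfg.max_te_ks,
                                   cfg.min_codons)
    hits["keep_ks"] = False
    hits.loc[keep_ks.index[keep_ks], "keep_ks"] = True
    retained = stage[keep_ks].copy()
    theta_by_hit = pd.Series(
        np.minimum(cfg.max_te_ks, quantiles[keep_ks]),
        index=retained.index,
    )

    communities, groups, retained = cluster_pipeline(
        retained, ds.identities, core, tree,
        copy_index=ds.copies,
        theta_by_hit=theta_by_hit,
        young_clade_age=cfg.young_clade_age,
        max_hits_per_pair=cfg.max_hits_per_pair,
        min_pass_fraction=cfg.criterion1_fraction,
        min_protein_overlap=cfg.min_protein_overlap,
        quantile=cfg.core_quantile,
        ks_cap=cfg.max_te_ks,
    )

    idt = IdentityTable(ds.identities)
    candidates_by_species: dict[str, list[str]] = {}
    for cid, te in ds.copies.items():
        if len(te.sequence) >= cfg.min_identity_len:
            candidates_by_species.setdefault(te.species, []).append(cid)
    audit_rows = []
    surviving = []
    for g in groups:
        htt_evaluate.retrieve_and_attribute(g, candidates_by_species, idt)
        keep_copies = htt_evaluate.copy_count_filter(
            g, cfg.min_copies_incl_retrieved, cfg.min_copies_excl_retrieved
        )
        keep_shape = htt_evaluate.truncation_filter(
            g, cfg.truncation_margin, cfg.truncation_excess
        )
        audit_rows.append({
            "group_id": g.group_id,
            "superfamily": g.superfamily,
            "n_copies_a": len(g.copies_a),
            "n_copies_b": len(g.copies_b),
            "n_retrieved_a": len(g.retrieved_a),
            "n_retrieved_b": len(g.retrieved_b),
            "max_ks": float(np.max(g.ks_values)) if len(g.ks_values) else
                      float("nan"),
            "theta": g.theta,
            "keep_copy_count": keep_copies,
            "keep_truncation": keep_shape,
        })
        if keep_copies and keep_shape:
            surviving.append(g)
    group_audit = pd.DataFrame(audit_rows)

    species_of_copy = dict(zip(ds.copies_meta["copy_id"],
                               ds.copies_meta["species"]))
    sim_index = htt_count.SimilarityIndex(retained, idt)
    events = htt_count.count_independent(surviving, retained,
                                         species_of_copy, sim_index)

    permutation_summaries: dict[str, list] = {}
    if run_permutations:
        independent = [e for e in events if e.independent]
        if independent:
            transfers = pd.DataFrame({
                "group_id": [e.group_id for e in independent],
                "superfamily": [e.superfamily for e in independent],
                "te_class": [e.te_class for e in independent],
                "sp1": [e.representative_pair[0] for e in independent],
                "sp2": [e.representative_pair[1] for e in independent],
            })
            partition = tree.clades_younger_than(cfg.min_transfer_age)
            clade_of = {
                sp: f"clade_{min(partition.members(partition.clade_of(sp)))}"
                for sp in tree.tips
            }
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 1]).generate_state(1)[0]
            )
            units = htt_permute.pool_and_subset(
                transfers, cfg.min_transfers_per_superfamily,
                cfg.max_transfers_per_unit, rng,
            )
            for name, unit in units.items():
                pairs = list(zip(unit["sp1"], unit["sp2"]))
                perms = htt_permute.permute_species(
                    pairs, tree, cfg.n_permutations,
                    cfg.min_transfer_age, rng,
                )
                permutation_summaries[name] = htt_permute.clade_count_test(
                    pairs, clade_of, perms
                )

    selection_summaries: list[selection_stats.SelectionSummary] = []
    if run_selection:
        wg = selection_stats.within_genome_pairs(
            communities, ds.copies, cfg.min_wg_coding_bp
        )
        dists = selection_stats.kaks_by_superfamily(retained, wg)
        selection_summaries = selection_stats.selection_table(dists)

    manifest = {
        "config": dataclasses.asdict(cfg),
        "n_hits_input": int(len(hits)),
        "n_hits_basic": int(hits["keep_basic"].sum()),
        "n_hits_after_dedup": int(hits["kept_dedup"].sum()),
        "n_hits_after_age": int(hits["keep_age"].sum()),
        "n_hits_after_prefilter": int(hits["keep_prefilter"].sum()),
        "n_hits_retained": int(hits["keep_ks"].sum()),
        "n_hits_clustered": int(len(retained)),
        "n_communities": len(communities),
        "n_hit_groups": len(groups),
        "n_groups_surviving": len(surviving),
        "n_independent_transfers": sum(e.independent for e in events),
    }

    result = PipelineResult(
        config=cfg,
        tree=tree,
        hits=hits,
        retained=retained,
        communities=communities,
        groups=groups,
        surviving_groups=surviving,
        group_audit=group_audit,
        events=events,
        permutation_summaries=permutation_summaries,
        selection_summaries=selection_summaries,
        manifest=manifest,
    )
    if outdir is not None:
        write_result(result, outdir)
    return result


def write_result(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.hits.to_csv(outdir / "hits_audit.tsv", sep="\t", index=True)
    result.retained.to_csv(outdir / "hits_retained.tsv", sep="\t", index=True)
    result.group_audit.to_csv(outdir / "groups_audit.tsv", sep="\t",
                              index=False)
    pd.DataFrame([{
        "group_id": e.group_id,
        "independent": e.independent,
        "reliability": e.reliability,
        "explained_by": ",".join(map(str, sorted(e.explained_by))),
        "required_for": ",".join(map(str, sorted(e.required_for))),
        "species_1": e.representative_pair[0],
        "species_2": e.representative_pair[1],
        "superfamily": e.superfamily,
        "te_class": e.te_class,
    } for e in result.events]).to_csv(outdir / "transfers.tsv", sep="\t",
                                      index=False)
    perm_rows = [
        {"unit": unit, **dataclasses.asdict(s)}
        for unit, summaries in result.permutation_summaries.items()
        for s in summaries
    ]
    pd.DataFrame(perm_rows).to_csv(outdir / "permutations.tsv", sep="\t",
                                   index=False)
    pd.DataFrame([dataclasses.asdict(s)
                  for s in result.selection_summaries]).to_csv(
        outdir / "selection.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
    lines = ["pipeline run summary", "===================="]
    for key, value in result.manifest.items():
        if key != "config":
            lines.append(f"{key}: {value}")
    for e in result.events:
        if e.independent:
            lines.append(
                f"independent transfer: group {e.group_id} "
                f"[{e.superfamily}] {e.representative_pair[0]} <-> "
                f"{e.representative_pair[1]}"
            )
    (outdir / "run.log").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# loading a dataset from the plain-text layout written by the simulator


def load_dataset(indir: str | Path) -> SyntheticDataset:
    """Read a dataset bundle (tree.nwk, copies.fasta, copies_meta.tsv,
    core_ks.tsv, hits.tsv, identities.tsv) from a directory."""
    from Bio import SeqIO

    indir = Path(indir)
    tree = parse_timetree((indir / "tree.nwk").read_text())
    meta = pd.read_csv(indir / "copies_meta.tsv", sep="\t",
                       keep_default_na=False)
    seqs = {rec.id: str(rec.seq)
            for rec in SeqIO.parse(indir / "copies.fasta", "fasta")}
    frames_path = indir / "frames.tsv"
    have_frames = frames_path.exists()
    frames_by_copy: dict[str, list[FrameSegment]] = {}
    if have_frames:
        for row in pd.read_csv(frames_path, sep="\t").itertuples(index=False):
            frames_by_copy.setdefault(row.copy_id, []).append(
                FrameSegment(int(row.start), int(row.end), int(row.phase),
                             row.protein_family, int(row.protein_start))
            )
    copies = {}
    for row in meta.itertuples(index=False):
        seq = seqs[row.copy_id]
        if have_frames:
            # a copy absent from the table has no annotated frame
            frames = frames_by_copy.get(row.copy_id, [])
        else:
            frames = [FrameSegment(0, len(seq) - len(seq) % 3, 0,
                                   f"{row.superfamily}#pol", 0)]
        copies[row.copy_id] = TECopy(
            copy_id=row.copy_id,
            species=row.species,
            superfamily=row.superfamily,
            te_class=row.te_class,
            sequence=seq,
            frame_segments=frames,
        )
    hits = pd.read_csv(
        indir / "hits.tsv", sep="\t", header=None,
        names=["qseqid", "sseqid", "pident", "length", "mismatch",
               "gapopen", "qstart", "qend", "sstart", "send", "evalue",
               "bitscore"],
    )
    for col in ("qstart", "sstart"):
        hits[col] = hits[col] - 1  # back to 0-based half-open
    core_ks = pd.read_csv(indir / "core_ks.tsv", sep="\t")
    identities = pd.read_csv(indir / "identities.tsv", sep="\t")
    return SyntheticDataset(
        config=SimulationConfig(newick=(indir / "tree.nwk").read_text().strip()),
        tree=tree,
        copies=copies,
        copies_meta=meta,
        core_ks=core_ks,
        hits=hits,
        identities=identities,
        truth=[],
    )
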