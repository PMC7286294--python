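"""Cross-cell-type differential Pol II occupancy.

Comparisons subtract log2-ratio profiles replicate-wise, average the
difference replicates, and re-use the gene-calling machinery (transcript
scores + permutation FDR) on the difference profile.  Significant genes
are kept only when also bound in the numerator dataset — negative log2
ratios otherwise let never-transcribed genes appear "enriched".

Unique enrichment/depletion across three cell types and the
stage-transition table follow.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gatc import AnnotationSet
from .genecalls import CallParams, GeneCallTable, call_genes, permutation_fdr
from .profiles import FragmentProfile, SampleMeta


@dataclass
class DifferentialResult:
    numerator: str
    denominator: str
    stage: str
    table: pd.DataFrame  # gene_id, transcript_id, score, fdr, significant, bound_in_numerator, enriched

    @property
    def enriched_genes(self) -> set[str]:
        return set(self.table.loc[self.table["enriched"], "gene_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class UniqueSets:
    stage: str
    enriched: dict[str, set[str]] = field(default_factory=dict)
    depleted: dict[str, set[str]] = field(default_factory=dict)


def comparison_seed(master_seed: int, stage: str, numerator: str, denominator: str) -> int:
    """Deterministic per-comparison seed derived from the master seed."""
    tag = f"{stage}|{numerator}|{denominator}".encode()
    return (master_seed * 1_000_003 + zlib.crc32(tag)) % (2**31)


def subtract_profiles(
    a_reps: list[FragmentProfile], b_reps: list[FragmentProfile]
) -> list[FragmentProfile]:
    """Replicate-wise elementwise difference of log2-ratio profiles."""
    if len(a_reps) != len(b_reps):
        raise ValueError(f"replicate count mismatch: {len(a_reps)} vs {len(b_reps)}")
    if not a_reps:
        raise ValueError("no replicates given")
    out = []
    for a, b in zip(a_reps, b_reps):
        if not a.map.same_map(b.map):
            raise ValueError("profiles use different fragment maps")
        if a.unit != "log2_ratio" or b.unit != "log2_ratio":
            raise ValueError("subtract_profiles expects log2_ratio profiles")
        meta = SampleMeta(
            sample_id=f"{a.meta.sample_id}-minus-{b.meta.sample_id}",
            cell_type=a.meta.cell_type,
            stage=a.meta.stage,
            replicate=a.meta.replicate,
            channel="dam_fusion",
            fusion_name=a.meta.fusion_name or "diff",
        )
        out.append(
            FragmentProfile(meta=meta, unit="log2_ratio", values=a.values - b.values, map=a.map)
        )
    return out


def differential_genes(
    diff_reps: list[FragmentProfile],
    annotation: AnnotationSet,
    numerator_calls: GeneCallTable,
    params: CallParams | None = None,
    numerator: str = "A",
    denominator: str = "B",
    stage: str = "",
    combine: str = "mean",
) -> DifferentialResult:
    """Call genes with significantly higher occupancy in the numerator.

    Replicate difference profiles are averaged fragment-wise (``combine=
    'mean'``) into one profile which then goes through transcript scoring,
    permutation FDR and per-gene reduction.  ``combine='intersect'`` calls
    each replicate separately and keeps genes significant in all.
    """
    if not diff_reps:
        raise ValueError("empty replicate list")
    params = params or CallParams()
    bound = numerator_calls.bound_genes

    def _one(profile: FragmentProfile) -> pd.DataFrame:
        t = permutation_fdr(profile, annotation, params)
        return call_genes(t, params).genes

    if combine == "mean":
        mean_vals = np.mean([p.values for p in diff_reps], axis=0)
        mean_profile = FragmentProfile(
            meta=diff_reps[0].meta, unit="log2_ratio", values=mean_vals, map=diff_reps[0].map
        )
        genes = _one(mean_profile)
        genes = genes.rename(columns={"bound": "significant"})
    elif combine == "intersect":
        per_rep = [_one(p) for p in diff_reps]
        genes = per_rep[0].rename(columns={"bound": "significant"})
        sig_all = set(genes.loc[genes["significant"], "gene_id"])
        for g in per_rep[1:]:
            sig_all &= set(g.loc[g["bound"], "gene_id"])
        genes["significant"] = genes["gene_id"].isin(sig_all)
    else:
        raise ValueError(f"unknown combine mode {combine!r}")

    genes["bound_in_numerator"] = genes["gene_id"].isin(bound)
    genes["enriched"] = genes["significant"] & genes["bound_in_numerator"]
    return DifferentialResult(
        numerator=numerator, denominator=denominator, stage=stage, table=genes
    )


def unique_sets(
    pairwise: dict[tuple[str, str], DifferentialResult],
    bound_tables: dict[str, GeneCallTable],
    stage: str = "",
) -> UniqueSets:
    """Uniquely enriched / depleted genes per cell type.

    ``pairwise`` must hold all 6 ordered comparisons among the 3 types.
    uniquely_enriched(X) = enriched(X vs Y) & enriched(X vs Z);
    uniquely_depleted(X) = enriched(Y vs X) & enriched(Z vs X), with the
    gene additionally bound in both Y and Z.
    """
    types = sorted({t for pair in pairwise for t in pair})
    if len(types) != 3:
        raise ValueError(f"expected 3 cell types, got {types}")
    for x in types:
        for y in types:
            if x != y and (x, y) not in pairwise:
                raise ValueError(f"missing comparison {x} vs {y}")
    out = UniqueSets(stage=stage)
    for x in types:
        y, z = [t for t in types if t != x]
        out.enriched[x] = (
            pairwise[(x, y)].enriched_genes & pairwise[(x, z)].enriched_genes
        )
        depleted = pairwise[(y, x)].enriched_genes & pairwise[(z, x)].enriched_genes
        depleted &= bound_tables[y].bound_genes & bound_tables[z].bound_genes
        out.depleted[x] = depleted
    return out


def filter_gene_class(
    genes: list[str] | set[str], class_map: dict[str, str], gene_class: str = "TF"
) -> list[str]:
    """Subset genes to one class (e.g. TF, lncRNA, miRNA), preserving input
    order; genes missing from the map count as class 'other'."""
    ordered = list(genes) if not isinstance(genes, set) else sorted(genes)
    return [g for g in ordered if class_map.get(g, "other") == gene_class]


def read_class_map(path: str | Path) -> dict[str, str]:
    """Load a gene -> class map from a two-column TSV (gene_id, class).
    One-column files assign every listed gene the class 'TF'."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "gene_id":
                continue
            out[cols[0]] = cols[1] if len(cols) > 1 else "TF"
    return out


def _state(sets: UniqueSets, gene: str) -> str:
    for x, s in sets.enriched.items():
        if gene in s:
            return f"enriched:{x}"
    for x, s in sets.depleted.items():
        if gene in s:
            return f"depleted:{x}"
    return "none"


def transition_table(per_stage: list[UniqueSets]) -> pd.DataFrame:
    """Track every gene ever appearing in a unique set through all stages
    and count state transitions between consecutive stages.

    Returns a long-format table (gene_id, stage_from, stage_to, state_from,
    state_to); per consecutive stage pair, rows sum to the tracked-gene
    count.
    """
    if len(per_stage) < 2:
        raise ValueError("need at least 2 stages for transitions")
    tracked = sorted(
        {
            g
            for us in per_stage
            for sets in (us.enriched, us.depleted)
            for s in sets.values()
            for g in s
        }
    )
    rows = []
    for us_from, us_to in zip(per_stage, per_stage[1:]):
        for g in tracked:
            rows.append(
                {
                    "gene_id": g,
                    "stage_from": us_from.stage,
                    "stage_to": us_to.stage,
                    "state_from": _state(us_from, g),
                    "state_to": _state(us_to, g),
                }
            )
    return pd.DataFrame(rows)


def transition_counts(long_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the long-format transition table into per-stage-pair
    state->state counts."""
    return (
        long_table.groupby(
            ["stage_from", "stage_to", "state_from", "state_to"], sort=True
        )
        .size()
        .reset_index(name="count")
    )
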