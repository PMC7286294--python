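"""End-to-end synthetic experiments and truth-table scoring.

Shared by the acceptance tests and the acceptance report: each function
runs a seeded simulation through the analysis pipeline and measures the
result against the planted truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import peaks as peaks_mod
from .differential import comparison_seed, differential_genes, subtract_profiles, unique_sets
from .gatc import build_fragment_map
from .genecalls import CallParams, call_polii_genes
from .profiles import log2_ratio, rpm_normalize
from .simulate import (
    SimulationConfig,
    simulate_damid_experiment,
    simulate_genome_annotation,
    simulate_tf_binding,
)


def mean_log2_profile(reps):
    """Fragment-wise mean of replicate log2-ratio profiles."""
    vals = np.mean([r.values for r in reps], axis=0)
    return dataclasses.replace(reps[0], values=vals)


def run_unique_sets_experiment(config: SimulationConfig, params: CallParams | None = None):
    """Simulate one stage of the three-type design and run it through
    gene calling, all six pairwise comparisons and unique-set
    classification.  Returns (unique_sets, truth, per-type calls)."""
    seed = config.master_seed
    rng = np.random.default_rng(seed)
    seqs, annotation, truth = simulate_genome_annotation(config, rng)
    fmap = build_fragment_map(seqs)
    profiles = simulate_damid_experiment(config, fmap, annotation, truth, rng)
    stage = config.stages[0]
    types = config.cell_types
    base = params or CallParams()

    ratios, mean_ratio = {}, {}
    for ct in types:
        reps = []
        for r in range(1, config.replicates + 1):
            lr = log2_ratio(
                rpm_normalize(profiles[(stage, ct, "dam_fusion", r)]),
                rpm_normalize(profiles[(stage, ct, "dam_only", r)]),
            )
            ratios[(ct, r)] = lr
            reps.append(lr)
        mean_ratio[ct] = mean_log2_profile(reps)

    calls = {
        ct: call_polii_genes(
            mean_ratio[ct],
            annotation,
            dataclasses.replace(base, seed=comparison_seed(seed, stage, ct, "polii")),
        )
        for ct in types
    }
    pairwise = {}
    for x in types:
        for y in types:
            if x == y:
                continue
            diffs = subtract_profiles(
                [ratios[(x, r)] for r in range(1, config.replicates + 1)],
                [ratios[(y, r)] for r in range(1, config.replicates + 1)],
            )
            pairwise[(x, y)] = differential_genes(
                diffs,
                annotation,
                calls[x],
                dataclasses.replace(base, seed=comparison_seed(seed, stage, x, y)),
                numerator=x,
                denominator=y,
                stage=stage,
            )
    us = unique_sets(pairwise, calls, stage=stage)
    return us, truth, calls


def self_comparison_enriched(config: SimulationConfig) -> int:
    """Number of genes called enriched when a cell type is compared with
    itself (expected: 0)."""
    seed = config.master_seed
    rng = np.random.default_rng(seed)
    seqs, annotation, truth = simulate_genome_annotation(config, rng)
    fmap = build_fragment_map(seqs)
    profiles = simulate_damid_experiment(config, fmap, annotation, truth, rng)
    stage, ct = config.stages[0], config.cell_types[0]
    reps = [
        log2_ratio(
            rpm_normalize(profiles[(stage, ct, "dam_fusion", r)]),
            rpm_normalize(profiles[(stage, ct, "dam_only", r)]),
        )
        for r in range(1, config.replicates + 1)
    ]
    calls = call_polii_genes(
        mean_log2_profile(reps), annotation,
        CallParams(seed=comparison_seed(seed, stage, ct, "polii")),
    )
    res = differential_genes(
        subtract_profiles(reps, reps), annotation, calls,
        CallParams(seed=comparison_seed(seed, stage, ct, ct)),
        numerator=ct, denominator=ct, stage=stage,
    )
    return len(res.enriched_genes)


def unique_set_metrics(us, truth, config: SimulationConfig) -> dict:
    """Pooled sensitivity/precision of predicted unique sets vs truth."""
    stage = config.stages[0]
    tp = fp = fn = 0
    for ct in config.cell_types:
        te = truth.unique_enriched.get((stage, ct), set())
        td = truth.unique_depleted.get((stage, ct), set())
        pe, pd_ = us.enriched[ct], us.depleted[ct]
        tp += len(te & pe) + len(td & pd_)
        fp += len(pe - te) + len(pd_ - td)
        fn += len(te - pe) + len(td - pd_)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
    }


def run_peak_experiment(
    config: SimulationConfig,
    shuffles: int = 1000,
    fdr: float = peaks_mod.SIGNIFICANCE_FDR,
    theta: float = 1.0,
    statistic: str = "sum",
):
    """Simulate TF-binding replicates with planted peaks, call significant
    peaks per replicate, and build the all-replicate consensus.

    Returns (consensus, truth, fragment_map).
    """
    seed = config.master_seed
    rng = np.random.default_rng(seed)
    seqs, annotation, truth = simulate_genome_annotation(config, rng)
    fmap = build_fragment_map(seqs)
    profiles = simulate_tf_binding(config, fmap, annotation, truth, rng)
    sig_by_rep = []
    for rep in range(1, config.peak_replicates + 1):
        ratio = log2_ratio(
            rpm_normalize(profiles[("dam_fusion", rep)]),
            rpm_normalize(profiles[("dam_only", rep)]),
        )
        sig = peaks_mod.call_peaks(
            ratio, theta=theta, statistic=statistic, shuffles=shuffles,
            seed=comparison_seed(seed, "peaks", "rep", str(rep)), fdr=fdr,
        )
        sig_by_rep.append(sig)
    return peaks_mod.replicate_consensus(sig_by_rep), truth, fmap


def peak_recall(consensus, truth) -> float:
    """Fraction of planted peaks overlapped by >= 1 consensus interval."""
    if not truth.peaks:
        return float("nan")
    hits = sum(
        1
        for p in truth.peaks
        if any(c.chrom == p["chrom"] and c.start < p["end"] and c.end > p["start"]
               for c in consensus)
    )
    return hits / len(truth.peaks)


def consensus_all_overlap_truth(consensus, truth) -> bool:
    """Every consensus interval overlaps some planted peak."""
    return all(
        any(c.chrom == p["chrom"] and c.start < p["end"] and c.end > p["start"]
            for p in truth.peaks)
        for c in consensus
    )
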