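"""Configuration and end-to-end orchestration.

A pipeline run is driven by a YAML config plus one master seed and writes
every artefact (tables, BED/bedGraph, truth, resolved config, log) into a
run directory.  Outputs are byte-deterministic given (config, seed): the
log carries input hashes and row counts but no timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catada as catada_mod
from . import peaks as peaks_mod
from . import reporting, scrna, simulate
from .differential import (
    comparison_seed,
    differential_genes,
    subtract_profiles,
    transition_counts,
    transition_table,
    unique_sets,
)
from .gatc import write_annotation
from .genecalls import CallParams, call_polii_genes
from .profiles import log2_ratio, rpm_normalize, write_bedgraph

DEFAULT_PARAMS = {
    "pseudocount": 10.0,
    "fdr_threshold": 0.01,
    "min_score": 0.2,
    "permutations": 100,
    "peak_shuffles": 300,
    "peak_fdr": 1e-4,
    # run-length-rewarding statistic and a positive entry threshold give
    # the best separation of planted peaks from shuffle nulls
    "theta": 1.0,
    "peak_statistic": "sum",
    "delta": 10.0,
    "min_run": 3,
    "window": 5000,
    "up": 5000,
    "down": 2000,
}

# The 10-RPM accessibility threshold presumes real-data fragment density
# (~200k fragments, mean RPM ~5); at demo scale (~1.6k fragments, mean RPM
# ~600) the equivalent robust-change cut is proportionally larger.
DEMO_CONFIG = {
    "seed": 0,
    "params": {**DEFAULT_PARAMS, "delta": 400.0},
    "simulate": {
        "chrom_length": 320_000,
        "n_genes": 60,
        "stages": ["larva", "adult"],
        "replicates": 3,
        "reads_per_sample": 100_000,
        "n_unique_enriched": 6,
        "n_unique_depleted": 3,
        "n_peaks": 10,
        "peak_reads_per_sample": 150_000,
        "scrna_genes": 60,
        "cells_per_type": 100,
        "n_planted_tfs": 4,
        "subpop_size": 20,
    },
}


class PipelineConfig:
    """Validated pipeline configuration (parameters + either a simulation
    block or paths to real inputs)."""

    def __init__(self, raw: dict, base_dir: Path | None = None):
        self.raw = raw
        self.seed = int(raw.get("seed", 0))
        self.params = dict(DEFAULT_PARAMS)
        self.params.update(raw.get("params", {}))
        if not 0 < self.params["fdr_threshold"] < 1:
            raise ValueError("fdr_threshold out of range")
        if self.params["pseudocount"] <= 0:
            raise ValueError("pseudocount must be > 0")
        self.simulate = raw.get("simulate")
        self.paths = raw.get("paths")
        if self.simulate is None and self.paths is None:
            raise ValueError("config needs either a 'simulate' or a 'paths' section")
        if self.paths is not None:
            base = base_dir or Path(".")
            for key, p in self.paths.items():
                full = (base / p).resolve()
                if not full.exists():
                    raise ValueError(f"configured path {key!r} does not exist: {full}")
                self.paths[key] = str(full)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(raw, base_dir=path.parent)

    def sim_config(self) -> simulate.SimulationConfig:
        kwargs = dict(self.simulate or {})
        for key in ("gene_length_range", "peak_len_range", "stages", "cell_types"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return dataclasses.replace(
            simulate.SimulationConfig(master_seed=self.seed), **kwargs
        )

    def digest(self) -> str:
        blob = json.dumps({"seed": self.seed, "params": self.params, "simulate": self.simulate},
                          sort_keys=True).encode()
        return hashlib.md5(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def _log(lines: list[str], stage: str, detail: str) -> None:
    lines.append(f"{stage}\t{detail}")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute all stages in dependency order; returns the run directory.

    fragment map -> profiles -> gene calls -> differential -> unique sets
    -> transitions; TF peaks; accessibility; scRNA overlap; reports.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config_digest\t{config.digest()}", f"master_seed\t{config.seed}"]
    p = config.params

    if config.simulate is None:
        raise NotImplementedError(
            "path-based runs are wired per subcommand via the CLI; "
            "`run` expects a simulate block"
        )
    sim = simulate.simulate_all(config.sim_config())
    inputs = out / "inputs"
    inputs.mkdir(exist_ok=True)
    simulate.write_fasta(sim["sequences"], inputs / "genome.fa")
    write_annotation(sim["annotation"], inputs / "annotation.gff3")
    simulate.write_truth(sim["truth"], inputs / "truth")
    for path in sorted(inputs.rglob("*")):
        if path.is_file():
            _log(log, "input", f"{path.relative_to(out)}\tmd5={hashlib.md5(path.read_bytes()).hexdigest()}")

    fmap = sim["fragment_map"]
    annotation = sim["annotation"]
    fmap.to_bed(out / "fragments.bed")
    _log(log, "fragment_map", f"n_fragments={fmap.n_fragments}")

    sim_cfg = config.sim_config()
    stages, types, n_reps = sim_cfg.stages, sim_cfg.cell_types, sim_cfg.replicates
    damid = sim["damid_profiles"]

    # per-sample log2 ratios; per (stage, type) replicate-mean profile
    ratios: dict[tuple[str, str, int], object] = {}
    mean_ratio: dict[tuple[str, str], object] = {}
    for stage in stages:
        for ct in types:
            reps = []
            for rep in range(1, n_reps + 1):
                fus = rpm_normalize(damid[(stage, ct, "dam_fusion", rep)])
                dam = rpm_normalize(damid[(stage, ct, "dam_only", rep)])
                r = log2_ratio(fus, dam, p["pseudocount"])
                ratios[(stage, ct, rep)] = r
                reps.append(r)
            mean_vals = np.mean([r.values for r in reps], axis=0)
            mp = dataclasses.replace(reps[0], values=mean_vals)
            mean_ratio[(stage, ct)] = mp
            write_bedgraph(mp, out / f"polii_{ct}_{stage}.log2.bedgraph")
    _log(log, "profiles", f"n_samples={len(ratios)}")

    # gene calls per (stage, type)
    calls = {}
    for stage in stages:
        for ct in types:
            params = CallParams(
                fdr_threshold=p["fdr_threshold"],
                min_score=p["min_score"],
                permutations=p["permutations"],
                seed=comparison_seed(config.seed, stage, ct, "polii"),
            )
            gct = call_polii_genes(mean_ratio[(stage, ct)], annotation, params)
            calls[(stage, ct)] = gct
            n = _write_tsv(gct.genes, out / f"genes_{ct}_{stage}.tsv")
            _log(log, "gene_calls", f"{ct}/{stage}\trows={n}\tbound={len(gct.bound_genes)}")

    # differential + unique sets per stage
    per_stage_unique = []
    for stage in stages:
        pairwise = {}
        for x in types:
            for y in types:
                if x == y:
                    continue
                diffs = subtract_profiles(
                    [ratios[(stage, x, r)] for r in range(1, n_reps + 1)],
                    [ratios[(stage, y, r)] for r in range(1, n_reps + 1)],
                )
                params = CallParams(
                    fdr_threshold=p["fdr_threshold"],
                    min_score=p["min_score"],
                    permutations=p["permutations"],
                    seed=comparison_seed(config.seed, stage, x, y),
                )
                res = differential_genes(
                    diffs, annotation, calls[(stage, x)], params,
                    numerator=x, denominator=y, stage=stage,
                )
                pairwise[(x, y)] = res
                n = _write_tsv(res.table, out / f"diff_{x}_vs_{y}_{stage}.tsv")
                _log(log, "differential", f"{x}_vs_{y}/{stage}\trows={n}\tenriched={len(res.enriched_genes)}")
        us = unique_sets(pairwise, {t: calls[(stage, t)] for t in types}, stage=stage)
        per_stage_unique.append(us)
        rows = []
        for ct in types:
            for g in sorted(us.enriched[ct]):
                rows.append({"stage": stage, "cell_type": ct, "category": "uniquely_enriched", "gene_id": g})
            for g in sorted(us.depleted[ct]):
                rows.append({"stage": stage, "cell_type": ct, "category": "uniquely_depleted", "gene_id": g})
        _write_tsv(pd.DataFrame(rows, columns=["stage", "cell_type", "category", "gene_id"]),
                   out / f"unique_sets_{stage}.tsv")
        _log(log, "unique_sets", f"{stage}\trows={len(rows)}")

    if len(stages) >= 2:
        tt = transition_table(per_stage_unique)
        _write_tsv(tt, out / "transitions_long.tsv")
        _write_tsv(transition_counts(tt), out / "transitions_counts.tsv")
        _log(log, "transitions", f"tracked={tt['gene_id'].nunique()}")

    # TF binding peaks (2 replicates by default)
    binding = sim["binding_profiles"]
    sig_by_rep = []
    for rep in range(1, sim_cfg.peak_replicates + 1):
        fus = rpm_normalize(binding[("dam_fusion", rep)])
        dam = rpm_normalize(binding[("dam_only", rep)])
        ratio = log2_ratio(fus, dam, p["pseudocount"])
        sig = peaks_mod.call_peaks(
            ratio,
            theta=p["theta"],
            statistic=p["peak_statistic"],
            shuffles=p["peak_shuffles"],
            seed=comparison_seed(config.seed, "peaks", "rep", str(rep)),
            fdr=p["peak_fdr"],
        )
        peaks_mod.peaks_to_bed(sig, out / f"peaks_rep{rep}.bed", prefix=f"r{rep}")
        sig_by_rep.append(sig)
        _log(log, "peaks", f"rep{rep}\tsignificant={len(sig)}")
    consensus = peaks_mod.replicate_consensus(sig_by_rep)
    consensus = peaks_mod.assign_genes(consensus, annotation, window=p["window"])
    cons_df, genes_df = peaks_mod.consensus_to_tables(consensus)
    _write_tsv(cons_df, out / "peaks_consensus.tsv")
    _write_tsv(genes_df, out / "peaks_genes.tsv")
    _log(log, "peaks_consensus", f"n={len(cons_df)}\tassignments={len(genes_df)}")

    # chromatin accessibility from Dam-only channels
    access = {}
    for stage in stages:
        for ct in types:
            prof = catada_mod.accessibility_profile(
                [damid[(stage, ct, "dam_only", r)] for r in range(1, n_reps + 1)]
            )
            access[(stage, ct)] = prof
            write_bedgraph(prof, out / f"accessibility_{ct}_{stage}.bedgraph")
    locus = catada_mod.locus_accessibility(
        access[(stages[0], types[0])], annotation, up=p["up"], down=p["down"]
    )
    _write_tsv(locus, out / "locus_accessibility.tsv")
    regions, summary = catada_mod.robust_diff_regions(
        access[(stages[0], types[0])], access[(stages[0], types[1])],
        delta=p["delta"], min_run=p["min_run"],
    )
    catada_mod.regions_to_bed(regions, out / "accessibility_diff_regions.bed")
    _log(log, "catada", f"regions={summary['n_regions']}\tfragments={summary['n_fragments']}")

    # scRNA-seq overlap on planted TFs
    simulate.write_mtx(sim["scrna_matrix"], inputs / "scrna.mtx")
    simulate.write_gene_index(sim["scrna_gene_ids"], inputs / "scrna_genes.tsv")
    simulate.write_cell_annotation(sim["cell_types"], inputs / "scrna_cells.tsv")
    expr = scrna.read_expression(inputs / "scrna.mtx", inputs / "scrna_genes.tsv")
    planted_tfs = sorted(sim["truth"].subpop_members)
    if len(planted_tfs) >= 2:
        counts, jac = scrna.overlap_matrix(
            expr, planted_tfs, sim["cell_types"], restrict_to_type=types[0]
        )
        counts.to_csv(out / "scrna_overlap_counts.tsv", sep="\t")
        jac.to_csv(out / "scrna_overlap_jaccard.tsv", sep="\t")
        _write_tsv(scrna.overlap_long(counts), out / "scrna_overlap_long.tsv")
        means_rows = []
        for tf in planted_tfs:
            try:
                means = scrna.type_normalized_means(expr, tf, sim["cell_types"], reference_type=types[0])
            except ValueError:
                continue
            for t, v in means.items():
                means_rows.append({"gene_id": tf, "cell_type": t, "normalized_mean": v})
        _write_tsv(pd.DataFrame(means_rows), out / "scrna_normalized_means.tsv")
        _log(log, "scrna", f"genes={len(planted_tfs)}")

    # correlation matrix of gene Pol II scores across samples
    score_cols = {}
    for (stage, ct), gct in calls.items():
        score_cols[f"{ct}_{stage}"] = gct.genes.set_index("gene_id")["score"]
    score_matrix = pd.DataFrame(score_cols).dropna()
    corr = reporting.correlation_matrix(score_matrix)
    corr.to_csv(out / "correlation_polii.tsv", sep="\t", na_rep="NA")
    _log(log, "correlation", f"samples={corr.shape[0]}")

    # gene-class composition of unique sets (class map: simulated TF list)
    class_map = _simulated_class_map(annotation, config.seed)
    with open(out / "gene_classes.tsv", "w") as fh:
        fh.write("gene_id\tclass\n")
        for g in sorted(class_map):
            fh.write(f"{g}\t{class_map[g]}\n")
    sets = {}
    for us in per_stage_unique:
        for ct in types:
            sets[f"{us.stage}:{ct}:enriched"] = us.enriched[ct]
            sets[f"{us.stage}:{ct}:depleted"] = us.depleted[ct]
    comp = reporting.class_composition(sets, class_map)
    comp.to_csv(out / "class_composition.tsv", sep="\t", index=False, na_rep="NA")
    _log(log, "class_composition", f"sets={len(comp)}")

    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(
            {"seed": config.seed, "params": config.params, "simulate": config.simulate},
            fh, sort_keys=True,
        )
    (out / "run.log").write_text("\n".join(log) + "\n")
    return out


def _simulated_class_map(annotation, seed: int) -> dict[str, str]:
    """Deterministic stand-in gene-class assignment (TF / ncRNA / other)."""
    rng = np.random.default_rng(seed + 97)
    out = {}
    for g in sorted(annotation.genes):
        u = rng.random()
        out[g] = "TF" if u < 0.3 else ("ncRNA" if u < 0.4 else "other")
    return out


def write_demo_config(path: str | Path, seed: int = 0) -> None:
    cfg = dict(DEMO_CONFIG)
    cfg["seed"] = seed
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
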