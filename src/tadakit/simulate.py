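"""Seeded synthetic data with the statistical structure the analysis assumes.

Generates a genome whose GATC motifs sit at exponential spacings, a
non-overlapping gene annotation, negative-binomial fragment counts for
Dam-only / Dam-fusion channels with planted cell-type-specific expressed
genes, planted multi-fragment binding peaks, and a sparse cell x gene
count matrix with planted TF-expressing subpopulations — together with
truth tables for parameter-recovery testing.

Background sequence is drawn from {A, C, T} only, so GATC motifs occur
exactly where planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .gatc import AnnotationSet, GatcFragmentMap, GeneModel, build_fragment_map
from .profiles import FragmentProfile, SampleMeta

_BACKGROUND = np.frombuffer(b"ACT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    # genome
    n_chroms: int = 1
    chrom_length: int = 1_000_000
    mean_gatc_spacing: int = 80
    min_gatc_spacing: int = 50  # exponential gap clip; must stay >= 8
    # annotation
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (3_500, 5_500)
    min_intergenic_gap: int = 100
    # experiment design
    cell_types: tuple[str, ...] = ("cholinergic", "GABAergic", "glutamatergic")
    stages: tuple[str, ...] = ("larva",)
    replicates: int = 3
    reads_per_sample: int = 100_000
    nb_dispersion: float = 0.2
    # effects
    baseline_sigma: float = 0.3  # log-normal sigma of per-bp accessibility
    effect_log2: float = 1.0  # beta: log2 fusion enrichment over expressed bases
    background_expressed_frac: float = 0.15
    n_unique_enriched: int = 20
    n_unique_depleted: int = 10
    # TF binding peaks
    n_peaks: int = 15
    peak_len_range: tuple[int, int] = (3, 5)
    peak_effect_log2: float = 2.0
    peak_replicates: int = 2
    # TF-binding libraries are deep and well-behaved relative to the
    # Pol II channel: fragment-level log2 noise ~0.3-0.4 sd per replicate
    peak_reads_per_sample: int = 400_000
    peak_nb_dispersion: float = 0.02
    # scRNA-seq
    scrna_genes: int = 100
    cells_per_type: int = 300
    capture_mean: float = 0.5
    n_planted_tfs: int = 5
    subpop_size: int = 40
    subpop_overlap: int = 0
    # seed
    master_seed: int = 0

    def __post_init__(self):
        if self.mean_gatc_spacing < 8:
            raise ValueError("mean GATC spacing must be >= 8 bp")
        if self.min_gatc_spacing < 8:
            raise ValueError("min GATC spacing must be >= 8 bp")
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 must be >= 0")
        for name in ("n_chroms", "chrom_length", "n_genes", "replicates", "reads_per_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthTables:
    expressed: dict[tuple[str, str], set[str]] = field(default_factory=dict)  # (stage, type)
    unique_enriched: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    unique_depleted: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    peaks: list[dict] = field(default_factory=list)  # chrom, start, end, fragments, target_gene
    subpop_members: dict[str, set[int]] = field(default_factory=dict)  # tf gene -> cell indices
    warnings: list[str] = field(default_factory=list)


def _exponential_scale(target_gap: float, clip: float) -> float:
    """Scale m of a clipped exponential max(clip, Exp(m)) whose mean is
    ``target_gap``: solves clip + m*exp(-clip/m) = target_gap."""
    if target_gap <= clip:
        return 1e-9  # clip dominates; every gap equals the clip
    lo, hi = 1e-6, 10.0 * target_gap
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if clip + mid * np.exp(-clip / mid) < target_gap:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _simulate_chromosome(
    length: int, mean_spacing: int, rng: np.random.Generator, min_spacing: int = 60
) -> str:
    seq = rng.choice(_BACKGROUND, size=length).copy()
    pos = 0
    motif = np.frombuffer(b"GATC", dtype="S1")
    # motif occupies 4 bp, so gaps target mean_spacing - 4 between motifs
    scale = _exponential_scale(mean_spacing - 4, min_spacing)
    while True:
        gap = max(min_spacing, int(round(rng.exponential(scale))))
        pos += gap
        if pos + 4 > length:
            break
        seq[pos : pos + 4] = motif
        pos += 4
    return seq.tobytes().decode("ascii")


def simulate_genome_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], AnnotationSet, TruthTables]:
    """Random genome + non-overlapping gene annotation + empty truth."""
    rng = rng or np.random.default_rng(config.master_seed)
    sequences = {
        f"chr{c + 1}": _simulate_chromosome(
            config.chrom_length, config.mean_gatc_spacing, rng, config.min_gatc_spacing
        )
        for c in range(config.n_chroms)
    }
    # distribute genes over chromosomes round-robin, place left to right
    per_chrom = {c: 0 for c in sequences}
    chrom_names = list(sequences)
    for i in range(config.n_genes):
        per_chrom[chrom_names[i % len(chrom_names)]] += 1
    genes = []
    gnum = 0
    lo_len, hi_len = config.gene_length_range
    for chrom, n_here in per_chrom.items():
        if n_here == 0:
            continue
        length = len(sequences[chrom])
        lens = rng.integers(lo_len, hi_len + 1, size=n_here)
        needed = int(lens.sum()) + config.min_intergenic_gap * (n_here + 1)
        if needed > length:
            raise ValueError(
                f"cannot fit {n_here} genes in {chrom} ({needed} bp needed, "
                f"{length} available); use a longer genome"
            )
        slack = length - needed
        extra = rng.multinomial(slack, np.ones(n_here + 1) / (n_here + 1))
        pos = 0
        for k in range(n_here):
            pos += config.min_intergenic_gap + int(extra[k])
            start, end = pos, pos + int(lens[k])
            gnum += 1
            gid = f"gene{gnum:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_tx = int(rng.integers(1, 4))
            transcripts = [(f"{gid}.t1", start, end)]
            for t in range(2, n_tx + 1):
                span = end - start
                ts = start + int(rng.integers(0, max(span // 4, 1)))
                te = end - int(rng.integers(0, max(span // 4, 1)))
                if te <= ts:
                    ts, te = start, end
                transcripts.append((f"{gid}.t{t}", ts, te))
            genes.append(GeneModel(gid, chrom, strand, start, end, transcripts))
            pos = end
    return sequences, AnnotationSet(genes), TruthTables()


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial via gamma-Poisson; dispersion -> 0 gives Poisson."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _coverage_fraction(
    fragment_map: GatcFragmentMap,
    annotation: AnnotationSet,
    genes: set[str],
) -> np.ndarray:
    """Fraction of each fragment covered by the union of the given gene spans."""
    frac = np.zeros(fragment_map.n_fragments)
    for chrom in fragment_map.chroms:
        length = fragment_map.chrom_length(chrom)
        covered = np.zeros(length, dtype=bool)
        for g in annotation.chrom_genes(chrom):
            if g.gene_id in genes:
                covered[g.start : g.end] = True
        cum = np.concatenate(([0], np.cumsum(covered)))
        sl = fragment_map.chrom_slice(chrom)
        s = fragment_map.starts[sl]
        e = fragment_map.ends[sl]
        frac[sl] = (cum[e] - cum[s]) / (e - s)
    return frac


def _plant_expression_sets(
    config: SimulationConfig,
    annotation: AnnotationSet,
    truth: TruthTables,
    rng: np.random.Generator,
) -> None:
    all_genes = sorted(annotation.genes)
    types = config.cell_types
    for stage in config.stages:
        perm = [all_genes[i] for i in rng.permutation(len(all_genes))]
        cursor = 0
        uniq_e, uniq_d = {}, {}
        for t in types:
            uniq_e[t] = set(perm[cursor : cursor + config.n_unique_enriched])
            cursor += config.n_unique_enriched
        for t in types:
            uniq_d[t] = set(perm[cursor : cursor + config.n_unique_depleted])
            cursor += config.n_unique_depleted
        remaining = perm[cursor:]
        n_bg = int(round(config.background_expressed_frac * len(all_genes)))
        background = set(remaining[:n_bg])
        if config.effect_log2 == 0 and (config.n_unique_enriched or config.n_unique_depleted):
            truth.warnings.append(
                f"stage {stage}: effect_log2=0 with planted unique genes — no recoverable signal"
            )
        for t in types:
            expressed = set(background) | uniq_e[t]
            for other in types:
                if other != t:
                    expressed |= uniq_d[other]  # depleted-in-other genes expressed here
            truth.expressed[(stage, t)] = expressed
            truth.unique_enriched[(stage, t)] = uniq_e[t]
            truth.unique_depleted[(stage, t)] = uniq_d[t]


def simulate_damid_experiment(
    config: SimulationConfig,
    fragment_map: GatcFragmentMap,
    annotation: AnnotationSet,
    truth: TruthTables,
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, str, str, int], FragmentProfile]:
    """NB fragment counts for every (stage, type, channel, replicate).

    Dam-only weight is the shared baseline accessibility a_f; the fusion
    weight multiplies it by 2^(beta * x_f) where x_f is the fraction of
    the fragment covered by genes expressed in that type/stage.
    """
    rng = rng or np.random.default_rng(config.master_seed + 1)
    if not truth.expressed:
        _plant_expression_sets(config, annotation, truth, rng)
    profiles = {}
    frag_len = fragment_map.lengths.astype(float)
    for stage in config.stages:
        # per-bp accessibility is lognormal; expected reads scale with
        # fragment length so length-weighted scoring downweights the
        # noisiest (shortest) fragments
        baseline = frag_len * rng.lognormal(
            mean=0.0, sigma=config.baseline_sigma, size=fragment_map.n_fragments
        )
        for cell_type in config.cell_types:
            xf = _coverage_fraction(fragment_map, annotation, truth.expressed[(stage, cell_type)])
            w_fusion = baseline * np.exp2(config.effect_log2 * xf)
            for channel, weights in (("dam_only", baseline), ("dam_fusion", w_fusion)):
                mean = config.reads_per_sample * weights / weights.sum()
                for rep in range(1, config.replicates + 1):
                    counts = _nb_counts(mean, config.nb_dispersion, rng)
                    meta = SampleMeta(
                        sample_id=f"{cell_type}_{stage}_{channel}_r{rep}",
                        cell_type=cell_type,
                        stage=stage,
                        replicate=rep,
                        channel=channel,
                        fusion_name="PolII" if channel == "dam_fusion" else "",
                    )
                    profiles[(stage, cell_type, channel, rep)] = FragmentProfile(
                        meta=meta, unit="count", values=counts.astype(float), map=fragment_map
                    )
    return profiles


def simulate_tf_binding(
    config: SimulationConfig,
    fragment_map: GatcFragmentMap,
    annotation: AnnotationSet,
    truth: TruthTables,
    rng: np.random.Generator | None = None,
    fusion_name: str = "TF",
) -> dict[tuple[str, int], FragmentProfile]:
    """Fusion + Dam-only replicate counts with planted multi-fragment peaks.

    Each peak is a run of consecutive fragments (length drawn from
    ``peak_len_range``) near a distinct target gene, with the fusion
    weight multiplied by 2^peak_effect_log2.
    """
    rng = rng or np.random.default_rng(config.master_seed + 2)
    lo_k, hi_k = config.peak_len_range
    if lo_k < 2:
        raise ValueError("planted peaks need at least 2 fragments")
    genes = sorted(annotation.genes)
    target_order = [genes[i] for i in rng.permutation(len(genes))]
    used = np.zeros(fragment_map.n_fragments, dtype=bool)
    planted: list[tuple[int, int]] = []
    for gid in target_order:
        if len(planted) >= config.n_peaks:
            break
        g = annotation[gid]
        k = int(rng.integers(lo_k, hi_k + 1))
        # place the run just upstream of the gene start, within 5 kb
        window_lo = max(g.start - 4000, 0)
        if window_lo >= g.start:
            continue
        idx = fragment_map.fragments_overlapping(g.chrom, window_lo, g.start)
        if idx.size < k + 2:
            continue
        run = idx[1 : 1 + k]  # skip one edge fragment for separation
        guard_lo = max(int(run[0]) - 1, 0)
        guard_hi = min(int(run[-1]) + 2, fragment_map.n_fragments)
        if used[guard_lo:guard_hi].any():
            continue
        used[guard_lo:guard_hi] = True
        planted.append((int(run[0]), int(run[-1]) + 1))
        truth.peaks.append(
            {
                "chrom": g.chrom,
                "start": int(fragment_map.starts[run[0]]),
                "end": int(fragment_map.ends[run[-1]]),
                "first_fragment": int(run[0]),
                "n_fragments": k,
                "target_gene": gid,
            }
        )
    if len(planted) < config.n_peaks:
        raise ValueError(
            f"could only place {len(planted)} of {config.n_peaks} requested peaks; "
            "increase genome size or fragment density"
        )
    baseline = fragment_map.lengths * rng.lognormal(
        0.0, config.baseline_sigma, size=fragment_map.n_fragments
    )
    w_fusion = baseline.copy()
    for lo, hi in planted:
        w_fusion[lo:hi] *= 2.0**config.peak_effect_log2
    profiles = {}
    for channel, weights in (("dam_only", baseline), ("dam_fusion", w_fusion)):
        mean = config.peak_reads_per_sample * weights / weights.sum()
        for rep in range(1, config.peak_replicates + 1):
            counts = _nb_counts(mean, config.peak_nb_dispersion, rng)
            meta = SampleMeta(
                sample_id=f"{fusion_name}_{channel}_r{rep}",
                cell_type=fusion_name,
                stage="adult",
                replicate=rep,
                channel=channel,
                fusion_name=fusion_name if channel == "dam_fusion" else "",
            )
            profiles[(channel, rep)] = FragmentProfile(
                meta=meta, unit="count", values=counts.astype(float), map=fragment_map
            )
    return profiles


def simulate_scrnaseq(
    config: SimulationConfig,
    truth: TruthTables,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[str], dict[int, str]]:
    """Dense count matrix (genes x cells), gene ids and 1-based cell
    annotation, with planted TFs expressed only in their cholinergic
    subpopulations.

    Planted subpopulation means are >= 4x the capture mean so the
    count >= 3 filter recovers the membership; outside the subpopulation
    the planted TFs are nearly silent.
    """
    rng = rng or np.random.default_rng(config.master_seed + 3)
    types = list(config.cell_types)
    n_cells = config.cells_per_type * len(types)
    cell_types = {}
    for i in range(n_cells):
        cell_types[i + 1] = types[i // config.cells_per_type]
    n_genes = config.scrna_genes
    if config.n_planted_tfs > n_genes:
        raise ValueError("more planted TFs than genes")
    gene_ids = [f"scgene{i + 1:03d}" for i in range(n_genes)]
    planted = gene_ids[: config.n_planted_tfs]
    chol_cells = [c for c, t in cell_types.items() if t == types[0]]
    need = config.n_planted_tfs * (config.subpop_size - config.subpop_overlap) + config.subpop_overlap
    if config.subpop_size > len(chol_cells) or need > len(chol_cells):
        raise ValueError("subpopulation sizes exceed the cholinergic cell count")
    order = [chol_cells[i] for i in rng.permutation(len(chol_cells))]
    cursor = 0
    for t, tf in enumerate(planted):
        n_fresh = config.subpop_size - (config.subpop_overlap if t else 0)
        members = set(order[cursor : cursor + n_fresh])
        if t and config.subpop_overlap:
            shared = sorted(truth.subpop_members[planted[t - 1]])[: config.subpop_overlap]
            members |= set(shared)
        cursor += n_fresh
        truth.subpop_members[tf] = members
    mat = _nb_counts(
        np.full((n_genes, n_cells), config.capture_mean), config.nb_dispersion, rng
    ).astype(np.int64)
    for t, tf in enumerate(planted):
        row = t
        silent = _nb_counts(np.full(n_cells, 0.02), config.nb_dispersion, rng)
        mat[row, :] = silent
        member_cols = np.array(sorted(truth.subpop_members[tf])) - 1
        hot = _nb_counts(
            np.full(member_cols.size, config.capture_mean * 8.0), config.nb_dispersion, rng
        )
        mat[row, member_cols] = np.maximum(hot, 3)
    return mat, gene_ids, cell_types


def write_mtx(matrix: np.ndarray, path: str | Path) -> None:
    """MatrixMarket coordinate integer output, 1-based, row-major order."""
    rows, cols = np.nonzero(matrix)
    with open(path, "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{matrix.shape[0]} {matrix.shape[1]} {rows.size}\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r + 1} {c + 1} {matrix[r, c]}\n")


def write_gene_index(gene_ids: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, g in enumerate(gene_ids, 1):
            fh.write(f"{i}\t{g}\n")


def write_cell_annotation(cell_types: dict[int, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_index\tcell_type\n")
        for c in sorted(cell_types):
            fh.write(f"{c}\t{cell_types[c]}\n")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth(truth: TruthTables, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "truth_expression.tsv", "w") as fh:
        fh.write("stage\tcell_type\tcategory\tgene_id\n")
        for cat, d in (
            ("expressed", truth.expressed),
            ("unique_enriched", truth.unique_enriched),
            ("unique_depleted", truth.unique_depleted),
        ):
            for (stage, ctype), genes in sorted(d.items()):
                for g in sorted(genes):
                    fh.write(f"{stage}\t{ctype}\t{cat}\t{g}\n")
    with open(directory / "truth_peaks.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tfirst_fragment\tn_fragments\ttarget_gene\n")
        for p in truth.peaks:
            fh.write(
                f"{p['chrom']}\t{p['start']}\t{p['end']}\t{p['first_fragment']}\t"
                f"{p['n_fragments']}\t{p['target_gene']}\n"
            )
    with open(directory / "truth_subpops.tsv", "w") as fh:
        fh.write("tf\tcell_index\n")
        for tf in sorted(truth.subpop_members):
            for c in sorted(truth.subpop_members[tf]):
                fh.write(f"{tf}\t{c}\n")


def validate_truth(
    truth: TruthTables, annotation: AnnotationSet, fragment_map: GatcFragmentMap
) -> None:
    """Consistency of truth tables with the generated genome/annotation."""
    for d in (truth.expressed, truth.unique_enriched, truth.unique_depleted):
        for genes in d.values():
            for g in genes:
                if g not in annotation:
                    raise AssertionError(f"truth gene {g!r} missing from annotation")
    for stage_type, genes in truth.unique_enriched.items():
        stage = stage_type[0]
        for other, genes2 in truth.unique_enriched.items():
            if other[0] == stage and other != stage_type and genes & genes2:
                raise AssertionError("unique-enriched sets overlap across types")
    for p in truth.peaks:
        if p["n_fragments"] < 2:
            raise AssertionError("planted peak with < 2 fragments")
        if not 0 <= p["start"] < p["end"] <= fragment_map.chrom_length(p["chrom"]):
            raise AssertionError("planted peak outside chromosome")


PRESETS = {
    "demo": {},
    "null": {"effect_log2": 0.0, "n_unique_enriched": 0, "n_unique_depleted": 0},
    # ~5,000 fragments at the default spacing
    "peaks": {"chrom_length": 420_000, "n_genes": 80, "n_peaks": 15, "peak_effect_log2": 2.0},
    "scrna": {},
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return replace(SimulationConfig(master_seed=seed), **kwargs)


def simulate_all(config: SimulationConfig):
    """Genome + annotation + DamID profiles + TF-binding profiles + scRNA
    matrix + truth, all from one seeded config."""
    rng = np.random.default_rng(config.master_seed)
    sequences, annotation, truth = simulate_genome_annotation(config, rng)
    fragment_map = build_fragment_map(sequences)
    damid = simulate_damid_experiment(config, fragment_map, annotation, truth, rng)
    binding = simulate_tf_binding(config, fragment_map, annotation, truth, rng)
    scrna_matrix, scrna_genes, cell_types = simulate_scrnaseq(config, truth, rng)
    validate_truth(truth, annotation, fragment_map)
    return {
        "sequences": sequences,
        "annotation": annotation,
        "fragment_map": fragment_map,
        "damid_profiles": damid,
        "binding_profiles": binding,
        "scrna_matrix": scrna_matrix,
        "scrna_gene_ids": scrna_genes,
        "cell_types": cell_types,
        "truth": truth,
    }
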