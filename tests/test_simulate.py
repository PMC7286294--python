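import re

import numpy as np
import pytest

from tadakit.gatc import build_fragment_map
from tadakit.simulate import (
    SimulationConfig,
    TruthTables,
    preset_config,
    simulate_all,
    simulate_damid_experiment,
    simulate_genome_annotation,
    simulate_scrnaseq,
    simulate_tf_binding,
    validate_truth,
    write_fasta,
    write_mtx,
)

SMALL = dict(chrom_length=150_000, n_genes=25, n_unique_enriched=2, n_unique_depleted=1,
             n_peaks=4, scrna_genes=30, cells_per_type=50, n_planted_tfs=3, subpop_size=10)


class TestGenomeAnnotation:
    def test_gene_count_and_non_overlap(self):
        cfg = SimulationConfig(master_seed=0, **SMALL)
        _, ann, _ = simulate_genome_annotation(cfg)
        assert len(ann) == 25
        genes = sorted(ann, key=lambda g: g.start)
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start

    def test_deterministic_fasta(self, tmp_path):
        cfg = SimulationConfig(master_seed=5, **SMALL)
        seq1, _, _ = simulate_genome_annotation(cfg)
        seq2, _, _ = simulate_genome_annotation(cfg)
        write_fasta(seq1, tmp_path / "a.fa")
        write_fasta(seq2, tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_realized_spacing_near_configured(self):
        cfg = SimulationConfig(master_seed=1, chrom_length=100_000, n_genes=10)
        seqs, _, _ = simulate_genome_annotation(cfg)
        starts = [m.start() for m in re.finditer("GATC", seqs["chr1"])]
        realized = np.diff(starts).mean()
        assert abs(realized - cfg.mean_gatc_spacing) / cfg.mean_gatc_spacing < 0.15

    def test_motifs_only_where_planted(self):
        # background alphabet {A,C,T} cannot form GATC
        cfg = SimulationConfig(master_seed=2, chrom_length=50_000, n_genes=5)
        seqs, _, _ = simulate_genome_annotation(cfg)
        s = seqs["chr1"]
        for m in re.finditer("G", s):
            assert s[m.start() : m.start() + 4] == "GATC"

    def test_genes_do_not_fit_error(self):
        cfg = SimulationConfig(master_seed=0, chrom_length=50_000, n_genes=40)
        with pytest.raises(ValueError, match="longer genome"):
            simulate_genome_annotation(cfg)


class TestDamidExperiment:
    def test_planted_sets_disjoint_and_counts(self):
        cfg = SimulationConfig(master_seed=3, **SMALL)
        rng = np.random.default_rng(3)
        seqs, ann, truth = simulate_genome_annotation(cfg, rng)
        fmap = build_fragment_map(seqs)
        profiles = simulate_damid_experiment(cfg, fmap, ann, truth, rng)
        stage = cfg.stages[0]
        enr = [truth.unique_enriched[(stage, t)] for t in cfg.cell_types]
        assert all(len(s) == 2 for s in enr)
        assert not (enr[0] & enr[1] or enr[0] & enr[2] or enr[1] & enr[2])
        # depleted-in-X genes expressed in both other types only
        for t in cfg.cell_types:
            for g in truth.unique_depleted[(stage, t)]:
                assert g not in truth.expressed[(stage, t)]
                others = [o for o in cfg.cell_types if o != t]
                assert all(g in truth.expressed[(stage, o)] for o in others)
        assert len(profiles) == 3 * 2 * cfg.replicates

    def test_determinism(self):
        outs = []
        for _ in range(2):
            cfg = SimulationConfig(master_seed=4, **SMALL)
            rng = np.random.default_rng(4)
            seqs, ann, truth = simulate_genome_annotation(cfg, rng)
            fmap = build_fragment_map(seqs)
            profiles = simulate_damid_experiment(cfg, fmap, ann, truth, rng)
            outs.append(profiles[(cfg.stages[0], "cholinergic", "dam_fusion", 1)].values)
        assert np.array_equal(outs[0], outs[1])

    def test_beta_zero_records_warning(self):
        cfg = SimulationConfig(master_seed=0, effect_log2=0.0, **SMALL)
        rng = np.random.default_rng(0)
        seqs, ann, truth = simulate_genome_annotation(cfg, rng)
        fmap = build_fragment_map(seqs)
        simulate_damid_experiment(cfg, fmap, ann, truth, rng)
        assert any("no recoverable signal" in w for w in truth.warnings)


class TestTfBinding:
    def test_truth_peaks_well_formed(self):
        cfg = SimulationConfig(master_seed=6, **SMALL)
        rng = np.random.default_rng(6)
        seqs, ann, truth = simulate_genome_annotation(cfg, rng)
        fmap = build_fragment_map(seqs)
        profs = simulate_tf_binding(cfg, fmap, ann, truth, rng)
        assert len(truth.peaks) == 4
        for p in truth.peaks:
            assert p["n_fragments"] >= 2
            assert 0 <= p["start"] < p["end"] <= fmap.chrom_length(p["chrom"])
            g = ann[p["target_gene"]]
            assert abs(g.start - p["end"]) <= 5000 or (p["start"] < g.end and p["end"] > g.start)
        assert len(profs) == 2 * cfg.peak_replicates

    def test_too_many_peaks_error(self):
        cfg = SimulationConfig(master_seed=0, **{**SMALL, "n_peaks": 26})
        rng = np.random.default_rng(0)
        seqs, ann, truth = simulate_genome_annotation(cfg, rng)
        fmap = build_fragment_map(seqs)
        with pytest.raises(ValueError, match="peaks"):
            simulate_tf_binding(cfg, fmap, ann, truth, rng)


class TestScrna:
    def test_header_and_subpops(self, tmp_path):
        cfg = SimulationConfig(master_seed=8, **SMALL)
        truth = TruthTables()
        mat, gene_ids, cell_types = simulate_scrnaseq(cfg, truth, np.random.default_rng(8))
        assert mat.shape == (30, 150)
        assert len(truth.subpop_members) == 3
        sizes = [len(v) for v in truth.subpop_members.values()]
        assert all(s == 10 for s in sizes)
        members = list(truth.subpop_members.values())
        assert not (members[0] & members[1])
        write_mtx(mat, tmp_path / "m.mtx")
        lines = (tmp_path / "m.mtx").read_text().splitlines()
        assert int(lines[1].split()[2]) == len(lines) - 2

    def test_mtx_bytes_deterministic(self, tmp_path):
        for name in ("a", "b"):
            cfg = SimulationConfig(master_seed=9, **SMALL)
            mat, _, _ = simulate_scrnaseq(cfg, TruthTables(), np.random.default_rng(9))
            write_mtx(mat, tmp_path / f"{name}.mtx")
        assert (tmp_path / "a.mtx").read_bytes() == (tmp_path / "b.mtx").read_bytes()

    def test_oversized_subpop_error(self):
        cfg = SimulationConfig(master_seed=0, **{**SMALL, "subpop_size": 60})
        with pytest.raises(ValueError, match="subpopulation"):
            simulate_scrnaseq(cfg, TruthTables(), np.random.default_rng(0))


def test_simulate_all_consistent():
    cfg = SimulationConfig(master_seed=11, **SMALL)
    sim = simulate_all(cfg)
    validate_truth(sim["truth"], sim["annotation"], sim["fragment_map"])
    assert sim["fragment_map"].n_fragments > 0


def test_presets():
    cfg = preset_config("null", seed=3)
    assert cfg.effect_log2 == 0.0 and cfg.master_seed == 3
    with pytest.raises(ValueError):
        preset_config("bogus")


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(mean_gatc_spacing=4)
    with pytest.raises(ValueError):
        SimulationConfig(effect_log2=-1)
    with pytest.raises(ValueError):
        SimulationConfig(n_genes=0)
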