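import numpy as np
import pytest

from tadakit.gatc import AnnotationSet, GeneModel
from tadakit.peaks import (
    Peak,
    assign_genes,
    candidate_peaks,
    call_peaks,
    ConsensusPeak,
    peak_fdr,
    replicate_consensus,
    significant_peaks,
)

from conftest import make_profile, uniform_map


def exhaustive_run_oracle(values, theta=0.0):
    """Enumerate every maximal run of values > theta by direct scan."""
    runs, i = [], 0
    while i < len(values):
        if values[i] > theta:
            j = i
            while j < len(values) and values[j] > theta:
                j += 1
            if j - i >= 2:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


class TestCandidatePeaks:
    def test_basic_run(self):
        m = uniform_map(4)
        peaks = candidate_peaks(make_profile([0.5, 0.6, -0.1, 0.7], m), statistic="mean")
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.first_fragment, p.n_fragments) == (0, 2)
        assert p.statistic == pytest.approx(0.55)
        assert (p.start, p.end) == (0, 200)
        # default statistic rewards run length (sum)
        assert candidate_peaks(make_profile([0.5, 0.6, -0.1, 0.7], m))[0].statistic == pytest.approx(1.1)

    def test_isolated_fragment_no_peak(self):
        m = uniform_map(5)
        assert candidate_peaks(make_profile([-1, 2.0, -1, -1, -1], m)) == []

    def test_strict_threshold(self):
        m = uniform_map(3)
        assert candidate_peaks(make_profile([0.0, 0.0, 0.0], m), theta=0.0) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        vals = rng.normal(0, 1, n)
        m = uniform_map(n)
        got = [(p.first_fragment, p.first_fragment + p.n_fragments)
               for p in candidate_peaks(make_profile(vals, m))]
        assert got == exhaustive_run_oracle(vals)

    def test_runs_do_not_cross_chromosomes(self):
        m = uniform_map(2, 100)
        import numpy as np_
        from tadakit.gatc import GatcFragmentMap
        m2 = GatcFragmentMap({"a": np_.array([0, 100, 200]), "b": np_.array([0, 100, 200])})
        prof = make_profile([1, 1, 1, 1], m2)
        peaks = candidate_peaks(prof)
        assert len(peaks) == 2
        assert {p.chrom for p in peaks} == {"a", "b"}

    def test_statistic_variants(self):
        m = uniform_map(3)
        prof = make_profile([1.0, 3.0, 2.0], m)
        assert candidate_peaks(prof, statistic="sum")[0].statistic == pytest.approx(6.0)
        assert candidate_peaks(prof, statistic="min")[0].statistic == pytest.approx(1.0)


class TestPeakFdr:
    def test_constant_profile_empty(self):
        m = uniform_map(10)
        prof = make_profile(np.zeros(10), m)
        assert peak_fdr(candidate_peaks(prof), prof, shuffles=100, seed=0) == []

    def test_planted_run_significant(self):
        # the canonical recovery setting: 4 fragments at +3.0 over N(0, 0.3)
        rng = np.random.default_rng(11)
        n = 5000
        vals = rng.normal(0, 0.3, n)
        vals[2000:2004] = 3.0
        m = uniform_map(n)
        prof = make_profile(vals, m)
        sig = call_peaks(prof, shuffles=1000, seed=42)
        assert any(p.first_fragment <= 2000 and p.first_fragment + p.n_fragments >= 2004
                   for p in sig)

    def test_fdr_monotone_in_statistic(self):
        rng = np.random.default_rng(3)
        m = uniform_map(200)
        prof = make_profile(rng.normal(0, 1, 200), m)
        peaks = peak_fdr(candidate_peaks(prof), prof, shuffles=100, seed=1)
        ordered = sorted(peaks, key=lambda p: p.statistic)
        fdrs = [p.fdr for p in ordered]
        assert all(a >= b - 1e-12 for a, b in zip(fdrs, fdrs[1:]))

    def test_too_few_shuffles(self):
        m = uniform_map(5)
        prof = make_profile([1, 1, -1, -1, -1], m)
        with pytest.raises(ValueError):
            peak_fdr(candidate_peaks(prof), prof, shuffles=50)


def _peak(chrom, start, end, rep_tag=0):
    n = max((end - start) // 100, 2)
    return Peak(chrom=chrom, start=start, end=end, first_fragment=0,
                n_fragments=n, statistic=1.0, fdr=0.0)


class TestReplicateConsensus:
    def test_overlap_in_both(self):
        cons = replicate_consensus([
            [_peak("c", 100, 300)],
            [_peak("c", 250, 500)],
        ])
        assert len(cons) == 1
        assert (cons[0].start, cons[0].end) == (100, 500)

    def test_single_replicate_support_dropped(self):
        cons = replicate_consensus([
            [_peak("c", 100, 300)],
            [],
        ])
        assert cons == []

    def test_chained_overlap_merges(self):
        cons = replicate_consensus([
            [_peak("c", 100, 600)],
            [_peak("c", 50, 150), _peak("c", 500, 700)],
        ])
        assert len(cons) == 1
        assert (cons[0].start, cons[0].end) == (50, 700)

    def test_touching_is_not_overlap(self):
        cons = replicate_consensus([
            [_peak("c", 100, 200)],
            [_peak("c", 200, 300)],
        ])
        assert cons == []

    def test_zero_replicates_error(self):
        with pytest.raises(ValueError):
            replicate_consensus([])


def _gene(gid, start, end, chrom="c", strand="+"):
    return GeneModel(gid, chrom, strand, start, end, [(gid + ".t1", start, end)])


def betweenness_oracle(peak, genes, window):
    """Direct enumeration of the assignment rule over all genes."""
    out = []
    for g in genes:
        if g.start < peak.end and g.end > peak.start:
            out.append((g.gene_id, "overlapping", 0))
            continue
        if g.end <= peak.start:
            relation, gap, lo, hi = "upstream", peak.start - g.end, g.end, peak.start
        else:
            relation, gap, lo, hi = "downstream", g.start - peak.end, peak.end, g.start
        if gap > window:
            continue
        blocked = any(
            h is not g
            and not (h.start < peak.end and h.end > peak.start)
            and ((h.end <= peak.start) == (g.end <= peak.start))
            and h.start < hi and h.end > lo
            for h in genes
        )
        if not blocked:
            out.append((g.gene_id, relation, gap))
    return sorted(out, key=lambda t: (t[2], t[0]))


class TestAssignGenes:
    def test_intervening_gene_blocks(self):
        ann = AnnotationSet([_gene("A", 12000, 13000), _gene("B", 14000, 15000)])
        cons = [ConsensusPeak("c", 10000, 10400, {0: [0]})]
        assign_genes(cons, ann)
        assert cons[0].genes == [("A", "downstream", 1600)]

    def test_window_boundary(self):
        ann = AnnotationSet([_gene("far", 15401, 16000)])  # gap 5001
        cons = [ConsensusPeak("c", 10000, 10400, {0: [0]})]
        assign_genes(cons, ann)
        assert cons[0].genes == []
        ann2 = AnnotationSet([_gene("edge", 15400, 16000)])  # gap 5000
        cons2 = [ConsensusPeak("c", 10000, 10400, {0: [0]})]
        assign_genes(cons2, ann2)
        assert cons2[0].genes == [("edge", "downstream", 5000)]

    def test_overlapping_plus_downstream(self):
        ann = AnnotationSet([_gene("ov", 10200, 11000), _gene("dn", 13000, 14000)])
        cons = [ConsensusPeak("c", 10000, 10400, {0: [0]})]
        assign_genes(cons, ann)
        assert ("ov", "overlapping", 0) in cons[0].genes
        assert ("dn", "downstream", 2600) in cons[0].genes

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_betweenness_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(int(rng.integers(1, 12))):
            s = int(rng.integers(0, 40000))
            genes.append(_gene(f"g{i}", s, s + int(rng.integers(200, 3000))))
        ann = AnnotationSet(genes)
        ps = int(rng.integers(0, 38000))
        peak = ConsensusPeak("c", ps, ps + int(rng.integers(100, 2000)), {0: [0]})
        assign_genes([peak], ann)
        assert peak.genes == betweenness_oracle(peak, genes, 5000)


def test_significant_peaks_threshold():
    peaks = [
        Peak("c", 0, 200, 0, 2, 1.0, fdr=5e-5),
        Peak("c", 400, 600, 4, 2, 0.5, fdr=1e-4),
    ]
    assert [p.fdr for p in significant_peaks(peaks)] == [5e-5]
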