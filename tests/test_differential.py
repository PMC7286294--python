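import numpy as np
import pandas as pd
import pytest

from tadakit.differential import (
    DifferentialResult,
    UniqueSets,
    comparison_seed,
    differential_genes,
    filter_gene_class,
    read_class_map,
    subtract_profiles,
    transition_counts,
    transition_table,
    unique_sets,
)
from tadakit.genecalls import CallParams, GeneCallTable

from conftest import make_profile, uniform_map


def _reps(values_list, m, **kw):
    return [make_profile(v, m, replicate=i + 1, **kw) for i, v in enumerate(values_list)]


class TestSubtractProfiles:
    def test_identity_gives_zero(self):
        m = uniform_map(5)
        a = _reps([np.ones(5)] * 3, m)
        out = subtract_profiles(a, a)
        assert all(np.all(p.values == 0) for p in out)

    def test_elementwise(self):
        m = uniform_map(1)
        out = subtract_profiles(_reps([[1.0]], m), _reps([[0.3]], m))
        assert out[0].values[0] == pytest.approx(0.7)

    def test_replicate_count_mismatch(self):
        m = uniform_map(2)
        with pytest.raises(ValueError, match="mismatch"):
            subtract_profiles(_reps([np.zeros(2)] * 3, m), _reps([np.zeros(2)] * 2, m))

    def test_produces_one_output_per_replicate(self):
        m = uniform_map(4)
        out = subtract_profiles(_reps([np.zeros(4)] * 3, m), _reps([np.ones(4)] * 3, m))
        assert len(out) == 3


def _calls_with_bound(genes_bound, all_genes):
    df = pd.DataFrame(
        {
            "gene_id": sorted(all_genes),
            "transcript_id": [g + ".t1" for g in sorted(all_genes)],
            "score": 1.0,
            "fdr": 0.0,
            "bound": [g in genes_bound for g in sorted(all_genes)],
        }
    )
    return GeneCallTable(transcripts=df, genes=df, params=CallParams())


class TestDifferentialGenes:
    def test_numerator_bound_filter(self, tiny_map):
        # plant a strong difference on g1 but mark it unbound in numerator;
        # equal-length transcripts keep the shuffle null away from the
        # planted score
        from tadakit.gatc import AnnotationSet, GeneModel

        ann = AnnotationSet(
            [
                GeneModel(f"g{i}", "chr1", "+", i * 400, (i + 1) * 400,
                          [(f"g{i}.t1", i * 400, (i + 1) * 400)])
                for i in range(5)
            ]
        )
        vals = np.zeros(20)
        vals[:4] = 5.0
        diffs = _reps([vals, vals, vals], tiny_map)
        calls = _calls_with_bound(set(), {f"g{i}" for i in range(5)})
        res = differential_genes(diffs, ann, calls, CallParams(permutations=50, seed=0))
        row = res.table.set_index("gene_id").loc["g0"]
        assert row["significant"]
        assert not row["enriched"]

    def test_self_comparison_null(self, tiny_map, toy_annotation):
        rng = np.random.default_rng(0)
        base = [rng.normal(0, 1, 20) for _ in range(3)]
        diffs = subtract_profiles(_reps(base, tiny_map), _reps(base, tiny_map))
        calls = _calls_with_bound({f"g{i}" for i in range(1, 6)}, {f"g{i}" for i in range(1, 6)})
        res = differential_genes(diffs, toy_annotation, calls, CallParams(permutations=30, seed=1))
        assert res.enriched_genes == set()

    def test_empty_replicates_error(self, toy_annotation):
        with pytest.raises(ValueError):
            differential_genes([], toy_annotation, _calls_with_bound(set(), set()), CallParams())


def _diff_result(x, y, enriched_genes):
    table = pd.DataFrame(
        {
            "gene_id": sorted(enriched_genes),
            "transcript_id": [g + ".t1" for g in sorted(enriched_genes)],
            "score": 1.0,
            "fdr": 0.0,
            "significant": True,
            "bound_in_numerator": True,
            "enriched": True,
        }
    )
    return DifferentialResult(numerator=x, denominator=y, stage="s", table=table)


def _six(enr):
    types = ["A", "B", "C"]
    return {
        (x, y): _diff_result(x, y, enr.get((x, y), set()))
        for x in types
        for y in types
        if x != y
    }


class TestUniqueSets:
    def test_uniquely_enriched(self):
        pairwise = _six({("A", "B"): {"g"}, ("A", "C"): {"g"}})
        bounds = {t: _calls_with_bound({"g"}, {"g"}) for t in "ABC"}
        us = unique_sets(pairwise, bounds, stage="s")
        assert us.enriched["A"] == {"g"}
        assert us.enriched["B"] == set() and us.enriched["C"] == set()

    def test_single_comparison_not_unique(self):
        pairwise = _six({("A", "B"): {"g"}})
        bounds = {t: _calls_with_bound({"g"}, {"g"}) for t in "ABC"}
        us = unique_sets(pairwise, bounds, stage="s")
        assert all(not s for s in us.enriched.values())
        assert all(not s for s in us.depleted.values())

    def test_uniquely_depleted_requires_bound_in_both(self):
        pairwise = _six({("B", "A"): {"g"}, ("C", "A"): {"g"}})
        bounds = {t: _calls_with_bound({"g"}, {"g"}) for t in "ABC"}
        us = unique_sets(pairwise, bounds, stage="s")
        assert us.depleted["A"] == {"g"}
        # unbound in C -> not depleted
        bounds["C"] = _calls_with_bound(set(), {"g"})
        us2 = unique_sets(pairwise, bounds, stage="s")
        assert us2.depleted["A"] == set()

    def test_missing_comparison_errors(self):
        pairwise = _six({})
        del pairwise[("A", "B")]
        bounds = {t: _calls_with_bound(set(), set()) for t in "ABC"}
        with pytest.raises(ValueError, match="missing comparison"):
            unique_sets(pairwise, bounds)

    def test_enriched_antisymmetry(self, tiny_map, toy_annotation):
        rng = np.random.default_rng(5)
        a = [rng.normal(0, 1, 20) for _ in range(3)]
        b = [rng.normal(0, 1, 20) for _ in range(3)]
        all_genes = {f"g{i}" for i in range(1, 6)}
        calls = _calls_with_bound(all_genes, all_genes)
        params = CallParams(permutations=30, seed=3)
        ab = differential_genes(
            subtract_profiles(_reps(a, tiny_map), _reps(b, tiny_map)),
            toy_annotation, calls, params)
        ba = differential_genes(
            subtract_profiles(_reps(b, tiny_map), _reps(a, tiny_map)),
            toy_annotation, calls, params)
        assert not (ab.enriched_genes & ba.enriched_genes)


class TestFilterGeneClass:
    def test_basic(self):
        assert filter_gene_class(["g1", "g2"], {"g1": "TF", "g2": "other"}, "TF") == ["g1"]

    def test_empty_map(self):
        assert filter_gene_class(["g1"], {}, "TF") == []

    def test_mirna_class(self):
        cmap = {"m1": "miRNA", "g1": "TF"}
        assert filter_gene_class(["m1", "g1"], cmap, "miRNA") == ["m1"]

    def test_read_class_map(self, tmp_path):
        p = tmp_path / "classes.tsv"
        p.write_text("gene_id\tclass\ng1\tTF\ng2\tlncRNA\n")
        assert read_class_map(p) == {"g1": "TF", "g2": "lncRNA"}
        p2 = tmp_path / "tf_list.txt"
        p2.write_text("g1\ng3\n")
        assert read_class_map(p2) == {"g1": "TF", "g3": "TF"}


def _us(stage, enriched=None, depleted=None):
    us = UniqueSets(stage=stage)
    us.enriched = {k: set(v) for k, v in (enriched or {}).items()}
    us.depleted = {k: set(v) for k, v in (depleted or {}).items()}
    return us


class TestTransitionTable:
    def test_path_through_stages(self):
        stages = [
            _us("e", enriched={"chol": {"g"}}),
            _us("l", enriched={"chol": {"g"}}),
            _us("a"),
        ]
        t = transition_table(stages)
        rows = t[t["gene_id"] == "g"].sort_values("stage_from")
        assert list(rows["state_from"]) == ["enriched:chol", "enriched:chol"]
        assert list(rows["state_to"]) == ["enriched:chol", "none"]

    def test_type_switch_recorded(self):
        stages = [
            _us("l", enriched={"chol": {"Dll"}}),
            _us("a", enriched={"GABA": {"Dll"}}),
        ]
        t = transition_table(stages)
        row = t.iloc[0]
        assert row["state_from"] == "enriched:chol" and row["state_to"] == "enriched:GABA"

    def test_counts_conserve_tracked_genes(self):
        stages = [
            _us("e", enriched={"chol": {"a", "b"}}, depleted={"glut": {"c"}}),
            _us("l", enriched={"chol": {"a"}}),
            _us("a", depleted={"glut": {"c", "d"}}),
        ]
        t = transition_table(stages)
        counts = transition_counts(t)
        tracked = {"a", "b", "c", "d"}
        for (_, _), grp in counts.groupby(["stage_from", "stage_to"]):
            assert grp["count"].sum() == len(tracked)

    def test_fewer_than_two_stages_errors(self):
        with pytest.raises(ValueError):
            transition_table([_us("only")])


def test_comparison_seed_deterministic_and_distinct():
    s1 = comparison_seed(7, "larva", "A", "B")
    assert s1 == comparison_seed(7, "larva", "A", "B")
    assert s1 != comparison_seed(7, "larva", "B", "A")
    assert s1 != comparison_seed(8, "larva", "A", "B")
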