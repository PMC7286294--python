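import numpy as np
import pytest

from tadakit.gatc import AnnotationSet, GatcFragmentMap, GeneModel
from tadakit.profiles import FragmentProfile, SampleMeta


def uniform_map(n_fragments: int, frag_len: int = 100, chrom: str = "chr1") -> GatcFragmentMap:
    """A single-chromosome map of equal-length fragments (no sequence needed)."""
    bounds = np.arange(n_fragments + 1, dtype=np.int64) * frag_len
    return GatcFragmentMap({chrom: bounds})


def make_profile(values, fragment_map, unit="log2_ratio", **meta_kw):
    meta_kw.setdefault("sample_id", "test")
    if meta_kw.get("channel") == "dam_fusion":
        meta_kw.setdefault("fusion_name", "X")
    return FragmentProfile(
        meta=SampleMeta(**meta_kw),
        unit=unit,
        values=np.asarray(values, dtype=float),
        map=fragment_map,
    )


@pytest.fixture
def tiny_map():
    return uniform_map(20, 100)


@pytest.fixture
def toy_annotation():
    """5 genes tiling a 2 kb chromosome (matches uniform_map(20, 100))."""
    genes = [
        GeneModel("g1", "chr1", "+", 0, 400, [("g1.t1", 0, 400)]),
        GeneModel("g2", "chr1", "-", 450, 800, [("g2.t1", 450, 800), ("g2.t2", 500, 700)]),
        GeneModel("g3", "chr1", "+", 850, 1200, [("g3.t1", 850, 1200)]),
        GeneModel("g4", "chr1", "+", 1250, 1600, [("g4.t1", 1250, 1600)]),
        GeneModel("g5", "chr1", "-", 1650, 1990, [("g5.t1", 1650, 1990)]),
    ]
    return AnnotationSet(genes)
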