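"""Transcribed-gene identification from Pol II occupancy log2 ratios.

Each transcript gets a score (length-weighted mean log2 ratio over the
fragments it intersects) and a permutation FDR.  Genes are reduced to
their most significant transcript, and called bound when the gene FDR is
below threshold and the gene score reaches the minimum log2 ratio
(defaults: FDR < 0.01, score >= 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .gatc import AnnotationSet, GatcFragmentMap
from .profiles import FragmentProfile


@dataclass(frozen=True)
class CallParams:
    fdr_threshold: float = 0.01
    min_score: float = 0.2
    permutations: int = 100
    seed: int = 0
    length_weighted: bool = True

    def __post_init__(self):
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.permutations < 10:
            raise ValueError("need at least 10 permutations")


@dataclass
class GeneCallTable:
    """Per-transcript scores/FDRs and the per-gene reduction."""

    transcripts: pd.DataFrame  # transcript_id, gene_id, score, fdr
    genes: pd.DataFrame  # gene_id, transcript_id, score, fdr, bound
    params: CallParams

    @property
    def bound_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes["bound"], "gene_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)


def transcript_weights(
    annotation: AnnotationSet,
    fragment_map: GatcFragmentMap,
    length_weighted: bool = True,
) -> tuple[list[tuple[str, str]], sparse.csr_matrix]:
    """Sparse (transcripts x fragments) weight matrix whose rows are the
    normalised intersection weights, so scores are ``W @ values``.

    Returns the (transcript_id, gene_id) row labels and the matrix.
    """
    rows, cols, data = [], [], []
    labels = []
    for r, (tid, gid, chrom, ts, te) in enumerate(annotation.all_transcripts()):
        idx = fragment_map.fragments_overlapping(chrom, ts, te)
        if idx.size == 0:
            raise ValueError(f"transcript {tid!r} overlaps no fragment (chromosome missing?)")
        if length_weighted:
            w = (
                np.minimum(fragment_map.ends[idx], te)
                - np.maximum(fragment_map.starts[idx], ts)
            ).astype(float)
        else:
            w = np.ones(idx.size)
        w /= w.sum()
        rows.extend([r] * idx.size)
        cols.extend(idx.tolist())
        data.extend(w.tolist())
        labels.append((tid, gid))
    mat = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(labels), fragment_map.n_fragments)
    )
    return labels, mat


def transcript_score(
    profile: FragmentProfile,
    transcript: tuple[str, int, int],
    fragment_map: GatcFragmentMap | None = None,
    length_weighted: bool = True,
) -> float:
    """Length-weighted mean log2 ratio over fragments intersecting the
    transcript span ``(chrom, start, end)``."""
    m = fragment_map or profile.map
    chrom, ts, te = transcript
    idx = m.fragments_overlapping(chrom, ts, te)
    if idx.size == 0:
        raise ValueError("transcript overlaps no fragment")
    if length_weighted:
        w = (np.minimum(m.ends[idx], te) - np.maximum(m.starts[idx], ts)).astype(float)
    else:
        w = np.ones(idx.size)
    return float(np.average(profile.values[idx], weights=w))


def _tail_fdr(observed: np.ndarray, null_per_perm: list[np.ndarray]) -> np.ndarray:
    """Raw permutation FDR per observed score, regularised to be monotone
    non-increasing in score.

    For observed score s: FDR(s) = mean over permutations of
    #{null >= s} / #{observed >= s}, clipped to [0, 1], then made monotone
    by a cumulative minimum from the highest score down.
    """
    n = observed.size
    order = np.argsort(observed)  # ascending
    s_sorted = observed[order]
    # observed tail counts (ties inclusive)
    obs_tail = n - np.searchsorted(s_sorted, s_sorted, side="left")
    null_tail = np.zeros(n)
    for null in null_per_perm:
        ns = np.sort(null)
        null_tail += ns.size - np.searchsorted(ns, s_sorted, side="left")
    raw = (null_tail / len(null_per_perm)) / obs_tail
    raw = np.clip(raw, 0.0, 1.0)
    # q-value regularisation: each score may use any less stringent
    # threshold's estimate, so FDR(s) = min over s' <= s of raw(s'),
    # making FDR monotone non-increasing in score
    mono = np.minimum.accumulate(raw)
    out = np.empty(n)
    out[order] = mono
    return out


def permutation_fdr(
    profile: FragmentProfile,
    annotation: AnnotationSet,
    params: CallParams,
) -> pd.DataFrame:
    """Score every transcript and assign a permutation FDR.

    The null shuffles fragment values uniformly genome-wide (seeded); all
    transcript scores are recomputed per permutation and upper-tail counts
    are compared with the observed score distribution.
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    labels, W = transcript_weights(annotation, profile.map, params.length_weighted)
    if len(labels) < 2:
        raise ValueError("need at least 2 transcripts for a permutation FDR")
    observed = W @ profile.values
    rng = np.random.default_rng(params.seed)
    nulls = []
    for _ in range(params.permutations):
        shuffled = profile.values[rng.permutation(profile.values.size)]
        nulls.append(W @ shuffled)
    fdr = _tail_fdr(observed, nulls)
    return pd.DataFrame(
        {
            "transcript_id": [t for t, _ in labels],
            "gene_id": [g for _, g in labels],
            "score": observed,
            "fdr": fdr,
        }
    )


def call_genes(transcript_table: pd.DataFrame, params: CallParams) -> GeneCallTable:
    """Reduce transcript scores/FDRs to per-gene calls.

    The gene takes its most significant transcript (lowest FDR; ties broken
    by higher score, then lexicographic transcript id).  ``bound`` requires
    FDR strictly below threshold and score at or above the minimum.
    """
    t = transcript_table.sort_values(
        ["gene_id", "fdr", "score", "transcript_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = t.groupby("gene_id", sort=True).head(1).reset_index(drop=True)
    genes = best[["gene_id", "transcript_id", "score", "fdr"]].copy()
    genes["bound"] = (genes["fdr"] < params.fdr_threshold) & (
        genes["score"] >= params.min_score
    )
    return GeneCallTable(transcripts=transcript_table, genes=genes, params=params)


def call_polii_genes(
    profile: FragmentProfile,
    annotation: AnnotationSet,
    params: CallParams | None = None,
) -> GeneCallTable:
    """Full gene-calling pass: transcript scores, permutation FDR, gene
    reduction."""
    params = params or CallParams()
    table = permutation_fdr(profile, annotation, params)
    return call_genes(table, params)
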