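"""Chromatin accessibility from Dam-only samples (CATaDa).

The untethered Dam control preferentially methylates open chromatin, so
its RPM profile is an accessibility readout.  Robust between-type changes
are maximal runs of >= 3 consecutive fragments whose RPM difference
exceeds 10 in a common direction (strict inequality).  Gene loci are
extended 5 kb upstream and 2 kb downstream (strand-oriented) before
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gatc import AnnotationSet
from .profiles import FragmentProfile, SampleMeta, rpm_normalize

DEFAULT_DELTA = 10.0  # RPM
DEFAULT_MIN_RUN = 3
DEFAULT_UP = 5000
DEFAULT_DOWN = 2000


@dataclass
class AccessibilityDiffRegion:
    chrom: str
    start: int
    end: int
    first_fragment: int
    n_fragments: int
    direction: int  # +1 = first sample higher
    differences: np.ndarray


def accessibility_profile(dam_only_reps: list[FragmentProfile]) -> FragmentProfile:
    """RPM-normalise each Dam-only replicate and average fragment-wise."""
    if not dam_only_reps:
        raise ValueError("no replicates")
    rpms = []
    for p in dam_only_reps:
        if not p.map.same_map(dam_only_reps[0].map):
            raise ValueError("replicates use different fragment maps")
        rpms.append(p if p.unit == "rpm" else rpm_normalize(p))
    mean_vals = np.mean([p.values for p in rpms], axis=0)
    meta = SampleMeta(
        sample_id=f"{dam_only_reps[0].meta.cell_type}_{dam_only_reps[0].meta.stage}_accessibility",
        cell_type=dam_only_reps[0].meta.cell_type,
        stage=dam_only_reps[0].meta.stage,
        channel="dam_only",
    )
    return FragmentProfile(meta=meta, unit="rpm", values=mean_vals, map=rpms[0].map)


def locus_accessibility(
    profile: FragmentProfile,
    annotation: AnnotationSet,
    up: int = DEFAULT_UP,
    down: int = DEFAULT_DOWN,
    stranded: bool = True,
) -> pd.DataFrame:
    """Mean RPM (length-weighted) over extended gene loci.

    For + strand genes the locus is [start-up, end+down); for - strand
    [start-down, end+up); unstranded mode uses up on both... the + rule
    for every gene.  Intervals are clipped to the chromosome.
    """
    if profile.unit != "rpm":
        raise ValueError("locus_accessibility expects an rpm profile")
    m = profile.map
    rows = []
    for gid in sorted(annotation.genes):
        g = annotation[gid]
        if stranded and g.strand == "-":
            lo, hi = g.start - down, g.end + up
        else:
            lo, hi = g.start - up, g.end + down
        lo = max(lo, 0)
        hi = min(hi, m.chrom_length(g.chrom))
        idx = m.fragments_overlapping(g.chrom, lo, hi)
        w = (np.minimum(m.ends[idx], hi) - np.maximum(m.starts[idx], lo)).astype(float)
        rows.append(
            {
                "gene_id": gid,
                "chrom": g.chrom,
                "start": lo,
                "end": hi,
                "mean_rpm": float(np.average(profile.values[idx], weights=w)),
            }
        )
    return pd.DataFrame(rows)


def robust_diff_regions(
    a: FragmentProfile,
    b: FragmentProfile,
    delta: float = DEFAULT_DELTA,
    min_run: int = DEFAULT_MIN_RUN,
) -> tuple[list[AccessibilityDiffRegion], dict[str, int]]:
    """Maximal same-sign runs of >= ``min_run`` fragments with
    |RPM difference| strictly above ``delta``.

    Returns the regions and a summary with total member-fragment and
    region counts.
    """
    if not a.map.same_map(b.map):
        raise ValueError("profiles use different fragment maps")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    m = a.map
    d = a.values - b.values
    regions = []
    for chrom in m.chroms:
        sl = m.chrom_slice(chrom)
        dv = d[sl]
        sign = np.where(dv > delta, 1, np.where(dv < -delta, -1, 0))
        i = 0
        n = sign.size
        while i < n:
            if sign[i] == 0:
                i += 1
                continue
            j = i
            while j < n and sign[j] == sign[i]:
                j += 1
            if j - i >= min_run:
                gi = sl.start + i
                regions.append(
                    AccessibilityDiffRegion(
                        chrom=chrom,
                        start=int(m.starts[gi]),
                        end=int(m.ends[sl.start + j - 1]),
                        first_fragment=gi,
                        n_fragments=j - i,
                        direction=int(sign[i]),
                        differences=dv[i:j].copy(),
                    )
                )
            i = j
    summary = {
        "n_fragments": int(sum(r.n_fragments for r in regions)),
        "n_regions": len(regions),
    }
    return regions, summary


def regions_to_bed(regions: list[AccessibilityDiffRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = f"region_{i}_{'up' if r.direction > 0 else 'down'}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{r.n_fragments}\t.\n")
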