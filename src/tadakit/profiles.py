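"""Per-sample fragment signal: loading, RPM normalisation and log2 ratios.

A :class:`FragmentProfile` carries one value per fragment of a
:class:`~tadakit.gatc.GatcFragmentMap`, in one of three units:
raw ``count``, ``rpm`` (counts scaled to sum to 1e6) or ``log2_ratio``
(Dam-fusion over Dam-only).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .gatc import GatcFragmentMap

# Pseudocount for ratio formation, in RPM.  At desk-scale depths 1 RPM is
# well under one read, which lets zero-count fragments produce extreme
# log2 values; 10 RPM (~1 read at 1e5 reads over 1e4 fragments) keeps
# the ratio finite-variance without biasing covered fragments.
DEFAULT_PSEUDOCOUNT = 10.0

VALID_CHANNELS = ("dam_only", "dam_fusion")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    cell_type: str = ""
    stage: str = ""
    replicate: int = 1
    channel: str = "dam_only"
    fusion_name: str = ""

    def __post_init__(self):
        if self.channel not in VALID_CHANNELS:
            raise ValueError(f"channel must be one of {VALID_CHANNELS}, got {self.channel!r}")
        if self.channel == "dam_only" and self.fusion_name:
            raise ValueError("dam_only samples carry no fusion_name")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def label(self) -> str:
        return f"{self.cell_type}_{self.stage}_{self.channel}_r{self.replicate}"


@dataclass
class FragmentProfile:
    meta: SampleMeta
    unit: str  # count | rpm | log2_ratio
    values: np.ndarray
    map: GatcFragmentMap

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.map.n_fragments,):
            raise ValueError(
                f"profile has {self.values.size} values for a map of "
                f"{self.map.n_fragments} fragments"
            )
        if self.unit not in ("count", "rpm", "log2_ratio"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.unit in ("count", "rpm") and np.any(self.values < 0):
            raise ValueError(f"negative values in a {self.unit} profile")


def load_fragment_signal(
    source: str | Path,
    fragment_map: GatcFragmentMap,
    meta: SampleMeta,
    fmt: str | None = None,
) -> FragmentProfile:
    """Load per-fragment counts from a bedGraph or a fragment-count TSV.

    bedGraph mass is allocated to fragments proportionally to overlap
    length, so total mass is conserved.  TSV rows are keyed by global
    fragment index and load verbatim.  Fragments absent from the input
    get 0.
    """
    source = Path(source)
    if fmt is None:
        fmt = "bedgraph" if source.suffix.lower() in (".bedgraph", ".bg") else "tsv"
    values = np.zeros(fragment_map.n_fragments, dtype=float)
    if fmt == "bedgraph":
        seen: dict[str, list[tuple[int, int]]] = {}
        with open(source) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                chrom, start_s, end_s, val_s = line.split()[:4]
                start, end, val = int(start_s), int(end_s), float(val_s)
                if val < 0:
                    raise ValueError(f"{source}:{lineno}: negative value {val}")
                if end <= start:
                    raise ValueError(f"{source}:{lineno}: empty interval")
                try:
                    idx = fragment_map.fragments_overlapping(chrom, start, end)
                except KeyError as exc:
                    raise ValueError(f"{source}:{lineno}: {exc.args[0]}") from exc
                seen.setdefault(chrom, []).append((start, end))
                fs = fragment_map.starts[idx]
                fe = fragment_map.ends[idx]
                overlap = np.minimum(fe, end) - np.maximum(fs, start)
                values[idx] += val * overlap / (end - start)
        for chrom, ivals in seen.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"{source}: overlapping bedGraph intervals on {chrom}: "
                        f"[{s1},{e1}) and [{s2},{e2})"
                    )
    elif fmt == "tsv":
        with open(source) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("fragment_index"):
                    continue
                idx_s, val_s = line.split("\t")[:2]
                idx, val = int(idx_s), float(val_s)
                if val < 0:
                    raise ValueError(f"{source}:{lineno}: negative value {val}")
                if not 0 <= idx < fragment_map.n_fragments:
                    raise ValueError(f"{source}:{lineno}: fragment index {idx} out of range")
                values[idx] = val
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return FragmentProfile(meta=meta, unit="count", values=values, map=fragment_map)


def write_fragment_tsv(profile: FragmentProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment_index\tvalue\n")
        for i, v in enumerate(profile.values):
            fh.write(f"{i}\t{float(v)!r}\n")


def write_bedgraph(profile: FragmentProfile, path: str | Path) -> None:
    m = profile.map
    with open(path, "w") as fh:
        for i, v in enumerate(profile.values):
            fh.write(f"{m.chrom_of[i]}\t{m.starts[i]}\t{m.ends[i]}\t{float(v)!r}\n")


def read_profile_bedgraph(
    path: str | Path,
    fragment_map: GatcFragmentMap,
    meta: SampleMeta,
    unit: str = "log2_ratio",
) -> FragmentProfile:
    """Read a per-fragment bedGraph (as written by :func:`write_bedgraph`)
    back into a profile.  Each interval's value is assigned to every
    fragment it overlaps; values may be negative for log2_ratio."""
    values = np.zeros(fragment_map.n_fragments, dtype=float)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start_s, end_s, val_s = line.split()[:4]
            idx = fragment_map.fragments_overlapping(chrom, int(start_s), int(end_s))
            values[idx] = float(val_s)
    return FragmentProfile(meta=meta, unit=unit, values=values, map=fragment_map)


def rpm_normalize(profile: FragmentProfile) -> FragmentProfile:
    """Scale a count profile so values sum to 1e6 (reads per million)."""
    if profile.unit != "count":
        raise ValueError(f"rpm_normalize expects a count profile, got {profile.unit!r}")
    total = profile.values.sum()
    if total <= 0:
        raise ValueError(f"all-zero profile {profile.meta.sample_id!r}: no library size")
    return FragmentProfile(
        meta=profile.meta, unit="rpm", values=profile.values * (1e6 / total), map=profile.map
    )


def log2_ratio(
    fusion: FragmentProfile,
    dam: FragmentProfile,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FragmentProfile:
    """Elementwise log2((fusion + psi) / (dam + psi)) on RPM profiles.

    Metadata is taken from the fusion sample.  Antisymmetric in its two
    arguments by construction.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if fusion.unit != "rpm" or dam.unit != "rpm":
        raise ValueError("log2_ratio expects rpm profiles")
    if not fusion.map.same_map(dam.map):
        raise ValueError("fusion and dam profiles use different fragment maps")
    # difference form keeps log2_ratio(A, B) == -log2_ratio(B, A) exact
    vals = np.log2(fusion.values + pseudocount) - np.log2(dam.values + pseudocount)
    return FragmentProfile(meta=fusion.meta, unit="log2_ratio", values=vals, map=fusion.map)


def median_center(profile: FragmentProfile) -> FragmentProfile:
    """Subtract the genome-wide median log2 ratio.  Disabled by default in
    the pipeline; provided as an optional between-channel scaling step."""
    if profile.unit != "log2_ratio":
        raise ValueError("median_center expects a log2_ratio profile")
    return replace(profile, values=profile.values - np.median(profile.values))
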