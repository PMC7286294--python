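"""GATC fragment coordinate system and gene annotation.

DamID signal is quantified on the intervals between DpnI cut sites (GATC
motifs).  :func:`build_fragment_map` derives those intervals from genome
sequence; :class:`GatcFragmentMap` is the shared coordinate system every
downstream profile, gene call and peak refers back to.

All internal coordinates are 0-based half-open.  GFF3 input (1-based
inclusive) is converted on read; BED output is written as-is.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

_GATC = re.compile("GATC")

# DpnI cuts GA^TC: fragment boundaries sit at motif start + 2.
CUT_OFFSET = 2


class GatcFragmentMap:
    """Ordered, chromosome-tiling GATC fragment intervals.

    Fragments tile each chromosome exactly (first start 0, last end =
    chromosome length, adjacent fragments abut).  A global fragment index
    runs over chromosomes in the order given at construction.
    """

    def __init__(self, boundaries: Mapping[str, np.ndarray]):
        """``boundaries[chrom]`` is the sorted array of fragment edges,
        beginning with 0 and ending with the chromosome length."""
        self.chroms: list[str] = list(boundaries)
        self._bounds: dict[str, np.ndarray] = {}
        self._offset: dict[str, int] = {}
        off = 0
        for chrom in self.chroms:
            b = np.asarray(boundaries[chrom], dtype=np.int64)
            if b.size < 2 or b[0] != 0 or np.any(np.diff(b) < 1):
                raise ValueError(f"invalid fragment boundaries for {chrom!r}")
            self._bounds[chrom] = b
            self._offset[chrom] = off
            off += b.size - 1
        self._n = off
        starts = np.empty(self._n, dtype=np.int64)
        ends = np.empty(self._n, dtype=np.int64)
        names = []
        for chrom in self.chroms:
            b = self._bounds[chrom]
            o = self._offset[chrom]
            k = b.size - 1
            starts[o:o + k] = b[:-1]
            ends[o:o + k] = b[1:]
            names.extend([chrom] * k)
        self.starts = starts
        self.ends = ends
        self.chrom_of = np.array(names, dtype=object)

    @property
    def n_fragments(self) -> int:
        return self._n

    def chrom_length(self, chrom: str) -> int:
        return int(self._bounds[chrom][-1])

    def chrom_slice(self, chrom: str) -> slice:
        """Global-index slice covering one chromosome's fragments."""
        if chrom not in self._offset:
            raise KeyError(f"unknown chromosome {chrom!r}")
        o = self._offset[chrom]
        return slice(o, o + self._bounds[chrom].size - 1)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def fragments_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of all fragments intersecting ``[start, end)`` by
        at least 1 bp, in genome order."""
        if chrom not in self._bounds:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start >= end:
            raise ValueError(f"empty interval [{start}, {end})")
        b = self._bounds[chrom]
        o = self._offset[chrom]
        lo = int(np.searchsorted(b, start, side="right")) - 1
        hi = int(np.searchsorted(b, end, side="left"))
        lo = max(lo, 0)
        hi = min(hi, b.size - 1)
        if hi <= lo:
            return np.empty(0, dtype=np.int64)
        return np.arange(o + lo, o + hi, dtype=np.int64)

    def same_map(self, other: "GatcFragmentMap") -> bool:
        if self is other:
            return True
        return (
            self.chroms == other.chroms
            and self._n == other._n
            and all(np.array_equal(self._bounds[c], other._bounds[c]) for c in self.chroms)
        )

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i in range(self._n):
                fh.write(f"{self.chrom_of[i]}\t{self.starts[i]}\t{self.ends[i]}\t{i}\n")


def read_fragment_map_bed(path: str | Path) -> GatcFragmentMap:
    """Rebuild a fragment map from the BED written by :meth:`to_bed`."""
    boundaries: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start_s, end_s = line.split("\t")[:3]
            b = boundaries.setdefault(chrom, [0])
            end = int(end_s)
            if int(start_s) != b[-1]:
                raise ValueError(f"fragment BED does not tile {chrom!r}")
            b.append(end)
    return GatcFragmentMap({c: np.array(b, dtype=np.int64) for c, b in boundaries.items()})


def build_fragment_map(sequences: Mapping[str, str] | str | Path) -> GatcFragmentMap:
    """Scan sequences for GATC motifs and tile each chromosome into
    fragments cut at motif start + :data:`CUT_OFFSET`.

    ``sequences`` is either a mapping of name -> sequence or a FASTA path.
    Matching is case-insensitive; ambiguity codes never match.  GATC is its
    own reverse complement, so one strand is scanned.
    """
    if isinstance(sequences, (str, Path)):
        sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(sequences), "fasta")}
    if not sequences:
        raise ValueError("empty sequence set")
    boundaries = {}
    for chrom, seq in sequences.items():
        n = len(seq)
        if n == 0:
            raise ValueError(f"zero-length chromosome {chrom!r}")
        cuts = [m.start() + CUT_OFFSET for m in _GATC.finditer(seq.upper())]
        edges = [0] + [c for c in cuts if 0 < c < n] + [n]
        boundaries[chrom] = np.array(sorted(set(edges)), dtype=np.int64)
    return GatcFragmentMap(boundaries)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.end <= self.start:
            raise ValueError(f"empty gene span for {self.gene_id}")


class AnnotationSet:
    """Genes keyed by id, with a sorted per-chromosome index for
    neighbour and overlap queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self.genes[g.gene_id] = g
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end, g.gene_id))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def chrom_genes(self, chrom: str) -> Sequence[GeneModel]:
        return self._by_chrom.get(chrom, [])

    def all_transcripts(self) -> list[tuple[str, str, str, int, int]]:
        """(transcript_id, gene_id, chrom, start, end) for every transcript,
        in gene-id order."""
        out = []
        for gid in sorted(self.genes):
            g = self.genes[gid]
            for tid, ts, te in g.transcripts:
                out.append((tid, gid, g.chrom, ts, te))
        return out


_TRANSCRIPT_TYPES = {
    "mRNA", "transcript", "tRNA", "rRNA", "snRNA", "snoRNA",
    "ncRNA", "lncRNA", "miRNA", "pre_miRNA", "pseudogenic_transcript",
}


def _gff_attributes(col9: str) -> dict[str, str]:
    attrs = {}
    for part in col9.strip().split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            attrs[k] = v
    return attrs


def read_annotation(path: str | Path) -> AnnotationSet:
    """Read gene/transcript features from GFF3 into an :class:`AnnotationSet`.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Transcripts are attached to their ``Parent`` gene; a gene with no
    annotated transcript gets a single transcript spanning the gene.
    """
    raw_genes: dict[str, GeneModel] = {}
    pending: list[tuple[str, str, int, int, int]] = []  # tid, parent, start, end, lineno
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"malformed GFF3 line {lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ValueError(f"malformed GFF3 line {lineno}: end < start")
            start, end = start1 - 1, end1
            attrs = _gff_attributes(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"GFF3 line {lineno}: gene without ID")
                raw_genes[gid] = GeneModel(gid, chrom, strand if strand in "+-" else "+", start, end)
            elif ftype in _TRANSCRIPT_TYPES:
                tid = attrs.get("ID", f"transcript:{lineno}")
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValueError(f"GFF3 line {lineno}: transcript without Parent")
                pending.append((tid, parent, start, end, lineno))
    for tid, parent, start, end, lineno in pending:
        if parent not in raw_genes:
            raise ValueError(f"GFF3 line {lineno}: transcript {tid!r} references missing gene {parent!r}")
        raw_genes[parent].transcripts.append((tid, start, end))
    for g in raw_genes.values():
        if not g.transcripts:
            g.transcripts.append((f"{g.gene_id}.span", g.start, g.end))
        for tid, ts, te in g.transcripts:
            if te <= ts:
                raise ValueError(f"empty transcript {tid!r}")
            if ts < g.start or te > g.end:
                # widen gene span to cover stray transcripts rather than fail
                g.start = min(g.start, ts)
                g.end = max(g.end, te)
    return AnnotationSet(raw_genes.values())


def write_annotation(annotation: AnnotationSet, path: str | Path) -> None:
    """Write genes and transcripts back to GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(annotation.genes):
            g = annotation[gid]
            fh.write(f"{g.chrom}\ttadakit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={gid}\n")
            for tid, ts, te in g.transcripts:
                fh.write(
                    f"{g.chrom}\ttadakit\tmRNA\t{ts + 1}\t{te}\t.\t{g.strand}\t.\tID={tid};Parent={gid}\n"
                )
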