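"""Readers/writers for external formats and shared interval arithmetic.

All internal coordinates are 0-based half-open on the forward strand.
GFF3 I/O converts to/from its 1-based inclusive convention at the boundary;
bedGraph is already 0-based half-open.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from intervaltree import IntervalTree

VALID_BASES = set("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval: start={self.start} end={self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance(self, other: "GenomicInterval") -> int:
        """Gap in bp between the two intervals; 0 if they touch or overlap."""
        if self.contig != other.contig:
            raise ValueError("distance across contigs is undefined")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


class GenomeSequence:
    """Named contigs of uppercase nucleotide sequence over {A,C,G,T,N}."""

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise ValueError("genome must contain at least one contig")
        clean: dict[str, str] = {}
        for name, seq in contigs.items():
            if not name:
                raise ValueError("contig names must be non-empty")
            seq = seq.upper().replace("U", "T")
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"contig {name!r} has illegal characters {sorted(bad)}")
            clean[name] = seq
        self.contigs = clean

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.contigs.items()}

    def fetch(self, iv: GenomicInterval) -> str:
        """Sequence of `iv` on the forward strand, reverse-complemented for '-'."""
        if iv.end > self.length(iv.contig):
            raise ValueError(f"interval {iv} exceeds contig length")
        seq = self.contigs[iv.contig][iv.start : iv.end]
        return revcomp(seq) if iv.strand == "-" else seq


@dataclass
class GffRecord:
    """One GFF3 line; non-coordinate columns are kept verbatim for round trips."""

    interval: GenomicInterval
    type: str
    source: str = "."
    score: str = "."
    phase: str = "."
    attributes: str = "."

    def attr_map(self) -> dict[str, str]:
        out = {}
        for part in self.attributes.split(";"):
            if "=" in part:
                k, v = part.split("=", 1)
                out[k.strip()] = v.strip()
        return out


class AnnotationSet:
    """GFF3-derived records queryable by overlap in O(log n) per query."""

    def __init__(self, records: list[GffRecord] | None = None):
        self.records: list[GffRecord] = []
        self._trees: dict[str, IntervalTree] = {}
        for rec in records or []:
            self.add(rec)

    def add(self, rec: GffRecord) -> None:
        idx = len(self.records)
        self.records.append(rec)
        tree = self._trees.setdefault(rec.interval.contig, IntervalTree())
        tree.addi(rec.interval.start, rec.interval.end, idx)

    def __len__(self) -> int:
        return len(self.records)

    def overlapping(self, iv: GenomicInterval) -> list[GffRecord]:
        tree = self._trees.get(iv.contig)
        if tree is None:
            return []
        hits = sorted(h.data for h in tree.overlap(iv.start, iv.end))
        return [self.records[i] for i in hits]

    def any_overlap(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.contig)
        return bool(tree is not None and tree.overlap(iv.start, iv.end))


@dataclass
class CoverageTrack:
    """Per-contig binned read density for one molecule class and condition."""

    bin_size: int
    values: dict[str, np.ndarray]
    normalization: str = "raw"  # {raw, RPKM}
    molecule: str = "sRNA"  # {sRNA, mRNA}
    condition: str = ""

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for c, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"track values for {c!r} must be finite and >= 0")
            self.values[c] = v

    def n_bins(self, contig: str) -> int:
        return len(self.values[contig])

    def same_binning(self, other: "CoverageTrack") -> bool:
        return self.bin_size == other.bin_size and set(self.values) == set(
            other.values
        ) and all(len(self.values[c]) == len(other.values[c]) for c in self.values)

    @classmethod
    def zeros(cls, genome_lengths: dict[str, int], bin_size: int, **kw) -> "CoverageTrack":
        vals = {
            c: np.zeros(math.ceil(n / bin_size)) for c, n in genome_lengths.items()
        }
        return cls(bin_size=bin_size, values=vals, **kw)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> GenomeSequence:
    """Parse a FASTA file into a GenomeSequence.

    Sequences are uppercased and U is mapped to T. Gap characters or any
    character outside {A,C,G,T,N,U} raise ParseError naming the line.
    """
    contigs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"line {lineno}: empty FASTA header")
                if name in contigs:
                    raise ParseError(f"line {lineno}: duplicate contig {name!r}")
                contigs[name] = []
            else:
                if name is None:
                    raise ParseError(f"line {lineno}: sequence before first header")
                chunk = line.upper().replace("U", "T")
                bad = set(chunk) - VALID_BASES
                if bad:
                    raise ParseError(
                        f"line {lineno}: illegal character(s) {sorted(bad)}"
                    )
                contigs[name].append(chunk)
    if not contigs:
        raise ParseError("line 0: no FASTA records found")
    return GenomeSequence({n: "".join(parts) for n, parts in contigs.items()})


def write_fasta(genome: GenomeSequence, path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | os.PathLike) -> AnnotationSet:
    """Read GFF3 (1-based inclusive) into internal 0-based half-open records."""
    out = AnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"line {lineno}: expected 9 columns, got {len(cols)}")
            contig, source, ftype, start, end, score, strand, phase, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates") from None
            if end_i < start_i:
                raise ParseError(f"line {lineno}: end < start")
            if strand not in ("+", "-", "."):
                raise ParseError(f"line {lineno}: bad strand {strand!r}")
            iv = GenomicInterval(contig, start_i - 1, end_i, strand)
            out.add(GffRecord(iv, ftype, source=source, score=score, phase=phase,
                              attributes=attrs))
    return out


def write_gff3(annotations: AnnotationSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in annotations.records:
            iv = rec.interval
            fh.write(
                "\t".join(
                    [iv.contig, rec.source, rec.type, str(iv.start + 1), str(iv.end),
                     rec.score, iv.strand, rec.phase, rec.attributes]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(
    path: str | os.PathLike,
    bin_size: int,
    genome_lengths: dict[str, int],
    **track_kw,
) -> CoverageTrack:
    """Rasterize a (possibly sparse) bedGraph onto fixed bins.

    Bin value is the length-weighted mean of interval values over the bin,
    with absent positions contributing zero. Overlapping input intervals are
    rejected as ambiguous.
    """
    track = CoverageTrack.zeros(genome_lengths, bin_size, **track_kw)
    last_end: dict[str, int] = {}
    seen: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) != 4:
                raise ParseError(f"line {lineno}: expected 4 columns")
            contig, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            if contig not in genome_lengths:
                raise ParseError(f"line {lineno}: unknown contig {contig!r}")
            if end <= start:
                raise ParseError(f"line {lineno}: end <= start")
            for s0, e0 in seen.setdefault(contig, []):
                if start < e0 and s0 < end:
                    raise ParseError(f"line {lineno}: overlapping intervals (ambiguous density)")
            seen[contig].append((start, end))
            vals = track.values[contig]
            b0, b1 = start // bin_size, (end - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo, hi = max(start, b * bin_size), min(end, (b + 1) * bin_size)
                vals[b] += value * (hi - lo) / bin_size
            last_end[contig] = max(last_end.get(contig, 0), end)
    return track


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Write bins as runs of equal value; zero runs are omitted (sparse)."""
    with open(path, "w") as fh:
        for contig in track.values:
            vals = track.values[contig]
            i = 0
            n = len(vals)
            while i < n:
                j = i
                while j < n and vals[j] == vals[i]:
                    j += 1
                if vals[i] != 0.0:
                    # repr round-trips the float exactly, keeping
                    # rasterize(write(read(x))) a fixpoint
                    fh.write(
                        f"{contig}\t{i * track.bin_size}\t{j * track.bin_size}"
                        f"\t{float(vals[i])!r}\n"
                    )
                i = j


# ---------------------------------------------------------------------------
# Mapped small-RNA reads

READS_TSV_HEADER = "#contig\tstart\tend\tstrand\tcount"


def read_reads(path: str | os.PathLike, genome: GenomeSequence | None = None):
    """Read mapped reads from the documented TSV or from SAM.

    TSV columns: contig, start (0-based), end (exclusive), strand, count.
    The 5' nucleotide is derived from the genome when one is supplied
    (minus-strand reads take the complement of the base at end-1).
    """
    from .srnaprof import ReadRecord

    path = os.fspath(path)
    if path.endswith(".sam"):
        return _read_sam(path, genome)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError(f"line {lineno}: expected >=4 columns")
            contig, start, end, strand = cols[0], int(cols[1]), int(cols[2]), cols[3]
            count = int(cols[4]) if len(cols) > 4 else 1
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: unknown strand symbol {strand!r}")
            if end <= start:
                raise ParseError(f"line {lineno}: end <= start")
            iv = GenomicInterval(contig, start, end, strand)
            out.append(
                ReadRecord(
                    interval=iv,
                    strand=strand,
                    length=end - start,
                    five_prime_nt=_five_prime_nt(genome, iv),
                    count=count,
                )
            )
    return out


def _five_prime_nt(genome: GenomeSequence | None, iv: GenomicInterval) -> str | None:
    """Biological 5' nucleotide of a mapped read, in RNA alphabet."""
    if genome is None:
        return None
    if iv.strand == "-":
        base = genome.contigs[iv.contig][iv.end - 1].translate(COMPLEMENT)
    else:
        base = genome.contigs[iv.contig][iv.start]
    return "U" if base == "T" else base


def _read_sam(path: str, genome: GenomeSequence | None):
    import pysam

    from .srnaprof import ReadRecord

    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            iv = GenomicInterval(
                aln.reference_name, aln.reference_start, aln.reference_end, strand
            )
            out.append(
                ReadRecord(
                    interval=iv,
                    strand=strand,
                    length=len(iv),
                    five_prime_nt=_five_prime_nt(genome, iv),
                    count=1,
                )
            )
    return out


def write_reads(reads, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(READS_TSV_HEADER + "\n")
        for r in reads:
            iv = r.interval
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{r.strand}\t{r.count}\n")
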