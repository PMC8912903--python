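"""Synthetic genome generator with planted LTR retroelements and read/coverage
simulation carrying the statistical structure the discovery analysis assumes.

The generator emulates the study system: a small multi-contig genome whose
"centromeric" windows are dense arrays of LTR retrotransposons from several
families in two lineages (Tf-like and Ty3-like), with

* wild-type small-RNA populations over every element: dual-strand, 23-24 nt
  modal length, 5'-uridine biased (bona fide siRNAs);
* loss of those siRNAs in the RNAi mutant, replaced - for one designated
  "mobilizing" family only - by sense-only degradation-like species of broad
  length; and
* mRNA coverage elevated over elements in the mutant.

Every planted feature is recorded in a TruthSet so downstream stages can be
scored for recall, precision, boundary accuracy and family recovery.

Randomness is split into one stream per artifact (genome, reads, coverage),
seeded as seed+offset, so regenerating reads never perturbs the genome.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import references
from .formats_io import (
    AnnotationSet,
    CoverageTrack,
    GenomeSequence,
    GenomicInterval,
    GffRecord,
    revcomp,
)

_STOPS = {"TAA", "TAG", "TGA"}

FULL_LENGTH = "full_length"
PARTIAL = "partial"
SOLO_LTR = "solo_LTR"


@dataclass
class SynthConfig:
    seed: int = 1
    contig_lengths: tuple[int, ...] = (800_000, 700_000, 500_000)
    gc: float = 0.40
    n_families: int = 5
    full_per_family: int = 2
    partial_per_family: int = 3
    solo_per_family: int = 3
    element_length: int = 5000
    ltr_length: int = 300
    within_family_divergence: float = 0.02
    between_family_divergence: float = 0.20
    sirna_reads_per_element: int = 2000
    sirna_length_probs: dict[int, float] = field(
        default_factory=lambda: {
            20: 0.05, 21: 0.05, 22: 0.05, 23: 0.35, 24: 0.35, 25: 0.05,
            26: 0.05, 27: 0.05,
        }
    )
    antisense_fraction: float = 0.5
    five_prime_u_target: float = 0.75
    degradation_reads_per_element: int = 2000
    degradation_length_range: tuple[int, int] = (18, 30)
    mobilizing_family_index: int = 2
    mrna_fold: float = 8.0
    mrna_background_rpkm: float = 5.0
    mrna_depth: float = 4.0  # expected read counts per RPKM unit per bin
    bin_size: int = 50
    minus_strand_fraction: float = 0.3
    n_clusters: int = 4
    n_gene_annotations: int = 25
    # array geometry: tight packing inside TE arrays, wide berth around solos
    # (so lone LTRs sit clear of coding elements, as recombination relics do)
    element_gap: tuple[int, int] = (60, 160)
    solo_gap: tuple[int, int] = (1300, 1800)
    min_spacer: int = 900
    partial_flank: tuple[int, int] = (30, 150)

    def validate(self) -> None:
        for p in (
            self.gc, self.within_family_divergence, self.between_family_divergence,
            self.antisense_fraction, self.five_prime_u_target,
            self.minus_strand_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        if abs(sum(self.sirna_length_probs.values()) - 1.0) > 1e-9:
            raise ValueError("siRNA length distribution must sum to 1")
        if min(self.contig_lengths, default=0) <= 0 or self.element_length <= 0:
            raise ValueError("lengths must be positive")
        if self.ltr_length <= 0 or self.bin_size <= 0:
            raise ValueError("lengths must be positive")
        planted = self.n_families * (
            self.full_per_family * self.element_length
            + self.partial_per_family * self.element_length // 2
            + self.solo_per_family * self.ltr_length
        )
        if planted > 0.4 * sum(self.contig_lengths):
            raise ValueError("planted sequence exceeds 40% of the genome")


@dataclass
class TruthElement:
    interval: GenomicInterval
    element_class: str
    family: str
    lineage: str
    ltrs: list[GenomicInterval] = field(default_factory=list)
    domains: list[tuple[str, GenomicInterval]] = field(default_factory=list)


@dataclass
class TruthSet:
    elements: list[TruthElement]
    mobilizing_family: str = ""

    def of_class(self, cls: str) -> list[TruthElement]:
        return [e for e in self.elements if e.element_class == cls]

    @property
    def coding_elements(self) -> list[TruthElement]:
        return [e for e in self.elements if e.element_class != SOLO_LTR]


# ---------------------------------------------------------------------------
# sequence-building helpers

def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def mutate_nt(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution at the given rate (no indels)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hit:
        cur = arr[i]
        options = bases[bases != cur]
        arr[i] = options[rng.integers(len(options))]
    return arr.tobytes().decode()


def _mutate_element(
    seq: str, rate: float, rng: np.random.Generator, orf_start: int, orf_end: int
) -> str:
    """Substitutions at ``rate`` that never introduce a stop codon inside the
    coding cassette (purifying selection on functional copies)."""
    if rate <= 0:
        return seq
    out = list(seq)
    hit = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hit:
        cur = out[i]
        options = [b for b in "ACGT" if b != cur]
        rng.shuffle(options)
        if orf_start <= i < orf_end - 3:  # keep the terminal stop itself intact
            codon_start = orf_start + ((i - orf_start) // 3) * 3
            placed = False
            for b in options:
                codon = out[codon_start : codon_start + 3]
                codon[i - codon_start] = b
                if "".join(codon) not in _STOPS:
                    out[i] = b
                    placed = True
                    break
            if not placed:
                continue  # every substitution would create a stop; skip site
        else:
            out[i] = options[0]
    return "".join(out)


@dataclass
class _Item:
    """One sequence to paste into the genome, with local truth coordinates."""

    seq: str
    element_class: str
    family: str
    lineage: str
    strand: str
    ltr_locals: list[tuple[int, int]] = field(default_factory=list)
    domain_locals: list[tuple[str, tuple[int, int]]] = field(default_factory=list)


def _build_family(
    idx: int, config: SynthConfig, rng: np.random.Generator
) -> tuple[str, str, dict]:
    """Assemble a family ancestor: LTR + spacer + in-frame domain cassette +
    spacer + LTR, derived from the bundled lineage references."""
    lineage = references.LINEAGES[1 - idx % 2]  # ty3_like for even indices
    family = f"fam{idx + 1}"
    proteins = references.lineage_proteins(lineage)
    order = references.CASSETTE_ORDER[lineage]
    orf = "ATG" + references.back_translate(
        "".join(proteins[d] for d in order), rng
    ) + "TAA"
    # family LTR diverges from the lineage ancestor; stop islands are
    # re-applied afterwards so the repeat stays ORF-free in every family
    ltr = references.sprinkle_stop_islands(
        mutate_nt(
            references.lineage_ltr(lineage, config.ltr_length),
            config.between_family_divergence,
            rng,
        )
    )
    s_total = config.element_length - 2 * config.ltr_length - len(orf)
    if s_total < 2 * config.min_spacer:
        raise ValueError(
            "element_length too small for LTRs + cassette + minimum spacers"
        )
    # fixed split: same-lineage families share their internal geometry, as
    # copies of a common ancestral layout do
    s1 = s_total // 2
    s2 = s_total - s1
    # spacers are non-coding: periodic stop islands keep every frame closed
    ancestor = (
        ltr
        + references.sprinkle_stop_islands(_random_nt(rng, s1, config.gc))
        + orf
        + references.sprinkle_stop_islands(_random_nt(rng, s2, config.gc))
        + ltr
    )
    orf_start = config.ltr_length + s1
    domains = []
    pos = orf_start + 3
    for d in order:
        L = 3 * len(proteins[d])
        domains.append((d, (pos, pos + L)))
        pos += L
    meta = {
        "ancestor": ancestor,
        "ltr": ltr,
        "orf_span": (orf_start, orf_start + len(orf)),
        "ltr_locals": [
            (0, config.ltr_length),
            (len(ancestor) - config.ltr_length, len(ancestor)),
        ],
        "domains": domains,
    }
    return family, lineage, meta


def _family_items(
    family: str, lineage: str, meta: dict, config: SynthConfig,
    rng: np.random.Generator,
) -> list[_Item]:
    items: list[_Item] = []
    orf_s, orf_e = meta["orf_span"]
    rt_idx = next(
        i for i, (d, _) in enumerate(meta["domains"])
        if d == "reverse_transcriptase"
    )
    for _ in range(config.full_per_family):
        seq = _mutate_element(
            meta["ancestor"], config.within_family_divergence, rng, orf_s, orf_e
        )
        items.append(
            _Item(seq, FULL_LENGTH, family, lineage, _pick_strand(rng, config),
                  ltr_locals=list(meta["ltr_locals"]),
                  domain_locals=[(d, span) for d, span in meta["domains"]])
        )
    for _ in range(config.partial_per_family):
        seq = _mutate_element(
            meta["ancestor"], config.within_family_divergence, rng, orf_s, orf_e
        )
        n_dom = len(meta["domains"])
        a = int(rng.integers(0, rt_idx + 1))
        b = int(rng.integers(rt_idx, n_dom))
        lo = meta["domains"][a][1][0]
        hi = meta["domains"][b][1][1]
        fl1 = int(rng.integers(*config.partial_flank))
        fl2 = int(rng.integers(*config.partial_flank))
        cut0, cut1 = lo - fl1, hi + fl2
        frag = seq[cut0:cut1]
        doms = [
            (d, (s - cut0, e - cut0))
            for d, (s, e) in meta["domains"][a : b + 1]
        ]
        items.append(
            _Item(frag, PARTIAL, family, lineage, _pick_strand(rng, config),
                  domain_locals=doms)
        )
    for _ in range(config.solo_per_family):
        seq = mutate_nt(meta["ltr"], config.within_family_divergence, rng)
        items.append(
            _Item(seq, SOLO_LTR, family, lineage, _pick_strand(rng, config),
                  ltr_locals=[(0, len(seq))])
        )
    return items


def _pick_strand(rng: np.random.Generator, config: SynthConfig) -> str:
    return "-" if rng.random() < config.minus_strand_fraction else "+"


def _arrange(items: list[_Item], rng: np.random.Generator) -> list[_Item]:
    """Order items so no two neighbours share a family, solo-LTRs at the array
    margins (they need clear flanks; see module docstring)."""
    solos = [i for i in items if i.element_class == SOLO_LTR]
    coding = [i for i in items if i.element_class != SOLO_LTR]
    for _ in range(2000):
        rng.shuffle(solos)
        rng.shuffle(coding)
        half = len(solos) // 2
        order = solos[:half] + coding + solos[half:]
        # no family recurs within a window of three consecutive items:
        # nearby same-family repeat copies (an element's LTRs, or solos)
        # could otherwise mimic a neighbouring element's border repeats
        if all(
            order[i].family != order[j].family
            for i in range(len(order))
            for j in (i + 1, i + 2)
            if j < len(order)
        ):
            return order
    # single-family (or otherwise constrained) clusters cannot satisfy the
    # interleaving rule; fall back to the last shuffle
    warnings.warn("cluster arranged with same-family neighbours; adjacent "
                  "same-family repeats may confound border detection")
    return order


def build_genome(config: SynthConfig) -> tuple[GenomeSequence, TruthSet]:
    """Generate the background genome and paste planted elements into
    clustered 'centromeric' windows; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed + 0)
    contig_names = [f"contig{i + 1}" for i in range(len(config.contig_lengths))]
    backgrounds = [
        np.frombuffer(_random_nt(rng, n, config.gc).encode(), dtype="S1").copy()
        for n in config.contig_lengths
    ]

    all_items: list[list[_Item]] = [[] for _ in range(config.n_clusters)]
    mobilizing = ""
    for idx in range(config.n_families):
        family, lineage, meta = _build_family(idx, config, rng)
        if idx == config.mobilizing_family_index % max(config.n_families, 1):
            mobilizing = family
        items = _family_items(family, lineage, meta, config, rng)
        for k, item in enumerate(items):
            all_items[(idx + k) % config.n_clusters].append(item)

    elements: list[TruthElement] = []
    per_contig_clusters: dict[int, int] = {}
    for c in range(config.n_clusters):
        per_contig_clusters[c % len(contig_names)] = (
            per_contig_clusters.get(c % len(contig_names), 0) + 1
        )
    seen_in_contig: dict[int, int] = {}
    for c, items in enumerate(all_items):
        if not items:
            continue
        order = _arrange(items, rng)
        ci = c % len(contig_names)
        slot = seen_in_contig.get(ci, 0)
        seen_in_contig[ci] = slot + 1
        n_slots = per_contig_clusters[ci]
        anchor = int((slot + 1) * config.contig_lengths[ci] / (n_slots + 1))
        pos = anchor
        prev_solo = False
        for item in order:
            is_solo = item.element_class == SOLO_LTR
            if pos != anchor:
                lo, hi = (
                    config.solo_gap if (is_solo or prev_solo) else config.element_gap
                )
                pos += int(rng.integers(lo, hi + 1))
            seq = revcomp(item.seq) if item.strand == "-" else item.seq
            L = len(seq)
            if pos + L > config.contig_lengths[ci] - 5000:
                raise ValueError("placement impossible: cluster exceeds contig")
            backgrounds[ci][pos : pos + L] = np.frombuffer(
                seq.encode(), dtype="S1"
            )
            elements.append(
                _to_truth(item, contig_names[ci], pos, L)
            )
            pos += L
            prev_solo = is_solo
    genome = GenomeSequence(
        {n: b.tobytes().decode() for n, b in zip(contig_names, backgrounds)}
    )
    elements.sort(key=lambda e: (e.interval.contig, e.interval.start))
    return genome, TruthSet(elements=elements, mobilizing_family=mobilizing)


def _to_truth(item: _Item, contig: str, pos: int, L: int) -> TruthElement:
    def map_local(span: tuple[int, int]) -> GenomicInterval:
        a, b = span
        if item.strand == "-":
            a, b = L - b, L - a
        return GenomicInterval(contig, pos + a, pos + b, item.strand)

    return TruthElement(
        interval=GenomicInterval(contig, pos, pos + L, item.strand),
        element_class=item.element_class,
        family=item.family,
        lineage=item.lineage,
        ltrs=[map_local(s) for s in item.ltr_locals],
        domains=[(d, map_local(s)) for d, s in item.domain_locals],
    )


def simulate_annotations(
    genome: GenomeSequence, truth: TruthSet, config: SynthConfig
) -> AnnotationSet:
    """Pre-existing gene annotations placed in background sequence, clear of
    the planted arrays (the discovery signature excludes annotated regions)."""
    rng = np.random.default_rng(config.seed + 7)
    out = AnnotationSet()
    names = list(genome.contigs)
    placed: list[GenomicInterval] = []
    margin = 3000
    tries = 0
    while len(out) < config.n_gene_annotations and tries < 10_000:
        tries += 1
        ci = int(rng.integers(len(names)))
        length = int(rng.integers(500, 2001))
        start = int(rng.integers(0, genome.length(names[ci]) - length))
        iv = GenomicInterval(names[ci], start, start + length,
                             "+" if rng.random() < 0.5 else "-")
        grown = GenomicInterval(iv.contig, max(0, iv.start - margin),
                                iv.end + margin)
        if any(grown.overlaps(e.interval) for e in truth.elements):
            continue
        if any(grown.overlaps(p) for p in placed):
            continue
        placed.append(iv)
        out.add(GffRecord(iv, "gene", source="synthio",
                          attributes=f"ID=gene{len(out) + 1}"))
    return out


# ---------------------------------------------------------------------------
# read simulation

def simulate_reads(
    genome: GenomeSequence, truth: TruthSet, config: SynthConfig, condition: str
):
    """Simulate mapped small-RNA reads for one condition.

    wild_type: per coding element, ``sirna_reads_per_element`` reads with the
    configured length distribution, Bernoulli(antisense_fraction) strand and a
    biased choice of start site so the realized 5'U fraction matches the
    configured target (starts are chosen among genuine genomic positions; bases
    are never overwritten). mutant: sense-only degradation-like reads of broad
    uniform length over the mobilizing family only, no 5' preference.
    """
    from .srnaprof import ReadRecord

    if condition not in ("wild_type", "mutant"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(
        config.seed + (1 if condition == "wild_type" else 2)
    )
    reads: list[ReadRecord] = []
    for el in truth.coding_elements:
        iv = el.interval
        if condition == "wild_type":
            n = config.sirna_reads_per_element
            lengths_list = sorted(config.sirna_length_probs)
            probs = [config.sirna_length_probs[l] for l in lengths_list]
            if len(iv) <= max(lengths_list):
                warnings.warn(f"element {iv} shorter than max read length; skipped")
                continue
            lens = rng.choice(lengths_list, size=n, p=probs)
            anti = rng.random(n) < config.antisense_fraction
            want_u = rng.random(n) < config.five_prime_u_target
            sense_strand = iv.strand if iv.strand in "+-" else "+"
            seq = genome.contigs[iv.contig][iv.start : iv.end]
            arr = np.frombuffer(seq.encode(), dtype="S1")
            is_t = arr == b"T"  # 5'U for a plus-strand read starting here
            is_a = arr == b"A"  # complement is U: 5' end of a minus-strand read
            for l in np.unique(lens):
                R = len(iv) - int(l) + 1
                for a_flag in (False, True):
                    strand = _flip(sense_strand) if a_flag else sense_strand
                    u_mask = is_t[:R] if strand == "+" else is_a[int(l) - 1 :][:R]
                    for u_flag in (False, True):
                        sel = (lens == l) & (anti == a_flag) & (want_u == u_flag)
                        cnt = int(sel.sum())
                        if cnt == 0:
                            continue
                        pool = np.flatnonzero(u_mask if u_flag else ~u_mask)
                        if len(pool) == 0:
                            pool = np.arange(R)
                        starts = rng.choice(pool, size=cnt)
                        for s in starts:
                            reads.append(_make_read(genome, iv, int(s), int(l), strand))
        else:
            if el.family != truth.mobilizing_family:
                continue
            n = config.degradation_reads_per_element
            lo, hi = config.degradation_length_range
            if len(iv) <= hi:
                warnings.warn(f"element {iv} shorter than max read length; skipped")
                continue
            lens = rng.integers(lo, hi + 1, size=n)
            sense_strand = iv.strand if iv.strand in "+-" else "+"
            for l in lens:
                s = int(rng.integers(0, len(iv) - int(l) + 1))
                reads.append(_make_read(genome, iv, s, int(l), sense_strand))
    return reads


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _make_read(genome: GenomeSequence, el: GenomicInterval, offset: int,
               length: int, strand: str):
    from .formats_io import _five_prime_nt
    from .srnaprof import ReadRecord

    iv = GenomicInterval(el.contig, el.start + offset, el.start + offset + length,
                         strand)
    return ReadRecord(
        interval=iv, strand=strand, length=length,
        five_prime_nt=_five_prime_nt(genome, iv), count=1,
    )


# ---------------------------------------------------------------------------
# coverage simulation

def simulate_coverage(
    genome: GenomeSequence,
    truth: TruthSet,
    config: SynthConfig,
    molecule: str,
    condition: str,
    reads=None,
) -> CoverageTrack:
    """RPKM coverage tracks: mRNA is background + fold-increase over elements
    in the mutant with Poisson bin noise; sRNA is rasterized from reads."""
    if molecule == "mRNA":
        offset = 3 if condition == "wild_type" else 4
        rng = np.random.default_rng(config.seed + offset)
        track = CoverageTrack.zeros(
            genome.lengths, config.bin_size, normalization="RPKM",
            molecule="mRNA", condition=condition,
        )
        for contig, vals in track.values.items():
            lam = np.full(len(vals), config.mrna_background_rpkm)
            if condition == "mutant":
                for el in truth.coding_elements:
                    if el.interval.contig != contig:
                        continue
                    _add_element_signal(
                        lam, el.interval, config.bin_size,
                        config.mrna_background_rpkm * (config.mrna_fold - 1.0),
                    )
            counts = rng.poisson(lam * config.mrna_depth)
            track.values[contig] = counts / config.mrna_depth
        return track
    if molecule != "sRNA":
        raise ValueError(f"unknown molecule {molecule!r}")
    if reads is None:
        reads = simulate_reads(genome, truth, config, condition)
    return rasterize_reads(reads, genome.lengths, config.bin_size,
                           condition=condition)


def _add_element_signal(lam: np.ndarray, iv: GenomicInterval, bin_size: int,
                        amount: float) -> None:
    b0, b1 = iv.start // bin_size, (iv.end - 1) // bin_size
    for b in range(b0, b1 + 1):
        lo = max(iv.start, b * bin_size)
        hi = min(iv.end, (b + 1) * bin_size)
        lam[b] += amount * (hi - lo) / bin_size


def rasterize_reads(reads, genome_lengths: dict[str, int], bin_size: int,
                    condition: str = "") -> CoverageTrack:
    """Overlap-weighted read counts per bin, RPKM-normalized to library size."""
    track = CoverageTrack.zeros(genome_lengths, bin_size, normalization="RPKM",
                                molecule="sRNA", condition=condition)
    total = sum(r.count for r in reads)
    for r in reads:
        iv = r.interval
        vals = track.values[iv.contig]
        b0, b1 = iv.start // bin_size, (iv.end - 1) // bin_size
        for b in range(b0, min(b1 + 1, len(vals))):
            lo = max(iv.start, b * bin_size)
            hi = min(iv.end, (b + 1) * bin_size)
            vals[b] += r.count * (hi - lo) / len(iv)
    if total > 0:
        scale = 1.0 / ((bin_size / 1000.0) * (total / 1e6))
        for contig in track.values:
            track.values[contig] *= scale
    return track


# ---------------------------------------------------------------------------
# truth <-> GFF3

def truth_to_annotations(truth: TruthSet) -> AnnotationSet:
    out = AnnotationSet()
    for i, el in enumerate(truth.elements, 1):
        eid = f"te{i}"
        attrs = (
            f"ID={eid};class={el.element_class};family={el.family};"
            f"lineage={el.lineage}"
        )
        out.add(GffRecord(el.interval, "transposable_element", source="synthio",
                          attributes=attrs))
        for j, ltr in enumerate(el.ltrs, 1):
            out.add(GffRecord(ltr, "long_terminal_repeat", source="synthio",
                              attributes=f"ID={eid}.ltr{j};Parent={eid}"))
        for d, iv in el.domains:
            out.add(GffRecord(iv, "protein_match", source="synthio",
                              attributes=f"Parent={eid};Name={d}"))
    return out


def truth_from_annotations(annotations: AnnotationSet) -> TruthSet:
    elements: dict[str, TruthElement] = {}
    for rec in annotations.records:
        attrs = rec.attr_map()
        if rec.type == "transposable_element":
            elements[attrs["ID"]] = TruthElement(
                interval=rec.interval,
                element_class=attrs["class"],
                family=attrs["family"],
                lineage=attrs["lineage"],
            )
        elif rec.type == "long_terminal_repeat":
            elements[attrs["Parent"]].ltrs.append(rec.interval)
        elif rec.type == "protein_match":
            elements[attrs["Parent"]].domains.append((attrs["Name"], rec.interval))
    out = sorted(elements.values(), key=lambda e: (e.interval.contig,
                                                   e.interval.start))
    return TruthSet(elements=out)
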