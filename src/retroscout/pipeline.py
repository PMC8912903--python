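"""End-to-end discovery pipeline and evaluation against a planted truth set.

Stage order follows the discovery procedure: differential-signature candidate
regions -> protein-domain scan -> direct-repeat (LTR) border definition and
classification -> genome-wide copy search -> family clustering and lineage
assignment -> solo-LTR search -> small-RNA profiling. Between the signature
and annotation stages the acceptance rule is enforced: candidate regions are
carried forward only if they are longer than 1 kb AND contain at least one
retrotransposon-related protein motif.

Merged candidate regions in dense element arrays can span several cassettes;
they are segmented by the order of domain ranks along the genome (a cassette
is a strictly increasing run of gag < protease < RT < RNase H < integrase <
chromodomain on '+', decreasing on '-'), and the direct-repeat search for
each cassette is capped at the neighbouring cassettes' anchors so an element
can never borrow a repeat copy from beyond its immediate neighbours.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import references, signature, synthio
from .domains import CORE_DOMAINS, DOMAIN_RANK, DomainHit, resolve_overlapping_hits, scan_domains
from .family import DomainTriplet, Family, LineageTree, assign_lineages, cluster_families
from .formats_io import (
    AnnotationSet,
    CoverageTrack,
    GenomeSequence,
    GenomicInterval,
    GffRecord,
    write_bedgraph,
    write_fasta,
    write_gff3,
    write_reads,
)
from .genomescan import find_copies, find_solo_ltrs
from .ltr import FULL_LENGTH, PARTIAL, SOLO_LTR, ElementCall, classify_element, find_direct_repeats
from .srnaprof import ReadIndex, SirnaClassParams, classify_profile, profile_small_rnas

logger = logging.getLogger("retroscout")


@dataclass
class LtrParams:
    flank: int = 5000
    k: int = 12
    min_len: int = 100
    min_identity: float = 0.80
    # reach of the widened (second-pass) border search beyond a cassette:
    # generous enough for a spacer plus LTR, short enough not to recruit
    # repeat copies from deeper in a dense array
    retry_reach: int = 2000


@dataclass
class CopyParams:
    # word size 12 (blastn-like): at the ~75% nucleotide identity of
    # same-lineage cross-family matches, exact 15-mers are too sparse to
    # seed short copies reliably
    k: int = 12
    min_len: int = 200
    min_identity: float = 0.70


@dataclass
class PipelineConfig:
    seed: int = 1
    synth: synthio.SynthConfig = field(default_factory=synthio.SynthConfig)
    thresholds: signature.SignatureThresholds = field(
        default_factory=signature.SignatureThresholds
    )
    ltr: LtrParams = field(default_factory=LtrParams)
    copies: CopyParams = field(default_factory=CopyParams)
    sirna: SirnaClassParams = field(default_factory=SirnaClassParams)
    domain_alpha: float = 1e-3
    domain_null_draws: int = 1000
    family_threshold: float = 0.95
    solo_exclusion: int = 1000
    solo_min_identity: float = 0.80
    region_pad: int = 600
    cassette_gap: int = 1500
    # a hit defines element structure only if it scores at least this
    # fraction of the way from the calibrated null threshold to the model's
    # consensus score: genuine (even diverged) domains sit above ~0.6, while
    # chimeric bridges across element junctions and composition noise stay
    # below ~0.3
    structural_score_fraction: float = 0.4
    reciprocal_overlap: float = 0.5
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build from a (TOML-derived) mapping; unknown keys are rejected."""
        def build(klass, d: dict):
            names = {f.name: f for f in dataclasses.fields(klass)}
            unknown = set(d) - set(names)
            if unknown:
                raise ValueError(f"unknown config key(s) {sorted(unknown)} "
                                 f"for {klass.__name__}")
            kwargs = {}
            for k, v in d.items():
                ftype = names[k].type
                if isinstance(v, dict):
                    sub = names[k].default_factory()  # type: ignore[misc]
                    kwargs[k] = build(type(sub), v)
                elif k == "sirna_length_probs":
                    kwargs[k] = {int(a): float(b) for a, b in v.items()}
                elif k in ("contig_lengths", "degradation_length_range",
                           "element_gap", "solo_gap", "partial_flank",
                           "modal_lengths"):
                    kwargs[k] = tuple(v)
                else:
                    kwargs[k] = v
            return klass(**kwargs)

        cfg = build(cls, data)
        if "seed" in data and "synth" in data and "seed" not in data["synth"]:
            cfg.synth.seed = cfg.seed
        elif "seed" in data:
            cfg.synth.seed = cfg.seed
        return cfg


@dataclass
class EvaluationReport:
    precision: dict[str, float]
    recall: dict[str, float]
    confusion: dict[str, dict[str, int]]
    called_base_precision: float
    boundary_errors: list[int]
    clustering_ari: float | None
    lineage_accuracy: float | None
    classifier_accuracy: float | None
    n_calls: int
    n_truth: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    genome: GenomeSequence
    truth: synthio.TruthSet | None
    annotations: AnnotationSet
    candidates: list
    calls: list[ElementCall]
    families: list[Family]
    lineages: LineageTree | None
    profiles: list[dict]
    report: EvaluationReport | None
    tracks: dict[str, CoverageTrack] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# cassette segmentation

def segment_cassettes(hits: list[DomainHit], max_gap: int) -> list[list[DomainHit]]:
    """Split a region's domain hits into per-element cassettes.

    Within one cassette, domain ranks increase strictly along the genome on
    '+' (decrease on '-') and neighbouring hits are close; a rank reversal or
    a large gap starts a new cassette.
    """
    cassettes: list[list[DomainHit]] = []
    for strand in ("+", "-"):
        sh = sorted(
            (h for h in hits if h.interval.strand == strand),
            key=lambda h: h.interval.start,
        )
        current: list[DomainHit] = []
        for h in sh:
            rank = DOMAIN_RANK[h.model]
            if current:
                prev = current[-1]
                gap = h.interval.start - prev.interval.end
                prev_rank = DOMAIN_RANK[prev.model]
                ok_rank = rank > prev_rank if strand == "+" else rank < prev_rank
                if not ok_rank or gap > max_gap:
                    cassettes.append(current)
                    current = []
            current.append(h)
        if current:
            cassettes.append(current)
    cassettes.sort(key=lambda c: min(h.interval.start for h in c))
    return cassettes


def _anchor_span(cassette: list[DomainHit]) -> tuple[int, int]:
    return (
        min(h.interval.start for h in cassette),
        max(h.interval.end for h in cassette),
    )


def _structural_hits(hits, models, fraction: float):
    cutoff = {
        m.name: m.threshold
        + fraction * (m.score_sequence(m.consensus) - m.threshold)
        for m in models
    }
    return [h for h in hits if h.score >= cutoff[h.model]]


def annotate_candidates(
    genome: GenomeSequence,
    candidates: list[signature.CandidateRegion],
    models,
    config: PipelineConfig,
) -> list[ElementCall]:
    """Domain scan + LTR definition + classification for candidate regions.

    Enforces the acceptance rule: only regions > 1 kb containing at least one
    retrotransposon protein motif are annotated.
    """
    th = config.thresholds
    calls: list[ElementCall] = []
    for cand in candidates:
        region = cand.interval
        pad = config.region_pad
        scan_iv = GenomicInterval(
            region.contig,
            max(0, region.start - pad),
            min(genome.length(region.contig), region.end + pad),
        )
        hits = _structural_hits(
            resolve_overlapping_hits(scan_domains(scan_iv, genome, models)),
            models, config.structural_score_fraction,
        )
        if len(region) <= th.min_region_length:
            logger.info("region %s dropped: length %d <= %d bp",
                        region, len(region), th.min_region_length)
            continue
        if not hits:
            logger.info("region %s dropped: no retrotransposon protein motif",
                        region)
            continue
        cassettes = segment_cassettes(hits, config.cassette_gap)
        calls.extend(
            _annotate_cassettes(genome, scan_iv, cassettes, config)
        )
    return calls


def _annotate_cassettes(
    genome: GenomeSequence,
    bounds: GenomicInterval,
    cassettes: list[list[DomainHit]],
    config: PipelineConfig,
) -> list[ElementCall]:
    contig_seq = genome.contigs[bounds.contig]
    calls = []
    for i, cassette in enumerate(cassettes):
        if not any(h.model in CORE_DOMAINS for h in cassette):
            continue  # auxiliary-domain-only evidence does not make a cassette
        a0, a1 = _anchor_span(cassette)
        lo = bounds.start
        hi = bounds.end
        # cap the repeat search at the neighbouring cassettes' anchors: the
        # stretch between two cassettes belongs to both, but nothing beyond a
        # neighbour's cassette (e.g. a same-family element further along the
        # array) may contribute a repeat copy
        lo_anchor = 0 if i == 0 else _anchor_span(cassettes[i - 1])[1]
        hi_anchor = (
            len(contig_seq) if i + 1 >= len(cassettes)
            else _anchor_span(cassettes[i + 1])[0]
        )
        lo = max(lo, lo_anchor)
        hi = min(hi, hi_anchor)
        pairs = find_direct_repeats(
            contig_seq, (a0, a1), flank=config.ltr.flank, k=config.ltr.k,
            min_len=config.ltr.min_len, min_identity=config.ltr.min_identity,
            search_bounds=(lo, hi),
        )
        if not pairs and (lo > lo_anchor or hi < hi_anchor):
            # a candidate region flagged only over the cassette (e.g. a
            # borderline signature) can be too tight to reach the borders;
            # retry capped at the neighbouring cassettes alone
            logger.info("cassette %s:%d-%d: no repeat pair within the "
                        "candidate region; widening to cassette bounds",
                        bounds.contig, a0, a1)
            pairs = find_direct_repeats(
                contig_seq, (a0, a1), flank=config.ltr.flank, k=config.ltr.k,
                min_len=config.ltr.min_len,
                min_identity=config.ltr.min_identity,
                search_bounds=(
                    max(lo_anchor, a0 - config.ltr.retry_reach),
                    min(hi_anchor, a1 + config.ltr.retry_reach),
                ),
            )
        call = classify_element(
            GenomicInterval(bounds.contig, a0, a1), cassette, pairs,
            seq=contig_seq, exclusion=config.solo_exclusion,
        )
        if call is not None:
            logger.info("cassette %s:%d-%d -> %s", bounds.contig, a0, a1,
                        call.element_class)
            calls.append(call)
    return calls


def _extract_triplet(genome: GenomeSequence, call: ElementCall) -> DomainTriplet | None:
    seqs = {}
    for h in call.domains:
        if h.model in references.TRIPLET_DOMAINS and h.model not in seqs:
            seqs[h.model] = genome.fetch(h.interval)
    if not seqs:
        return None
    return DomainTriplet(
        element_id=call.element_id,
        sequences=seqs,
        sort_key=(call.interval.contig, call.interval.start),
        length=len(call.interval),
    )


def _assign_ids(calls: list[ElementCall]) -> None:
    calls.sort(key=lambda c: (c.interval.contig, c.interval.start))
    for i, c in enumerate(calls, 1):
        c.element_id = f"e{i}"


def _covered_by(new, existing, fraction: float = 0.5) -> bool:
    """True when an existing call covers at least ``fraction`` of the new
    interval; a large new locus is not blocked by a small call inside it."""
    return new.overlap_len(existing) >= fraction * len(new)


def _dedupe_calls(calls: list[ElementCall]) -> list[ElementCall]:
    """Drop calls mostly contained in a stronger call (more domain evidence,
    then longer): small fragments swallowed by a full annotation go."""
    ranked = sorted(
        calls, key=lambda c: (-len(c.domains), -len(c.interval),
                              c.interval.contig, c.interval.start),
    )
    kept: list[ElementCall] = []
    for c in ranked:
        if not any(_covered_by(c.interval, k.interval) for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: (c.interval.contig, c.interval.start))
    return kept


def rescue_copies(
    genome: GenomeSequence,
    calls: list[ElementCall],
    families: list[Family],
    models,
    config: PipelineConfig,
) -> list[ElementCall]:
    """Search each family representative against the whole genome and annotate
    any matched locus not already called (the 'additional copies' step)."""
    by_id = {c.element_id: c for c in calls}
    new_calls: list[ElementCall] = []
    for fam in families:
        rep = by_id[fam.representative]
        query = genome.fetch(rep.interval)
        matches = find_copies(
            query, genome, query_id=fam.family_id, k=config.copies.k,
            min_len=config.copies.min_len,
            min_identity=config.copies.min_identity, exclude=rep.interval,
        )
        # cross-family matches typically align over the conserved cassette
        # only; the repeat search must then reach out by the query's own
        # cassette-to-border offsets (same-lineage layouts are shared)
        if rep.domains:
            env_start = min(h.interval.start for h in rep.domains)
            env_end = max(h.interval.end for h in rep.domains)
            off_left = env_start - rep.interval.start + 250
            off_right = rep.interval.end - env_end + 250
        else:
            off_left = off_right = 250
        for m in matches:
            if any(_covered_by(m.target, c.interval)
                   for c in calls + new_calls):
                continue
            scan_iv = GenomicInterval(
                m.target.contig,
                max(0, m.target.start - config.region_pad),
                min(genome.length(m.target.contig),
                    m.target.end + config.region_pad),
            )
            hits = _structural_hits(
                resolve_overlapping_hits(scan_domains(scan_iv, genome, models)),
                models, config.structural_score_fraction,
            )
            if not hits:
                continue  # repeat-only locus; left to the solo-LTR search
            contig_seq = genome.contigs[m.target.contig]
            qcov = (m.query_span[1] - m.query_span[0]) / len(query)
            if qcov >= 0.8:  # match already spans the whole element
                pad_left = pad_right = 250
            else:
                pad_left, pad_right = off_left, off_right
            for cassette in segment_cassettes(hits, config.cassette_gap):
                if not any(h.model in CORE_DOMAINS for h in cassette):
                    continue
                a0, a1 = _anchor_span(cassette)
                lo = max(0, m.target.start - pad_left)
                hi = min(len(contig_seq), m.target.end + pad_right)
                pairs = find_direct_repeats(
                    contig_seq, (a0, a1), flank=config.ltr.flank,
                    k=config.ltr.k, min_len=config.ltr.min_len,
                    min_identity=config.ltr.min_identity,
                    search_bounds=(lo, hi),
                )
                call = classify_element(
                    GenomicInterval(m.target.contig, a0, a1), cassette, pairs,
                    seq=contig_seq, exclusion=config.solo_exclusion,
                )
                if call is not None and not any(
                    _covered_by(call.interval, c.interval)
                    for c in calls + new_calls
                ):
                    logger.info("rescued copy of %s at %s (%s)",
                                fam.family_id, call.interval,
                                call.element_class)
                    new_calls.append(call)
    return new_calls


def scan_solo_ltrs(
    genome: GenomeSequence,
    calls: list[ElementCall],
    families: list[Family],
    config: PipelineConfig,
) -> list[ElementCall]:
    by_id = {c.element_id: c for c in calls}
    solos: list[ElementCall] = []
    for fam in families:
        rep = by_id[fam.representative]
        pair = rep.ltr_pair
        if pair is None:
            for member in fam.members:
                if by_id[member].ltr_pair is not None:
                    pair = by_id[member].ltr_pair
                    rep = by_id[member]
                    break
        if pair is None:
            logger.info("family %s has no LTR-bearing member; solo search "
                        "skipped", fam.family_id)
            continue
        consensus = genome.fetch(
            GenomicInterval(rep.interval.contig, pair.left.start, pair.left.end)
        )
        found = find_solo_ltrs(
            consensus, genome, calls, family=fam.family_id,
            exclusion=config.solo_exclusion,
            min_identity=config.solo_min_identity, k=config.copies.k,
            min_len=config.copies.min_len,
        )
        for s in found:
            if not any(s.interval.overlaps(x.interval) for x in solos):
                solos.append(s)
    return solos


# ---------------------------------------------------------------------------
# full synthetic pipeline

def run_pipeline(
    config: PipelineConfig, outdir: str | os.PathLike | None = None
) -> PipelineResult:
    """Simulate the study system and run the full discovery analysis.

    Pure function of (config, seed): reruns produce byte-identical outputs.
    """
    logging.basicConfig(level=config.log_level)
    synth = config.synth
    genome, truth = synthio.build_genome(synth)
    annotations = synthio.simulate_annotations(genome, truth, synth)
    reads_wt = synthio.simulate_reads(genome, truth, synth, "wild_type")
    reads_mut = synthio.simulate_reads(genome, truth, synth, "mutant")
    tracks = {
        "srna_wt": synthio.simulate_coverage(genome, truth, synth, "sRNA",
                                             "wild_type", reads=reads_wt),
        "srna_mut": synthio.simulate_coverage(genome, truth, synth, "sRNA",
                                              "mutant", reads=reads_mut),
        "mrna_wt": synthio.simulate_coverage(genome, truth, synth, "mRNA",
                                             "wild_type"),
        "mrna_mut": synthio.simulate_coverage(genome, truth, synth, "mRNA",
                                              "mutant"),
    }
    candidates = signature.call_candidates(
        tracks["srna_wt"], tracks["srna_mut"], tracks["mrna_wt"],
        tracks["mrna_mut"], annotations, config.thresholds,
    )
    models = references.build_domain_models(
        alpha=config.domain_alpha, null_draws=config.domain_null_draws,
        seed=0,
    )
    calls = annotate_candidates(genome, candidates, models, config)
    _assign_ids(calls)
    families = _cluster_calls(genome, calls, config)
    rescued = rescue_copies(genome, calls, families, models, config)
    if rescued:
        calls.extend(rescued)
        calls = _dedupe_calls(calls)
        _assign_ids(calls)
        families = _cluster_calls(genome, calls, config)
    solos = scan_solo_ltrs(genome, calls, families, config)
    calls.extend(solos)
    _assign_ids(calls)
    families = _cluster_calls(genome, calls, config)
    _label_families(calls, families)
    lineages = None
    if families:
        triplets = {
            t.element_id: t
            for t in (_extract_triplet(genome, c) for c in calls)
            if t is not None
        }
        lineages = assign_lineages(families, triplets, references.reference_triplets())
    profiles = _profile_calls(calls, reads_wt, reads_mut, config)
    report = evaluate(
        calls, truth, reciprocal=config.reciprocal_overlap,
        families=families, profiles=profiles, lineages=lineages,
    )
    result = PipelineResult(
        genome=genome, truth=truth, annotations=annotations,
        candidates=candidates, calls=calls, families=families,
        lineages=lineages, profiles=profiles, report=report, tracks=tracks,
    )
    if outdir is not None:
        write_outputs(result, reads_wt, reads_mut, outdir)
    return result


def _cluster_calls(genome, calls, config) -> list[Family]:
    triplets = [
        t for t in (_extract_triplet(genome, c) for c in calls) if t is not None
    ]
    return cluster_families(triplets, threshold=config.family_threshold)


def _label_families(calls: list[ElementCall], families: list[Family]) -> None:
    member_of = {}
    for fam in families:
        for m in fam.members:
            member_of[m] = fam.family_id
    for c in calls:
        if c.family is None:
            c.family = member_of.get(c.element_id)


def _profile_calls(calls, reads_wt, reads_mut, config) -> list[dict]:
    out = []
    for condition, reads in (("wild_type", ReadIndex(reads_wt)),
                             ("mutant", ReadIndex(reads_mut))):
        for c in calls:
            if c.element_class == SOLO_LTR:
                continue
            prof = profile_small_rnas(reads, c.interval, element_id=c.element_id)
            if prof.total_reads == 0:
                continue
            out.append(
                {
                    "element_id": c.element_id,
                    "family": c.family or "",
                    "element_class": c.element_class,
                    "condition": condition,
                    "total_reads": prof.total_reads,
                    "strand_bias": prof.strand_bias,
                    "five_prime_u_fraction": prof.five_prime_u_fraction,
                    "modal_length": prof.modal_length,
                    "label": classify_profile(prof, config.sirna),
                }
            )
    return out


# ---------------------------------------------------------------------------
# evaluation

def evaluate(
    calls: list[ElementCall],
    truth: synthio.TruthSet,
    reciprocal: float = 0.5,
    families: list[Family] | None = None,
    profiles: list[dict] | None = None,
    lineages: LineageTree | None = None,
) -> EvaluationReport:
    """Score calls against the planted truth.

    A call matches a truth element when their reciprocal overlap is >= the
    threshold; the confusion matrix crosses truth class with call class;
    boundary errors are per-edge absolute differences for matched full-length
    calls.
    """
    if not truth.elements:
        raise ValueError("empty truth set")
    classes = (FULL_LENGTH, PARTIAL, SOLO_LTR)
    confusion = {t: {c: 0 for c in classes + ("missed",)} for t in classes}
    match_of: dict[int, ElementCall] = {}
    used = set()
    for ti, te in enumerate(truth.elements):
        best = None
        best_ol = 0
        for c in calls:
            ol = te.interval.overlap_len(c.interval)
            if (
                ol >= reciprocal * len(te.interval)
                and ol >= reciprocal * len(c.interval)
                and ol > best_ol
            ):
                best, best_ol = c, ol
        if best is None:
            confusion[te.element_class]["missed"] += 1
        else:
            confusion[te.element_class][best.element_class] += 1
            match_of[ti] = best
            used.add(id(best))
    recall = {}
    for cls in classes:
        n = sum(1 for e in truth.elements if e.element_class == cls)
        recall[cls] = confusion[cls][cls] / n if n else float("nan")
    precision = {}
    for cls in classes:
        n_calls_cls = sum(1 for c in calls if c.element_class == cls)
        correct = confusion[cls][cls]
        precision[cls] = correct / n_calls_cls if n_calls_cls else float("nan")
    # called-base precision vs planted element bases
    total_called = sum(len(c.interval) for c in calls)
    overlap_bases = 0
    for c in calls:
        # truth elements are mutually disjoint, so summing overlaps is exact
        overlap_bases += sum(
            te.interval.overlap_len(c.interval)
            for te in truth.elements
            if te.interval.contig == c.interval.contig
        )
    base_precision = overlap_bases / total_called if total_called else float("nan")
    boundary = []
    for ti, c in match_of.items():
        te = truth.elements[ti]
        if te.element_class == FULL_LENGTH and c.element_class == FULL_LENGTH:
            boundary.append(abs(c.interval.start - te.interval.start))
            boundary.append(abs(c.interval.end - te.interval.end))
    ari = None
    if families is not None:
        member_fam = {}
        for fam in families:
            for m in fam.members:
                member_fam[m] = fam.family_id
        y_true, y_pred = [], []
        for ti, c in match_of.items():
            if c.element_id in member_fam:
                y_true.append(truth.elements[ti].family)
                y_pred.append(member_fam[c.element_id])
        if y_true:
            from sklearn.metrics import adjusted_rand_score

            ari = float(adjusted_rand_score(y_true, y_pred))
    lineage_acc = None
    if lineages is not None and families is not None:
        fam_truth_lineage: dict[str, list[str]] = {}
        member_fam = {m: f.family_id for f in families for m in f.members}
        for ti, c in match_of.items():
            if c.element_id in member_fam:
                fam_truth_lineage.setdefault(member_fam[c.element_id], []).append(
                    truth.elements[ti].lineage
                )
        scored = []
        for fam_id, lins in fam_truth_lineage.items():
            expected = max(set(lins), key=lins.count)
            got = lineages.labels.get(fam_id)
            scored.append(1.0 if got == expected else 0.0)
        if scored:
            lineage_acc = float(np.mean(scored))
    classifier_acc = None
    if profiles:
        call_by_id = {c.element_id: c for c in calls}
        call_truth: dict[str, str] = {}
        for ti, c in match_of.items():
            call_truth[c.element_id] = truth.elements[ti].family
        scored = []
        for row in profiles:
            fam_true = call_truth.get(row["element_id"])
            if fam_true is None:
                continue
            if row["condition"] == "wild_type":
                expected = "siRNA_like"
            elif fam_true == truth.mobilizing_family:
                expected = "sense_degradation_like"
            else:
                continue
            scored.append(1.0 if row["label"] == expected else 0.0)
        if scored:
            classifier_acc = float(np.mean(scored))
    return EvaluationReport(
        precision=precision,
        recall=recall,
        confusion={k: dict(v) for k, v in confusion.items()},
        called_base_precision=base_precision,
        boundary_errors=sorted(boundary),
        clustering_ari=ari,
        lineage_accuracy=lineage_acc,
        classifier_accuracy=classifier_acc,
        n_calls=len(calls),
        n_truth=len(truth.elements),
    )


# ---------------------------------------------------------------------------
# output writing

def calls_to_annotations(calls: list[ElementCall]) -> AnnotationSet:
    out = AnnotationSet()
    for c in calls:
        attrs = f"ID={c.element_id};class={c.element_class}"
        if c.family:
            attrs += f";family={c.family}"
        if c.tg_ca_flag:
            attrs += ";tg_ca=1"
        out.add(GffRecord(c.interval, "transposable_element",
                          source="retroscout", attributes=attrs))
        if c.ltr_pair is not None:
            for tag, iv in (("ltr1", c.ltr_pair.left), ("ltr2", c.ltr_pair.right)):
                out.add(
                    GffRecord(
                        GenomicInterval(c.interval.contig, iv.start, iv.end,
                                        c.interval.strand),
                        "long_terminal_repeat", source="retroscout",
                        attributes=f"ID={c.element_id}.{tag};Parent={c.element_id}",
                    )
                )
        for h in c.domains:
            out.add(
                GffRecord(h.interval, "protein_match", source="retroscout",
                          score=f"{h.score:.2f}",
                          attributes=f"Parent={c.element_id};Name={h.model}")
            )
    return out


def write_outputs(result: PipelineResult, reads_wt, reads_mut, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    write_fasta(result.genome, p("genome.fa"))
    if result.truth is not None:
        write_gff3(synthio.truth_to_annotations(result.truth), p("truth.gff3"))
    write_gff3(result.annotations, p("annotations.gff3"))
    write_reads(reads_wt, p("reads_wt.tsv"))
    write_reads(reads_mut, p("reads_mut.tsv"))
    for name, track in result.tracks.items():
        write_bedgraph(track, p(f"{name}.bedgraph"))
    with open(p("candidates.bed"), "w") as fh:
        for cand in result.candidates:
            iv = cand.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{cand.signature_class}"
                f"\t{cand.mrna_fold_change:.4f}\n"
            )
    write_gff3(calls_to_annotations(result.calls), p("elements.gff3"))
    with open(p("families.tsv"), "w") as fh:
        fh.write("family\trepresentative\tlineage\tmembers\n")
        for fam in result.families:
            lin = result.lineages.labels.get(fam.family_id, "") if result.lineages else ""
            fh.write(
                f"{fam.family_id}\t{fam.representative}\t{lin}\t"
                + ",".join(fam.members) + "\n"
            )
    if result.lineages is not None:
        with open(p("tree.nwk"), "w") as fh:
            fh.write(result.lineages.newick + "\n")
    with open(p("profiles.tsv"), "w") as fh:
        cols = ["element_id", "family", "element_class", "condition",
                "total_reads", "strand_bias", "five_prime_u_fraction",
                "modal_length", "label"]
        fh.write("\t".join(cols) + "\n")
        for row in result.profiles:
            vals = []
            for c in cols:
                v = row[c]
                vals.append(f"{v:.6f}" if isinstance(v, float) else str(v))
            fh.write("\t".join(vals) + "\n")
    if result.report is not None:
        with open(p("report.json"), "w") as fh:
            json.dump(result.report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
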