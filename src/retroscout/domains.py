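"""Retrotransposon protein-domain detection by six-frame PSSM scanning.

Candidate regions are translated in all six frames and scored against
position-specific score matrices (log-odds vs a uniform amino-acid background)
built from bundled reference alignments for the six domain classes carried by
LTR retrotransposons: gag, protease, reverse transcriptase, RNase H, integrase
and chromodomain. Score thresholds are calibrated empirically against random
sequences. Windows containing a stop codon are rejected outright: an intact
domain is an open reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .formats_io import GenomeSequence, GenomicInterval, revcomp

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
STOP_CODE = len(AA_ALPHABET)  # '*' and unknowns

DOMAIN_NAMES = (
    "gag",
    "protease",
    "reverse_transcriptase",
    "rnase_h",
    "integrase",
    "chromodomain",
)
DOMAIN_RANK = {name: i + 1 for i, name in enumerate(DOMAIN_NAMES)}

#: domains that can define a cassette on their own; a chromodomain is an
#: auxiliary feature of Ty3-type elements and occurs in many chromatin
#: proteins, so alone it is not evidence of a retroelement
CORE_DOMAINS = frozenset(DOMAIN_NAMES[:5])


@dataclass
class DomainModel:
    """Ungapped log-odds profile over the 20 amino acids."""

    name: str
    pssm: np.ndarray  # (length, 20) bits
    threshold: float = -np.inf

    def __post_init__(self):
        if not np.all(np.isfinite(self.pssm)):
            raise ValueError("PSSM must be finite")

    @property
    def length(self) -> int:
        return self.pssm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in np.argmax(self.pssm, axis=1))

    def score_sequence(self, aa: str) -> float:
        """Score a stop-free sequence of exactly model length."""
        if len(aa) != self.length:
            raise ValueError("sequence length must equal model length")
        idx = np.array([AA_INDEX[c] for c in aa])
        return float(self.pssm[np.arange(self.length), idx].sum())


@dataclass(frozen=True)
class DomainHit:
    interval: GenomicInterval  # nucleotide coordinates, strand from frame sign
    frame: int  # +1,+2,+3,-1,-2,-3
    model: str
    score: float


@dataclass
class FrameTranslation:
    frame: int
    aa: str

    def nt_interval(self, residue_start: int, residue_end: int, seq_len: int):
        """Nucleotide (start, end) within the translated sequence for a
        residue slice [residue_start, residue_end)."""
        f = abs(self.frame) - 1
        if self.frame > 0:
            return f + 3 * residue_start, f + 3 * residue_end
        # reverse frames index from the right end of the forward sequence
        end = seq_len - f - 3 * residue_start
        start = seq_len - f - 3 * residue_end
        return start, end


def six_frame_translate(seq: str) -> list[FrameTranslation]:
    """Translate all six frames with the standard genetic code ('*' = stop)."""
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    out = []
    rc = revcomp(seq)
    for f in range(3):
        for frame, s in ((f + 1, seq), (-(f + 1), rc)):
            sub = s[f : f + 3 * ((len(s) - f) // 3)]
            aa = str(Seq(sub).translate()) if sub else ""
            out.append(FrameTranslation(frame=frame, aa=aa))
    return out


def build_model(
    aligned_proteins: list[str],
    name: str = "",
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> DomainModel:
    """Build a log2-odds PSSM from an ungapped alignment of >= 2 proteins.

    Column score for residue r: log2(((count_r + pc) / (N + 20*pc)) / bg_r).
    """
    if len(aligned_proteins) < 2:
        raise ValueError("need at least 2 aligned sequences")
    lengths = {len(s) for s in aligned_proteins}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    L = lengths.pop()
    n = len(aligned_proteins)
    if background is None:
        background = np.full(20, 1.0 / 20)
    counts = np.zeros((L, 20))
    for s in aligned_proteins:
        for j, c in enumerate(s.upper()):
            if c not in AA_INDEX:
                raise ValueError(f"illegal residue {c!r} in alignment")
            counts[j, AA_INDEX[c]] += 1
    probs = (counts + pseudocount) / (n + 20 * pseudocount)
    return DomainModel(name=name, pssm=np.log2(probs / background))


def calibrate_threshold(
    model: DomainModel,
    null_draws: int = 1000,
    alpha: float = 1e-3,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> float:
    """(1-alpha) quantile of scores of random background sequences of model
    length. With alpha=1 this is the minimum null score."""
    if background is None:
        background = np.full(20, 1.0 / 20)
    rng = np.random.default_rng(seed)
    draws = rng.choice(20, size=(null_draws, model.length), p=background)
    scores = model.pssm[np.arange(model.length)[None, :], draws].sum(axis=1)
    return float(np.quantile(scores, 1.0 - alpha))


def _encode_aa(aa: str) -> np.ndarray:
    out = np.full(len(aa), STOP_CODE, dtype=np.int64)
    for i, c in enumerate(aa):
        out[i] = AA_INDEX.get(c, STOP_CODE)
    return out


def _window_scores(model: DomainModel, codes: np.ndarray) -> np.ndarray:
    """Score every window; windows containing a stop/unknown get -inf."""
    L = model.length
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    pssm_ext = np.hstack([model.pssm, np.full((L, 1), 0.0)])  # col for stops
    scores = np.zeros(n_win)
    for j in range(L):
        scores += pssm_ext[j, codes[j : j + n_win]]
    stop_mask = codes == STOP_CODE
    if stop_mask.any():
        bad = np.convolve(stop_mask.astype(int), np.ones(L, dtype=int), "valid") > 0
        scores[bad] = -np.inf
    return scores


def scan_domains(
    region: GenomicInterval,
    genome: GenomeSequence,
    models: list[DomainModel],
    reduce_overlaps: bool = True,
    merge_slack: int = 100,
) -> list[DomainHit]:
    """Scan every window of each frame against every model.

    Windows scoring >= the model threshold become hits; overlapping (or nearly
    adjacent, within ``merge_slack`` bp) hits of the same model are reduced to
    the best-scoring one. Hit intervals are nucleotide coordinates on the
    genome, wholly inside ``region``.
    """
    seq = genome.contigs[region.contig][region.start : region.end]
    if len(seq) < 3:
        return []
    frames = six_frame_translate(seq)
    hits: list[DomainHit] = []
    for ft in frames:
        codes = _encode_aa(ft.aa)
        for model in models:
            scores = _window_scores(model, codes)
            for w in np.nonzero(scores >= model.threshold)[0]:
                nt_s, nt_e = ft.nt_interval(int(w), int(w) + model.length, len(seq))
                strand = "+" if ft.frame > 0 else "-"
                hits.append(
                    DomainHit(
                        interval=GenomicInterval(
                            region.contig, region.start + nt_s, region.start + nt_e,
                            strand,
                        ),
                        frame=ft.frame,
                        model=model.name,
                        score=float(scores[w]),
                    )
                )
    if reduce_overlaps:
        hits = _reduce_same_model(hits, merge_slack)
    hits.sort(key=lambda h: (h.interval.start, h.interval.end, h.model))
    return hits


def resolve_overlapping_hits(hits: list[DomainHit]) -> list[DomainHit]:
    """Cross-model overlap resolution: a nucleotide window encodes only one
    domain, so genomically overlapping hits (any model, any strand) are
    reduced to the best-scoring one. Weak within-ORF composition noise is
    thereby subordinated to the true cassette hits."""
    kept: list[DomainHit] = []
    for h in sorted(hits, key=lambda x: (-x.score, x.interval.start)):
        if not any(h.interval.overlaps(c.interval) for c in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.interval.start, h.interval.end))
    return kept


def _reduce_same_model(hits: list[DomainHit], slack: int) -> list[DomainHit]:
    kept: list[DomainHit] = []
    for model in {h.model for h in hits}:
        group = sorted(
            (h for h in hits if h.model == model), key=lambda h: -h.score
        )
        chosen: list[DomainHit] = []
        for h in group:
            clash = any(
                h.interval.contig == c.interval.contig
                and h.interval.start < c.interval.end + slack
                and c.interval.start < h.interval.end + slack
                for c in chosen
            )
            if not clash:
                chosen.append(h)
        kept.extend(chosen)
    return kept
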