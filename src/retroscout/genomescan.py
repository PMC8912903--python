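"""Genome-wide copy search by k-mer seeding and banded local alignment.

Discovered elements are searched against the whole genome, on both strands,
to locate additional copies and family-wide solo-LTRs. Exact k-mer seeds are
chained by diagonal and chains are extended with banded affine
Smith-Waterman; overlapping matches are reduced to the best-scoring one.
Scoring and cutoffs are heuristic stand-ins for a BLAST search and are
config-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._align import banded_sw
from .formats_io import GenomeSequence, GenomicInterval, revcomp
from .ltr import SOLO_LTR, ElementCall

_CODE = {65: 0, 67: 1, 71: 2, 84: 3, 78: 4}  # A C G T N


@dataclass
class CopyMatch:
    query_id: str
    target: GenomicInterval
    strand: str
    identity: float
    aligned_length: int
    score: int
    query_span: tuple[int, int] = (0, 0)


def _encode_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(len(raw), 4, dtype=np.int64)
    for byte, code in _CODE.items():
        out[raw == byte] = code
    return out


def _kmer_ints(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-5 integer encoding of every k-mer (values containing N never
    collide with ACGT-only k-mers because query k-mers with N are skipped)."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    n_win = len(codes) - k + 1
    out = np.zeros(n_win, dtype=np.int64)
    for j in range(k):  # Horner evaluation, no large temporaries
        out = out * 5 + codes[j : j + n_win]
    return out


def _seed_hits(query: str, target_kmers: np.ndarray, k: int):
    """(query_pos, target_pos) pairs of exact shared k-mers."""
    q_codes = _encode_codes(query)
    q_kmers = _kmer_ints(q_codes, k)
    has_n = np.convolve((q_codes == 4).astype(int), np.ones(k, int), "valid") > 0
    index: dict[int, list[int]] = {}
    for i, kv in enumerate(q_kmers):
        if not has_n[i]:
            index.setdefault(int(kv), []).append(i)
    mask = np.isin(target_kmers, np.fromiter(index.keys(), dtype=np.int64,
                                             count=len(index)))
    hits = []
    for t in np.nonzero(mask)[0]:
        for q in index[int(target_kmers[t])]:
            hits.append((q, int(t)))
    return hits


def _chain_and_extend(
    query: str, target: str, hits, k: int, diag_slack: int = 30,
    pos_gap: int = 2500, margin: int = 200,
):
    # pos_gap is generous: at ~75% identity exact 15-mer seeds are rare
    # (~1 per 100 bp), so same-diagonal seeds may sit far apart; the banded
    # extension decides what actually aligns
    """Group seeds into diagonal chains; banded-extend each chain."""
    triples = sorted((t - q, t, q) for q, t in hits)
    chains: list[list[tuple[int, int, int]]] = []
    for h in triples:
        placed = False
        for chain in chains:
            d0, t0, _ = chain[-1]
            if abs(h[0] - d0) <= diag_slack and 0 <= h[1] - t0 <= pos_gap:
                chain.append(h)
                placed = True
                break
        if not placed:
            chains.append([h])
    alignments = []
    for chain in chains:
        if len(chain) < 2:
            continue  # lone seeds are overwhelmingly chance matches
        q_lo = min(h[2] for h in chain)
        q_hi = max(h[2] for h in chain) + k
        t_lo = min(h[1] for h in chain)
        t_hi = max(h[1] for h in chain) + k
        diags = [h[0] for h in chain]
        qa, qb = max(0, q_lo - margin), min(len(query), q_hi + margin)
        ta, tb = max(0, t_lo - margin), min(len(target), t_hi + margin)
        d_center = min(diags) - (ta - qa)
        d_spread = max(diags) - min(diags)
        aln = banded_sw(query[qa:qb], target[ta:tb], d_center - d_spread - 48,
                        d_center + d_spread + 48)
        if aln is None:
            continue
        alignments.append((aln, qa, ta))
    return alignments


def find_copies(
    query_seq: str,
    genome: GenomeSequence,
    query_id: str = "query",
    k: int = 15,
    min_len: int = 200,
    min_identity: float = 0.70,
    exclude: GenomicInterval | None = None,
) -> list[CopyMatch]:
    """Locate copies of ``query_seq`` anywhere in the genome, both strands.

    The query's own locus, when given via ``exclude``, is removed from the
    results; overlapping matches are reduced to the best score.
    """
    if len(query_seq) < k:
        raise ValueError("query shorter than the seed size")
    matches: list[CopyMatch] = []
    for contig in genome.contigs:
        fwd = genome.contigs[contig]
        for strand in ("+", "-"):
            target = fwd if strand == "+" else revcomp(fwd)
            t_kmers = _kmer_ints(_encode_codes(target), k)
            hits = _seed_hits(query_seq, t_kmers, k)
            if not hits:
                continue
            for aln, qa, ta in _chain_and_extend(query_seq, target, hits, k):
                t_start = ta + aln.b_start
                t_end = ta + aln.b_end
                if strand == "-":
                    t_start, t_end = len(fwd) - t_end, len(fwd) - t_start
                length = aln.b_end - aln.b_start
                if length < min_len or aln.identity < min_identity:
                    continue
                matches.append(
                    CopyMatch(
                        query_id=query_id,
                        target=GenomicInterval(contig, t_start, t_end, strand),
                        strand=strand,
                        identity=aln.identity,
                        aligned_length=length,
                        score=aln.score,
                        query_span=(qa + aln.a_start, qa + aln.a_end),
                    )
                )
    matches = _reduce_overlaps(matches)
    if exclude is not None:
        matches = [m for m in matches if not m.target.overlaps(exclude)]
    matches.sort(key=lambda m: (m.target.contig, m.target.start))
    return matches


def _reduce_overlaps(matches: list[CopyMatch]) -> list[CopyMatch]:
    kept: list[CopyMatch] = []
    for m in sorted(matches, key=lambda x: -x.score):
        if not any(m.target.overlaps(o.target) for o in kept):
            kept.append(m)
    return kept


def find_solo_ltrs(
    ltr_consensus: str,
    genome: GenomeSequence,
    element_calls: list[ElementCall],
    family: str | None = None,
    exclusion: int = 1000,
    min_identity: float = 0.80,
    k: int = 15,
    min_len: int = 200,
) -> list[ElementCall]:
    """Genome-wide solo-LTR search with a family's LTR consensus.

    Matches within ``exclusion`` bp of any domain-bearing call (whose own
    LTRs they usually are) are removed; the remainder become solo_LTR calls.
    """
    matches = find_copies(
        ltr_consensus, genome, query_id="ltr", k=k,
        min_len=min(min_len, max(50, int(0.6 * len(ltr_consensus)))),
        min_identity=min_identity,
    )
    coding = [
        c for c in element_calls
        if c.element_class != SOLO_LTR and c.domains
    ]
    out = []
    for m in matches:
        near = any(
            c.interval.contig == m.target.contig
            and m.target.distance(c.interval) <= exclusion
            for c in coding
        )
        if near:
            continue
        out.append(
            ElementCall(interval=m.target, element_class=SOLO_LTR, family=family)
        )
    return out
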