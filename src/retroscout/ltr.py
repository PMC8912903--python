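"""Direct-repeat (LTR) detection and element classification.

An intact LTR retrotransposon is delimited by a pair of near-identical direct
repeats flanking its coding cassette. Given the outermost protein-domain hits
as an anchor, the up- and downstream flanks are searched for shared k-mers,
seed chains are extended by banded local alignment, and qualifying repeat
pairs define the element borders. Elements are then classed full-length
(paired LTRs plus reverse transcriptase and integrase), partial (>= 1 domain,
no complete LTR pair) or solo-LTR (a lone repeat with no nearby domain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._align import banded_sw
from .domains import DomainHit
from .formats_io import GenomicInterval

FULL_LENGTH = "full_length"
PARTIAL = "partial"
SOLO_LTR = "solo_LTR"


@dataclass
class LtrPair:
    left: GenomicInterval
    right: GenomicInterval
    identity: float
    repeat_length: int

    def __post_init__(self):
        if self.left.end > self.right.start:
            raise ValueError("left LTR must lie strictly upstream of right LTR")

    @property
    def enclosed_span(self) -> int:
        return self.right.start - self.left.end

    @property
    def rank_score(self) -> float:
        return self.repeat_length * self.identity


@dataclass
class ElementCall:
    interval: GenomicInterval
    element_class: str
    domains: list[DomainHit] = field(default_factory=list)
    ltr_pair: LtrPair | None = None
    family: str | None = None
    tg_ca_flag: bool = False
    element_id: str = ""

    @property
    def domain_models(self) -> set[str]:
        return {h.model for h in self.domains}


def _kmer_chains(up: str, down: str, k: int, diag_slack: int = 25,
                 pos_gap: int = 500):
    """Shared k-mer seeds between the two flanks, chained by diagonal."""
    index: dict[str, list[int]] = {}
    for i in range(len(up) - k + 1):
        index.setdefault(up[i : i + k], []).append(i)
    hits = []
    for j in range(len(down) - k + 1):
        for i in index.get(down[j : j + k], ()):
            hits.append((j - i, i, j))
    hits.sort()
    chains: list[list[tuple[int, int, int]]] = []
    for h in hits:
        placed = False
        for chain in chains:
            d0, i0, j0 = chain[-1]
            if abs(h[0] - d0) <= diag_slack and 0 <= h[1] - i0 <= pos_gap:
                chain.append(h)
                placed = True
                break
        if not placed:
            chains.append([h])
    return chains


def find_direct_repeats(
    seq: str,
    anchor_span: tuple[int, int],
    flank: int = 5000,
    k: int = 12,
    min_len: int = 100,
    min_identity: float = 0.80,
    search_bounds: tuple[int, int] | None = None,
) -> list[LtrPair]:
    """Direct repeats with one copy upstream and one downstream of the anchor.

    ``seq`` is a contig-local sequence; coordinates in the returned pairs are
    relative to ``seq``. ``search_bounds`` optionally caps the searched flanks
    (e.g. at the midpoint to a neighbouring cassette in dense arrays) on top
    of the ``flank`` span; flanks truncated at the sequence edge are searched
    as-is. Pairs are sorted by repeat length x identity, ties broken by the
    smaller enclosed span.
    """
    a0, a1 = anchor_span
    if not (0 <= a0 < a1 <= len(seq)):
        raise ValueError("anchor span outside sequence")
    lo = max(0, a0 - flank)
    hi = min(len(seq), a1 + flank)
    if search_bounds is not None:
        lo = max(lo, search_bounds[0])
        hi = min(hi, search_bounds[1])
    up = seq[lo:a0]
    down = seq[a1:hi]
    if len(up) < k or len(down) < k:
        return []
    pairs: list[LtrPair] = []
    for chain in _kmer_chains(up, down, k):
        i_lo = min(h[1] for h in chain)
        i_hi = max(h[1] for h in chain) + k
        j_lo = min(h[2] for h in chain)
        j_hi = max(h[2] for h in chain) + k
        diags = [h[0] for h in chain]
        margin = max(min_len, 200)
        ia, ib = max(0, i_lo - margin), min(len(up), i_hi + margin)
        ja, jb = max(0, j_lo - margin), min(len(down), j_hi + margin)
        sub_a = up[ia:ib]
        sub_b = down[ja:jb]
        d_center = min(diags) - (ja - ia)
        d_spread = max(diags) - min(diags)
        aln = banded_sw(sub_a, sub_b, d_center - d_spread - 32,
                        d_center + d_spread + 32)
        if aln is None:
            continue
        rep_len = max(aln.a_end - aln.a_start, aln.b_end - aln.b_start)
        if rep_len < min_len or aln.identity < min_identity:
            continue
        left = GenomicInterval(
            "_", lo + ia + aln.a_start, lo + ia + aln.a_end
        )
        right = GenomicInterval("_", a1 + ja + aln.b_start, a1 + ja + aln.b_end)
        if left.end > right.start:
            continue
        pairs.append(
            LtrPair(left=left, right=right, identity=aln.identity,
                    repeat_length=rep_len)
        )
    # deduplicate near-identical pairs, keep the best-ranked of each locus
    pairs.sort(key=lambda p: (-p.rank_score, p.enclosed_span))
    kept: list[LtrPair] = []
    for p in pairs:
        if not any(
            p.left.overlaps(q.left) and p.right.overlaps(q.right) for q in kept
        ):
            kept.append(p)
    return kept


def classify_element(
    region: GenomicInterval,
    domain_hits: list[DomainHit],
    ltr_pairs: list[LtrPair],
    seq: str | None = None,
    exclusion: int = 1000,
    lone_ltr: GenomicInterval | None = None,
) -> ElementCall | None:
    """Apply the class rules to one cassette's evidence.

    Full-length requires a repeat pair plus reverse-transcriptase and
    integrase hits, and spans the outer LTR bounds; partial spans the
    domain-hit envelope; a lone repeat with no domain within the exclusion
    distance is a solo-LTR. ``seq`` (contig sequence) enables the advisory
    TG...CA terminus flag.
    """
    best = ltr_pairs[0] if ltr_pairs else None
    models = {h.model for h in domain_hits}
    if domain_hits:
        strand = "-" if sum(
            1 for h in domain_hits if h.frame < 0
        ) > len(domain_hits) / 2 else "+"
        env_start = min(h.interval.start for h in domain_hits)
        env_end = max(h.interval.end for h in domain_hits)
        if best and {"reverse_transcriptase", "integrase"} <= models:
            iv = GenomicInterval(region.contig, best.left.start, best.right.end,
                                 strand)
            return ElementCall(iv, FULL_LENGTH, domains=list(domain_hits),
                               ltr_pair=best,
                               tg_ca_flag=_tg_ca(best, seq))
        iv = GenomicInterval(region.contig, env_start, env_end, strand)
        return ElementCall(iv, PARTIAL, domains=list(domain_hits),
                           ltr_pair=None)
    if best is not None:
        iv = GenomicInterval(region.contig, best.left.start, best.left.end)
    elif lone_ltr is not None:
        iv = lone_ltr
    else:
        return None
    # lone repeat evidence: solo only when no domain is anywhere near
    near = any(
        h.interval.contig == iv.contig and iv.distance(h.interval) <= exclusion
        for h in domain_hits
    )
    if near:
        return None
    return ElementCall(iv, SOLO_LTR)


def _tg_ca(pair: LtrPair, seq: str | None) -> bool:
    if seq is None:
        return False
    left = seq[pair.left.start : pair.left.end]
    right = seq[pair.right.start : pair.right.end]
    return left.startswith("TG") and right.endswith("CA")
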