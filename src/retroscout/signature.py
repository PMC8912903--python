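"""Differential-coverage candidate calling.

Unannotated regions carrying the discovery signature - small-RNA signal lost
(or changed) together with increased mRNA coverage in the RNAi mutant versus
wild type - are candidate retroelement loci. The published identification of
such regions was manual; this module codifies it as a sliding-window scan
with explicit, configurable thresholds over RPKM-normalized tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import AnnotationSet, CoverageTrack, GenomicInterval

LOST = "lost"
CHANGED = "changed"


@dataclass
class SignatureThresholds:
    srna_loss_fold: float = 4.0
    min_wt_srna_rpkm: float = 5.0
    mrna_gain_fold: float = 2.0
    pseudocount: float = 1.0
    window: int = 500
    step: int = 100
    merge_gap: int = 500
    min_region_length: int = 1000  # regions >1 kb (with a domain) are kept

    def validate(self) -> None:
        if self.srna_loss_fold <= 1 or self.mrna_gain_fold <= 1:
            raise ValueError("fold thresholds must be > 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.step > self.window:
            raise ValueError("step must be <= window")


@dataclass
class CandidateRegion:
    interval: GenomicInterval
    srna_fold_change: float  # mutant/wild-type, pseudocounted
    mrna_fold_change: float
    signature_class: str  # lost | changed
    long_enough: bool = True


def ratio_track(
    mut: CoverageTrack, wt: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """Per-bin (mut + p) / (wt + p); mirrors IP/input ratio-track arithmetic."""
    if not mut.same_binning(wt):
        raise ValueError("tracks have mismatched binning")
    values = {
        c: (mut.values[c] + pseudocount) / (wt.values[c] + pseudocount)
        for c in mut.values
    }
    return CoverageTrack(
        bin_size=mut.bin_size, values=values, normalization=mut.normalization,
        molecule=mut.molecule, condition=f"{mut.condition}/{wt.condition}",
    )


def _window_means(vals: np.ndarray, w_bins: int, s_bins: int) -> np.ndarray:
    if len(vals) < w_bins:
        return np.empty(0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    starts = np.arange(0, len(vals) - w_bins + 1, s_bins)
    return (csum[starts + w_bins] - csum[starts]) / w_bins


def call_candidates(
    srna_wt: CoverageTrack,
    srna_mut: CoverageTrack,
    mrna_wt: CoverageTrack,
    mrna_mut: CoverageTrack,
    annotations: AnnotationSet,
    thresholds: SignatureThresholds | None = None,
) -> list[CandidateRegion]:
    """Sliding-window scan for the discovery signature.

    A window is flagged when (a) its small-RNA signal is "lost" (wild-type
    density above the floor and a >= loss-fold drop in the mutant) or
    "changed" (>= loss-fold shift in either direction), AND (b) mutant mRNA
    is up >= gain-fold. Flagged windows are merged across gaps <= merge_gap;
    merged regions overlapping existing annotations are discarded. Regions
    shorter than the minimum length are retained but marked: the final
    ">1 kb with a domain" rule belongs to the annotation stage.
    """
    th = thresholds or SignatureThresholds()
    th.validate()
    for tr in (srna_wt, srna_mut, mrna_wt, mrna_mut):
        if tr.normalization == "raw":
            raise ValueError("tracks must be depth-normalized (RPKM), not raw")
        if not tr.same_binning(srna_wt):
            raise ValueError("tracks have mismatched binning")
    bs = srna_wt.bin_size
    w_bins = max(1, th.window // bs)
    s_bins = max(1, th.step // bs)
    p = th.pseudocount
    out: list[CandidateRegion] = []
    for contig in srna_wt.values:
        sw = _window_means(srna_wt.values[contig], w_bins, s_bins)
        sm = _window_means(srna_mut.values[contig], w_bins, s_bins)
        mw = _window_means(mrna_wt.values[contig], w_bins, s_bins)
        mm = _window_means(mrna_mut.values[contig], w_bins, s_bins)
        if len(sw) == 0:
            continue
        srna_drop = (sw + p) / (sm + p)
        srna_up = (sm + p) / (sw + p)
        lost = (sw >= th.min_wt_srna_rpkm) & (srna_drop >= th.srna_loss_fold)
        changed = (srna_drop >= th.srna_loss_fold) | (srna_up >= th.srna_loss_fold)
        mrna_up = (mm + p) / (mw + p) >= th.mrna_gain_fold
        flagged = np.nonzero((lost | changed) & mrna_up)[0]
        if len(flagged) == 0:
            continue
        # merge flagged windows into regions
        spans: list[list[int]] = []
        for w in flagged:
            start = int(w) * s_bins * bs
            end = start + w_bins * bs
            if spans and start - spans[-1][1] <= th.merge_gap:
                spans[-1][1] = max(spans[-1][1], end)
                spans[-1][2] = spans[-1][2] or bool(lost[w])
            else:
                spans.append([start, end, bool(lost[w])])
        n_bins = len(srna_wt.values[contig])
        for start, end, any_lost in spans:
            end = min(end, n_bins * bs)
            iv = GenomicInterval(contig, start, end)
            if annotations.any_overlap(iv):
                continue
            b0, b1 = start // bs, (end + bs - 1) // bs
            sw_m = float(srna_wt.values[contig][b0:b1].mean())
            sm_m = float(srna_mut.values[contig][b0:b1].mean())
            mw_m = float(mrna_wt.values[contig][b0:b1].mean())
            mm_m = float(mrna_mut.values[contig][b0:b1].mean())
            out.append(
                CandidateRegion(
                    interval=iv,
                    srna_fold_change=(sm_m + p) / (sw_m + p),
                    mrna_fold_change=(mm_m + p) / (mw_m + p),
                    signature_class=LOST if any_lost else CHANGED,
                    long_enough=(end - start) >= th.min_region_length,
                )
            )
    out.sort(key=lambda r: (r.interval.contig, r.interval.start))
    return out
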