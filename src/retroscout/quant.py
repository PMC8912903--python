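"""Relative-quantification arithmetic for qPCR and ChIP experiments.

Implements the standard comparative-Ct calculations used for expression and
copy-number panels (fold relative to a reference gene such as his3+,
normalised to a wild-type calibrator) and for ChIP-qPCR enrichment (ratio of
product of interest to control product in IP over input). Amplification
efficiency is fixed at 2 per cycle; folds are computed per replicate and
reported as mean +/- SD on the fold scale, matching how such panels are
plotted. Copy-number tables (genomic DNA) use arithmetic identical to
expression tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample", "replicate", "target", "ct")


@dataclass
class QuantResult:
    sample: str
    mean_fold: float
    sd_fold: float
    n_replicates: int


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s) {missing}")
    if not np.isfinite(df["ct"]).all():
        raise ValueError("Ct values must be finite")
    return df


def _ct_lookup(df: pd.DataFrame, sample: str, replicate, target: str,
               extra: dict | None = None) -> float:
    sel = (df["sample"] == sample) & (df["replicate"] == replicate) & (
        df["target"] == target
    )
    for col, val in (extra or {}).items():
        sel &= df[col] == val
    rows = df[sel]
    if len(rows) == 0:
        where = f"sample={sample!r} replicate={replicate!r} target={target!r}"
        if extra:
            where += " " + " ".join(f"{k}={v!r}" for k, v in extra.items())
        raise ValueError(f"missing Ct row: {where}")
    return float(rows["ct"].mean())


def relative_quantity(
    ct: pd.DataFrame,
    target: str,
    reference: str = "his3",
    calibrator: str = "wild_type",
) -> list[QuantResult]:
    """Comparative-Ct fold per sample: per replicate dCt = Ct(target) -
    Ct(reference); fold = 2^-(dCt - mean calibrator dCt); mean +/- SD of the
    per-replicate folds."""
    ct = validate_ct_table(ct)
    samples = list(dict.fromkeys(ct["sample"]))
    dct: dict[str, list[float]] = {}
    for sample in samples:
        reps = sorted(
            set(ct.loc[ct["sample"] == sample, "replicate"]), key=str
        )
        vals = []
        for rep in reps:
            t = _ct_lookup(ct, sample, rep, target)
            r = _ct_lookup(ct, sample, rep, reference)
            vals.append(t - r)
        dct[sample] = vals
    if calibrator not in dct:
        raise ValueError(f"calibrator sample {calibrator!r} absent from table")
    cal_mean = float(np.mean(dct[calibrator]))
    out = []
    for sample in samples:
        folds = np.array([2.0 ** -(d - cal_mean) for d in dct[sample]])
        out.append(
            QuantResult(
                sample=sample,
                mean_fold=float(folds.mean()),
                sd_fold=float(folds.std(ddof=1)) if len(folds) > 1 else 0.0,
                n_replicates=len(folds),
            )
        )
    return out


def chip_enrichment(
    ct: pd.DataFrame,
    target: str,
    control: str = "his3",
    sample: str | None = None,
    replicate=None,
) -> float:
    """Relative enrichment = [2^-(Ct_IP(target) - Ct_input(target))] /
    [2^-(Ct_IP(control) - Ct_input(control))].

    The table must carry a ``fraction`` column with values IP / input.
    When sample/replicate are omitted the table must be unambiguous.
    """
    ct = validate_ct_table(ct)
    if "fraction" not in ct.columns:
        raise ValueError("ChIP table requires a 'fraction' column (IP/input)")
    if sample is None:
        uniq = set(ct["sample"])
        if len(uniq) != 1:
            raise ValueError("multiple samples present; specify one")
        sample = uniq.pop()
    if replicate is None:
        uniq = set(ct["replicate"])
        if len(uniq) != 1:
            raise ValueError("multiple replicates present; specify one")
        replicate = uniq.pop()
    ip_t = _ct_lookup(ct, sample, replicate, target, {"fraction": "IP"})
    in_t = _ct_lookup(ct, sample, replicate, target, {"fraction": "input"})
    ip_c = _ct_lookup(ct, sample, replicate, control, {"fraction": "IP"})
    in_c = _ct_lookup(ct, sample, replicate, control, {"fraction": "input"})
    return (2.0 ** -(ip_t - in_t)) / (2.0 ** -(ip_c - in_c))


def chip_enrichment_panel(
    ct: pd.DataFrame,
    target: str,
    control: str = "his3",
    calibrator: str | None = None,
) -> list[QuantResult]:
    """Per-sample mean +/- SD ChIP enrichment over replicates, optionally
    renormalised to a calibrator sample."""
    ct = validate_ct_table(ct)
    samples = list(dict.fromkeys(ct["sample"]))
    per_sample: dict[str, np.ndarray] = {}
    for s in samples:
        reps = sorted(set(ct.loc[ct["sample"] == s, "replicate"]), key=str)
        per_sample[s] = np.array(
            [chip_enrichment(ct, target, control, s, r) for r in reps]
        )
    scale = 1.0
    if calibrator is not None:
        if calibrator not in per_sample:
            raise ValueError(f"calibrator sample {calibrator!r} absent")
        scale = float(per_sample[calibrator].mean())
        if scale <= 0:
            raise ValueError("calibrator enrichment must be positive")
    out = []
    for s in samples:
        vals = per_sample[s] / scale
        out.append(
            QuantResult(
                sample=s, mean_fold=float(vals.mean()),
                sd_fold=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                n_replicates=len(vals),
            )
        )
    return out


def normalized_mark_ratio(
    enrichment_mark: float, enrichment_histone: float,
    calibrator_ratio: float | None = None,
) -> float:
    """Histone-mark enrichment normalised to total-histone enrichment, e.g.
    H3K9me2/H3; optionally renormalised to a calibrator sample's ratio."""
    if enrichment_histone <= 0:
        raise ValueError("histone enrichment must be positive")
    ratio = enrichment_mark / enrichment_histone
    if calibrator_ratio is not None:
        if calibrator_ratio <= 0:
            raise ValueError("calibrator ratio must be positive")
        ratio /= calibrator_ratio
    return ratio
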