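"""Persistence phenotypes from barcode frequencies.

Persistence is the fractional change of a barcode's frequency in a sample
relative to the injected pool, ``(f_TF - f_T0) / f_T0``, residualised
against the mean raw phenotype of rich-medium plate controls to remove
on-plate growth differences.  Aggregation divides raw phenotypes by days
since injection, plate-corrects, and averages within brain / nonbrain
sample groups; the brain - nonbrain difference is the differential
persistence phenotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def raw_phenotype(f_tf, f_t0):
    """``(f_TF - f_T0) / f_T0``; NaN where ``f_T0`` is 0 (unmeasurable)."""
    f_tf = np.asarray(f_tf, dtype=float)
    f_t0 = np.asarray(f_t0, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (f_tf - f_t0) / f_t0
    return np.where(f_t0 > 0, out, np.nan)


def plate_correct(sample_values, control_means) -> np.ndarray:
    """Residualise one sample's raw phenotypes on the control means.

    Ordinary least squares of ``phenotype_sample ~ phenotype_control`` across
    barcodes; the residuals are the persistence values.  A constant control
    regressor degenerates to intercept-only centering.  Barcodes missing in
    either vector come back NaN.
    """
    y = np.asarray(sample_values, dtype=float)
    x = np.asarray(control_means, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 3:
        raise ValueError("need at least 3 barcodes with sample and control values")
    resid = np.full(len(y), np.nan)
    xo, yo = x[ok], y[ok]
    if np.ptp(xo) == 0:
        resid[ok] = yo - yo.mean()
        return resid
    X = np.column_stack([np.ones(ok.sum()), xo])
    beta, *_ = np.linalg.lstsq(X, yo, rcond=None)
    resid[ok] = yo - X @ beta
    return resid


def control_mean_raw(freq: pd.DataFrame, meta: pd.DataFrame, f_t0: pd.Series) -> pd.Series:
    """Mean raw phenotype over the plate-control samples, per barcode."""
    controls = meta.index[meta["type"] == "plate_control"]
    if len(controls) == 0:
        raise ValueError("no plate-control samples in metadata")
    raw = np.vstack([raw_phenotype(freq.loc[s].to_numpy(), f_t0.to_numpy())
                     for s in controls])
    return pd.Series(np.nanmean(raw, axis=0), index=freq.columns, name="control_mean")


def persistence_matrix(freq: pd.DataFrame, meta: pd.DataFrame,
                       time_correct: bool = False) -> pd.DataFrame:
    """Samples x barcodes matrix of plate-corrected persistence.

    ``freq`` holds normalised barcode frequencies with a ``T0`` row and
    plate-control rows identified via ``meta``.  With ``time_correct`` the
    raw organ phenotypes are divided by days since injection before the
    plate-control residualisation (the aggregation path).
    """
    t0_rows = meta.index[meta["type"] == "T0"]
    if len(t0_rows) != 1:
        raise ValueError("exactly one T0 sample required")
    f_t0 = freq.loc[t0_rows[0]]
    control = control_mean_raw(freq, meta, f_t0)
    organ_samples = meta.index[meta["type"] == "organ"]
    rows = {}
    for s in organ_samples:
        raw = raw_phenotype(freq.loc[s].to_numpy(), f_t0.to_numpy())
        if time_correct:
            raw = raw / float(meta.loc[s, "day"])
        rows[s] = plate_correct(raw, control.to_numpy())
    out = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    out.columns = freq.columns
    out.index.name = "sample_id"
    return out


def to_segregant_level(matrix: pd.DataFrame, barcode_assignment: pd.DataFrame,
                       replicate_index: int = 1) -> pd.DataFrame:
    """Keep one barcode per segregant and relabel columns to segregant ids."""
    sel = barcode_assignment[barcode_assignment["replicate_index"] == replicate_index]
    out = matrix[sel["barcode"].to_numpy()].copy()
    out.columns = sel["segregant_id"].to_numpy()
    return out


def aggregate(persistence: pd.DataFrame, brain_samples, nonbrain_samples) -> pd.DataFrame:
    """Per-segregant brain / nonbrain means and their difference.

    ``persistence`` is a samples x segregants matrix of (time-corrected)
    plate-corrected values.  A segregant absent from every sample of a group
    gets a missing aggregate.
    """
    brain_samples = list(brain_samples)
    nonbrain_samples = list(nonbrain_samples)
    if not brain_samples or not nonbrain_samples:
        raise ValueError("each group needs at least one sample")
    brain = persistence.loc[brain_samples].mean(axis=0, skipna=True)
    nonbrain = persistence.loc[nonbrain_samples].mean(axis=0, skipna=True)
    out = pd.DataFrame({"brain": brain, "nonbrain": nonbrain})
    out["difference"] = out["brain"] - out["nonbrain"]
    out.index = out.index.rename("segregant_id")
    return out
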