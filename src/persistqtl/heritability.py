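"""Broad-sense heritability from replicated measurements.

H² is the one-way sum-of-squares ratio SS_genotype / SS_total, with
genotype identity as the grouping factor: within a sample the groups are
the internally replicated segregants (3 barcodes each), across samples the
groups are segregants and the samples act as replicates.  The same one-way
ANOVA F-test, Bonferroni-corrected over the number of samples tested,
filters samples without significant heritable variation.

Note this ratio estimates the *realised* genotype share of the sum of
squares; with few replicates per genotype it sits well above the generating
genetic-variance fraction (its null expectation is (G-1)/(N-1), not 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator


@dataclass
class HeritabilityEstimate:
    scope: str
    h2: float
    ss_genotype: float
    ss_total: float
    n_observations: int
    n_genotypes: int
    f_statistic: float
    p_value: float


class HeritabilityEstimator(BaseEstimator):
    """One-way sum-of-squares H² estimator.

    ``fit(y, groups)`` decomposes the observations by genotype identity and
    exposes ``h2_``, ``f_``, ``p_value_`` and the full
    :class:`HeritabilityEstimate` as ``estimate_``.

    Parameters
    ----------
    scope : str, default "within_sample"
        Label recorded on the estimate (within_sample / across_samples).
    """

    def __init__(self, scope: str = "within_sample"):
        self.scope = scope

    def fit(self, y, groups):
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        ok = np.isfinite(y)
        y, groups = y[ok], groups[ok]
        labels, inverse = np.unique(groups, return_inverse=True)
        n, g = len(y), len(labels)
        if g < 2:
            raise ValueError("need at least 2 genotypes")
        counts = np.bincount(inverse)
        if counts.max() < 2:
            raise ValueError("need at least one genotype with >= 2 observations")
        grand = y.mean()
        means = np.bincount(inverse, weights=y) / counts
        ss_g = float(np.sum(counts * (means - grand) ** 2))
        ss_tot = float(np.sum((y - grand) ** 2))
        if ss_tot == 0:
            raise ValueError("zero total sum of squares: H2 undefined")
        h2 = ss_g / ss_tot
        df1, df2 = g - 1, n - g
        if df2 <= 0 or ss_tot - ss_g <= 0:
            f = np.inf
            p = 0.0
        else:
            f = (ss_g / df1) / ((ss_tot - ss_g) / df2)
            p = float(stats.f.sf(f, df1, df2))
        self.estimate_ = HeritabilityEstimate(
            scope=self.scope, h2=h2, ss_genotype=ss_g, ss_total=ss_tot,
            n_observations=n, n_genotypes=g, f_statistic=float(f), p_value=p,
        )
        self.h2_, self.f_, self.p_value_ = h2, float(f), p
        return self


def h2_from_replicates(values, genotype_labels,
                       scope: str = "within_sample") -> HeritabilityEstimate:
    """H² from observations grouped by genotype identity."""
    return HeritabilityEstimator(scope=scope).fit(values, genotype_labels).estimate_


def across_sample_h2(persistence: pd.DataFrame) -> HeritabilityEstimate:
    """H² across samples: segregants are groups, samples are replicates.

    ``persistence`` is samples x segregants (one barcode per segregant).
    """
    if len(persistence) < 2:
        raise ValueError("need at least 2 samples")
    long = persistence.stack(future_stack=True).dropna()
    return h2_from_replicates(
        long.to_numpy(), long.index.get_level_values(1).to_numpy(),
        scope="across_samples",
    )


def significance_filter(
    persistence: pd.DataFrame,
    barcode_assignment: pd.DataFrame,
    alpha: float = 0.05,
    n_samples_tested: int | None = None,
    exclude=(),
) -> pd.DataFrame:
    """Per-sample replicated-segregant ANOVA with a Bonferroni threshold.

    For each sample, the triplicate-barcode segregants provide a one-way
    ANOVA of persistence on segregant identity; samples are kept when
    P <= alpha / n_samples_tested.  ``exclude`` lists sample_ids dropped by
    configuration (e.g. distorted libraries).  Returns a frame with columns
    ``h2, p_value, kept, reason`` indexed by sample.
    """
    reps = barcode_assignment[
        barcode_assignment["segregant_id"].map(
            barcode_assignment["segregant_id"].value_counts()) >= 2
    ]
    if len(reps) == 0:
        raise ValueError("no replicated barcodes available")
    if n_samples_tested is None:
        n_samples_tested = len(persistence)
    threshold = alpha / n_samples_tested
    rows = {}
    for sample in persistence.index:
        vals = persistence.loc[sample, reps["barcode"]].to_numpy(dtype=float)
        labels = reps["segregant_id"].to_numpy()
        ok = np.isfinite(vals)
        reason = ""
        if sample in exclude:
            h2, p, kept, reason = np.nan, np.nan, False, "excluded_by_config"
        else:
            try:
                est = h2_from_replicates(vals[ok], labels[ok])
                h2, p = est.h2, est.p_value
                kept = p <= threshold
                if not kept:
                    reason = "not_significant"
            except ValueError as err:
                h2, p, kept, reason = np.nan, np.nan, False, str(err)
        rows[sample] = (h2, p, kept, reason)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["h2", "p_value", "kept", "reason"])
    out.index.name = "sample_id"
    out.attrs["bonferroni_threshold"] = threshold
    return out


def apply_organ_replicate_rule(filter_table: pd.DataFrame, meta: pd.DataFrame,
                               min_replicates: int = 2) -> pd.DataFrame:
    """Drop organs with fewer than ``min_replicates`` significant samples.

    A lone significant sample of an organ cannot be checked for
    reproducibility, so its organ is removed from downstream analysis.
    """
    out = filter_table.copy()
    organs = meta.loc[out.index, "organ"]
    for organ, grp in out.groupby(organs):
        if grp["kept"].sum() < min_replicates and grp["kept"].any():
            sel = (organs == organ) & out["kept"]
            out.loc[sel, "kept"] = False
            out.loc[sel, "reason"] = "organ_below_min_replicates"
    return out
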