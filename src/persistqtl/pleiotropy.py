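"""General vs antagonistically pleiotropic loci and their joint effects.

A locus with same-sign brain and nonbrain effects is *general*: one allele
helps everywhere in the host.  Opposite signs mark *antagonistic
pleiotropy*: each parental allele is beneficial in a different body
compartment.  Allele-dose analyses then count, per segregant, the
beneficial alleles at general loci and the brain-favouring alleles at
antagonistic loci, classify segregants as enriched/depleted for each set,
and relate the counts to persistence (dose regressions, per-segregant time
slopes, a 2x2 contingency test, and a day-1 to day-5 time-course summary).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def classify(brain_delta: float, nonbrain_delta: float) -> dict:
    """Quadrant classification of a locus from its two context effects.

    Returns a dict with ``locus_class`` (general/antagonistic), the
    beneficial allele in each context (3S when the delta is positive, else
    BY) and a ``degenerate`` flag for an exactly-zero delta, which is
    classified by the other context's sign.
    """
    if not (np.isfinite(brain_delta) and np.isfinite(nonbrain_delta)):
        raise ValueError("deltas must be finite")
    degenerate = brain_delta == 0 or nonbrain_delta == 0
    b = brain_delta if brain_delta != 0 else nonbrain_delta
    n = nonbrain_delta if nonbrain_delta != 0 else brain_delta
    if b == 0 and n == 0:
        raise ValueError("both deltas are exactly zero; class undefined")
    cls = "general" if np.sign(b) == np.sign(n) else "antagonistic"
    return {
        "locus_class": cls,
        "beneficial_brain": "3S" if b > 0 else "BY",
        "beneficial_nonbrain": "3S" if n > 0 else "BY",
        "degenerate": degenerate,
    }


def classify_table(effects: pd.DataFrame) -> pd.DataFrame:
    """Classify every locus of an effect table (``brain_delta``/``nonbrain_delta``)."""
    rows = []
    for _, row in effects.iterrows():
        rec = {"locus_id": row["locus_id"], "effect_marker": row["effect_marker"],
               "brain_delta": row["brain_delta"], "nonbrain_delta": row["nonbrain_delta"]}
        rec.update(classify(row["brain_delta"], row["nonbrain_delta"]))
        rows.append(rec)
    return pd.DataFrame(rows)


def allele_dose(genotypes: pd.DataFrame, locus_classes: pd.DataFrame,
                general_enriched: int = 7, general_depleted: int = 3,
                brain_enriched: int = 6, brain_depleted: int = 3,
                auto_tune: bool = False, max_enriched_fraction: float = 0.25
                ) -> pd.DataFrame:
    """Beneficial-allele counts and enrichment classes per segregant.

    ``n_general_beneficial`` counts beneficial alleles at general loci;
    ``n_brain_favoring`` counts brain-favouring alleles at antagonistic
    loci.  Segregants with counts at/above the enriched cutoff (defaults 7
    general, 6 brain) are "enriched"; below the depleted cutoff (< 3)
    "depleted"; otherwise "neither".  ``auto_tune`` instead raises/lowers
    each pair of cutoffs symmetrically until no more than
    ``max_enriched_fraction`` of segregants fall in either tail.
    """
    if len(locus_classes) == 0 or "locus_class" not in locus_classes.columns:
        general = antagonistic = locus_classes.iloc[0:0]
    else:
        general = locus_classes[locus_classes["locus_class"] == "general"]
        antagonistic = locus_classes[locus_classes["locus_class"] == "antagonistic"]

    def count(loci: pd.DataFrame, context: str) -> np.ndarray:
        total = np.zeros(len(genotypes), dtype=int)
        for _, row in loci.iterrows():
            alleles = genotypes[row["effect_marker"]].to_numpy()
            beneficial_is_3s = row[f"beneficial_{context}"] == "3S"
            total += np.where(alleles == 1, beneficial_is_3s, not beneficial_is_3s)
        return total

    n_gen = count(general, "brain")  # general loci: same allele in both contexts
    n_brain = count(antagonistic, "brain")

    def tune(counts, n_loci, enriched, depleted):
        if not auto_tune or len(counts) == 0 or n_loci == 0:
            return enriched, depleted
        enriched, depleted = n_loci, 1
        while enriched > 1 and np.mean(counts >= enriched - 1) <= max_enriched_fraction:
            enriched -= 1
        while depleted < n_loci and np.mean(counts < depleted + 1) <= max_enriched_fraction:
            depleted += 1
        return enriched, depleted

    ge, gd = tune(n_gen, len(general), general_enriched, general_depleted)
    be, bd = tune(n_brain, len(antagonistic), brain_enriched, brain_depleted)

    def label(counts, enriched, depleted, n_loci):
        if n_loci == 0:
            return np.full(len(counts), "neither", dtype=object)
        out = np.full(len(counts), "neither", dtype=object)
        out[counts >= enriched] = "enriched"
        out[counts < depleted] = "depleted"
        return out

    out = pd.DataFrame({
        "n_general_beneficial": n_gen,
        "n_brain_favoring": n_brain,
        "general_class": label(n_gen, ge, gd, len(general)),
        "brain_class": label(n_brain, be, bd, len(antagonistic)),
    }, index=genotypes.index.rename("segregant_id"))
    out.attrs["thresholds"] = {"general": (ge, gd), "brain": (be, bd)}
    return out


def dose_regression(aggregate_values, counts):
    """Simple OLS of a context aggregate on an allele-dose count.

    Returns ``(r_squared, p_value, slope)`` of ``phenotype ~ num_loci``.
    """
    y = np.asarray(aggregate_values, dtype=float)
    x = np.asarray(counts, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 3:
        raise ValueError("need at least 3 segregants")
    if np.ptp(x[ok]) == 0:
        raise ValueError("constant allele-dose count; regression undefined")
    res = stats.linregress(x[ok], y[ok])
    return float(res.rvalue ** 2), float(res.pvalue), float(res.slope)


def time_slope(values, days):
    """OLS slope of one segregant's persistence on days postinjection."""
    y = np.asarray(values, dtype=float)
    t = np.asarray(days, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    if len(np.unique(t[ok])) < 2:
        raise ValueError("need at least 2 distinct days")
    return float(stats.linregress(t[ok], y[ok]).slope)


def time_slopes(persistence: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
    """Per-segregant time slopes over a set of organ samples."""
    days = meta.loc[persistence.index, "day"].to_numpy(dtype=float)
    out = {}
    for seg in persistence.columns:
        try:
            out[seg] = time_slope(persistence[seg].to_numpy(), days)
        except ValueError:
            out[seg] = np.nan
    return pd.Series(out, name="time_slope")


def enrichment_contingency(doses: pd.DataFrame, slopes: pd.Series):
    """2x2 chi-square: enriched-for-both vs not x positive slope vs not.

    Pearson chi-square on 1 df without continuity correction.  Returns
    ``(chi2, p_value, table)``.
    """
    common = doses.index.intersection(slopes.dropna().index)
    both = ((doses.loc[common, "general_class"] == "enriched")
            & (doses.loc[common, "brain_class"] == "enriched"))
    positive = slopes.loc[common] > 0
    table = np.array([
        [int((both & positive).sum()), int((both & ~positive).sum())],
        [int((~both & positive).sum()), int((~both & ~positive).sum())],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), table


def timecourse_summary(persistence: pd.DataFrame, meta: pd.DataFrame,
                       doses: pd.DataFrame, n_boot: int = 1000,
                       seed: int = 0) -> pd.DataFrame:
    """Mean day-5 persistence change per enrichment group, with bootstrap.

    Per segregant, mean day-1 and day-5 persistence are computed over the
    supplied samples and the day-5 mean is normalised by subtracting the
    day-1 mean.  Segregants are grouped 2x2 by general enrichment
    (enriched vs depleted) and brain enrichment; each group's mean
    normalised change, standard error and ``n_boot`` bootstrap means of the
    change are reported.  Empty groups are omitted.
    """
    days = meta.loc[persistence.index, "day"]
    d1 = persistence.loc[days[days == 1].index].mean(axis=0, skipna=True)
    d5 = persistence.loc[days[days == 5].index].mean(axis=0, skipna=True)
    if d1.isna().all() or d5.isna().all():
        raise ValueError("day-1 and day-5 samples are both required")
    change = d5 - d1
    rng = np.random.default_rng(seed)
    rows = []
    for g_cls in ("enriched", "depleted"):
        for b_cls in ("enriched", "depleted"):
            segs = doses.index[(doses["general_class"] == g_cls)
                               & (doses["brain_class"] == b_cls)]
            vals = change.reindex(segs).dropna().to_numpy()
            if len(vals) == 0:
                continue
            boots = vals[rng.integers(0, len(vals), size=(n_boot, len(vals)))].mean(axis=1)
            rows.append({
                "general_class": g_cls, "brain_class": b_cls,
                "n_segregants": len(vals),
                "mean_change": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                "boot_low": float(np.percentile(boots, 2.5)),
                "boot_high": float(np.percentile(boots, 97.5)),
            })
    return pd.DataFrame(rows)
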