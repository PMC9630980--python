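"""Merging detections into distinct loci and measuring allele effects.

Two detections belong to the same locus when their confidence intervals
overlap (closed intervals; a shared endpoint counts).  Merging is
transitive: overlap chains on a chromosome form connected components, each
becoming one consolidated locus with a union interval (merge extent) and an
intersection interval (locus resolution).  A chain whose intersection is
empty is flagged and the intersection collapses to a zero-length point at
the region of deepest interval coverage.

Effect sizes are allele-class mean differences, 3S minus BY, with
percentile bootstrap confidence intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def consolidate(detections: pd.DataFrame) -> pd.DataFrame:
    """Merge detections with overlapping CIs into consolidated loci.

    Expects the detection-table columns ``chromosome, ci_start_position,
    ci_end_position`` (plus ``peak_p``/``peak_marker`` used to pick each
    locus's representative marker).  Returns one row per locus with union
    and intersection bounds, member count and member row labels.
    """
    cols = ["locus_id", "chromosome", "union_start", "union_end",
            "intersection_start", "intersection_end", "intersection_empty",
            "n_detections", "effect_marker", "members"]
    if len(detections) == 0:
        return pd.DataFrame(columns=cols)
    loci = []
    for chrom, grp in detections.groupby("chromosome", sort=True):
        grp = grp.sort_values(["ci_start_position", "ci_end_position"],
                              kind="mergesort")
        component: list = []
        reach = None
        for label, row in grp.iterrows():
            s, e = int(row["ci_start_position"]), int(row["ci_end_position"])
            if reach is not None and s > reach:
                loci.append((chrom, component))
                component = []
            component.append((label, s, e))
            reach = e if reach is None or s > reach else max(reach, e)
        if component:
            loci.append((chrom, component))

    rows = []
    for k, (chrom, members) in enumerate(loci):
        starts = np.array([s for _, s, _ in members])
        ends = np.array([e for _, _, e in members])
        inter_s, inter_e = int(starts.max()), int(ends.min())
        empty = inter_s > inter_e
        if empty:
            # zero-length point at the deepest-coverage boundary
            events = sorted([(s, 1) for s in starts] + [(e + 1, -1) for e in ends])
            depth = best = 0
            at = int(starts.min())
            for pos, d in events:
                depth += d
                if depth > best:
                    best, at = depth, pos
            inter_s = inter_e = int(at)
        labels = [lab for lab, _, _ in members]
        sub = detections.loc[labels]
        rep = sub["peak_marker"].iloc[int(np.argmin(sub["peak_p"].to_numpy()))]
        rows.append({
            "locus_id": f"locus_{chrom:02d}_{k:03d}",
            "chromosome": int(chrom),
            "union_start": int(starts.min()), "union_end": int(ends.max()),
            "intersection_start": inter_s, "intersection_end": inter_e,
            "intersection_empty": bool(empty),
            "n_detections": len(members),
            "effect_marker": rep,
            "members": ";".join(str(lab) for lab in labels),
        })
    return pd.DataFrame(rows, columns=cols)


def locus_effect(phenotypes, alleles) -> float:
    """Allele-class mean difference ``mean(3S) - mean(BY)``.

    A positive value means the 3S allele is beneficial in this context.
    Raises if either allele class has no measured segregant.
    """
    y = np.asarray(phenotypes, dtype=float)
    a = np.asarray(alleles)
    ok = np.isfinite(y)
    y, a = y[ok], a[ok]
    if not np.any(a == 1) or not np.any(a == 0):
        raise ValueError("both allele classes must be non-empty")
    return float(y[a == 1].mean() - y[a == 0].mean())


def bootstrap_ci(phenotypes, alleles, n_boot: int = 1000, seed: int = 0,
                 level: float = 0.95):
    """Percentile bootstrap CI for the allele-effect difference.

    Each allele class is resampled with replacement ``n_boot`` times and the
    3S-BY mean difference recomputed; the interval is the (2.5th, 97.5th)
    percentiles at the default level.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y = np.asarray(phenotypes, dtype=float)
    a = np.asarray(alleles)
    ok = np.isfinite(y)
    y, a = y[ok], a[ok]
    y1, y0 = y[a == 1], y[a == 0]
    if len(y1) == 0 or len(y0) == 0:
        raise ValueError("both allele classes must be non-empty")
    rng = np.random.default_rng(seed)
    m1 = y1[rng.integers(0, len(y1), size=(n_boot, len(y1)))].mean(axis=1)
    m0 = y0[rng.integers(0, len(y0), size=(n_boot, len(y0)))].mean(axis=1)
    deltas = m1 - m0
    alpha = (1.0 - level) / 2.0
    return (float(np.percentile(deltas, 100 * alpha)),
            float(np.percentile(deltas, 100 * (1 - alpha))))


def locus_effect_table(loci: pd.DataFrame, aggregates: pd.DataFrame,
                       genotypes: pd.DataFrame, n_boot: int = 1000,
                       seed: int = 0) -> pd.DataFrame:
    """Brain and nonbrain effects with bootstrap CIs for consolidated loci.

    ``aggregates`` is the per-segregant frame with ``brain`` and
    ``nonbrain`` columns; ``genotypes`` provides alleles at each locus's
    effect marker.
    """
    rows = []
    common = aggregates.index.intersection(genotypes.index)
    agg = aggregates.loc[common]
    for i, row in loci.iterrows():
        alleles = genotypes.loc[common, row["effect_marker"]].to_numpy()
        rec = {"locus_id": row["locus_id"], "effect_marker": row["effect_marker"]}
        for ctx in ("brain", "nonbrain"):
            y = agg[ctx].to_numpy()
            rec[f"{ctx}_delta"] = locus_effect(y, alleles)
            lo, hi = bootstrap_ci(y, alleles, n_boot=n_boot, seed=seed + i)
            rec[f"{ctx}_ci_low"], rec[f"{ctx}_ci_high"] = lo, hi
        rows.append(rec)
    return pd.DataFrame(rows)
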