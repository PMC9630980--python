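"""Genotype correction for low-coverage sequencing of a haploid cross.

Noisy per-site 3S-fraction tracks are thresholded into preliminary binary
calls and then corrected per chromosome with a two-state hidden Markov model
(states = parental alleles BY/3S).  Missing sites emit with likelihood 1 in
both states, so the Viterbi path imputes them from their neighbours.
Adjacent markers that never recombine across the panel carry identical
information and are collapsed to a single representative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

MISSING = -1  # internal code for missing calls


def threshold_calls(fractions) -> np.ndarray:
    """Threshold observed 3S fractions into preliminary calls.

    Fractions above 0.5 are called 3S (1), below 0.5 BY (0).  Exactly 0.5
    carries no information for a haploid and is treated as missing, as are
    NaN (zero-coverage) sites.  Returns an int8 array with -1 for missing.
    """
    frac = np.asarray(fractions, dtype=float)
    finite = np.isfinite(frac)
    if np.any((frac[finite] < 0) | (frac[finite] > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    calls = np.full(frac.shape, MISSING, dtype=np.int8)
    calls[finite & (frac > 0.5)] = 1
    calls[finite & (frac < 0.5)] = 0
    return calls


def viterbi_path(calls, stay_probability=0.9999, concordant_emission=0.75) -> np.ndarray:
    """Most probable state path for one chromosome of binary calls.

    ``calls`` uses -1 for missing sites (emission likelihood 1 in both
    states).  Initial distribution is uniform; ties prefer state 0.
    """
    calls = np.asarray(calls)
    n = len(calls)
    if n == 0:
        return np.zeros(0, dtype=np.int8)
    if not 0 < stay_probability < 1 or not 0 < concordant_emission < 1:
        raise ValueError("probabilities must lie in (0, 1)")
    log_stay = np.log(stay_probability)
    log_switch = np.log(1.0 - stay_probability)
    log_hit = np.log(concordant_emission)
    log_miss = np.log(1.0 - concordant_emission)

    def emit(obs):
        if obs == MISSING:
            return (0.0, 0.0)
        return (log_hit, log_miss) if obs == 0 else (log_miss, log_hit)

    delta = np.array(emit(calls[0]))  # uniform prior cancels in argmax
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        e = emit(calls[t])
        new = np.empty(2)
        for j in (0, 1):
            from_same = delta[j] + log_stay
            from_other = delta[1 - j] + log_switch
            # strict > keeps the lower-numbered predecessor on ties
            if from_other > from_same:
                back[t, j] = 1 - j
                new[j] = from_other + e[j]
            else:
                back[t, j] = j
                new[j] = from_same + e[j]
        delta = new
    path = np.empty(n, dtype=np.int8)
    path[-1] = 0 if delta[0] >= delta[1] else 1
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


class HmmGenotypeCorrector(BaseEstimator, TransformerMixin):
    """HMM correction and imputation of preliminary genotype calls.

    A two-state chain per chromosome with a high stay probability (default
    0.9999) models the meiotic block structure; emissions are 0.75 for the
    concordant call and 0.25 for the discordant one.  ``transform`` maps a
    segregants x markers frame of observed 3S fractions (NaN = missing) to a
    fully called 0/1 genotype matrix via the Viterbi path.

    Parameters
    ----------
    stay_probability : float, default 0.9999
        Per-step probability of remaining in the same parental state.
    concordant_emission : float, default 0.75
        Probability that a preliminary call matches the hidden state.
    """

    def __init__(self, stay_probability: float = 0.9999,
                 concordant_emission: float = 0.75):
        self.stay_probability = stay_probability
        self.concordant_emission = concordant_emission

    def fit(self, X=None, y=None):
        if not 0 < self.stay_probability < 1 or not 0 < self.concordant_emission < 1:
            raise ValueError("probabilities must lie in (0, 1)")
        self.n_states_ = 2
        return self

    def correct_track(self, calls, chromosomes) -> np.ndarray:
        """Correct one segregant's preliminary calls, chromosome by chromosome."""
        calls = np.asarray(calls)
        chromosomes = np.asarray(chromosomes)
        out = np.empty(len(calls), dtype=np.int8)
        for chrom in pd.unique(chromosomes):
            sel = chromosomes == chrom
            out[sel] = viterbi_path(
                calls[sel], self.stay_probability, self.concordant_emission
            )
        return out

    def transform(self, X: pd.DataFrame, marker_map: pd.DataFrame) -> pd.DataFrame:
        """Threshold + Viterbi-correct a frame of observed 3S fractions."""
        self.fit()
        chroms = marker_map["chromosome"].to_numpy()
        if len(chroms) != X.shape[1]:
            raise ValueError("marker map length does not match track length")
        rows = [self.correct_track(threshold_calls(X.iloc[i].to_numpy()), chroms)
                for i in range(len(X))]
        return pd.DataFrame(np.vstack(rows), index=X.index, columns=X.columns, dtype=np.int8)


def hmm_correct(fractions: pd.DataFrame, marker_map: pd.DataFrame,
                stay_probability: float = 0.9999,
                concordant_emission: float = 0.75) -> pd.DataFrame:
    """Functional wrapper over :class:`HmmGenotypeCorrector`."""
    return HmmGenotypeCorrector(stay_probability, concordant_emission).transform(
        fractions, marker_map
    )


def collapse_markers(genotypes: pd.DataFrame, marker_map: pd.DataFrame):
    """Collapse adjacent markers that never recombine across the panel.

    Maximal runs of adjacent same-chromosome markers with identical genotype
    columns are replaced by their first marker.  Returns ``(reduced
    genotypes, reduced map)`` where the map gains ``group_start, group_end,
    n_collapsed`` columns recording each run's physical extent.
    """
    if genotypes.isna().any().any():
        raise ValueError("genotype matrix must be fully called")
    marker_map = marker_map.reset_index(drop=True)
    G = genotypes.to_numpy()
    chroms = marker_map["chromosome"].to_numpy()
    keep, starts, ends, sizes = [], [], [], []
    i = 0
    while i < G.shape[1]:
        j = i + 1
        while (j < G.shape[1] and chroms[j] == chroms[i]
               and np.array_equal(G[:, j], G[:, i])):
            j += 1
        keep.append(i)
        starts.append(int(marker_map["position"].iloc[i]))
        ends.append(int(marker_map["position"].iloc[j - 1]))
        sizes.append(j - i)
        i = j
    reduced = genotypes.iloc[:, keep].copy()
    rmap = marker_map.iloc[keep].copy().reset_index(drop=True)
    rmap["group_start"] = starts
    rmap["group_end"] = ends
    rmap["n_collapsed"] = sizes
    return reduced, rmap
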