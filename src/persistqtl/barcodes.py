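"""From barcode sequencing reads to per-sample frequencies.

Reads arrive as flat records (sample, 20-mer barcode, UMI, mean base
quality, flank flag).  Processing follows the assay's logic: drop reads
below the quality floor or lacking the landing-pad flank, collapse PCR
duplicates to one read per UMI within a sample, assign each read to the
unique whitelist barcode within a Hamming radius (the barcode library is
known, so de novo clustering is unnecessary), and normalise counts to
frequencies within each sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

READ_COLUMNS = ["sample_id", "barcode", "umi", "quality", "flank_ok"]


def _encode(seqs) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


def filter_and_dedup(reads: pd.DataFrame, min_quality: float = 30.0,
                     require_flank: bool = True) -> pd.DataFrame:
    """Quality/flank filter, then one read per (sample, UMI).

    Reads with mean quality below ``min_quality`` (boundary inclusive: 30.0
    is kept) or with a missing landing-pad flank are removed; within each
    sample the first read per distinct UMI is retained.
    """
    if len(reads) == 0:
        return reads.copy()
    kept = reads[reads["quality"] >= min_quality]
    if require_flank:
        kept = kept[kept["flank_ok"].astype(bool)]
    return kept.drop_duplicates(subset=["sample_id", "umi"], keep="first").reset_index(drop=True)


def check_whitelist_separation(known_barcodes, max_hamming: int) -> None:
    """Require pairwise Hamming distance > 2*max_hamming on the whitelist."""
    enc = _encode(list(known_barcodes))
    if len(enc) < 2:
        return
    # chunked pairwise distances; whitelists are ~1e3 so this is cheap
    for i in range(0, len(enc), 256):
        block = enc[i:i + 256]
        d = (block[:, None, :] != enc[None, :, :]).sum(axis=2)
        np.fill_diagonal(d[:, i:i + block.shape[0]], 2 * max_hamming + 1)
        if d.min() <= 2 * max_hamming:
            raise ValueError(
                "whitelist barcodes are closer than 2*max_hamming; assignment "
                "within the radius would be ambiguous"
            )


def cluster_to_known(reads: pd.DataFrame, known_barcodes,
                     max_hamming: int = 3) -> pd.DataFrame:
    """Assign reads to whitelist barcodes within a Hamming radius.

    Each read is counted toward the unique known barcode within
    ``max_hamming`` mismatches; reads farther than that from every known
    barcode are discarded.  Returns a samples x known-barcodes count table
    (all whitelist columns present, zero-filled).
    """
    known = list(known_barcodes)
    check_whitelist_separation(known, max_hamming)
    samples = sorted(reads["sample_id"].unique()) if len(reads) else []
    counts = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"),
                          columns=known, dtype=np.int64)
    if len(reads) == 0:
        return counts
    enc_known = _encode(known)
    seqs = reads["barcode"].to_numpy()
    assigned = np.full(len(reads), -1, dtype=np.int64)
    for i in range(0, len(reads), 4096):
        block = _encode(list(seqs[i:i + 4096]))
        d = (block[:, None, :] != enc_known[None, :, :]).sum(axis=2)
        best = d.argmin(axis=1)
        ok = d[np.arange(len(block)), best] <= max_hamming
        assigned[i:i + len(block)][ok] = best[ok]
    hit = assigned >= 0
    tab = pd.crosstab(reads.loc[hit, "sample_id"], assigned[hit])
    for col in tab.columns:
        counts.loc[tab.index, known[col]] += tab[col].to_numpy()
    return counts


def normalize(counts: pd.DataFrame):
    """Per-sample frequencies ``f = count / sample total``.

    Returns ``(frequencies, unusable)``: samples with zero total reads get
    NaN frequencies and are listed in ``unusable``.
    """
    totals = counts.sum(axis=1)
    unusable = list(totals.index[totals == 0])
    freq = counts.div(totals.where(totals > 0), axis=0)
    return freq, unusable


def true_barcode_share(counts: pd.DataFrame, min_share: float = 0.05) -> pd.DataFrame:
    """Validation utility: barcodes holding > ``min_share`` of a sample's reads.

    Mirrors the library-determination rule used when assigning barcodes to
    strains; it is not part of the quantification path.
    """
    freq, _ = normalize(counts)
    return freq.gt(min_share)
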