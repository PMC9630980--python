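"""Plain-TSV readers and writers for every pipeline table.

All tables are tab-separated with header rows; genomic coordinates are
1-based inclusive; missing values are written as ``NA``.  Floats are
formatted with a fixed ``%.10g`` so repeated runs with the same seed are
byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format=FLOAT_FORMAT)


def read_marker_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[["marker_id", "chromosome", "position"]].assign(
        chromosome=lambda d: d["chromosome"].astype(int),
        position=lambda d: d["position"].astype(int),
    )


def read_matrix(path, dtype=float) -> pd.DataFrame:
    """Rows x columns numeric table with a leading index column."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return df.astype(dtype)


def read_genotypes(path) -> pd.DataFrame:
    return read_matrix(path, dtype="int8")


def read_counts(path) -> pd.DataFrame:
    return read_matrix(path, dtype="int64")


def read_sample_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                     na_values=[])
    df["day"] = df["day"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    return df


def read_barcode_assignment(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[["barcode", "segregant_id", "replicate_index"]].assign(
        replicate_index=lambda d: d["replicate_index"].astype(int)
    )


def read_reads(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["flank_ok"] = df["flank_ok"].astype(bool)
    return df


def write_truth(truth: dict, directory) -> None:
    directory = Path(directory)
    write_tsv(truth["loci"], directory / "truth_loci.tsv", index=False)
    write_tsv(truth["t0_frequencies"].to_frame(), directory / "truth_t0_frequencies.tsv")
    write_tsv(truth["plate_log_growth"].to_frame(), directory / "truth_plate_growth.tsv")
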