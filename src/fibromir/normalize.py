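"""Per-platform abundance normalizations.

Small-RNA profiles are scaled to transcripts per million (TPM) without a
length term: mature miRNAs are near-constant in length, so small-RNA TPM is a
count-per-million. mRNA profiles are standardized as fragments per kilobase
of transcript per million mapped fragments (FPKM), which requires a per-gene
length table.

Differential-expression testing operates on raw counts with size factors, not
on these normalized matrices; TPM/FPKM feed the cross-sample Pearson
correlations of the integration stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, FormatError


@dataclass
class ExpressionMatrix:
    """Non-negative real-valued abundances with a unit tag."""

    values: pd.DataFrame
    unit: str  # "TPM" | "FPKM" | "normalized-count"

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    def log2p1(self) -> pd.DataFrame:
        """log2(x + 1), the default transform for correlation analysis."""
        return np.log2(self.values + 1.0)


def tpm_mirna(counts: CountMatrix) -> ExpressionMatrix:
    """Transcripts per million for small-RNA counts (no length term).

    value = count / column-total x 1e6; every column sums to 1e6.
    """
    mat = counts.counts.astype(float)
    totals = mat.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValueError(f"all-zero sample column {zero.index[0]!r}")
    return ExpressionMatrix(mat.div(totals, axis=1) * 1e6, unit="TPM")


def fpkm(counts: CountMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Fragments per kilobase per million mapped fragments.

    value = count / (length/1e3) / (column-total/1e6).
    ``lengths`` maps every feature to its length in bp (> 0).
    """
    missing = counts.features.difference(lengths.index)
    if len(missing) > 0:
        raise ValueError(f"missing length for feature {missing[0]!r}")
    lens = lengths.loc[counts.features].astype(float)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0][0]
        raise ValueError(f"non-positive length for feature {bad!r}")
    mat = counts.counts.astype(float)
    totals = mat.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValueError(f"all-zero sample column {zero.index[0]!r}")
    per_kb = mat.div(lens / 1e3, axis=0)
    return ExpressionMatrix(per_kb.div(totals / 1e6, axis=1), unit="FPKM")


def read_lengths(path: str | Path) -> pd.Series:
    """Read a gene-length TSV with columns ``gene`` and ``length_bp``."""
    tab = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "length_bp"):
        if col not in tab.columns:
            raise FormatError(f"{Path(path).name}: missing column {col!r}")
    return pd.Series(tab["length_bp"].values, index=tab["gene"].values, name="length_bp")


def write_lengths(lengths: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"gene": lengths.index, "length_bp": lengths.values}).to_csv(
        path, sep="\t", index=False
    )
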