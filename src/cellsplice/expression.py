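"""Gene-expression quantification: mappability-corrected RPKM and
median-of-ratios size-factor normalization.

cRPKM (corrected reads per kilobase per million mapped reads) divides a
gene's read count by the number of uniquely mappable positions in the
gene rather than its annotated length, so genes with repetitive or
poorly mappable sequence are not under-quantified:

    cRPKM = raw * 1e9 / (mappable_positions * total_mapped)

Size factors follow the median-of-ratios scheme: each sample's factor is
the median, across genes expressed in every sample, of the ratio of its
count to the gene's geometric mean across samples.  Dividing counts by
the factors removes library-size and composition differences.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def compute_crpkm(raw: float, mappable_positions: int, total_mapped: float) -> float:
    """cRPKM of one gene in one sample."""
    if mappable_positions <= 0:
        raise ValueError("mappable_positions must be > 0")
    if total_mapped <= 0:
        raise ValueError("total_mapped (library size) must be > 0")
    if raw < 0:
        raise ValueError("raw count must be >= 0")
    return raw * 1e9 / (mappable_positions * total_mapped)


def crpkm_matrix(raw: pd.DataFrame, mappable_positions: pd.Series) -> pd.DataFrame:
    """cRPKM for a gene x sample count matrix.

    The per-sample library size is the column sum of ``raw``.
    """
    lengths = mappable_positions.reindex(raw.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:5]
        raise ValueError(f"mappable positions missing for genes {missing}")
    if (lengths <= 0).any():
        raise ValueError("mappable positions must be > 0 for every gene")
    totals = raw.sum(axis=0)
    if (totals <= 0).any():
        empty = totals[totals <= 0].index.tolist()
        raise ValueError(f"samples with zero mapped reads: {empty}")
    return raw.div(lengths, axis=0).div(totals, axis=1) * 1e9


def _lower_median(values: np.ndarray) -> float:
    # Deterministic lower-median: element (n-1)//2 of the sorted values.
    srt = np.sort(values)
    return float(srt[(len(srt) - 1) // 2])


def size_factors(raw: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Genes with a zero count in any sample are excluded from the
    reference; with a single sample the factor is 1 by convention.
    """
    if raw.shape[1] == 1:
        return pd.Series([1.0], index=raw.columns)
    nonzero = raw[(raw > 0).all(axis=1)]
    if nonzero.empty:
        raise ValueError(
            "no gene has nonzero counts in every sample; size factors are undefined "
            "(consider a pseudo-reference over nonzero genes)"
        )
    log_geomean = np.log(nonzero).mean(axis=1)
    ratios = np.log(nonzero).sub(log_geomean, axis=0)
    factors = ratios.apply(lambda col: np.exp(_lower_median(col.to_numpy())), axis=0)
    return factors


@dataclass
class ExpressionMatrix:
    """Gene x sample expression container.

    Holds the raw integer counts, per-gene mappable positions, derived
    cRPKM, size factors and size-factor-normalized counts.
    """

    raw: pd.DataFrame
    mappable_positions: pd.Series
    crpkm: pd.DataFrame
    norm_counts: pd.DataFrame
    size_factors: pd.Series

    @classmethod
    def from_raw(cls, raw: pd.DataFrame, mappable_positions: pd.Series) -> "ExpressionMatrix":
        if (raw.to_numpy() < 0).any():
            raise ValueError("raw counts must be >= 0")
        crpkm = crpkm_matrix(raw, mappable_positions)
        factors = size_factors(raw)
        norm = raw.div(factors, axis=1)
        return cls(raw=raw, mappable_positions=mappable_positions.reindex(raw.index),
                   crpkm=crpkm, norm_counts=norm, size_factors=factors)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.raw.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.raw.columns)
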