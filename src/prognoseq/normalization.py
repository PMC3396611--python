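"""Third-quartile normalization of log2 RNA counts, with RLE diagnostics.

Raw counts are log2-transformed with the convention log2(0) := 0 (which
collides with log2(1) = 0 by construction; the collision is deliberate and
retained, not patched with pseudocounts). Each sample is then shifted so that
its 3rd quartile over a reference feature class (RefSeq for RefSeq and
intergenic matrices, intronic for intronic matrices) equals the cohort mean
3rd quartile. Features never reaching a maximum count of 5 in any sample are
excluded beforehand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountMatrix


@dataclass
class NormalizedMatrix:
    """Log2-scale feature x sample matrix plus the quartile bookkeeping.

    ``q3_per_sample``/``cohort_mean_q3`` are filled by
    :func:`third_quartile_normalize` and record the reference-class 3rd
    quartiles *before* shifting; after normalization every sample's reference
    Q3 equals ``cohort_mean_q3`` to machine precision.
    """

    values: pd.DataFrame
    feature_class: str = "refseq"
    reference_class: str | None = None
    q3_per_sample: pd.Series | None = None
    cohort_mean_q3: float | None = None


def log2_transform(raw: CountMatrix) -> NormalizedMatrix:
    """log2 each count, mapping 0 counts to 0 (so 0 and 1 both map to 0)."""
    arr = raw.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    out = np.zeros_like(arr)
    np.log2(arr, out=out, where=arr >= 1)
    return NormalizedMatrix(
        values=pd.DataFrame(out, index=raw.values.index, columns=raw.values.columns),
        feature_class=raw.feature_class,
    )


def max_count_filter(raw: CountMatrix, threshold: int = 5) -> tuple[pd.Index, int]:
    """Drop features whose count never reaches ``threshold`` in any sample.

    Returns (retained feature IDs, number removed). A feature is retained iff
    its maximum count across samples is >= threshold.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    max_per_feature = raw.values.max(axis=1)
    retained = raw.values.index[max_per_feature >= threshold]
    return retained, raw.n_features - len(retained)


def third_quartile_normalize(
    m: NormalizedMatrix,
    reference: NormalizedMatrix | None = None,
    quartile_method: str = "linear",
) -> NormalizedMatrix:
    """Shift each sample by (cohort mean Q3 - sample Q3) of reference log2 counts.

    ``reference`` supplies the feature set over which per-sample 3rd quartiles
    are computed (same samples, possibly a different feature class); when
    omitted the matrix is its own reference. Q3 uses linear interpolation
    between order statistics ("type 7") by default; all reference-class
    features, including zeros, enter the quartile.
    """
    ref = reference if reference is not None else m
    if list(ref.values.columns) != list(m.values.columns):
        raise ValueError("reference matrix must cover the same samples in the same order")
    if ref.values.shape[0] == 0:
        raise ValueError("reference feature set is empty")
    if ref.values.shape[0] == 1:
        warnings.warn("single-feature reference set: 3rd quartile is degenerate", stacklevel=2)
    q3 = np.percentile(ref.values.to_numpy(dtype=float), 75, axis=0, method=quartile_method)
    cohort_mean = float(q3.mean())
    shifted = m.values.to_numpy(dtype=float) + (cohort_mean - q3)[None, :]
    return NormalizedMatrix(
        values=pd.DataFrame(shifted, index=m.values.index, columns=m.values.columns),
        feature_class=m.feature_class,
        reference_class=ref.feature_class,
        q3_per_sample=pd.Series(q3, index=m.values.columns, name="q3"),
        cohort_mean_q3=cohort_mean,
    )


def rle_diagnostic(m: NormalizedMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative log expression: value minus the within-sample median over features.

    Returns (RLE matrix, per-sample summary with median and IQR). Well
    normalized cohorts have per-sample RLE medians centered on zero.
    """
    if m.values.shape[0] < 2:
        raise ValueError("RLE needs at least 2 features")
    arr = m.values.to_numpy(dtype=float)
    rle = arr - np.median(arr, axis=0)[None, :]
    rle_df = pd.DataFrame(rle, index=m.values.index, columns=m.values.columns)
    q1, med, q3 = np.percentile(rle, [25, 50, 75], axis=0)
    summary = pd.DataFrame(
        {"median": med, "iqr": q3 - q1}, index=m.values.columns
    )
    return rle_df, summary
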