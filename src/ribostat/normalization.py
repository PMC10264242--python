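"""Median-of-ratios library-size normalization.

The reference pseudo-sample is the per-transcript geometric mean across
samples, computed over transcripts with strictly positive counts in every
sample; each sample's size factor is the median ratio of its counts to the
reference. RNA and RPF matrices are normalized separately; no cross-assay
factor is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, DataError, SizeFactors

try:  # sklearn is optional at runtime; estimators degrade to plain classes
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    BaseEstimator = object

    class TransformerMixin:  # type: ignore[no-redef]
        pass


@dataclass
class NormalizedCounts:
    """A CountMatrix scaled by its size factors."""

    matrix: CountMatrix
    size_factors: SizeFactors
    reference: pd.Series  # geometric-mean pseudo-sample over usable transcripts

    @property
    def counts(self) -> pd.DataFrame:
        return self.matrix.counts


def size_factors(matrix: CountMatrix, allow_fallback: bool = False) -> SizeFactors:
    """Median-of-ratios size factors.

    Parameters
    ----------
    matrix : CountMatrix
    allow_fallback : bool
        If no transcript is positive in every sample, return factors of 1
        instead of raising.
    """
    counts = matrix.counts.to_numpy()
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        if allow_fallback:
            return SizeFactors(pd.Series(1.0, index=matrix.counts.columns))
        raise DataError(
            "no transcript has positive counts in all samples; filter low "
            "transcripts or pass allow_fallback=True for unit factors"
        )
    sub = counts[usable]
    logs = np.log(sub)
    log_ref = logs.mean(axis=1)
    # median taken in log space (geometric interpolation between the two
    # middle ratios at even counts), matching the DESeq2 convention
    factors = np.exp(np.median(logs - log_ref[:, None], axis=0))
    return SizeFactors(pd.Series(factors, index=matrix.counts.columns))


def reference_pseudo_sample(matrix: CountMatrix) -> pd.Series:
    counts = matrix.counts.to_numpy()
    usable = (counts > 0).all(axis=1)
    ref = np.full(len(counts), np.nan)
    ref[usable] = np.exp(np.log(counts[usable]).mean(axis=1))
    return pd.Series(ref, index=matrix.counts.index)


def apply_size_factors(matrix: CountMatrix, factors: SizeFactors) -> NormalizedCounts:
    """Divide each sample column by its size factor (all transcripts)."""
    missing = set(matrix.sample_ids) - set(factors.factors.index)
    if missing:
        raise DataError(f"no size factor for sample(s): {sorted(missing)}")
    scaled = matrix.counts / factors.factors[matrix.counts.columns]
    return NormalizedCounts(
        CountMatrix(scaled, matrix.read_type),
        factors,
        reference_pseudo_sample(matrix),
    )


def normalize(matrix: CountMatrix, allow_fallback: bool = False) -> NormalizedCounts:
    """size_factors + apply_size_factors in one call."""
    return apply_size_factors(matrix, size_factors(matrix, allow_fallback))


class MedianOfRatiosNormalizer(TransformerMixin, BaseEstimator):
    """Transformer wrapping median-of-ratios normalization.

    fit(X) learns per-sample size factors from a transcript x sample
    DataFrame (or CountMatrix); transform(X) divides columns by them.

    Attributes
    ----------
    size_factors_ : pd.Series
    reference_ : pd.Series
        Geometric-mean pseudo-sample (NaN for transcripts with any zero).
    """

    def __init__(self, allow_fallback: bool = False):
        self.allow_fallback = allow_fallback

    @staticmethod
    def _as_matrix(X) -> CountMatrix:
        if isinstance(X, CountMatrix):
            return X
        return CountMatrix(pd.DataFrame(X))

    def fit(self, X, y=None):
        m = self._as_matrix(X)
        self.size_factors_ = size_factors(m, self.allow_fallback).factors
        self.reference_ = reference_pseudo_sample(m)
        return self

    def transform(self, X):
        m = self._as_matrix(X)
        nc = apply_size_factors(m, SizeFactors(self.size_factors_))
        return nc.counts if not isinstance(X, CountMatrix) else nc
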