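"""Consistent Excess of Loess Predictions (CELP): ribosome stalling-bias
detection and correction.

Stalling pauses the ribosome at particular codons and piles up footprint
(RPF) reads there; those reads reflect locally obstructed elongation, not
more translation, and inflate naive per-transcript RPF totals. CELP scores
each codon's excess over the transcript background and divides it out:

1. smooth each sample's codon-count profile with a deterministic local
   linear (loess-type) fit over a +-radius codon window with tricube
   weights w(d) = (1 - (|d|/(radius+1))^3)^3;
2. background M = median of the sample's non-zero smoothed counts;
3. bias coefficient b_i = geometric mean over samples of smoothed_i / M
   (per codon, per transcript);
4. debiased codon count = smoothed_i / b_i; debiased transcript count =
   the sum over codons.

Codons where any pooled sample has a zero smoothed count (or zero
background) get b = 1, i.e. no correction — zeros carry no evidence of
stalling. Bias coefficients are scale-invariant per sample, so library
depth does not affect them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CodonProfileSet, CountMatrix, DataError, ReadType

try:
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    BaseEstimator = object

    class TransformerMixin:  # type: ignore[no-redef]
        pass


@dataclass
class CelpConfig:
    """Tunable parameters of the correction.

    radius : half-width of the smoothing window, in codons (default 5).
    group_labels : optional sample -> group map; bias coefficients are then
        computed per group instead of from the pooled samples.
    min_codons : transcripts shorter than this are passed through unsmoothed.
    clip_at_one : restrict correction to peaks (b = max(b, 1)); by default
        b < 1 inflates valleys exactly as the formula states.
    """

    radius: int = 5
    group_labels: Mapping[str, str] | None = None
    min_codons: int = 2
    clip_at_one: bool = False

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise DataError("radius must be >= 1")


def _loess_kernels(L: int, radius: int) -> np.ndarray:
    """Per-position prediction kernels for the windowed tricube linear fit.

    Returns a (L, L) matrix A with smoothed = A @ y. Interior positions of a
    long transcript share one symmetric kernel; short transcripts
    (L < 2*radius+1) use all codons in every window.
    """
    A = np.zeros((L, L))
    full = L >= 2 * radius + 1
    for i in range(L):
        if full:
            lo, hi = max(0, i - radius), min(L, i + radius + 1)
        else:
            lo, hi = 0, L
        d = np.arange(lo, hi) - i
        w = (1.0 - (np.abs(d) / (radius + 1.0)) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        # weighted linear fit on (1, d); prediction at d=0 is the intercept
        D = np.column_stack([np.ones(hi - lo), d])
        WD = D * w[:, None]
        G = D.T @ WD
        try:
            coef_map = np.linalg.solve(G, WD.T)  # (2, window)
        except np.linalg.LinAlgError:  # degenerate window (single point)
            coef_map = np.zeros((2, hi - lo))
            coef_map[0] = w / w.sum()
        A[i, lo:hi] = coef_map[0]
    return A


_KERNEL_CACHE: dict[tuple[int, int], np.ndarray] = {}


def loess_smooth_profile(counts: np.ndarray, radius: int = 5) -> np.ndarray:
    """Smooth one codon-count vector; deterministic, clipped below at 0."""
    y = np.asarray(counts, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise DataError("codon profile must be a vector of length >= 2")
    if not y.any():
        return np.zeros_like(y)
    key = (len(y), radius)
    A = _KERNEL_CACHE.get(key)
    if A is None:
        A = _loess_kernels(len(y), radius)
        if len(_KERNEL_CACHE) > 512:
            _KERNEL_CACHE.clear()
        _KERNEL_CACHE[key] = A
    return np.clip(A @ y, 0.0, None)


def _smooth_frame(df: pd.DataFrame, radius: int, min_codons: int) -> pd.DataFrame:
    vals = df.to_numpy(dtype=float)
    if len(vals) < max(2, min_codons):
        return df.astype(float)
    key = (len(vals), radius)
    A = _KERNEL_CACHE.get(key)
    if A is None:
        A = _loess_kernels(len(vals), radius)
        if len(_KERNEL_CACHE) > 512:
            _KERNEL_CACHE.clear()
        _KERNEL_CACHE[key] = A
    sm = np.clip(A @ vals, 0.0, None)
    sm[:, ~vals.any(axis=0)] = 0.0  # all-zero samples stay all-zero
    return pd.DataFrame(sm, index=df.index, columns=df.columns)


@dataclass
class CelpProfile:
    """CELP state for one transcript."""

    smoothed: pd.DataFrame        # codons x samples loess predictions
    background: pd.Series         # per sample: median of non-zero smoothed
    bias: pd.DataFrame            # codons x groups (single column "pooled" if ungrouped)
    zero_flag: pd.DataFrame       # codons x groups: True where b was forced to 1
    excluded: bool = False        # background zero in every sample


def celp_coefficients(
    smoothed: pd.DataFrame,
    background: pd.Series,
    samples: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """b_i over one sample pool; returns (bias, forced-to-one flags)."""
    Y = smoothed[list(samples)].to_numpy(dtype=float)
    M = background[list(samples)].to_numpy(dtype=float)
    ok = (Y > 0).all(axis=1) & (M > 0).all()
    b = np.ones(len(Y))
    if ok.any() and (M > 0).all():
        logratio = np.log(Y[ok]) - np.log(M)[None, :]
        b[ok] = np.exp(logratio.mean(axis=1))
    return b, ~ok


class StallingBiasCorrector(TransformerMixin, BaseEstimator):
    """Estimate per-codon stalling-bias coefficients and debias RPF counts.

    fit() smooths the codon profiles and computes per-codon bias
    coefficients; transform() returns the debiased transcript x sample
    count matrix (real-valued), ready for the TER test.

    Attributes
    ----------
    profiles_ : dict[str, CelpProfile]
    excluded_ : list[str]
        Transcripts with zero background in every sample (left uncorrected).
    """

    def __init__(
        self,
        radius: int = 5,
        group_labels: Mapping[str, str] | None = None,
        min_codons: int = 2,
        clip_at_one: bool = False,
    ):
        self.radius = radius
        self.group_labels = group_labels
        self.min_codons = min_codons
        self.clip_at_one = clip_at_one

    def _config(self) -> CelpConfig:
        return CelpConfig(
            radius=self.radius,
            group_labels=self.group_labels,
            min_codons=self.min_codons,
            clip_at_one=self.clip_at_one,
        )

    def fit(self, profiles: CodonProfileSet, y=None):
        cfg = self._config()
        self.profiles_ = {}
        self.excluded_ = []
        for tx in profiles.transcript_ids:
            df = profiles[tx]
            sm = _smooth_frame(df, cfg.radius, cfg.min_codons)
            background = sm.apply(
                lambda col: np.median(col[col > 0]) if (col > 0).any() else 0.0
            )
            if cfg.group_labels is None:
                pools = {"pooled": list(sm.columns)}
            else:
                pools = {}
                for s in sm.columns:
                    pools.setdefault(cfg.group_labels[s], []).append(s)
            bias = {}
            flags = {}
            for g, samples in pools.items():
                b, flag = celp_coefficients(sm, background, samples)
                if cfg.clip_at_one:
                    b = np.maximum(b, 1.0)
                bias[g] = b
                flags[g] = flag
            excluded = bool((background <= 0).all())
            if excluded:
                self.excluded_.append(tx)
                bias = {g: np.ones(len(sm)) for g in bias}
            self.profiles_[tx] = CelpProfile(
                smoothed=sm,
                background=background,
                bias=pd.DataFrame(bias, index=sm.index),
                zero_flag=pd.DataFrame(flags, index=sm.index),
                excluded=excluded,
            )
        return self

    def _bias_for_sample(self, prof: CelpProfile, sample: str) -> np.ndarray:
        if self.group_labels is None:
            return prof.bias["pooled"].to_numpy()
        return prof.bias[self.group_labels[sample]].to_numpy()

    def debiased_profiles(self) -> CodonProfileSet:
        """Per-codon debiased counts y_smoothed / b."""
        out = {}
        for tx, prof in self.profiles_.items():
            cols = {
                s: prof.smoothed[s].to_numpy() / self._bias_for_sample(prof, s)
                for s in prof.smoothed.columns
            }
            out[tx] = pd.DataFrame(cols, index=prof.smoothed.index)
        return CodonProfileSet(out)

    def transform(self, X=None) -> CountMatrix:
        """Debiased transcript x sample RPF counts (sum over codons).

        The argument is accepted for transformer-pipeline compatibility but
        the debiasing always uses the fitted profiles.
        """
        deb = self.debiased_profiles()
        return deb.transcript_totals(ReadType.RPF)

    def debiased_counts(self) -> CountMatrix:
        return self.transform(None)

    def bias_table(self) -> pd.DataFrame:
        """Long-format b table: transcript_id, codon_index, group, bias, zero_flag."""
        rows = []
        for tx, prof in self.profiles_.items():
            for g in prof.bias.columns:
                rows.append(
                    pd.DataFrame(
                        {
                            "transcript_id": tx,
                            "codon_index": np.arange(len(prof.bias)),
                            "group": g,
                            "bias": prof.bias[g].to_numpy(),
                            "zero_flag": prof.zero_flag[g].to_numpy(),
                            "excluded": prof.excluded,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def celp_debias(
    profiles: CodonProfileSet,
    radius: int = 5,
    group_labels: Mapping[str, str] | None = None,
    clip_at_one: bool = False,
) -> tuple[CountMatrix, StallingBiasCorrector]:
    """One-shot smooth + bias + debias; returns (counts, fitted corrector)."""
    corr = StallingBiasCorrector(
        radius=radius, group_labels=group_labels, clip_at_one=clip_at_one
    ).fit(profiles)
    return corr.transform(None), corr
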