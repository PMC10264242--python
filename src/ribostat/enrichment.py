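"""Binned target-set enrichment over a per-transcript statistic.

Transcripts are ranked by a statistic (logTER or logAPAR), divided into
equally populated bins, and a target set (e.g. mRNAs bound by an RBP, or
carrying a 3' UTR motif) is tested for over/under-representation in each
bin — hypergeometric two-tail by default, or a logistic regression of
membership on the bin indicator. A global mutual-information score between
the bin variable and membership, standardized against label permutations
(z-score), summarizes the association; a Wilcoxon rank-sum association is
provided for comparing an annotated subset's statistic against background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._logit import fit_binomial_logit
from .io import DataError
from .ter import adjust_pvalues


@dataclass
class BinAssignment:
    """Equally populated bins over a ranked statistic."""

    bins: pd.Series        # transcript -> bin index (0-based, ascending value)
    boundaries: pd.DataFrame  # per bin: n, value min/max


def bin_values(values: pd.Series, nbins: int = 10) -> BinAssignment:
    """Assign transcripts to nbins equally populated bins, ascending.

    Contiguous rank blocks whose sizes differ by at most one; ties broken by
    stable transcript-id order.
    """
    if nbins < 2:
        raise DataError("nbins must be >= 2")
    values = values.dropna()
    n = len(values)
    if n < nbins:
        raise DataError(f"need >= {nbins} finite values, got {n}")
    order = values.sort_values(kind="stable").index
    base, extra = divmod(n, nbins)
    sizes = [base + (1 if b < extra else 0) for b in range(nbins)]
    assignment = np.repeat(np.arange(nbins), sizes)
    bins = pd.Series(assignment, index=order, name="bin").reindex(values.index)
    rows = []
    for b in range(nbins):
        members = values[bins == b]
        rows.append(
            {"bin": b, "n": len(members), "min": members.min(), "max": members.max()}
        )
    return BinAssignment(bins, pd.DataFrame(rows).set_index("bin"))


def _bin_counts(assignment: BinAssignment, target_set) -> tuple[np.ndarray, np.ndarray]:
    bins = assignment.bins
    targets = set(target_set) & set(bins.index)
    member = bins.index.isin(targets)
    nbins = len(assignment.boundaries)
    n_bin = np.array([(bins == b).sum() for b in range(nbins)])
    k_bin = np.array([int(member[(bins == b).to_numpy()].sum()) for b in range(nbins)])
    return n_bin, k_bin


def bin_enrichment(
    assignment: BinAssignment, target_set, test: str = "hypergeometric"
) -> pd.DataFrame:
    """Per-bin over/under-representation of the target set.

    hypergeometric: both one-sided tail p-values; the smaller is reported
    with its direction. logistic: Wald p of membership ~ bin indicator.
    BH correction across bins.
    """
    targets = set(target_set) & set(assignment.bins.index)
    if not targets:
        raise DataError("target set is empty (or disjoint from the universe)")
    n_bin, k_bin = _bin_counts(assignment, targets)
    N = int(n_bin.sum())
    K = len(targets)
    member = assignment.bins.index.isin(targets).astype(float)
    rows = []
    for b, (n, k) in enumerate(zip(n_bin, k_bin)):
        expected = K * n / N
        if test == "hypergeometric":
            over = float(stats.hypergeom.sf(k - 1, N, K, n))
            under = float(stats.hypergeom.cdf(k, N, K, n))
        elif test == "logistic":
            ind = (assignment.bins == b).to_numpy(dtype=float)
            X = np.column_stack([np.ones(N), ind])
            res = fit_binomial_logit(member, 1.0 - member, X)
            if res.separated or not np.isfinite(res.se[1]):
                # pure bins separate perfectly; Wald collapses, use the LRT
                null = fit_binomial_logit(member, 1.0 - member, X[:, :1])
                lr = max(0.0, 2.0 * (res.loglik - null.loglik))
                p = float(stats.chi2.sf(lr, df=1))
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    z = res.beta[1] / res.se[1]
                p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            over = under = p
        else:
            raise DataError("test must be 'hypergeometric' or 'logistic'")
        if k > expected:
            direction, p = "enriched", over
        elif k < expected:
            direction, p = "depleted", under
        else:
            direction, p = "none", min(1.0, min(over, under))
        rows.append(
            {
                "bin": b,
                "value_min": assignment.boundaries.loc[b, "min"],
                "value_max": assignment.boundaries.loc[b, "max"],
                "n": int(n),
                "n_targets": int(k),
                "expected_targets": expected,
                "direction": direction,
                "p": min(1.0, p),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = adjust_pvalues(out["p"].to_numpy())
    return out


def mutual_information(assignment: BinAssignment, target_set) -> float:
    """Plug-in MI (bits) between bin index and target membership."""
    n_bin, k_bin = _bin_counts(assignment, set(target_set))
    return _mi_from_counts(n_bin, k_bin)


def _mi_from_counts(n_bin: np.ndarray, k_bin: np.ndarray) -> float:
    N = n_bin.sum()
    joint = np.stack([k_bin, n_bin - k_bin]) / N        # (2, nbins)
    pm = joint.sum(axis=1, keepdims=True)               # membership marginal
    pb = joint.sum(axis=0, keepdims=True)               # bin marginal
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log2(joint / (pm * pb))
    return float(np.nansum(term[joint > 0]))


def mi_zscore(
    assignment: BinAssignment,
    target_set,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Permutation z-score of the MI: labels shuffled, bins fixed.

    Returns (MI observed, z, permuted MI values). sd = 0 yields z = NaN.
    """
    if n_perm < 100:
        raise DataError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    bins = assignment.bins.to_numpy()
    member = assignment.bins.index.isin(set(target_set))
    nbins = len(assignment.boundaries)
    n_bin = np.bincount(bins, minlength=nbins)
    mi_obs = _mi_from_counts(n_bin, np.bincount(bins, weights=member, minlength=nbins).astype(int))
    perms = np.empty(n_perm)
    lab = member.copy()
    for i in range(n_perm):
        rng.shuffle(lab)
        k = np.bincount(bins, weights=lab, minlength=nbins).astype(int)
        perms[i] = _mi_from_counts(n_bin, k)
    sd = perms.std(ddof=1)
    z = (mi_obs - perms.mean()) / sd if sd > 0 else np.nan
    return mi_obs, float(z), perms


def rank_association(values: pd.Series, annotation) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum of annotated vs background values.

    annotation: boolean mask or id collection selecting the annotated group.
    Exact for small tie-free groups, normal approximation with tie
    correction otherwise.
    """
    if isinstance(annotation, (pd.Series, np.ndarray)) and np.asarray(annotation).dtype == bool:
        mask = pd.Series(np.asarray(annotation), index=values.index)
    else:
        mask = values.index.isin(set(annotation))
        mask = pd.Series(mask, index=values.index)
    a = values[mask].dropna().to_numpy()
    b = values[~mask].dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise DataError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def enrichment_analysis(
    values: pd.Series,
    target_set,
    nbins: int = 10,
    test: str = "hypergeometric",
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full figure-style analysis: bins, per-bin tests, MI and its z-score."""
    assignment = bin_values(values, nbins)
    table = bin_enrichment(assignment, target_set, test)
    mi, z, _ = mi_zscore(assignment, target_set, n_perm=n_perm, seed=seed)
    stats_d = {"mi_bits": mi, "mi_z": z, "n_perm": n_perm, "seed": seed}
    return table, stats_d
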