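"""Differential poly(A)-site usage by per-transcript multinomial logistic
regression, and the logAPAR effect size.

Transcripts with several annotated cleavage/poly(A) sites distribute their
3'-end reads across those sites; condition-dependent shifts in that
distribution change 3' UTR length. Site usage is modelled per transcript
with a baseline-category multinomial logit on the site counts:

    log(Alt.site / Ref.site) = alpha + sum_i beta_i * x_i

Three modes:

* ``overall``   — one likelihood-ratio (deviance) test per transcript of the
  covariate model against the intercept-only model, chi-square with
  (S - 1) x p_cov degrees of freedom; exactly one test per transcript.
* ``vs_reference`` — every non-reference site against a reference site
  (alphabetically first by default; most proximal or user-given optionally),
  Wald p per site and covariate.
* ``pairwise``  — a binomial logit for every unordered site pair; the
  highest-resolution view.

logAPAR is the condition coefficient of the proximal-vs-distal pairwise
fit with log(proximal/distal) as the modelled odds: logAPAR > 0 means
relatively MORE proximal usage (3' UTR shortening) at the higher covariate
level; logAPAR < 0 a proximal-to-distal switch (3' UTR lengthening).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._logit import (
    fit_binomial_logit,
    fit_multinomial_logit,
    multinomial_null_loglik,
)
from .io import CountMatrix, DataError, DesignMatrix, PasCountTable, ReadType
from .normalization import size_factors
from .ter import adjust_pvalues

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    BaseEstimator = object

MODES = ("overall", "vs_reference", "pairwise")
REFERENCE_RULES = ("alphabetical", "proximal")


def _normalize_pas(pas: PasCountTable) -> pd.DataFrame:
    """Median-of-ratios over the full site x sample matrix.

    Within-transcript usage proportions are scale-invariant, so this mainly
    guards pooled summaries; it never changes which sites win.
    """
    flat = CountMatrix(
        pas.counts.set_axis([f"{a}::{b}" for a, b in pas.counts.index]),
        ReadType.PAS,
    )
    try:
        sf = size_factors(flat)
    except DataError:
        return pas.counts.astype(float)
    return (pas.counts / sf.factors[pas.counts.columns]).astype(float)


class PasUsageTester(BaseEstimator):
    """Per-transcript multinomial test of differential poly(A)-site usage.

    Parameters
    ----------
    mode : {"overall", "vs_reference", "pairwise"}
    reference_rule : {"alphabetical", "proximal"} or dict transcript->site
        How to pick the reference site in vs_reference mode.
    normalize : bool
        Median-of-ratios normalize the site x sample matrix first.
    separation_cap : float
        |beta| beyond this flags separation.

    Attributes
    ----------
    results_ : pd.DataFrame — one row per test (see mode docstrings).
    untestable_ : list[str] — transcripts with < 2 sites or degenerate counts.
    """

    def __init__(
        self,
        mode: str = "overall",
        reference_rule="alphabetical",
        normalize: bool = True,
        separation_cap: float = 10.0,
    ):
        self.mode = mode
        self.reference_rule = reference_rule
        self.normalize = normalize
        self.separation_cap = separation_cap

    # ------------------------------------------------------------------

    def fit(self, pas: PasCountTable, design: DesignMatrix):
        if self.mode not in MODES:
            raise DataError(f"mode must be one of {MODES}")
        counts = _normalize_pas(pas) if self.normalize else pas.counts.astype(float)
        samples = list(counts.columns)
        X = design.matrix(samples)
        cov_names = [c for c in design.columns if c != "intercept"]
        self.design_columns_ = design.columns
        self.untestable_ = []
        rows = []
        for tx in pas.transcript_ids:
            sub = counts.loc[tx]                       # sites x samples
            ranks = pas.ranks.loc[tx]
            if len(sub) < 2:
                self.untestable_.append(tx)
                continue
            Y_all = sub.to_numpy(dtype=float).T        # samples x sites
            used = (Y_all.sum(axis=1) > 0)
            if used.sum() < 2 or (Y_all.sum(axis=0) > 0).sum() < 2:
                # all counts in one site, or fewer than two usable samples
                self.untestable_.append(tx)
                continue
            if self.mode == "overall":
                rows.append(self._overall(tx, sub, X, used, cov_names))
            elif self.mode == "vs_reference":
                rows.extend(self._vs_reference(tx, sub, ranks, X, used, cov_names))
            else:
                rows.extend(self._pairwise(tx, sub, ranks, X, cov_names))
        self.results_ = pd.DataFrame(rows)
        if not self.results_.empty:
            self.results_["fdr"] = adjust_pvalues(self.results_["p"].to_numpy())
        return self

    # ------------------------------------------------------------------

    def _order_sites(self, sub: pd.DataFrame, ranks: pd.Series, ref: str):
        sites = list(sub.index)
        others = [s for s in sites if s != ref]
        return others + [ref]  # reference LAST for the baseline-category fit

    def _pick_reference(self, tx: str, sub: pd.DataFrame, ranks: pd.Series) -> str:
        rule = self.reference_rule
        if isinstance(rule, dict):
            ref = rule.get(tx)
            if ref is None or ref not in sub.index:
                raise DataError(f"reference site for {tx!r} absent: {ref!r}")
            return ref
        if rule == "alphabetical":
            return sorted(sub.index)[0]
        if rule == "proximal":
            return ranks.idxmin()
        raise DataError(f"unknown reference rule: {rule!r}")

    def _overall(self, tx, sub, X, used, cov_names) -> dict:
        # sites with no reads anywhere carry no usage information; drop them
        sub = sub[sub.sum(axis=1) > 0]
        order = sorted(sub.index)
        Y = sub.loc[order].to_numpy(dtype=float).T[used]
        Xs = X[used]
        res = fit_multinomial_logit(Y, Xs, separation_cap=self.separation_cap)
        # null = intercept-only: closed-form pooled proportions
        ll0 = multinomial_null_loglik(Y)
        dev = max(0.0, 2.0 * (res.loglik - ll0))
        df = (Y.shape[1] - 1) * len(cov_names)
        p = stats.chi2.sf(dev, df) if df > 0 else np.nan
        return {
            "transcript_id": tx,
            "n_sites": Y.shape[1],
            "deviance": dev,
            "df": df,
            "p": p,
            "status": "ok" if res.converged else "not_converged",
        }

    def _vs_reference(self, tx, sub, ranks, X, used, cov_names) -> list[dict]:
        sub = sub[sub.sum(axis=1) > 0]
        if len(sub) < 2:
            self.untestable_.append(tx)
            return []
        ref = self._pick_reference(tx, sub, ranks)
        order = self._order_sites(sub, ranks, ref)
        Y = sub.loc[order].to_numpy(dtype=float).T[used]
        Xs = X[used]
        res = fit_multinomial_logit(Y, Xs, separation_cap=self.separation_cap)
        out = []
        cols = self.design_columns_
        for m, site in enumerate(order[:-1]):
            for j, term in enumerate(cols):
                if term == "intercept":
                    continue
                beta = res.beta[m, j]
                se = res.se[m, j]
                degenerate = not np.isfinite(se) or se > 1e6
                with np.errstate(invalid="ignore", divide="ignore"):
                    z = beta / se
                p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
                out.append(
                    {
                        "transcript_id": tx,
                        "site": site,
                        "reference": ref,
                        "term": term,
                        "beta": beta,
                        "se": se,
                        "p": p,
                        "status": (
                            "se_inf"
                            if degenerate
                            else (
                                "separated"
                                if res.separated
                                else ("ok" if res.converged else "not_converged")
                            )
                        ),
                    }
                )
        return out

    def _pairwise(self, tx, sub, ranks, X, cov_names) -> list[dict]:
        out = []
        cols = self.design_columns_
        # order each pair proximal-first so beta models log(prox/dist)
        for a, b in combinations(sorted(sub.index, key=lambda s: ranks[s]), 2):
            prox_counts = sub.loc[a].to_numpy(dtype=float)
            dist_counts = sub.loc[b].to_numpy(dtype=float)
            keep = (prox_counts + dist_counts) > 0
            dropped = int((~keep).sum())
            if keep.sum() < 2:
                continue
            res = fit_binomial_logit(
                prox_counts[keep], dist_counts[keep], X[keep],
                separation_cap=self.separation_cap,
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                z = res.beta / res.se
            p = 2 * stats.norm.sf(np.abs(z))
            for j, term in enumerate(cols):
                if term == "intercept":
                    continue
                out.append(
                    {
                        "transcript_id": tx,
                        "proximal_site": a,
                        "distal_site": b,
                        "proximal_rank": int(ranks[a]),
                        "distal_rank": int(ranks[b]),
                        "term": term,
                        "beta": res.beta[j],
                        "se": res.se[j],
                        "p": p[j],
                        "n_dropped_samples": dropped,
                        "status": (
                            "separated"
                            if res.separated
                            else ("ok" if res.converged else "not_converged")
                        ),
                    }
                )
        return out


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_overall(pas, design, **kw) -> pd.DataFrame:
    return PasUsageTester(mode="overall", **kw).fit(pas, design).results_

def fit_vs_reference(pas, design, reference_rule="alphabetical", **kw) -> pd.DataFrame:
    return (
        PasUsageTester(mode="vs_reference", reference_rule=reference_rule, **kw)
        .fit(pas, design)
        .results_
    )

def fit_pairwise(pas, design, **kw) -> pd.DataFrame:
    return PasUsageTester(mode="pairwise", **kw).fit(pas, design).results_


def compute_logapar(
    pairwise: pd.DataFrame,
    pas: PasCountTable,
    term: str | None = None,
    pairs: str = "extreme",
    log2: bool = False,
) -> pd.DataFrame:
    """logAPAR per transcript from the pairwise fits.

    Parameters
    ----------
    pairwise : output of fit_pairwise (beta models log(proximal/distal)).
    term : design column to read the condition effect from (default: the
        only non-intercept term; ambiguous designs must name one).
    pairs : "extreme" (rank-1 vs rank-S site, the default) or "adjacent"
        (all rank-adjacent pairs).
    log2 : report log2 instead of natural log.

    Positive logAPAR = shift toward proximal usage in the second condition;
    a proximal-to-distal switch (3' UTR lengthening) is negative.
    """
    if pairwise.empty:
        return pd.DataFrame(
            columns=["transcript_id", "proximal_site", "distal_site", "logAPAR", "p", "fdr"]
        )
    if pas.rank_source == "lexicographic" and pas.positions is None:
        pass  # ranks exist either way; BED only changes their source
    terms = sorted(pairwise["term"].unique())
    if term is None:
        if len(terms) != 1:
            raise DataError(f"ambiguous condition term, choose one of {terms}")
        term = terms[0]
    df = pairwise[pairwise["term"] == term].copy()
    if pairs == "extreme":
        keep = []
        for tx, grp in df.groupby("transcript_id", sort=False):
            n_sites = pas.n_sites(tx)
            sel = grp[(grp["proximal_rank"] == 1) & (grp["distal_rank"] == n_sites)]
            keep.append(sel)
        df = pd.concat(keep, ignore_index=True)
    elif pairs == "adjacent":
        df = df[df["distal_rank"] == df["proximal_rank"] + 1].reset_index(drop=True)
    else:
        raise DataError("pairs must be 'extreme' or 'adjacent'")
    scale = 1.0 / np.log(2.0) if log2 else 1.0
    out = df[["transcript_id", "proximal_site", "distal_site", "p", "status"]].copy()
    out.insert(3, "logAPAR", df["beta"].to_numpy() * scale)
    out["fdr"] = adjust_pvalues(out["p"].to_numpy())
    return out
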