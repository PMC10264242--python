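"""Per-transcript translation-efficiency-ratio (TER) test.

Translation efficiency (TE) is modelled as the odds of drawing an RPF read
rather than an RNA read for a transcript: imagine pooling all reads of a
sample and drawing one — the RPF:RNA odds estimate ribosome density per
mRNA. Differences in TE across conditions are then odds ratios, tested per
transcript by logistic regression:

    logit P(read is RPF) = log(RPF/RNA) = alpha + sum_i beta_i * x_i

Each sample contributes its (normalized, optionally CELP-debiased) RPF
count as successes and RNA count as failures; real-valued counts enter the
likelihood as weights. The TE ratio between two covariate settings is

    TER = exp( sum_i beta_i * (x_i,2 - x_i,1) )

For two unreplicated samples and a binary covariate the fit is saturated
and beta equals the 2x2 log odds ratio, with chi-square / Fisher tests as
the built-in QC oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._logit import LogitFit, binomial_loglik, fit_binomial_logit
from .io import CountMatrix, DataError, DesignMatrix
from .normalization import NormalizedCounts

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    BaseEstimator = object


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up over non-NA entries; NAs propagate."""
    if method.lower() not in {"bh", "fdr_bh"}:
        raise ValueError(f"unsupported adjustment method: {method}")
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return out
    ps = p[ok]
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def ter_2x2_oracle(
    rpf1: float, rna1: float, rpf2: float, rna2: float, pseudocount: float = 0.0
) -> tuple[float, float, float]:
    """2x2 contingency statistics for the unreplicated two-sample case.

    Table rows are samples, columns are read types (RPF, RNA). Returns
    (log odds ratio, chi-square p, Fisher exact p). A zero margin gives an
    NA odds ratio unless a pseudocount (e.g. Haldane 0.5) is requested.
    """
    table = np.array([[rpf1, rna1], [rpf2, rna2]], dtype=float)
    t = table + pseudocount
    if (t == 0).any():
        log_or = np.nan
    else:
        log_or = float(np.log((t[1, 0] / t[1, 1]) / (t[0, 0] / t[0, 1])))
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return log_or, np.nan, np.nan
    chi2_p = float(stats.chi2_contingency(table, correction=False)[1])
    fisher_p = float(stats.fisher_exact(np.round(table).astype(int))[1])
    return log_or, chi2_p, fisher_p


@dataclass
class TerFit:
    """Per-transcript regression fit (one row per design column)."""

    transcript_id: str
    coef: pd.DataFrame  # index = design columns; beta, se, z, p
    loglik: float
    converged: bool
    separated: bool
    status: str  # "ok" | "low_count" | "separated" | "not_converged"


class TranslationEfficiencyTester(BaseEstimator):
    """Fit the per-transcript RPF-vs-RNA logistic regression.

    Parameters
    ----------
    min_total : float
        Transcripts whose normalized RPF+RNA total falls below this in any
        sample are marked untestable (NA results). Default 10.
    pseudocount : float or "auto"
        Added to both counts of every sample before fitting; "auto" applies
        Haldane 0.5 only to transcripts with a zero cell. Default 0.
    dispersion : bool
        Inflate Wald SEs by sqrt(Pearson chi2 / df), floored at 1
        (quasi-binomial), for datasets overdispersed relative to binomial.
    separation_cap : float
        |beta| beyond this flags separation; the coefficient p-value is then
        recomputed by a likelihood-ratio test. Default 10.

    Attributes
    ----------
    fits_ : dict[str, TerFit]
    results_ : pd.DataFrame
        One row per transcript x coefficient, with beta, se, z, p.
    design_columns_ : list[str]
    """

    def __init__(
        self,
        min_total: float = 10.0,
        pseudocount: float | str = 0.0,
        dispersion: bool = False,
        separation_cap: float = 10.0,
    ):
        self.min_total = min_total
        self.pseudocount = pseudocount
        self.dispersion = dispersion
        self.separation_cap = separation_cap

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        rpf: NormalizedCounts | CountMatrix,
        rna: NormalizedCounts | CountMatrix,
        design: DesignMatrix,
    ):
        rpf_df = rpf.counts if not isinstance(rpf, pd.DataFrame) else rpf
        rna_df = rna.counts if not isinstance(rna, pd.DataFrame) else rna
        if list(rpf_df.columns) != list(rna_df.columns):
            common = [s for s in rpf_df.columns if s in set(rna_df.columns)]
            if not common:
                raise DataError("RPF and RNA matrices share no samples")
            rpf_df, rna_df = rpf_df[common], rna_df[common]
        shared = rpf_df.index.intersection(rna_df.index)
        if shared.empty:
            raise DataError("RPF and RNA matrices share no transcripts")
        rpf_df = rpf_df.loc[shared]
        rna_df = rna_df.loc[shared]
        X = design.matrix(list(rpf_df.columns))
        self.design_columns_ = design.columns
        self.design_ = design

        fits: dict[str, TerFit] = {}
        S = rpf_df.to_numpy(dtype=float)
        F = rna_df.to_numpy(dtype=float)
        totals = S + F
        for idx, tx in enumerate(shared):
            s, f = S[idx], F[idx]
            if (totals[idx] < self.min_total).any():
                fits[tx] = self._na_fit(tx, "low_count")
                continue
            pc = self._pc(s, f)
            fits[tx] = self._fit_one(tx, s + pc, f + pc, X)
        self.fits_ = fits
        self.results_ = self._collect()
        return self

    def _pc(self, s: np.ndarray, f: np.ndarray) -> float:
        if self.pseudocount == "auto":
            return 0.5 if ((s == 0).any() or (f == 0).any()) else 0.0
        return float(self.pseudocount)

    def _na_fit(self, tx: str, status: str) -> TerFit:
        coef = pd.DataFrame(
            np.nan,
            index=self.design_columns_,
            columns=["beta", "se", "z", "p"],
        )
        return TerFit(tx, coef, np.nan, False, False, status)

    def _fit_one(self, tx: str, s, f, X) -> TerFit:
        res = fit_binomial_logit(s, f, X, separation_cap=self.separation_cap)
        se = res.se.copy()
        if self.dispersion:
            se = se * self._dispersion_factor(res, s, f, X)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = res.beta / se
        p = 2 * stats.norm.sf(np.abs(z))
        status = "ok"
        if not res.converged:
            status = "not_converged"
            p = np.full_like(p, np.nan)
        elif res.separated:
            status = "separated"
            p = self._lrt_pvalues(res, s, f, X)
        coef = pd.DataFrame(
            {"beta": res.beta, "se": se, "z": z, "p": p},
            index=self.design_columns_,
        )
        return TerFit(tx, coef, res.loglik, res.converged, res.separated, status)

    def _dispersion_factor(self, res: LogitFit, s, f, X) -> float:
        tot = s + f
        eta = X @ res.beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        df = len(s) - X.shape[1]
        if df <= 0:
            return 1.0
        pearson = ((s - tot * mu) ** 2 / np.clip(tot * mu * (1 - mu), 1e-12, None)).sum()
        return float(max(1.0, np.sqrt(pearson / df)))

    def _lrt_pvalues(self, res: LogitFit, s, f, X) -> np.ndarray:
        """Per-coefficient LRT p (drop one column), used under separation."""
        p = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            if X.shape[1] == 1:
                ll0 = binomial_loglik(np.zeros(1), X * 0.0, s, f)
            else:
                Xr = np.delete(X, j, axis=1)
                ll0 = fit_binomial_logit(
                    s, f, Xr, separation_cap=self.separation_cap
                ).loglik
            lr = max(0.0, 2.0 * (res.loglik - ll0))
            p[j] = stats.chi2.sf(lr, df=1)
        return p

    def _collect(self) -> pd.DataFrame:
        rows = []
        for tx, fit in self.fits_.items():
            df = fit.coef.copy()
            df.insert(0, "transcript_id", tx)
            df.insert(1, "term", df.index)
            df["status"] = fit.status
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    # -- prediction / summary ----------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "fits_"):
            raise DataError("estimator is not fitted")

    def predict_ter(self, x1, x2) -> pd.DataFrame:
        """TER = exp(sum beta_i (x2_i - x1_i)) per transcript.

        x1/x2 are mappings over non-intercept design columns (missing
        entries default to 0).
        """
        self._check_fitted()
        cols = [c for c in self.design_columns_ if c != "intercept"]
        unknown = (set(x1) | set(x2)) - set(cols)
        if unknown:
            raise DataError(f"unknown design column(s): {sorted(unknown)}")
        delta = np.array([float(x2.get(c, 0.0)) - float(x1.get(c, 0.0)) for c in cols])
        rows = {}
        for tx, fit in self.fits_.items():
            beta = fit.coef.loc[cols, "beta"].to_numpy()
            logter = float(beta @ delta) if np.isfinite(beta).all() else np.nan
            rows[tx] = {"logTER": logter, "TER": np.exp(logter)}
        return pd.DataFrame.from_dict(rows, orient="index")

    def summary(
        self,
        contrast: tuple[str, float, float] | str,
        empirical_null: bool = False,
    ) -> pd.DataFrame:
        """TerTable for one contrast.

        contrast: design column name (unit change), or (column, v1, v2).
        Columns: transcript_id, logTER, TER, p, fdr, status.

        empirical_null=True recalibrates significance against an empirical
        null estimated from the bulk of transcripts (median/MAD
        standardization of the Wald z-values, and median-centering of
        logTER). This absorbs transcriptome-wide shifts that are artifacts
        of composition — e.g. one-directional differential translation
        biasing the median-of-ratios size factors — under the standard
        assumption that most transcripts are unchanged.
        """
        self._check_fitted()
        if isinstance(contrast, str):
            col, v1, v2 = contrast, 0.0, 1.0
        else:
            col, v1, v2 = contrast
        if col not in self.design_columns_:
            raise DataError(f"unknown design column: {col!r}")
        delta = float(v2) - float(v1)
        recs = []
        for tx, fit in self.fits_.items():
            beta = fit.coef.loc[col, "beta"]
            logter = beta * delta
            recs.append(
                {
                    "transcript_id": tx,
                    "logTER": logter,
                    "TER": np.exp(logter),
                    "z": fit.coef.loc[col, "z"] * np.sign(delta) if delta else np.nan,
                    "p": fit.coef.loc[col, "p"],
                    "status": fit.status,
                }
            )
        out = pd.DataFrame(recs)
        if empirical_null:
            z = out["z"].to_numpy(dtype=float)
            ok = np.isfinite(z)
            if ok.sum() >= 10:
                loc = np.median(z[ok])
                scale = np.median(np.abs(z[ok] - loc)) / 0.6744897501960817
                scale = max(scale, 1e-8)
                z_adj = (z - loc) / scale
                wald = out["status"].isin(["ok"]).to_numpy() & ok
                out.loc[wald, "p"] = 2 * stats.norm.sf(np.abs(z_adj[wald]))
                shift = np.median(out.loc[ok, "logTER"])
                out["logTER"] = out["logTER"] - shift
                out["TER"] = np.exp(out["logTER"])
        out["fdr"] = adjust_pvalues(out["p"].to_numpy())
        return out[["transcript_id", "logTER", "TER", "z", "p", "fdr", "status"]]


def fit_ter(
    rpf,
    rna,
    design: DesignMatrix,
    min_total: float = 10.0,
    pseudocount: float | str = 0.0,
    dispersion: bool = False,
) -> TranslationEfficiencyTester:
    """Functional wrapper over TranslationEfficiencyTester.fit."""
    return TranslationEfficiencyTester(
        min_total=min_total, pseudocount=pseudocount, dispersion=dispersion
    ).fit(rpf, rna, design)


def predict_ter(fit: TranslationEfficiencyTester, x1, x2) -> pd.DataFrame:
    return fit.predict_ter(x1, x2)
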