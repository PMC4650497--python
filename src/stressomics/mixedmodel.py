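"""Per-gene linear mixed models adjusting for white-cell composition.

For every differentially expressed gene the model

    x_it = b0 + b1_t + b2 * (L/G)_it + U_i + e_it

is fitted by REML: time enters as a fixed factor (baseline as reference
level), the lymphocyte/granulocyte ratio (L/G) as a fixed covariate
capturing glucocorticoid-driven leukocyte redistribution, and each animal
gets a random intercept ``U_i``.  Two question are then asked per gene: does
time remain significant after the cell-composition adjustment (Wald test of
each ``b1_t``, BH-corrected across genes within each time point), and does
the L/G ratio itself explain expression (Wald test of ``b2``, BH-corrected
across genes)?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .differential import adjust

__all__ = [
    "GeneMixedModel",
    "MixedModelFit",
    "fit_lmm",
    "fit_genes",
    "test_time_effect",
    "test_lg_effect",
    "lg_ratio_from_counts",
]


def lg_ratio_from_counts(
    lymphocytes: pd.Series, granulocytes: pd.Series, log: bool = False
) -> pd.Series:
    """Lymphocyte/granulocyte ratio per sample, optionally log-transformed."""
    ratio = pd.Series(
        np.asarray(lymphocytes, dtype=float) / np.asarray(granulocytes, dtype=float),
        index=lymphocytes.index,
        name="lg_ratio",
    )
    return np.log(ratio) if log else ratio


@dataclass
class MixedModelFit:
    """REML fit of the cell-composition mixed model for one gene."""

    gene: str
    params: pd.Series  # intercept, time levels, lg_ratio
    bse: pd.Series
    pvalues: pd.Series
    re_variance: float
    resid_variance: float
    converged: bool
    baseline: float
    times: tuple

    def summary(self) -> str:
        lines = [
            f"Mixed model for gene {self.gene!r} "
            f"({'converged' if self.converged else 'NOT converged'})",
            f"  random-intercept variance: {self.re_variance:.6g}",
            f"  residual variance:         {self.resid_variance:.6g}",
            f"  {'term':<12} {'coef':>10} {'se':>10} {'p':>12}",
        ]
        for term in self.params.index:
            lines.append(
                f"  {term:<12} {self.params[term]:>10.4f} "
                f"{self.bse[term]:>10.4f} {self.pvalues[term]:>12.3e}"
            )
        return "\n".join(lines)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            }
        )


class GeneMixedModel:
    """Model object for one gene's expression over animals x times.

    Parameters
    ----------
    endog : Series of expression values per sample.
    lg_ratio : Series of L/G ratios aligned with ``endog``.
    animal, time : per-sample annotations aligned with ``endog``.
    baseline : reference time level (coefficient fixed at 0).
    """

    def __init__(self, endog, lg_ratio, animal, time, baseline: float = 0, gene: str = ""):
        self.endog = np.asarray(endog, dtype=float)
        self.lg = np.asarray(lg_ratio, dtype=float)
        self.animal = np.asarray(animal)
        self.time = np.asarray(time)
        self.baseline = baseline
        self.gene = gene
        if not (len(self.endog) == len(self.lg) == len(self.animal) == len(self.time)):
            raise ValueError("endog, lg_ratio and annotations must be aligned")
        if np.ptp(self.lg) == 0:
            raise ValueError(
                "L/G ratio is constant across observations: b2 is collinear "
                "with the intercept and inestimable"
            )
        self.times = tuple(t for t in np.unique(self.time) if t != baseline)
        self._names = (
            ["intercept"]
            + [f"time_{_tl(t)}" for t in self.times]
            + ["lg_ratio"]
        )

    def _design(self) -> np.ndarray:
        X = np.ones((len(self.endog), len(self._names)))
        for j, t in enumerate(self.times, start=1):
            X[:, j] = (self.time == t).astype(float)
        X[:, -1] = self.lg
        return X

    def fit(self) -> MixedModelFit:
        X = self._design()
        # boundary warnings (random-effect variance estimated at 0) are a
        # legitimate outcome, not a convergence failure
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(self.endog, X, groups=self.animal)
            try:
                res = model.fit(reml=True)
                converged = bool(getattr(res, "converged", True))
            except (np.linalg.LinAlgError, ValueError):
                res, converged = None, False
            if res is None or not converged:
                try:
                    res = model.fit(reml=True, method="nm", maxiter=2000)
                    converged = bool(getattr(res, "converged", True))
                except (np.linalg.LinAlgError, ValueError):
                    if res is None:
                        raise
                    converged = False
        k = len(self._names)
        params = pd.Series(np.asarray(res.params[:k]), index=self._names)
        bse = pd.Series(np.asarray(res.bse[:k]), index=self._names)
        pvalues = pd.Series(np.asarray(res.pvalues[:k]), index=self._names)
        if not np.isfinite(bse.values).all():
            converged = False
        return MixedModelFit(
            gene=self.gene,
            params=params,
            bse=bse,
            pvalues=pvalues,
            re_variance=float(np.squeeze(np.asarray(res.cov_re))),
            resid_variance=float(res.scale),
            converged=converged,
            baseline=self.baseline,
            times=self.times,
        )


def _tl(t) -> str:
    return str(int(t)) if float(t).is_integer() else str(t)


def fit_lmm(endog, lg_ratio, animal, time, baseline: float = 0, gene: str = "") -> MixedModelFit:
    """Convenience wrapper: build a :class:`GeneMixedModel` and fit it."""
    return GeneMixedModel(endog, lg_ratio, animal, time, baseline=baseline, gene=gene).fit()


def fit_genes(
    expression: pd.DataFrame,
    lg_ratio: pd.Series,
    sample_map: pd.DataFrame,
    baseline: float = 0,
) -> pd.DataFrame:
    """Fit the mixed model for every gene (rows of ``expression``).

    Returns one row per gene with coefficient estimates, standard errors,
    Wald p-values, variance components and a convergence flag.
    """
    lg = lg_ratio.loc[expression.columns]
    animal = sample_map.loc[expression.columns, "animal"]
    time = sample_map.loc[expression.columns, "time"]
    rows = []
    for gene, values in expression.iterrows():
        fit = fit_lmm(values.values, lg.values, animal.values, time.values,
                      baseline=baseline, gene=str(gene))
        row = {"gene": gene, "converged": fit.converged,
               "re_variance": fit.re_variance, "resid_variance": fit.resid_variance}
        for term in fit.params.index:
            row[f"beta_{term}"] = fit.params[term]
            row[f"se_{term}"] = fit.bse[term]
            row[f"p_{term}"] = fit.pvalues[term]
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def test_time_effect(fits: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust the Wald p-values of each time coefficient across genes.

    Non-converged fits are excluded from the adjustment families and
    reported with NaN adjusted p-values.  Returns a tidy table (gene, time
    term, beta, p, adj_p, significant).
    """
    time_terms = [c[2:] for c in fits.columns if c.startswith("p_time_")]
    records = []
    for term in time_terms:
        p = fits[f"p_{term}"].where(fits["converged"], np.nan)
        adj = adjust(p.values, "BH")
        for gene, beta, praw, padj in zip(fits.index, fits[f"beta_{term}"], p, adj):
            records.append(
                {
                    "gene": gene,
                    "term": term,
                    "beta": beta,
                    "p": praw,
                    "adj_p": padj,
                    "significant": bool(padj < alpha) if np.isfinite(padj) else False,
                }
            )
    return pd.DataFrame(records)


def test_lg_effect(fits: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust the Wald test of the L/G coefficient across genes.

    Reports the coefficient sign: a negative significant coefficient means
    the gene is over-expressed when the L/G ratio falls (granulocyte
    predominance).
    """
    p = fits["p_lg_ratio"].where(fits["converged"], np.nan)
    adj = adjust(p.values, "BH")
    out = pd.DataFrame(
        {
            "beta_lg": fits["beta_lg_ratio"],
            "se_lg": fits["se_lg_ratio"],
            "p": p,
            "adj_p": adj,
        },
        index=fits.index,
    )
    out["significant"] = (out["adj_p"] < alpha).fillna(False)
    out["sign"] = np.where(
        out["significant"], np.where(out["beta_lg"] < 0, "negative", "positive"), ""
    )
    return out
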