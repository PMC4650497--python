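"""Time-course differential testing and multiple-testing control.

Covers the univariate arm of the pipeline: repeated-measures ANOVA of the
global time effect, a two-way (split-plot) ANOVA for sex, paired t-tests of
each post-challenge time against baseline, Benjamini-Hochberg / Bonferroni
adjustment of the pooled p-value list, consolidation of duplicated probes to
unique genes, and correlation of within-animal features to the within-animal
hormonal anchor (cortisol at its +1 h peak).

All results are tidy :class:`pandas.DataFrame` tables with one row per
feature (or feature x contrast) — the layouts documented in each function.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DesignError, LongitudinalMatrix

__all__ = [
    "adjust",
    "rm_anova",
    "two_way_anova_sex",
    "paired_tests",
    "consolidate_probes",
    "correlate_to_anchor",
]


# --------------------------------------------------------------------------- #
# Multiple-testing adjustment
# --------------------------------------------------------------------------- #
def adjust(pvalues, method: str = "BH") -> np.ndarray:
    """Adjust a vector of p-values by Benjamini-Hochberg or Bonferroni.

    NaN entries (undefined tests, e.g. zero-variance features) are excluded
    from the family size ``m`` and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if valid.sum() == 0:
        return out
    if method in ("BH", "fdr_bh"):
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    elif method.lower() == "bonferroni":
        out[valid] = np.minimum(p[valid] * valid.sum(), 1.0)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return out


# --------------------------------------------------------------------------- #
# Repeated-measures ANOVA
# --------------------------------------------------------------------------- #
def _pivot(matrix: LongitudinalMatrix, column: str) -> pd.DataFrame:
    """animal x time table for one feature (balanced design assumed)."""
    return pd.DataFrame(
        {
            "animal": matrix.animal.values,
            "time": matrix.time.values,
            "value": matrix.values[column].values,
        }
    ).pivot(index="animal", columns="time", values="value")


def rm_anova(matrix: LongitudinalMatrix, adjust_method: str = "BH") -> pd.DataFrame:
    """One-way repeated-measures ANOVA of the time effect, per variable.

    Time is the within-subject factor; the subject (animal) sum of squares is
    removed from the error term.  Returns a table indexed by variable with
    columns F, p and adj_p (BH over variables).
    """
    matrix.require_balanced()
    if matrix.n_animals < 2:
        raise DesignError("repeated-measures ANOVA needs at least 2 animals")
    if matrix.n_times < 2:
        raise DesignError("repeated-measures ANOVA needs at least 2 time points")

    rows = []
    for col in matrix.values.columns:
        wide = _pivot(matrix, col).values
        n, T = wide.shape
        grand = wide.mean()
        ss_time = n * ((wide.mean(axis=0) - grand) ** 2).sum()
        ss_subj = T * ((wide.mean(axis=1) - grand) ** 2).sum()
        ss_total = ((wide - grand) ** 2).sum()
        ss_error = max(ss_total - ss_time - ss_subj, 0.0)
        df_time = T - 1
        df_error = (n - 1) * (T - 1)
        if ss_time <= 1e-300:
            F, p = 0.0, 1.0
        elif ss_error <= 1e-300:
            F, p = np.inf, 0.0
        else:
            F = (ss_time / df_time) / (ss_error / df_error)
            p = float(stats.f.sf(F, df_time, df_error))
        rows.append({"variable": col, "F": F, "df1": df_time, "df2": df_error, "p": p})
    out = pd.DataFrame(rows).set_index("variable")
    out["adj_p"] = adjust(out["p"].values, adjust_method)
    return out


def two_way_anova_sex(matrix: LongitudinalMatrix, adjust_method: str = "BH") -> pd.DataFrame:
    """Split-plot ANOVA: sex (between-animal factor) with time repeated.

    Tests the sex main effect against the between-animal (subject within sex)
    error stratum.  Returns per-variable F, p and BH-adjusted p.
    """
    matrix.require_balanced()
    if matrix.sex is None:
        raise DesignError("matrix carries no sex annotation")
    sexes = pd.unique(matrix.sex)
    if len(sexes) < 2:
        raise DesignError("both sexes must be present to test a sex effect")

    animal_sex = (
        pd.DataFrame({"animal": matrix.animal.values, "sex": matrix.sex.values})
        .drop_duplicates()
        .set_index("animal")["sex"]
    )
    T = matrix.n_times
    rows = []
    for col in matrix.values.columns:
        wide = _pivot(matrix, col)
        subj_means = wide.mean(axis=1)
        grand = subj_means.mean()
        groups = subj_means.groupby(animal_sex.loc[subj_means.index].values)
        ss_sex = T * sum(len(g) * (g.mean() - grand) ** 2 for _, g in groups)
        ss_subj_within = T * sum(((g - g.mean()) ** 2).sum() for _, g in groups)
        df_sex = len(sexes) - 1
        df_err = len(subj_means) - len(sexes)
        if df_err < 1:
            raise DesignError("not enough animals per sex")
        if ss_sex <= 1e-300:
            F, p = 0.0, 1.0
        elif ss_subj_within <= 1e-300:
            F, p = np.inf, 0.0
        else:
            F = (ss_sex / df_sex) / (ss_subj_within / df_err)
            p = float(stats.f.sf(F, df_sex, df_err))
        rows.append({"variable": col, "F": F, "df1": df_sex, "df2": df_err, "p": p})
    out = pd.DataFrame(rows).set_index("variable")
    out["adj_p"] = adjust(out["p"].values, adjust_method)
    return out


# --------------------------------------------------------------------------- #
# Paired contrasts
# --------------------------------------------------------------------------- #
def paired_tests(
    matrix: LongitudinalMatrix,
    baseline: float = 0,
    times: Sequence[float] | None = None,
    adjust_method: str = "BH",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t-tests of each post-baseline time against the baseline time.

    One test per feature x contrast; the *full pooled list* of p-values is
    adjusted in a single family (the adjustment scope used throughout the
    pipeline: BH for biological variables, Bonferroni for transcripts).

    Returns a tidy table with columns feature, contrast, diff, t, df, p,
    adj_p and direction ('up'/'down' where adj_p < alpha, '' elsewhere).
    Zero-variance differences yield NaN p-values, which are reported but
    excluded from the adjustment family.
    """
    matrix.require_balanced()
    if times is None:
        times = [t for t in matrix.times if t != baseline]
    if baseline not in matrix.times:
        raise DesignError(f"baseline time {baseline!r} not present")
    if matrix.n_animals < 3:
        raise DesignError("paired tests need at least 3 animals")

    base = matrix.at_time(baseline)
    records = []
    for t in times:
        other = matrix.at_time(t)
        D = other.values - base.loc[other.index].values
        n = D.shape[0]
        mean = D.mean(axis=0)
        sd = D.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = mean / (sd / math.sqrt(n))
        df = n - 1
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        zero_var = sd == 0
        if zero_var.any():
            # all-zero differences are a true null (t = 0); a nonzero constant
            # difference has an undefined t -> NaN with a warning
            degenerate = zero_var & (mean != 0)
            tstat = np.where(degenerate, np.nan, np.where(zero_var, 0.0, tstat))
            p = np.where(degenerate, np.nan, np.where(zero_var, 1.0, p))
            if degenerate.any():
                warnings.warn(
                    f"{int(degenerate.sum())} feature(s) with zero-variance "
                    f"differences at contrast {baseline} vs {t}; p reported as NA"
                )
        for j, feature in enumerate(base.columns):
            records.append(
                {
                    "feature": feature,
                    "contrast": f"{_tlabel(baseline)}_vs_{_tlabel(t)}",
                    "time": t,
                    "diff": mean[j],
                    "t": tstat[j],
                    "df": df,
                    "p": p[j],
                }
            )
    out = pd.DataFrame(records)
    out["adj_p"] = adjust(out["p"].values, adjust_method)
    out["direction"] = np.where(
        out["adj_p"] < alpha, np.where(out["diff"] > 0, "up", "down"), ""
    )
    return out


def _tlabel(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else str(t)


def de_features(results: pd.DataFrame, alpha: float = 0.05) -> list:
    """Features significant (adj_p < alpha) in at least one contrast."""
    sig = results[results["adj_p"] < alpha]
    return sorted(sig["feature"].unique().tolist())


# --------------------------------------------------------------------------- #
# Duplicate-probe consolidation
# --------------------------------------------------------------------------- #
def consolidate_probes(
    results: pd.DataFrame,
    expression: pd.DataFrame,
    probe_map: pd.DataFrame,
    min_fraction: float = 0.75,
    min_corr: float = 0.65,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse probe-level differential results to unique genes.

    A gene with multiple probes passes iff at least ``ceil(min_fraction *
    n_probes)`` of its probes are differentially expressed (some contrast
    with adjusted p < ``alpha``) *and* every pair of those DE probes has
    Pearson correlation >= ``min_corr`` across samples.  Single-probe genes
    pass on differential expression alone.  The retained representative is
    the gene's most significant probe.

    Parameters
    ----------
    results : paired_tests output over probes.
    expression : probes x samples matrix (for the probe-probe correlations).
    probe_map : DataFrame indexed by probe with a 'gene' column; probes with
        an empty gene are routed to the unannotated report.

    Returns
    -------
    consolidation : per-gene table (n_probes, n_de_probes, min_pairwise_corr,
        passes, representative, best_adj_p, best_time, direction)
    unannotated : per-probe report of DE probes lacking a gene annotation
    """
    best = (
        results.sort_values("adj_p", kind="stable")
        .groupby("feature", sort=False)
        .first()
    )
    de_probes = set(best.index[best["adj_p"] < alpha])

    genes = probe_map.loc[probe_map.index.intersection(results["feature"].unique()), "gene"]
    annotated = genes[genes.astype(str).str.len() > 0].dropna()
    unannotated_probes = sorted(set(genes.index) - set(annotated.index))
    unannotated = pd.DataFrame(
        {
            "probe": [p for p in unannotated_probes],
            "is_de": [p in de_probes for p in unannotated_probes],
        }
    ).set_index("probe")

    records = []
    for gene, probes in annotated.groupby(annotated.values).groups.items():
        probes = list(probes)
        de = [p for p in probes if p in de_probes]
        n_needed = math.ceil(min_fraction * len(probes))
        if len(probes) == 1:
            passes = len(de) == 1
            min_r = np.nan
        else:
            if len(de) >= 2:
                R = np.corrcoef(expression.loc[de].values)
                min_r = float(R[np.triu_indices_from(R, k=1)].min())
            else:
                min_r = np.nan
            passes = len(de) >= n_needed and (len(de) < 2 or min_r >= min_corr)
        if de:
            rep = best.loc[de, "adj_p"].idxmin()
            rep_row = best.loc[rep]
        else:
            rep, rep_row = None, None
        records.append(
            {
                "gene": gene,
                "n_probes": len(probes),
                "n_de_probes": len(de),
                "min_pairwise_corr": min_r,
                "passes": bool(passes),
                "representative": rep,
                "best_adj_p": rep_row["adj_p"] if rep_row is not None else np.nan,
                "best_time": rep_row["time"] if rep_row is not None else np.nan,
                "direction": rep_row["direction"] if rep_row is not None else "",
            }
        )
    consolidation = pd.DataFrame(records).set_index("gene").sort_index()
    return consolidation, unannotated


# --------------------------------------------------------------------------- #
# Anchor correlations
# --------------------------------------------------------------------------- #
def correlate_to_anchor(
    features: LongitudinalMatrix,
    anchor: pd.Series,
    times: Iterable[float] | None = None,
    adjust_method: str = "BH",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate within-animal features at each time to a within-animal anchor.

    ``features`` must already be the within-animal component (see
    :func:`stressomics.multilevel.decompose`); ``anchor`` is the within-animal
    anchor value per animal — typically cortisol at its +1 h peak.  For each
    feature x time the Pearson correlation across animals is reported with
    its standard error ``sqrt((1 - r^2)/(n - 2))`` and the standard t-test
    for a correlation coefficient on ``n - 2`` degrees of freedom; the full
    feature x time list of p-values is adjusted globally.

    Zero-variance features at a time point give NaN with a warning and are
    excluded from the adjustment family.
    """
    if times is None:
        times = features.times
    anchor = pd.Series(anchor)
    records = []
    for t in times:
        block = features.at_time(t)
        a = anchor.loc[block.index].values
        n = len(a)
        if n < 3:
            raise DesignError("anchor correlation needs at least 3 animals")
        a_c = a - a.mean()
        denom_a = np.sqrt((a_c**2).sum())
        V = block.values - block.values.mean(axis=0)
        denom_v = np.sqrt((V**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (V.T @ a_c) / (denom_v * denom_a)
        bad = (denom_v == 0) | (denom_a == 0)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} zero-variance feature(s) at time {t}; "
                "correlation reported as NA"
            )
        r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
        df = n - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt((1.0 - r**2) / df)
            tstat = r * np.sqrt(df / (1.0 - r**2))
        p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(tstat), df))
        p = np.where(np.isnan(r), np.nan, p)
        for j, feature in enumerate(block.columns):
            records.append(
                {
                    "feature": feature,
                    "time": t,
                    "r": r[j],
                    "se": se[j],
                    "n": n,
                    "p": p[j],
                }
            )
    out = pd.DataFrame(records)
    out["adj_p"] = adjust(out["p"].values, adjust_method)
    out["significant"] = out["adj_p"] < alpha
    return out
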