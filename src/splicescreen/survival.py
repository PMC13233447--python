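"""Survival-based prioritisation and clinical baseline tables.

Clinical records travel as a pandas DataFrame with one row per patient:
``patient_id``, covariates (``age`` in years, categorical ``stage`` /
``grade`` / ``race``), a continuous ``expression`` column for the gene under
evaluation, and per-endpoint ``<endpoint>_time`` (days) / ``<endpoint>_event``
(0/1) columns.  Any of these may be missing; baseline tables use
available-case denominators, while each hazard model applies its own
complete-case filter.

Cox proportional-hazards models are fitted by partial-likelihood
maximisation with Breslow tie handling (statsmodels ``PHReg``); group
comparisons use the standard 1-df log-rank test (lifelines).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy.stats import chi2_contingency, fisher_exact, norm
from statsmodels.duration.hazard_regression import PHReg

from .config import log, log_funnel

ENDPOINTS = ("os", "pfs", "dfs", "dss")


@dataclass
class SurvivalFit:
    """One covariate's hazard estimate from a proportional-hazards model."""

    endpoint: str
    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    n_events: int


class FitError(RuntimeError):
    pass


def median_split(values: pd.Series) -> pd.Series:
    """Split a cohort at the median expression: value <= median -> "low",
    value > median -> "high".  Ties at the median go to the low group."""
    values = values.dropna()
    if len(values) < 2:
        raise ValueError("need >= 2 patients for a median split")
    med = values.median()
    labels = pd.Series(np.where(values > med, "high", "low"),
                       index=values.index, name="group")
    if (labels == "low").all():
        log.warning("degenerate median split: all values <= median")
    return labels


def complete_case_filter(records: pd.DataFrame, covariates: list[str],
                         endpoint: str) -> pd.DataFrame:
    """Model-specific complete-case subset for one endpoint.

    Drops patients missing any named covariate, missing the endpoint's time
    or event indicator, or with a follow-up time of zero days.
    """
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    for col in list(covariates) + [tcol, ecol]:
        if col not in records.columns:
            raise KeyError(f"column {col!r} absent from records")
    keep = records[list(covariates) + [tcol, ecol]].notna().all(axis=1)
    keep &= records[tcol].fillna(0) > 0
    out = records[keep]
    log_funnel(f"complete-case ({endpoint})", len(records), len(out))
    return out


def _design_matrix(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        s = records[cov]
        if pd.api.types.is_numeric_dtype(s):
            cols[cov] = s.astype(float)
        else:
            dummies = pd.get_dummies(s.astype("category"), prefix=cov,
                                     drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c]
    return pd.DataFrame(cols, index=records.index)


def fit_ph(records: pd.DataFrame, covariates: list[str], endpoint: str,
           alpha: float = 0.05) -> list[SurvivalFit]:
    """Cox proportional-hazards fit; one :class:`SurvivalFit` per term.

    Records are complete-case filtered for this model first.  Categorical
    covariates are expanded to treatment-coded indicator terms.  Ties are
    handled with the Breslow approximation; HR = exp(coefficient) with Wald
    confidence intervals and p-values.
    """
    sub = complete_case_filter(records, covariates, endpoint)
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    n_events = int(sub[ecol].sum())
    if n_events < 1:
        raise FitError(f"no events for endpoint {endpoint}")
    X = _design_matrix(sub, covariates)
    variances = X.var(axis=0)
    dead = variances[variances == 0].index.tolist()
    if dead:
        raise FitError(f"zero-variance covariate terms: {dead}")
    try:
        model = PHReg(np.asarray(sub[tcol], float), np.asarray(X, float),
                      status=np.asarray(sub[ecol], float), ties="breslow")
        res = model.fit(disp=False)
    except Exception as exc:  # pragma: no cover - numerical failure path
        raise FitError(f"PH fit failed for {endpoint}: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        raise FitError(f"PH fit did not converge for {endpoint}")
    z = norm.ppf(1 - alpha / 2)
    fits = []
    for name, beta, se in zip(X.columns, res.params, res.bse):
        pval = 2 * norm.sf(abs(beta / se)) if se > 0 else float("nan")
        fits.append(SurvivalFit(
            endpoint=endpoint, covariate=name, hr=float(np.exp(beta)),
            ci_low=float(np.exp(beta - z * se)),
            ci_high=float(np.exp(beta + z * se)),
            p=float(pval), n_used=len(sub), n_events=n_events))
    return fits


def logrank(records: pd.DataFrame, labels: pd.Series, endpoint: str,
            ) -> tuple[float, float]:
    """Two-group log-rank test (1 df) on one endpoint.

    ``labels`` maps patient index -> group label; exactly two non-empty
    groups are required.  Returns (chi-square statistic, p).
    """
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    sub = records.loc[labels.index].dropna(subset=[tcol, ecol])
    labels = labels.loc[sub.index]
    groups = labels.unique()
    if len(groups) != 2 or any((labels == g).sum() == 0 for g in groups):
        raise ValueError("log-rank needs exactly 2 non-empty groups")
    a = sub[labels == groups[0]]
    b = sub[labels == groups[1]]
    res = logrank_test(a[tcol], b[tcol], event_observed_A=a[ecol],
                       event_observed_B=b[ecol])
    return float(res.test_statistic), float(res.p_value)


def survival_triage(fits_by_gene: dict[str, list[SurvivalFit]],
                    survival_p: float = 0.05) -> dict[str, bool]:
    """Flag genes with stable prognostic value across endpoints.

    A gene is "stable" iff every supplied endpoint fit has HR > 1 and
    p < survival_p (direction-consistent significance); at least two
    endpoints are required per gene.
    """
    flags = {}
    for gene, fits in fits_by_gene.items():
        if len({f.endpoint for f in fits}) < 2:
            raise ValueError(f"{gene}: need fits for >= 2 endpoints")
        flags[gene] = all(f.hr > 1 and f.p < survival_p for f in fits)
    return flags


def clinical_table(records: pd.DataFrame, labels: pd.Series,
                   characteristics: list[str]) -> pd.DataFrame:
    """Baseline characteristics table with available-case percentages.

    For each categorical characteristic, per-group counts and percentages
    are computed with the denominator equal to the number of records
    *non-missing for that characteristic in that group* (available-case
    analysis: denominators differ across characteristics).  Groups are
    compared with a chi-square test, falling back to Fisher's exact test
    for 2x2 tables with any expected cell below 5.  A characteristic with a
    single observed level is reported without a test.
    """
    groups = [g for g in ["low", "high"] if g in set(labels)] or \
        sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("clinical_table expects exactly 2 groups")
    rows = []
    for char in characteristics:
        sub = records.loc[labels.index, char]
        levels = sorted(sub.dropna().unique().tolist())
        counts = {
            g: sub[labels == g].value_counts().reindex(levels).fillna(0)
            .astype(int)
            for g in groups}
        denoms = {g: int(counts[g].sum()) for g in groups}
        table = np.array([[counts[g][lv] for g in groups] for lv in levels])
        p = np.nan
        if len(levels) >= 2 and min(denoms.values()) > 0:
            expected = chi2_contingency(table)[3]
            if table.shape == (2, 2) and (expected < 5).any():
                p = fisher_exact(table)[1]
            else:
                p = chi2_contingency(table)[1]
        elif len(levels) < 2:
            log.warning("characteristic %s has a single observed level; "
                        "test skipped", char)
        for lv in levels:
            row = {"characteristic": char, "level": lv, "p": p}
            for g in groups:
                n = counts[g][lv]
                row[f"{g}_n"] = int(n)
                row[f"{g}_pct"] = (100.0 * n / denoms[g]
                                   if denoms[g] > 0 else np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
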