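"""Evaluation statistics for crossed-design texture studies.

The analysis layer of the assay: full factorial fixed-effects ANOVA F-tests
(day x treatment x internal replicate, all interactions), pooled t-test,
Fisher-LSD post-hoc contrasts, Holm step-down multiple-testing correction,
variable-correlation grouping, treatment-effect vs evaporation-time
correlation, and the processing-order diagnostic with linear detrending.

Sums of squares are partial (Type-III style, effects coding); on balanced
complete data they reduce to the classical decomposition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaTable",
    "VariableGroups",
    "factorial_anova",
    "two_sample_t",
    "lsd_posthoc",
    "holm_correction",
    "correlate_and_group",
    "processing_order_test",
    "order_correction",
    "effect_vs_evaporation",
]


@dataclass
class AnovaTable:
    """Per-effect F statistics for a full crossed fixed-effects model."""

    table: pd.DataFrame  # index: effect names + "Residual"; cols df, sum_sq, F, p
    residual_df: float
    residual_ms: float
    n_obs: int

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def F(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    @property
    def effects(self) -> list[str]:
        return [e for e in self.table.index if e != "Residual"]


def _effect_names(factors: list[str]) -> list[str]:
    names = []
    for k in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, k):
            names.append(":".join(combo))
    return names


def factorial_anova(
    data: pd.DataFrame, response: str, factors: list[str]
) -> AnovaTable:
    """Full crossed fixed-effects ANOVA with all interactions.

    Uses effects (Sum) coding and partial sums of squares, so mildly
    unbalanced data (e.g. after plate discards) are handled; balanced data
    reduce to the classical decomposition.  A constant response yields
    SS = 0 and p = 1 for every effect rather than failing the run.
    """
    if len(factors) < 1:
        raise ValueError("need at least one factor")
    df = data[[response] + factors].dropna().copy()
    n = len(df)
    if n == 0:
        raise ValueError("no data")
    for f in factors:
        levels = df[f].nunique()
        if levels < 2:
            raise ValueError(f"factor {f!r} has {levels} level(s); needs >= 2")
    # estimability: the full interaction needs every cell occupied
    cell_sizes = df.groupby(factors, observed=True).size()
    n_cells = int(np.prod([df[f].nunique() for f in factors]))
    if len(cell_sizes) < n_cells:
        missing = n_cells - len(cell_sizes)
        raise ValueError(
            f"effect {':'.join(factors)} is not estimable: {missing} empty cell(s)"
        )
    if n <= n_cells:
        raise ValueError(
            "model is saturated: no residual degrees of freedom "
            f"({n} observations for {n_cells} cells)"
        )

    y = df[response].to_numpy(float)
    names = _effect_names(factors)
    if np.ptp(y) == 0 or np.allclose(y, y.mean(), rtol=0, atol=1e-12 * max(1, abs(y.mean()))):
        rows = {nm: dict(df=np.nan, sum_sq=0.0, F=0.0, p=1.0) for nm in names}
        tab = pd.DataFrame(rows).T
        tab.loc["Residual"] = dict(df=float(n - n_cells), sum_sq=0.0, F=np.nan, p=np.nan)
        return AnovaTable(tab, residual_df=float(n - n_cells), residual_ms=0.0, n_obs=n)

    # neutral internal names: raw column names inside a patsy formula can
    # collide with formula syntax (a factor called "C" or "Sum")
    safe = {f: f"_f{i}" for i, f in enumerate(factors)}
    df = df.rename(columns={response: "_y", **safe})
    terms = " * ".join(f"C({safe[f]}, Sum)" for f in factors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = ols(f"_y ~ {terms}", data=df).fit()
        aov = anova_lm(fit, typ=3)

    unsafe = {v: k for k, v in safe.items()}

    def _clean(term: str) -> str:
        return ":".join(
            unsafe[t.split("(")[1].split(",")[0]] for t in term.split(":")
        )

    rows = {}
    for term in aov.index:
        if term in ("Intercept",):
            continue
        if term == "Residual":
            continue
        rows[_clean(term)] = dict(
            df=float(aov.loc[term, "df"]),
            sum_sq=float(aov.loc[term, "sum_sq"]),
            F=float(aov.loc[term, "F"]),
            p=float(aov.loc[term, "PR(>F)"]),
        )
    res_df = float(aov.loc["Residual", "df"])
    res_ss = float(aov.loc["Residual", "sum_sq"])
    tab = pd.DataFrame([rows[nm] for nm in names], index=names)
    tab.loc["Residual"] = dict(df=res_df, sum_sq=res_ss, F=np.nan, p=np.nan)
    tab = tab.rename(columns={})
    tab.columns = ["df", "sum_sq", "F", "p"]
    return AnovaTable(
        tab,
        residual_df=res_df,
        residual_ms=res_ss / res_df if res_df > 0 else np.nan,
        n_obs=n,
    )


def two_sample_t(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance t-test."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def lsd_posthoc(
    anova: AnovaTable,
    data: pd.DataFrame,
    response: str,
    group_col: str,
    group_a,
    group_b,
) -> tuple[float, float]:
    """Fisher LSD contrast of two cell means.

    The t statistic uses the omnibus model's residual mean square and
    residual degrees of freedom.
    """
    a = data.loc[data[group_col] == group_a, response].dropna().to_numpy(float)
    b = data.loc[data[group_col] == group_b, response].dropna().to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"group(s) absent from data: {group_a!r} / {group_b!r}")
    se = np.sqrt(anova.residual_ms * (1 / len(a) + 1 / len(b)))
    if se == 0:
        return 0.0, 1.0
    t = (a.mean() - b.mean()) / se
    p = 2 * stats.t.sf(abs(t), anova.residual_df)
    return float(t), float(p)


def holm_correction(
    pvalues, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down correction: (reject flags, adjusted p), input order."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.array([], bool), np.array([])
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, p_adj


@dataclass
class VariableGroups:
    """Correlation structure of the texture variables.

    ``labels`` maps each variable to "I" (not evaporation-linked), "II"
    (evaporation-linked) or "intermediate" (singleton in the thresholded
    correlation graph).
    """

    corr: pd.DataFrame
    evap_corr: pd.Series
    components: list[set[str]] = field(default_factory=list)
    labels: dict[str, str] = field(default_factory=dict)
    r_group: float = 0.6
    r_evap: float = 0.46


def correlate_and_group(
    features: pd.DataFrame,
    evap: pd.Series | np.ndarray,
    r_group: float = 0.6,
    r_evap: float = 0.46,
) -> VariableGroups:
    """Group texture variables by their between-plate correlation graph.

    Variables are nodes; edges join pairs with |r| >= ``r_group``; groups are
    the connected components.  Each variable's correlation with evaporation
    time is reported against ``r_evap``: components whose median |r_evap|
    reaches the threshold are labelled "II" (evaporation-linked), the others
    "I"; singleton components are "intermediate".
    """
    if len(features) < 3:
        raise ValueError("need >= 3 plates")
    evap = np.asarray(evap, float)
    feats = features.copy()
    dropped = [c for c in feats.columns if feats[c].std() == 0]
    if dropped:
        warnings.warn(f"excluding zero-variance variables: {dropped}")
        feats = feats.drop(columns=dropped)
    corr = feats.corr()
    ev = pd.Series(
        {c: np.corrcoef(feats[c], evap)[0, 1] for c in feats.columns}, name="r_evap"
    )
    # connected components by union-find
    cols = list(feats.columns)
    parent = {c: c for c in cols}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for aa, bb in itertools.combinations(cols, 2):
        if abs(corr.loc[aa, bb]) >= r_group:
            parent[find(aa)] = find(bb)
    comps: dict[str, set[str]] = {}
    for c in cols:
        comps.setdefault(find(c), set()).add(c)
    components = sorted(comps.values(), key=len, reverse=True)
    labels = {}
    for comp in components:
        if len(comp) == 1:
            lab = "intermediate"
        else:
            med = np.median([abs(ev[c]) for c in comp])
            lab = "II" if med >= r_evap else "I"
        for c in comp:
            labels[c] = lab
    return VariableGroups(corr, ev, components, labels, r_group, r_evap)


def processing_order_test(
    control_data: pd.DataFrame,
    response: str,
    day_col: str = "day",
    order_col: str = "processing_order",
    mode: str = "ratio",
) -> float:
    """One-way ANOVA p for a processing-order effect in the control group.

    Control values are normalised to their day mean (``ratio``: divided;
    ``subtract``: centred), pooled across days, and tested against the
    processing-order factor.  Days without control data are excluded with a
    warning; a degenerate (constant) response reports p = 1.
    """
    if mode not in ("ratio", "subtract"):
        raise ValueError(f"unknown mode {mode!r}")
    df = control_data[[response, day_col, order_col]].dropna().copy()
    if df.empty:
        raise ValueError("no control data")
    norm = []
    for day, sub in df.groupby(day_col):
        m = sub[response].mean()
        if mode == "ratio":
            if m == 0:
                warnings.warn(f"day {day}: zero mean, excluded from ratio normalisation")
                continue
            vals = sub[response] / m
        else:
            vals = sub[response] - m
        norm.append(pd.DataFrame({order_col: sub[order_col], "v": vals}))
    pooled = pd.concat(norm)
    groups = [g["v"].to_numpy() for _, g in pooled.groupby(order_col)]
    if len(groups) < 2:
        raise ValueError("need >= 2 processing-order levels")
    if np.ptp(pooled["v"].to_numpy()) == 0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.f_oneway(*groups)
    return 1.0 if np.isnan(p) else float(p)


def order_correction(
    values, order
) -> tuple[np.ndarray, float]:
    """Remove the linear processing-order trend; grand mean preserved.

    Fits a least-squares slope of the response on the order number and
    subtracts ``slope * (order - mean(order))``.  Returns (corrected values,
    fitted slope).  Idempotent: correcting corrected data changes nothing.
    """
    values = np.asarray(values, float)
    order = np.asarray(order, float)
    if len(np.unique(order)) < 2:
        raise ValueError("need >= 2 distinct processing-order values")
    slope = np.polyfit(order, values, 1)[0]
    return values - slope * (order - order.mean()), float(slope)


def effect_vs_evaporation(effects, evap) -> tuple[float, float]:
    """Pearson correlation of per-day treatment-effect sizes with per-day
    mean evaporation times, with the two-sided t-transform p-value."""
    effects = np.asarray(effects, float)
    evap = np.asarray(evap, float)
    if len(effects) != len(evap):
        raise ValueError("length mismatch")
    if len(effects) < 3:
        raise ValueError("need >= 3 days")
    if np.std(effects) == 0 or np.std(evap) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(effects, evap)
    return float(r), float(p)
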