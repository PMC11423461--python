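"""Carrier-burden association: prevalence comparison between disease groups
and controls via Pearson chi-square, and odds ratios from a logistic model
(intercept + carrier indicator) with Wald inference.

For a single binary covariate the logistic coefficient equals the log
cross-product ratio of the 2x2 table, which the tests exploit as an exact
oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class AssociationResult:
    group: str
    n_cases: int
    n_case_carriers: int
    n_controls: int
    n_control_carriers: int
    case_freq: float
    control_freq: float
    odds_ratio: float
    log_or: float
    se_log_or: float
    wald_p: float
    chi2_stat: float
    chi2_p: float
    ci95: tuple[float, float]
    corrected: bool = False  # Haldane-Anscombe 0.5 applied to a zero cell


def carrier_frequency(cohort: pd.DataFrame, group: str) -> float:
    """Fraction of LD carriers within a cohort group."""
    sub = cohort[cohort["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} is empty or absent")
    return float(sub["is_carrier"].mean())


def render_percent(fraction: float) -> str:
    """Integer-percent rendering with round-half-up (0.109 -> ``'11%'``)."""
    pct = math.floor(fraction * 100 + 0.5)
    return f"{pct}%"


def logistic_or(
    a: int, b: int, c: int, d: int, *, group: str = "", one_sided: bool = False
) -> AssociationResult:
    """Odds ratio for a 2x2 table (a=case carriers, b=case non-carriers,
    c=control carriers, d=control non-carriers) by IRLS logistic fit.

    Zero cells get the Haldane-Anscombe 0.5 correction (flagged on the
    result); an empty arm raises. ``se_log_or`` is the usual
    sqrt(1/a + 1/b + 1/c + 1/d); the Wald p uses the normal approximation.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("empty case or control arm")
    corrected = False
    af, bf, cf, df = float(a), float(b), float(c), float(d)
    if min(a, b, c, d) == 0:
        af, bf, cf, df = af + 0.5, bf + 0.5, cf + 0.5, df + 0.5
        corrected = True

    # binomial GLM on two aggregated rows: carriers/(carriers+non-carriers).
    # The fit is saturated (2 rows, 2 parameters), which statsmodels flags
    # even though the IRLS estimate is exact; silence those warnings.
    endog = np.array([[af, bf], [cf, df]])
    exog = sm.add_constant(np.array([1.0, 0.0]))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    log_or = float(fit.params[1])
    se = math.sqrt(1 / af + 1 / bf + 1 / cf + 1 / df)
    z = log_or / se
    wald_p = float(stats.norm.sf(abs(z)) * (1 if one_sided else 2))
    chi2_stat, chi2_p = pearson_chi2(a, b, c, d)
    ci = (math.exp(log_or - 1.959963984540054 * se),
          math.exp(log_or + 1.959963984540054 * se))
    return AssociationResult(
        group=group,
        n_cases=a + b,
        n_case_carriers=a,
        n_controls=c + d,
        n_control_carriers=c,
        case_freq=a / (a + b),
        control_freq=c / (c + d),
        odds_ratio=math.exp(log_or),
        log_or=log_or,
        se_log_or=se,
        wald_p=wald_p,
        chi2_stat=chi2_stat,
        chi2_p=chi2_p,
        ci95=ci,
        corrected=corrected,
    )


def pearson_chi2(
    a: int, b: int, c: int, d: int, *, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction by
    default. Warns when an expected cell is < 1."""
    table = np.array([[a, b], [c, d]], dtype=float)
    expected = stats.contingency.expected_freq(table)
    if (expected < 1).any():
        import warnings

        warnings.warn("expected cell count < 1; consider an exact test")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)


def prevalence_chi2(
    cohort: pd.DataFrame, group_a: str, group_b: str, *, yates: bool = False
) -> tuple[float, float]:
    """Chi-square comparison of carrier prevalence between two groups."""
    cells = []
    for g in (group_a, group_b):
        sub = cohort[cohort["group"] == g]
        if sub.empty:
            raise ValueError(f"group {g!r} is empty or absent")
        k = int(sub["is_carrier"].sum())
        cells.extend([k, len(sub) - k])
    return pearson_chi2(*cells, yates=yates)


def associate_groups(
    cohort: pd.DataFrame,
    control_label: str = "CONTROL",
    *,
    include_pooled: bool = True,
    pooled_label: str = "MPN",
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-group association vs the control arm; one row per disease group
    (optionally plus the pooled cases). Raw p-values by default, matching
    the single-comparison reporting convention; BH optional."""
    controls = cohort[cohort["group"] == control_label]
    if controls.empty:
        raise ValueError(f"control group {control_label!r} absent")
    c = int(controls["is_carrier"].sum())
    d = len(controls) - c

    groups = [g for g in cohort["group"].unique() if g != control_label]
    rows = []
    contrasts: list[tuple[str, pd.DataFrame]] = [(g, cohort[cohort["group"] == g]) for g in groups]
    if include_pooled and len(groups) > 1:
        contrasts.append((pooled_label, cohort[cohort["group"] != control_label]))
    for name, sub in contrasts:
        a = int(sub["is_carrier"].sum())
        b = len(sub) - a
        res = logistic_or(a, b, c, d, group=name)
        rows.append(
            {
                "group": name,
                "n_cases": res.n_cases,
                "n_case_carriers": a,
                "n_controls": res.n_controls,
                "n_control_carriers": c,
                "case_freq": res.case_freq,
                "control_freq": res.control_freq,
                "case_pct": render_percent(res.case_freq),
                "odds_ratio": res.odds_ratio,
                "ci95_low": res.ci95[0],
                "ci95_high": res.ci95[1],
                "wald_p": res.wald_p,
                "chi2_stat": res.chi2_stat,
                "chi2_p": res.chi2_p,
            }
        )
    out = pd.DataFrame(rows)
    if bh_adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        out["wald_q"] = multipletests(out["wald_p"], method="fdr_bh")[1]
    return out
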