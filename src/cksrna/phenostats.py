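"""Growth/yield trait statistics.

Per trait and experimental repetition, a two-group comparison is chosen by
assumption checks: Shapiro-Wilk normality on both groups and an F-ratio
variance test. Both normal and homoscedastic -> pooled two-sample t test;
normal but heteroscedastic -> Welch t; otherwise the exact two-sided
Mann-Whitney-Wilcoxon. P values are Benjamini-Hochberg corrected within each
repetition's trait family, averaged across repetitions, and mapped to
significance stars. The treatment effect is reported as
100 * (mean_treated - mean_control) / mean_control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

STAR_THRESHOLDS = ((0.0001, "***"), (0.001, "**"), (0.05, "*"))


@dataclass
class TraitResult:
    trait: str
    mean_control: float
    mean_treated: float
    si_effect_percent: float
    test_used: str                 # 't' | 'mww' (per-repetition, joined by '/')
    p_values: tuple                # raw p per repetition
    adjusted_p: tuple              # BH-adjusted p per repetition
    mean_adjusted_p: float
    stars: str


def si_effect(mean_treated: float, mean_control: float) -> float:
    """Treatment effect as percent change over the control mean."""
    if mean_control == 0:
        raise ValueError("control mean of zero: effect undefined")
    return 100.0 * (mean_treated - mean_control) / mean_control


def _f_variance_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F test for equal variances (larger variance on top)."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    (v1, n1), (v2, n2) = sorted(
        [(va, len(a)), (vb, len(b))], key=lambda t: -t[0])
    if v2 == 0:
        return 0.0
    f = v1 / v2
    return float(min(1.0, 2 * stats.f.sf(f, n1 - 1, n2 - 1)))


def choose_and_run_test(control, treated,
                        alpha_assumption: float = 0.05) -> tuple:
    """Assumption-guided two-group test; returns (test_used, p_value)."""
    a = np.asarray(control, dtype=float)
    b = np.asarray(treated, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3 for normality checking")
    normal = True
    for grp in (a, b):
        if np.ptp(grp) == 0:
            # Shapiro-Wilk is undefined on constant data; treat as normal
            continue
        if stats.shapiro(grp).pvalue < alpha_assumption:
            normal = False
    if normal:
        equal_var = _f_variance_p(a, b) >= alpha_assumption
        p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
        return "t", float(p)
    method = "exact" if max(len(a), len(b)) <= 8 else "auto"
    p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    return "mww", float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assign_stars(mean_adjusted_p: float) -> str:
    """Map an averaged adjusted p value to a significance label."""
    if not 0.0 <= mean_adjusted_p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    for threshold, label in STAR_THRESHOLDS:
        if mean_adjusted_p <= threshold:
            return label
    return "ns"


def analyze_traits(table: pd.DataFrame, control_label: str = "control",
                   treated_label: str = "Si",
                   alpha_assumption: float = 0.05) -> pd.DataFrame:
    """Full trait analysis of a (trait, group, replicate, value) table.

    BH families are the traits tested within one repetition; star labels are
    assigned to the across-repetition average of the adjusted p values.
    """
    required = {"trait", "group", "replicate", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"trait table must have columns {sorted(required)}")
    traits = list(dict.fromkeys(table["trait"]))
    reps = list(dict.fromkeys(table["replicate"]))
    raw: dict = {t: [] for t in traits}
    used: dict = {t: [] for t in traits}
    for rep in reps:
        sub = table[table["replicate"] == rep]
        family = []
        for t in traits:
            grp = sub[sub["trait"] == t]
            ctrl = grp[grp["group"] == control_label]["value"].to_numpy()
            trt = grp[grp["group"] == treated_label]["value"].to_numpy()
            test, p = choose_and_run_test(ctrl, trt, alpha_assumption)
            family.append(p)
            used[t].append(test)
        adjusted = bh_adjust(family)
        for t, adj in zip(traits, adjusted):
            raw_p = family[traits.index(t)]
            raw[t].append((raw_p, float(adj)))
    rows = []
    for t in traits:
        grp = table[table["trait"] == t]
        mean_c = float(grp[grp["group"] == control_label]["value"].mean())
        mean_t = float(grp[grp["group"] == treated_label]["value"].mean())
        p_raw = tuple(p for p, _ in raw[t])
        p_adj = tuple(a for _, a in raw[t])
        mean_adj = float(np.mean(p_adj))
        rows.append(TraitResult(
            trait=t, mean_control=mean_c, mean_treated=mean_t,
            si_effect_percent=si_effect(mean_t, mean_c),
            test_used="/".join(used[t]), p_values=p_raw, adjusted_p=p_adj,
            mean_adjusted_p=mean_adj, stars=assign_stars(mean_adj),
        ))
    return pd.DataFrame([r.__dict__ for r in rows])
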