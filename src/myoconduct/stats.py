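"""Group comparison and feature-conductivity regression analysis.

Relationships between tissue features (e.g. Vmyo, Vfibrosis, Vgj) and the
directional conductivities are assessed with ordinary least squares; the
fit is summarized by R^2 and the p-value of the F-test against the
intercept-only model. Effect sizes follow the conventional R^2 bands:
weak below 0.3, moderate from 0.3 to 0.5 (inclusive), strong above 0.5.
Control and infarct groups are additionally reported separately when the
pooled fit hides a group-specific relationship: significance (p < 0.05)
in exactly one group but not combined, or an R^2 gap above 0.1 between
the groups. Group differences use the two-sided pooled-variance Student
t-test with significance at p < 0.05; no multiple-testing correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DegenerateFitError

P_SIGNIFICANT = 0.05


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    group: str = "all"
    reported_separately: bool = False

    @property
    def effect_size(self) -> str:
        if self.r_squared < 0.3:
            return "weak"
        if self.r_squared <= 0.5:
            return "moderate"
        return "strong"


@dataclass
class GroupComparison:
    t: float
    p: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float

    @property
    def significant(self) -> bool:
        return self.p < P_SIGNIFICANT

    def summary(self) -> str:
        return (
            f"{self.mean_a:.3f} +/- {self.sd_a:.3f} vs "
            f"{self.mean_b:.3f} +/- {self.sd_b:.3f} "
            f"(t = {self.t:.3f}, p = {self.p:.3g})"
        )


def _ols(x: np.ndarray, y: np.ndarray, group: str) -> RegressionResult:
    if len(x) < 3:
        raise ValueError(f"need >= 3 points per fitted group, got {len(x)} for {group!r}")
    if np.ptp(x) == 0:
        raise DegenerateFitError(f"predictor has zero variance in group {group!r}")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.f_pvalue),
        n=len(x),
        group=group,
    )


def linear_relationship(x, y, groups=None) -> dict[str, RegressionResult]:
    """Fit y on x by OLS, pooled and (optionally) per group.

    Parameters
    ----------
    x, y
        Feature and conductivity values, one entry per stack.
    groups
        Optional per-stack labels (e.g. ``"control"`` / ``"MI"``). When
        given, per-group fits are returned alongside the pooled fit and
        ``reported_separately`` is set on all results if either split rule
        fires: (a) p < 0.05 in exactly one group while the pooled fit is
        not significant, or (b) the groups' R^2 differ by more than 0.1.

    Returns
    -------
    dict mapping ``"all"`` and each group label to its fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = {"all": _ols(x, y, "all")}
    if groups is None:
        return out
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))  # preserve order
    for g in labels:
        sel = groups == g
        out[str(g)] = _ols(x[sel], y[sel], str(g))
    if len(labels) == 2:
        a, b = (out[str(g)] for g in labels)
        sig = [r.p_value < P_SIGNIFICANT for r in (a, b)]
        rule_a = sum(sig) == 1 and out["all"].p_value >= P_SIGNIFICANT
        rule_b = abs(a.r_squared - b.r_squared) > 0.1
        if rule_a or rule_b:
            for r in out.values():
                r.reported_separately = True
    return out


def group_compare(control, mi) -> GroupComparison:
    """Two-sided pooled-variance Student t-test between two groups.

    Returns the t statistic, p-value, and per-group mean +/- SD (sample
    SD, ddof=1).
    """
    control = np.asarray(control, dtype=float)
    mi = np.asarray(mi, dtype=float)
    if len(control) < 2 or len(mi) < 2:
        raise ValueError("each group needs >= 2 values")
    t, p = sps.ttest_ind(control, mi, equal_var=True)
    return GroupComparison(
        t=float(t),
        p=float(p),
        mean_a=float(control.mean()),
        sd_a=float(control.std(ddof=1)),
        mean_b=float(mi.mean()),
        sd_b=float(mi.std(ddof=1)),
    )
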