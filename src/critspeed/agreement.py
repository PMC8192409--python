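"""Agreement battery for comparing fitting procedures across a cohort.

Two procedures applied to the same subjects yield paired estimates of CS
(or d').  Agreement is assessed Bland--Altman style: the mean of the
paired differences is the *systematic bias*, its spread the *random
error* (reported as a multiple of the SD of differences, 1.6 by default,
1.96 for conventional limits of agreement), and the slope of the
differences regressed on the pair means the *proportional bias*.  The
battery also carries the gating diagnostics of that workflow: a paired
two-sided t-test on the differences, Shapiro--Wilk normality of the
differences, and the Durbin--Watson statistic of the proportional-bias
regression residuals (acceptance window 1.5--2.5).

For three or more procedures at once, a one-way repeated-measures ANOVA
with Mauchly's sphericity test (gating a Greenhouse--Geisser correction)
and Holm-adjusted pairwise post hoc t-tests is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.stattools import durbin_watson as _sm_dw

__all__ = [
    "PairedEstimates",
    "BlandAltmanResult",
    "RmAnovaResult",
    "PosthocComparison",
    "bland_altman",
    "durbin_watson",
    "rm_anova_with_posthoc",
    "normality_check",
]

#: Durbin-Watson window within which residual autocorrelation is deemed absent
DW_WINDOW = (1.5, 2.5)


@dataclass(frozen=True)
class PairedEstimates:
    """Per-subject estimates of one quantity from two procedures."""

    a: np.ndarray
    b: np.ndarray
    label_a: str = "A"
    label_b: str = "B"
    quantity: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired estimates must be 1-d arrays of equal length")
        if len(a) < 3:
            raise ValueError(f"need >= 3 paired subjects, got {len(a)}")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired estimates must not contain missing values")

    def __len__(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Systematic bias +/- random error, proportional bias, and gates.

    Sign convention: differences are ``a - b``, so a negative systematic
    bias means procedure ``a`` yields the smaller estimates.
    ``degenerate`` is set when the differences have zero variance, which
    leaves the t-test (and normality test) undefined.
    """

    systematic_bias: float
    random_error: float  # re_multiplier * SD of differences
    t_statistic: float
    p_systematic: float
    prop_slope: float
    prop_rse: float
    p_proportional: float
    durbin_watson: float
    dw_pass: bool
    shapiro_p: float
    n: int
    re_multiplier: float
    label_a: str
    label_b: str
    quantity: str
    differences: np.ndarray = field(repr=False)
    means: np.ndarray = field(repr=False)
    degenerate: bool = False


def bland_altman(pairs: PairedEstimates, re_multiplier: float = 1.6) -> BlandAltmanResult:
    """Bland--Altman agreement analysis of two procedures' estimates.

    ``re_multiplier`` scales the SD of differences into the reported
    random error; 1.6 by default, 1.96 for conventional 95% limits of
    agreement.
    """
    a, b = pairs.a, pairs.b
    d = a - b
    m = (a + b) / 2.0
    n = len(d)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    re = re_multiplier * sd

    degenerate = sd == 0.0
    if degenerate:
        t_stat = p_sys = shap_p = np.nan
    else:
        t_res = stats.ttest_1samp(d, 0.0)
        t_stat, p_sys = float(t_res.statistic), float(t_res.pvalue)
        shap_p = float(stats.shapiro(d).pvalue) if np.ptp(d) > 0 else np.nan

    # proportional bias: OLS of differences on pair means
    if np.ptp(m) == 0:
        slope, prop_rse_, p_prop, dw = np.nan, np.nan, np.nan, np.nan
        resid = np.full(n, np.nan)
    else:
        mm = m - m.mean()
        sxx = float(np.sum(mm**2))
        slope = float(np.sum(mm * (d - bias)) / sxx)
        intercept = bias - slope * m.mean()
        resid = d - (intercept + slope * m)
        rss = float(np.sum(resid**2))
        prop_rse_ = float(np.sqrt(rss / (n - 2))) if n > 2 else np.nan
        se_slope = prop_rse_ / np.sqrt(sxx) if n > 2 else np.nan
        if se_slope and np.isfinite(se_slope) and se_slope > 0:
            t_slope = slope / se_slope
            p_prop = float(2 * stats.t.sf(abs(t_slope), df=n - 2))
        else:
            p_prop = np.nan
        dw = float(_sm_dw(resid)) if np.any(resid != 0) else np.nan

    dw_pass = bool(np.isfinite(dw) and DW_WINDOW[0] <= dw <= DW_WINDOW[1])

    return BlandAltmanResult(
        systematic_bias=bias,
        random_error=re,
        t_statistic=t_stat,
        p_systematic=p_sys,
        prop_slope=slope,
        prop_rse=prop_rse_,
        p_proportional=p_prop,
        durbin_watson=dw,
        dw_pass=dw_pass,
        shapiro_p=shap_p,
        n=n,
        re_multiplier=re_multiplier,
        label_a=pairs.label_a,
        label_b=pairs.label_b,
        quantity=pairs.quantity,
        differences=d,
        means=m,
        degenerate=degenerate,
    )


def durbin_watson(residuals) -> tuple[float, bool]:
    """Durbin--Watson statistic and its 1.5--2.5 acceptance flag.

    DW = sum (e_i - e_{i-1})^2 / sum e_i^2, order-sensitive; values near
    2 indicate no first-order autocorrelation.
    """
    e = np.asarray(residuals, dtype=float)
    if e.ndim != 1 or len(e) < 2:
        raise ValueError("need an ordered sequence of >= 2 residuals")
    if np.all(e == 0):
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    d = float(_sm_dw(e))
    return d, DW_WINDOW[0] <= d <= DW_WINDOW[1]


def normality_check(values) -> tuple[float, float]:
    """Shapiro--Wilk W statistic and p-value."""
    v = np.asarray(values, dtype=float)
    if not 3 <= len(v) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PosthocComparison:
    a: str
    b: str
    t_statistic: float
    p_raw: float
    p_holm: float


@dataclass(frozen=True)
class RmAnovaResult:
    """One-way within-subject ANOVA with sphericity handling.

    ``p_omnibus`` is Greenhouse--Geisser corrected when Mauchly's test
    rejects sphericity (p <= 0.05), and uncorrected otherwise; both raw
    p-values are kept.  ``df_num``/``df_den`` carry the epsilon
    correction whenever it was applied.
    """

    f_statistic: float
    df_num: float
    df_den: float
    p_omnibus: float
    p_uncorrected: float
    p_gg_corrected: float
    mauchly_w: float
    mauchly_p: float
    epsilon: float
    sphericity_ok: bool
    posthoc: tuple[PosthocComparison, ...]


def rm_anova_with_posthoc(
    estimates: pd.DataFrame,
    alpha_sphericity: float = 0.05,
) -> RmAnovaResult:
    """RM-ANOVA across >= 3 procedures with Holm-adjusted post hocs.

    Parameters
    ----------
    estimates
        Wide table: one row per subject, one column per procedure
        (condition).  The design must be complete — no missing cells.
    alpha_sphericity
        Mauchly p-value at or below which the Greenhouse--Geisser df
        correction is applied to the omnibus test.
    """
    wide = pd.DataFrame(estimates)
    if wide.isna().any().any():
        raise ValueError("incomplete design: missing cells are not imputed")
    n_subj, n_cond = wide.shape
    if n_subj < 3 or n_cond < 3:
        raise ValueError("need >= 3 subjects and >= 3 conditions")

    long = wide.reset_index(drop=True).reset_index(names="subject").melt(
        id_vars="subject", var_name="procedure", value_name="estimate"
    )
    aov = pg.rm_anova(
        data=long,
        dv="estimate",
        within="procedure",
        subject="subject",
        correction=True,
        detailed=True,
    ).iloc[0]

    eps = float(aov["eps"])
    mauchly_w = float(aov["W_spher"])
    mauchly_p = float(aov["p_spher"])
    p_unc = float(aov["p_unc"])
    p_gg = float(aov["p_GG_corr"])
    df_num, df_den = float(aov["DF"]), float((n_subj - 1) * (n_cond - 1))

    apply_gg = mauchly_p <= alpha_sphericity
    if apply_gg:
        p_omni = p_gg
        df_num, df_den = eps * df_num, eps * df_den
    else:
        p_omni = p_unc

    ph = pg.pairwise_tests(
        data=long,
        dv="estimate",
        within="procedure",
        subject="subject",
        padjust="holm",
    )
    posthoc = tuple(
        PosthocComparison(
            a=str(row["A"]),
            b=str(row["B"]),
            t_statistic=float(row["T"]),
            p_raw=float(row["p_unc"]),
            p_holm=float(row["p_corr"]),
        )
        for _, row in ph.iterrows()
    )

    return RmAnovaResult(
        f_statistic=float(aov["F"]),
        df_num=df_num,
        df_den=df_den,
        p_omnibus=p_omni,
        p_uncorrected=p_unc,
        p_gg_corrected=p_gg,
        mauchly_w=mauchly_w,
        mauchly_p=mauchly_p,
        epsilon=eps,
        sphericity_ok=not apply_gg,
        posthoc=posthoc,
    )
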