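"""High-level workflow: simulate -> fit all procedures -> compare.

These functions tie the modules together into the standard analysis of a
fixed-speed critical-speed study: every configured fitting procedure is
applied to every subject, the per-subject estimates are summarised as a
cohort table (mean +/- SD of CS, d', their SEEs, %SEE and RSE per
procedure), and pairs of procedures are compared with the Bland--Altman
battery plus repeated-measures ANOVA blocks.  The command-line interface
in :mod:`critspeed.cli` is a thin wrapper over these functions; they do
no arithmetic of their own beyond table assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agreement, fitting
from .fitting import FittingProcedure, ModelVariant, Regression, STUDY_PROCEDURES
from .models import SubjectTrials
from .selector import ExperimentDesign, Variable, classify_procedure

__all__ = [
    "DEFAULT_COMPARISON_PAIRS",
    "fit_cohort",
    "summarize_fits",
    "compare_procedures",
    "anova_blocks",
]

logger = logging.getLogger("critspeed")

_TS_WLS = FittingProcedure(ModelVariant.T_OF_S, Regression.WLS)
_DS_WLS = FittingProcedure(ModelVariant.D_OF_S, Regression.WLS)
_ST_LS = FittingProcedure(ModelVariant.S_OF_T, Regression.LS)
_DT_LS = FittingProcedure(ModelVariant.D_OF_T, Regression.LS)

#: The five standard pairings: appropriate vs appropriate, and each
#: appropriate procedure vs both inappropriate ones.
DEFAULT_COMPARISON_PAIRS: tuple[tuple[FittingProcedure, FittingProcedure], ...] = (
    (_TS_WLS, _DS_WLS),
    (_TS_WLS, _ST_LS),
    (_TS_WLS, _DT_LS),
    (_DS_WLS, _ST_LS),
    (_DS_WLS, _DT_LS),
)

_QUANTITY_COLUMNS = {"cs": "cs_mps", "d_prime": "dprime_m"}


def fit_cohort(
    subjects: list[SubjectTrials],
    procedures: tuple[FittingProcedure, ...] = STUDY_PROCEDURES,
    design: ExperimentDesign | None = None,
) -> pd.DataFrame:
    """Fit every procedure to every subject; one row per subject x procedure.

    ``design`` defaults to a fixed-speed experiment, which classifies
    each procedure's appropriateness on every output row.  Non-converged
    fits are logged and kept (flagged in the ``converged`` column).
    """
    if not subjects:
        raise ValueError("empty cohort")
    if design is None:
        design = ExperimentDesign(fixed_variable=Variable.SPEED)
    rows = []
    for subj in subjects:
        for proc in procedures:
            status = classify_procedure(proc, design)
            res = fitting.fit(subj, proc)
            if not res.converged:
                logger.warning(
                    "fit did not converge: subject=%s procedure=%s iterations=%d",
                    subj.subject_id,
                    proc.label,
                    res.n_iterations,
                )
            logger.debug(
                "fit subject=%s procedure=%s (%s) iterations=%d converged=%s",
                subj.subject_id,
                proc.label,
                status.value,
                res.n_iterations,
                res.converged,
            )
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "variant": proc.variant.value,
                    "regression": proc.regression.value,
                    "procedure": proc.label,
                    "appropriateness": status.value,
                    "cs_mps": res.params.cs,
                    "dprime_m": res.params.d_prime,
                    "see_cs": res.see_cs,
                    "see_dprime": res.see_dprime,
                    "pct_see": res.pct_see,
                    "rse": res.rse,
                    "converged": res.converged,
                }
            )
    return pd.DataFrame(rows)


def summarize_fits(estimates: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary per procedure: mean +/- SD of each fit quantity."""
    cols = ["cs_mps", "dprime_m", "see_cs", "see_dprime", "pct_see", "rse"]
    out = []
    for proc, grp in estimates.groupby("procedure", sort=False):
        row = {
            "procedure": proc,
            "appropriateness": grp["appropriateness"].iloc[0],
            "n_subjects": len(grp),
            "n_converged": int(grp["converged"].sum()),
        }
        for c in cols:
            row[f"{c}_mean"] = grp[c].mean()
            row[f"{c}_sd"] = grp[c].std(ddof=1)
        out.append(row)
    return pd.DataFrame(out)


def _pivot(estimates: pd.DataFrame, column: str) -> pd.DataFrame:
    wide = estimates.pivot(index="subject_id", columns="procedure", values=column)
    if wide.isna().any().any():
        raise ValueError("estimates table is not a complete subject x procedure design")
    return wide


def compare_procedures(
    estimates: pd.DataFrame,
    pairs: tuple[tuple[FittingProcedure, FittingProcedure], ...] = DEFAULT_COMPARISON_PAIRS,
    re_multiplier: float = 1.6,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bland--Altman agreement for each pair and quantity (CS and d').

    Returns the report table (one row per pair x quantity: bias, random
    error, proportional bias, gates, significance flags at ``alpha``)
    and a points table (per-subject mean/difference) for plotting.
    """
    report_rows, point_rows = [], []
    for proc_a, proc_b in pairs:
        for qty, col in _QUANTITY_COLUMNS.items():
            wide = _pivot(estimates, col)
            for p in (proc_a, proc_b):
                if p.label not in wide.columns:
                    raise ValueError(f"procedure {p.label!r} not present in estimates")
            pairs_obj = agreement.PairedEstimates(
                a=wide[proc_a.label].to_numpy(),
                b=wide[proc_b.label].to_numpy(),
                label_a=proc_a.label,
                label_b=proc_b.label,
                quantity=qty,
            )
            ba = agreement.bland_altman(pairs_obj, re_multiplier=re_multiplier)
            report_rows.append(
                {
                    "procedure_a": ba.label_a,
                    "procedure_b": ba.label_b,
                    "quantity": qty,
                    "systematic_bias": ba.systematic_bias,
                    "random_error": ba.random_error,
                    "p_systematic": ba.p_systematic,
                    "systematic_significant": bool(
                        np.isfinite(ba.p_systematic) and ba.p_systematic <= alpha
                    ),
                    "prop_slope": ba.prop_slope,
                    "prop_rse": ba.prop_rse,
                    "p_proportional": ba.p_proportional,
                    "proportional_significant": bool(
                        np.isfinite(ba.p_proportional) and ba.p_proportional <= alpha
                    ),
                    "durbin_watson": ba.durbin_watson,
                    "dw_pass": ba.dw_pass,
                    "shapiro_p": ba.shapiro_p,
                    "n": ba.n,
                }
            )
            for sid, mean_i, diff_i in zip(wide.index, ba.means, ba.differences):
                point_rows.append(
                    {
                        "procedure_a": ba.label_a,
                        "procedure_b": ba.label_b,
                        "quantity": qty,
                        "subject_id": sid,
                        "mean": mean_i,
                        "difference": diff_i,
                    }
                )
    return pd.DataFrame(report_rows), pd.DataFrame(point_rows)


def anova_blocks(
    estimates: pd.DataFrame,
    appropriate: tuple[FittingProcedure, ...] = (_TS_WLS, _DS_WLS),
    inappropriate: tuple[FittingProcedure, ...] = (_ST_LS, _DT_LS),
) -> pd.DataFrame:
    """RM-ANOVA of each appropriate procedure vs the inappropriate ones.

    One omnibus test per (appropriate procedure, quantity): a three-way
    within-subject comparison with Mauchly-gated Greenhouse--Geisser
    correction and Holm post hocs.  Returns one row per block with the
    post hoc p-values flattened into columns.
    """
    rows = []
    for proc in appropriate:
        conds = [proc] + list(inappropriate)
        for qty, col in _QUANTITY_COLUMNS.items():
            wide = _pivot(estimates, col)[[p.label for p in conds]]
            res = agreement.rm_anova_with_posthoc(wide)
            row = {
                "anchor": proc.label,
                "quantity": qty,
                "f_statistic": res.f_statistic,
                "df_num": res.df_num,
                "df_den": res.df_den,
                "p_omnibus": res.p_omnibus,
                "mauchly_w": res.mauchly_w,
                "mauchly_p": res.mauchly_p,
                "epsilon": res.epsilon,
                "sphericity_ok": res.sphericity_ok,
            }
            for ph in res.posthoc:
                row[f"p_holm[{ph.a} vs {ph.b}]"] = ph.p_holm
            rows.append(row)
    return pd.DataFrame(rows)
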