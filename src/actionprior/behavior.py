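"""Repeated-measures 2x2 ANOVA with generalized eta-squared, and
repeated-measures ANCOVA with a continuous between-subject covariate.

The within-subject decomposition tests each effect against its own
subject-by-effect interaction; generalized eta-squared follows the
fully-within convention (subject SS and all error SS in the denominator).
With 2x2 factors every effect has one numerator df, so no sphericity
correction is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EffectResult:
    F: float
    df: tuple
    p: float
    ges: float | None = None


def _cell_table(df: pd.DataFrame, value: str, factor_a: str, factor_b: str,
                subject: str) -> np.ndarray:
    """Pivot a long table into subjects x levelsA x levelsB; error on
    missing cells."""
    wide = df.pivot_table(index=subject, columns=[factor_a, factor_b],
                          values=value, aggfunc="mean")
    if wide.isna().any().any() or wide.shape[1] != 4:
        raise ValueError("every subject must have exactly one value in all 4 cells")
    a_levels = sorted({c[0] for c in wide.columns})
    b_levels = sorted({c[1] for c in wide.columns})
    cube = np.empty((wide.shape[0], 2, 2))
    for i, a in enumerate(a_levels):
        for j, b in enumerate(b_levels):
            cube[:, i, j] = wide[(a, b)].to_numpy()
    return cube


def rm_anova_2x2(df: pd.DataFrame, value: str, factor_a: str = "effort",
                 factor_b: str = "reward", subject: str = "participant_id") -> dict:
    """Two-way fully-within-subjects ANOVA on a complete 2x2 cell table.

    Returns a dict with EffectResult for ``factor_a``, ``factor_b`` and
    ``"interaction"``.  If an error SS is zero the F ratio is reported as 0
    with p = 1 and ges = 0 by convention.
    """
    cube = _cell_table(df, value, factor_a, factor_b, subject)
    n = cube.shape[0]
    grand = cube.mean()
    subj = cube.mean(axis=(1, 2))
    a_mean = cube.mean(axis=(0, 2))
    b_mean = cube.mean(axis=(0, 1))
    ab_mean = cube.mean(axis=0)
    sa_mean = cube.mean(axis=2)   # subject x A
    sb_mean = cube.mean(axis=1)   # subject x B

    ss_a = n * 2 * np.sum((a_mean - grand) ** 2)
    ss_b = n * 2 * np.sum((b_mean - grand) ** 2)
    ss_ab = n * np.sum((ab_mean - a_mean[:, None] - b_mean[None, :] + grand) ** 2)
    ss_subj = 4 * np.sum((subj - grand) ** 2)
    ss_as = 2 * np.sum((sa_mean - subj[:, None] - a_mean[None, :] + grand) ** 2)
    ss_bs = 2 * np.sum((sb_mean - subj[:, None] - b_mean[None, :] + grand) ** 2)
    ss_total = np.sum((cube - grand) ** 2)
    ss_abs = ss_total - (ss_a + ss_b + ss_ab + ss_subj + ss_as + ss_bs)
    ss_abs = max(ss_abs, 0.0)

    ss_error_all = ss_as + ss_bs + ss_abs
    dfe = n - 1

    def effect(ss_eff, ss_err):
        if ss_err <= 0:
            return EffectResult(F=0.0, df=(1, dfe), p=1.0,
                                ges=0.0 if ss_eff <= 0 else 1.0)
        F = (ss_eff / 1) / (ss_err / dfe)
        p = float(stats.f.sf(F, 1, dfe))
        denom = ss_eff + ss_subj + ss_error_all
        ges = float(ss_eff / denom) if denom > 0 else 0.0
        return EffectResult(F=float(F), df=(1, dfe), p=p, ges=ges)

    return {
        factor_a: effect(ss_a, ss_as),
        factor_b: effect(ss_b, ss_bs),
        "interaction": effect(ss_ab, ss_abs),
        "_ss": {"a": ss_a, "b": ss_b, "ab": ss_ab, "subject": ss_subj,
                "as": ss_as, "bs": ss_bs, "abs": ss_abs, "total": ss_total},
    }


def anova_table(results: dict) -> pd.DataFrame:
    rows = [{"effect": k, "F": v.F, "df1": v.df[0], "df2": v.df[1],
             "p": v.p, "ges": v.ges}
            for k, v in results.items() if isinstance(v, EffectResult)]
    return pd.DataFrame(rows)


def rm_ancova_covariate(df: pd.DataFrame, covariate: pd.Series, value: str,
                        factor_a: str = "effort", factor_b: str = "reward",
                        subject: str = "participant_id") -> dict:
    """Covariate x within-factor interaction tests via the within-subject
    contrast regression formulation.

    For each within-subject contrast (main effect of each factor and their
    interaction) the per-subject contrast score is regressed on the
    mean-centered covariate; the slope's F test (df 1, n-2) is the
    covariate-by-factor interaction test.  Invariant to shifting the
    covariate by a constant.
    """
    cube = _cell_table(df, value, factor_a, factor_b, subject)
    wide_index = df.pivot_table(index=subject, columns=[factor_a, factor_b],
                                values=value, aggfunc="mean").index
    cov = covariate.reindex(wide_index).to_numpy(dtype=float)
    if np.any(np.isnan(cov)):
        raise ValueError("covariate missing for some subjects")
    if np.std(cov) == 0:
        raise ValueError("covariate is constant")
    cov = cov - cov.mean()
    n = len(cov)

    contrasts = {
        factor_a: cube[:, 1, :].mean(axis=1) - cube[:, 0, :].mean(axis=1),
        factor_b: cube[:, :, 1].mean(axis=1) - cube[:, :, 0].mean(axis=1),
        "interaction": (cube[:, 1, 1] - cube[:, 1, 0]) - (cube[:, 0, 1] - cube[:, 0, 0]),
    }
    out = {}
    for name, c in contrasts.items():
        sxx = np.dot(cov, cov)
        beta = np.dot(cov, c - c.mean()) / sxx
        resid = c - c.mean() - beta * cov
        dfe = n - 2
        mse = np.dot(resid, resid) / dfe
        F = beta ** 2 * sxx / mse if mse > 0 else 0.0
        out[name] = EffectResult(F=float(F), df=(1, dfe),
                                 p=float(stats.f.sf(F, 1, dfe)))
    return out
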