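"""Cohort-level inference on zone scores.

Paired two-sided t-tests compare, within each case, the K17-negative and
K17-positive zone densities of one marker in one compartment; the companion
"fraction of cases" statistic reports how often the per-case K17-/K17+
ratio exceeds 1 among cases where it is defined.  Stratified analyses rerun
the same paired test within clinical subgroups (stage, grade, nodal status,
neoadjuvant treatment, mutation status, ...).

No multiple-testing correction is applied; every result carries an explicit
``multiplicity_adjusted=False`` flag so downstream users can add one.
Significance convention: two-sided p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: significance threshold used in reports (two-sided)
ALPHA = 0.05


@dataclass
class PairedTestResult:
    """Paired t-test of zs_neg vs zs_pos for one marker x compartment."""

    marker: str
    compartment: str
    n_cases: int
    mean_diff: float          # mean of (zs_neg - zs_pos)
    t_statistic: float
    df: int
    p_value: float
    fraction_neg_dominant: float   # #{ratio > 1} / #{ratio defined}
    n_ratio_defined: int
    n_excluded: int
    stratum: str | None = None
    skipped_reason: str | None = None
    multiplicity_adjusted: bool = False


def _paired_t(diffs: np.ndarray) -> tuple[float, int, float]:
    """Exact paired t statistic and two-sided p from the t distribution."""
    n = diffs.size
    df = n - 1
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(mean)) * np.inf, df, 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, p


def paired_test(scores: pd.DataFrame) -> PairedTestResult:
    """Two-sided paired t-test on per-case ``zs_neg - zs_pos`` differences.

    ``scores`` is a slice of the cohort table for a single marker and
    compartment, with columns ``zs_pos``, ``zs_neg`` and (optionally)
    ``ratio_neg_over_pos``.  Cases with an undefined density pair are
    excluded and counted; fewer than 3 usable cases is an error.
    """
    for col in ("zs_pos", "zs_neg"):
        if col not in scores.columns:
            raise ValueError(f"scores table lacks column {col!r}")
    for col in ("marker", "compartment"):
        if col in scores.columns and scores[col].nunique() > 1:
            raise ValueError(
                f"paired_test expects a single {col}, "
                f"got {sorted(scores[col].unique())}"
            )
    usable = scores[np.isfinite(scores["zs_pos"]) & np.isfinite(scores["zs_neg"])]
    n = len(usable)
    n_excluded = len(scores) - n
    if n < 3:
        raise ValueError(
            f"paired test needs >= 3 usable cases, got {n} "
            f"({n_excluded} excluded)"
        )
    diffs = (usable["zs_neg"] - usable["zs_pos"]).to_numpy(dtype=float)
    t, df, p = _paired_t(diffs)

    if "ratio_neg_over_pos" in scores.columns:
        ratios = scores["ratio_neg_over_pos"].to_numpy(dtype=float)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = scores["zs_neg"].to_numpy(float) / scores["zs_pos"].to_numpy(float)
    defined = np.isfinite(ratios)
    n_def = int(np.count_nonzero(defined))
    frac = float(np.count_nonzero(ratios[defined] > 1.0)) / n_def if n_def else np.nan

    marker = str(scores["marker"].iloc[0]) if "marker" in scores.columns else ""
    compartment = (str(scores["compartment"].iloc[0])
                   if "compartment" in scores.columns else "")
    return PairedTestResult(
        marker=marker, compartment=compartment, n_cases=n,
        mean_diff=float(np.mean(diffs)), t_statistic=t, df=df, p_value=p,
        fraction_neg_dominant=frac, n_ratio_defined=n_def,
        n_excluded=n_excluded,
    )


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    Two-sided p via the t-distribution approximation.  A constant input
    vector yields the undefined sentinel ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (np.nan, np.nan)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def cohort_tests(scores: pd.DataFrame) -> list[PairedTestResult]:
    """Paired tests for every marker x compartment present in the table."""
    out = []
    for (marker, compartment), grp in scores.groupby(
        ["marker", "compartment"], sort=True
    ):
        out.append(paired_test(grp))
    return out


def stratified_analysis(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    group_column: str,
) -> list[PairedTestResult]:
    """Paired tests per stratum of ``group_column`` (marker x compartment).

    Strata with fewer than 3 usable cases are reported as skipped records,
    never silently dropped.  Cases with missing stratum value form their own
    reported-but-skipped pseudo-stratum when present.
    """
    if group_column not in metadata.columns:
        raise KeyError(f"metadata has no column {group_column!r}")
    merged = scores.merge(
        metadata[["case_id", group_column]], on="case_id", how="left"
    )
    merged[group_column] = merged[group_column].astype(object).where(
        merged[group_column].notna(), "<missing>"
    )
    out: list[PairedTestResult] = []
    for stratum, sgrp in merged.groupby(group_column, sort=True):
        for (marker, compartment), grp in sgrp.groupby(
            ["marker", "compartment"], sort=True
        ):
            try:
                res = paired_test(grp)
                res.stratum = str(stratum)
                out.append(res)
            except ValueError as exc:
                out.append(PairedTestResult(
                    marker=str(marker), compartment=str(compartment),
                    n_cases=len(grp), mean_diff=np.nan,
                    t_statistic=np.nan, df=max(len(grp) - 1, 0),
                    p_value=np.nan, fraction_neg_dominant=np.nan,
                    n_ratio_defined=0, n_excluded=len(grp),
                    stratum=str(stratum), skipped_reason=str(exc),
                ))
    return out
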