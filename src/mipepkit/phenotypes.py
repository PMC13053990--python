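"""Quantification formulas for cell- and organism-level phenotype readouts.

These are the small, exactly specified computations applied to measurement
tables produced by imaging, flow cytometry, qPCR, luminometry and wing
micrographs:

* cell volumes normalized to the mean of a reference group;
* lysosomal stain density (integrated fluorescence density per unit volume);
* G1 fraction by subtraction of the other cell-cycle phase areas;
* wing epidermal cell density and mean cell area from cuticular hair counts
  (one hair per cell);
* relative qPCR expression by the 2^−ΔΔCt method;
* split-luciferase signals normalized to the per-replicate median of all
  conditions, and fold over a negative control;
* one-way ANOVA with Tukey HSD post-hoc, and two-group t-tests (Student or
  Welch).

Measurement tables are long-format pandas DataFrames with at least a group
column and a value column.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


def normalize_volumes(
    table: pd.DataFrame,
    reference_group: str,
    group_col: str = "group",
    value_col: str = "value",
) -> pd.DataFrame:
    """Divide every volume by the mean volume of the reference group.

    After normalization the reference group has mean exactly 1. Returns a copy
    with a ``normalized`` column.
    """
    ref = table.loc[table[group_col] == reference_group, value_col]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")
    if (table[value_col] <= 0).any():
        raise ValueError("volumes must be > 0")
    out = table.copy()
    out["normalized"] = out[value_col] / ref.mean()
    return out


def percent_size_difference(
    normalized: pd.DataFrame,
    reference_group: str,
    test_group: str,
    group_col: str = "group",
    statistic: str = "median",
) -> float:
    """Percent by which the test group is smaller than the reference
    (positive = smaller), on group medians by default or means."""
    agg = {"median": np.median, "mean": np.mean}[statistic]
    ref = agg(normalized.loc[normalized[group_col] == reference_group, "normalized"])
    test = agg(normalized.loc[normalized[group_col] == test_group, "normalized"])
    return 100.0 * (ref - test) / ref


def lysotracker_density(raw_integrated_density: float, volume: float) -> float:
    """Integrated fluorescence density per unit cell volume."""
    if volume <= 0:
        raise ValueError("volume must be > 0")
    return raw_integrated_density / volume


def g1_fraction(s: float, g2: float, m: float) -> float:
    """G1 phase area fraction (%) by subtracting the other phases from 100."""
    for name, v in (("s", s), ("g2", g2), ("m", m)):
        if v < 0:
            raise ValueError(f"{name} fraction must be >= 0")
    total_other = s + g2 + m
    if total_other > 100:
        raise ValueError(f"phase fractions sum to {total_other} > 100")
    return 100.0 - total_other


def wing_cell_metrics(hair_count: int, area_mm2: float = 0.01) -> tuple[float, float]:
    """(cell density per mm², mean cell area in mm²) from a cuticular hair
    count in a wing square, one hair per epidermal cell."""
    if hair_count < 1:
        raise ValueError("hair_count must be >= 1")
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be > 0")
    return hair_count / area_mm2, area_mm2 / hair_count


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by 2^−ΔΔCt.

    ΔΔCt = (Ct_target − Ct_reference) in the case sample minus the same
    difference in the control sample; the fold change is 2^−ΔΔCt.
    """
    for v in (ct_target_case, ct_ref_case, ct_target_control, ct_ref_control):
        if v <= 0:
            raise ValueError("Ct values must be positive")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


def normalize_luminescence(
    table: pd.DataFrame,
    replicate_col: str = "replicate",
    condition_col: str = "condition",
    value_col: str = "value",
) -> pd.DataFrame:
    """Normalize each condition's luminescence by the median of all conditions
    within the same replicate. Returns a copy with a ``normalized`` column."""
    out = table.copy()
    normalized = np.empty(len(out), dtype=float)
    for rep, idx in out.groupby(replicate_col).groups.items():
        med = out.loc[idx, value_col].median()
        if med == 0:
            raise ValueError(f"median luminescence of replicate {rep!r} is 0")
        normalized[out.index.get_indexer(idx)] = out.loc[idx, value_col] / med
    out["normalized"] = normalized
    return out


def fold_over_control(
    normalized: pd.DataFrame,
    candidate: str,
    control: str,
    condition_col: str = "condition",
) -> float:
    """Mean normalized signal of the candidate over the mean of the control."""
    cand = normalized.loc[normalized[condition_col] == candidate, "normalized"]
    ctrl = normalized.loc[normalized[condition_col] == control, "normalized"]
    if cand.empty or ctrl.empty:
        raise ValueError("candidate or control condition absent")
    return cand.mean() / ctrl.mean()


def group_comparison(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA with Tukey HSD post-hoc over ≥2 groups.

    Returns (F, p, pairwise table with Tukey-adjusted p-values). Identical
    groups (zero between-group variance with positive within-group variance)
    give F = 0, p = 1; degenerate inputs (any group with < 2 values, or zero
    variance everywhere) raise ``ValueError``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical; ANOVA undefined")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(arrays))]
    f_stat, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    group_ids = np.concatenate([[lab] * a.size for lab, a in zip(labels, arrays)])
    tukey = pairwise_tukeyhsd(values, group_ids)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return float(f_stat), float(p), pairwise


def two_group_t(
    x: Sequence[float],
    y: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test; Student (pooled variance) by default for
    wing-count comparisons, Welch when variances may differ."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
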