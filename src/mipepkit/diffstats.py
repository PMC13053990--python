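"""Welch-test + fold-change filters for two-condition proteome comparisons.

Two applications share the same rule: whole-proteome comparison of two
transfection conditions, and the interactome comparison of a motif-mutant
bait against the wild-type bait (restricted to proteins already called as
interactors). A protein is classed ``up``/``down`` only when its log2 fold
change is strictly greater than 1 / strictly less than −1 **and** the
two-sided Welch t-test p-value is below 0.05.

Conventions: the fold change is the log2 of the ratio of arithmetic means of
the observed intensities (condition B over A); the t-test is computed on the
log2-transformed observed intensities, where log-normal proteomics intensities
are closest to the test's normality assumption. Benjamini–Hochberg adjusted
p-values are emitted alongside but play no role in classing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .interactome import CallingResult, InteractorCall
from .io_formats import ProteinQuantTable

LOG2_FC_BOUND = 1.0
P_THRESHOLD = 0.05
MIN_VALID_PER_GROUP = 2


@dataclass
class DifferentialResult:
    """Per-protein differential record (condition B relative to A)."""

    protein_id: str
    log2_fc: float
    t_stat: float
    df: float
    p_value: float
    q_value: float
    n_valid: tuple[int, int]
    cls: str  # up | down | ns | not_tested
    degenerate: bool = False


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Unequal-variance t statistic, Welch–Satterthwaite df, two-sided p.

    Degenerate zero-variance cases follow a fixed convention: equal means give
    (t=0, p=1); unequal means with zero variance in both groups give p=0 with
    an infinite t.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        t = math.inf if x.mean() > y.mean() else -math.inf
        return t, float(x.size + y.size - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _classify(log2_fc: float, p: float) -> str:
    if p < P_THRESHOLD and log2_fc > LOG2_FC_BOUND:
        return "up"
    if p < P_THRESHOLD and log2_fc < -LOG2_FC_BOUND:
        return "down"
    return "ns"


def _test_rows(
    ids: Sequence[str],
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
) -> list[DifferentialResult]:
    results: list[DifferentialResult] = []
    for pid in ids:
        a = group_a.loc[pid].dropna().to_numpy(dtype=float)
        b = group_b.loc[pid].dropna().to_numpy(dtype=float)
        n_valid = (a.size, b.size)
        if a.size < MIN_VALID_PER_GROUP or b.size < MIN_VALID_PER_GROUP:
            results.append(
                DifferentialResult(pid, math.nan, math.nan, math.nan, math.nan, math.nan,
                                   n_valid, "not_tested")
            )
            continue
        log2_fc = math.log2(b.mean() / a.mean())
        t, df, p = welch_t(np.log2(b), np.log2(a))
        degenerate = not math.isfinite(t)
        results.append(
            DifferentialResult(pid, log2_fc, t, df, p, math.nan, n_valid,
                               _classify(log2_fc, p), degenerate)
        )
    tested = [r for r in results if r.cls != "not_tested"]
    if tested:
        q = multipletests([r.p_value for r in tested], method="fdr_bh")[1]
        for r, qv in zip(tested, q):
            r.q_value = float(qv)
    return results


def differential_proteome(table: ProteinQuantTable) -> list[DifferentialResult]:
    """Class every protein of a two-condition table as up/down/ns/not_tested.

    The two condition labels are ordered lexicographically (first = A,
    second = B, e.g. conditionA/conditionB); fold changes are B over A, so the
    orientation follows the labels, not the column layout. Proteins observed
    in fewer than two replicates of either condition are not tested.
    """
    conds = sorted(table.conditions())
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, found {conds}")
    cols_a = table.condition_columns(conds[0])
    cols_b = table.condition_columns(conds[1])
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    return _test_rows(table.protein_ids, table.intensities[cols_a], table.intensities[cols_b])


def differential_interactome(
    calls: CallingResult | Sequence[InteractorCall],
    wt_table: ProteinQuantTable,
    mut_table: ProteinQuantTable,
) -> list[DifferentialResult]:
    """Differential association of called interactors between a wild-type bait
    IP and a motif-mutant bait IP.

    Only proteins with ``is_interactor`` true are tested; fold changes are
    mutant over wild type, so an interaction lost on motif mutation appears as
    ``down``. Both tables contribute their bait sample columns (all columns
    when no bait-labelled column exists).
    """
    interactors = sorted({c.protein_id for c in calls if c.is_interactor})

    def bait_block(table: ProteinQuantTable) -> pd.DataFrame:
        cols = table.condition_columns("bait") or list(table.intensities.columns)
        return table.intensities[cols]

    wt = bait_block(wt_table)
    mut = bait_block(mut_table)
    missing = [pid for pid in interactors if pid not in mut.index or pid not in wt.index]
    if missing:
        raise ValueError(f"interactors absent from one of the tables: {missing[:5]}")
    return _test_rows(interactors, wt, mut)


def results_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    """Volcano-ready table: log2_fc, −log10 p, class and supporting columns."""
    rows = []
    for r in results:
        rows.append(
            {
                "protein_id": r.protein_id,
                "log2_fc": r.log2_fc,
                "t_stat": r.t_stat,
                "df": r.df,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "neg_log10_p": -math.log10(r.p_value) if r.p_value and r.p_value > 0 else math.inf
                if r.p_value == 0
                else math.nan,
                "n_valid_a": r.n_valid[0],
                "n_valid_b": r.n_valid[1],
                "class": r.cls,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")
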