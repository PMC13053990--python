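"""Worst-case-ratio interactor calling for bait vs. control AP-MS tables.

The procedure scores each prey protein by its most conservative enrichment
estimate — the minimum intensity across bait (tagged-microprotein IP)
replicates divided by the maximum intensity across control (tag-only IP)
replicates — and calls interactors with three rules:

1. **IQR fence on log2 ratios.** The calling threshold is
   ``Q3 + k·(Q3 − Q1)`` (default k = 1.5) computed over the log2 worst-case
   ratios of every protein quantified on both sides; a protein passes when its
   log2 ratio reaches the fence. The fence is a property of each dataset's
   ratio distribution, not a constant of the method.
2. **Spectral-count ratio.** The mean bait spectral count over the mean
   control spectral count must reach ``sc_min_ratio`` (default 2). A zero
   control mean with nonzero bait counts yields +inf (passes); a zero bait
   mean yields 0 (fails).
3. **Bait-only rescue (Q1 rule).** A protein never observed in controls but
   observed in the bait IPs has no defined ratio; it is called when at least
   one observed bait intensity exceeds Q1 of the pooled distribution of all
   observed intensities in the experiment (and rule 2 holds).

Proteins with no observed bait intensity are never evaluable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .io_formats import ProteinQuantTable


class Route(str, Enum):
    RATIO_BASED = "ratio_based"
    BAIT_ONLY = "bait_only"
    NOT_EVALUABLE = "not_evaluable"


class QuartileConvention(str, Enum):
    """How Q1/Q3 are computed: linear interpolation of order statistics
    (mainstream numeric-library default) or Tukey hinges (median-of-halves)."""

    LINEAR = "linear"
    TUKEY = "tukey"


class ThresholdComparison(str, Enum):
    GE = "ge"
    GT = "gt"


@dataclass
class CallingParameters:
    """Tunable parameters of the interactor-calling rules."""

    fence_multiplier: float = 1.5
    sc_min_ratio: float = 2.0
    quartile_convention: QuartileConvention = QuartileConvention.LINEAR
    threshold_comparison: ThresholdComparison = ThresholdComparison.GE

    def __post_init__(self) -> None:
        if self.fence_multiplier < 0:
            raise ValueError("fence_multiplier must be >= 0")
        if self.sc_min_ratio <= 0:
            raise ValueError("sc_min_ratio must be > 0")
        self.quartile_convention = QuartileConvention(self.quartile_convention)
        self.threshold_comparison = ThresholdComparison(self.threshold_comparison)


@dataclass
class InteractorCall:
    """Per-protein calling record with every intermediate statistic."""

    protein_id: str
    worst_case_ratio: float | None
    log2_ratio: float | None
    route: Route
    passes_ratio_threshold: bool
    passes_sc_ratio: bool
    passes_q1_rule: bool | None  # None = not applicable (ratio-based route)
    is_interactor: bool


def _observed(values: Sequence[float | None]) -> list[float]:
    out = []
    for v in values:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if v < 0:
            raise ValueError(f"negative intensity {v}")
        out.append(float(v))
    return out


def worst_case_ratio(
    bait_intensities: Sequence[float | None],
    control_intensities: Sequence[float | None],
) -> float | None:
    """min(observed bait) / max(observed control).

    Returns ``None`` when either side has no observed value: no control means
    the protein is a bait-only candidate; no bait means it cannot be evaluated.
    """
    bait = _observed(bait_intensities)
    ctrl = _observed(control_intensities)
    if not bait or not ctrl:
        return None
    return min(bait) / max(ctrl)


def quartiles(values: Sequence[float], convention: QuartileConvention) -> tuple[float, float]:
    """(Q1, Q3) under the chosen convention."""
    arr = np.sort(np.asarray(values, dtype=float))
    if convention is QuartileConvention.LINEAR:
        q1, q3 = np.quantile(arr, [0.25, 0.75])
        return float(q1), float(q3)
    # Tukey hinges: medians of the lower and upper halves (median included
    # in both halves when n is odd).
    n = arr.size
    half = (n + 1) // 2
    return float(np.median(arr[:half])), float(np.median(arr[n - half :]))


def ratio_fence_threshold(
    log2_ratios: Sequence[float],
    fence_multiplier: float = 1.5,
    convention: QuartileConvention = QuartileConvention.LINEAR,
) -> float:
    """Upper outlier fence ``Q3 + fence_multiplier * (Q3 - Q1)`` of the log2
    ratio distribution. Requires at least 4 defined ratios."""
    vals = [v for v in log2_ratios if not math.isnan(v)]
    if len(vals) < 4:
        raise ValueError(f"need >= 4 defined log2 ratios to place the fence, got {len(vals)}")
    q1, q3 = quartiles(vals, QuartileConvention(convention))
    return q3 + fence_multiplier * (q3 - q1)


def spectral_count_ratio(
    bait_sc: Sequence[int],
    control_sc: Sequence[int],
) -> float:
    """mean(bait counts) / mean(control counts); +inf when the control mean is
    zero and the bait mean positive; 0 when the bait mean is zero."""
    if len(bait_sc) == 0 or len(control_sc) == 0:
        raise ValueError("spectral-count lists must be nonempty")
    if any(c < 0 for c in bait_sc) or any(c < 0 for c in control_sc):
        raise ValueError("spectral counts must be non-negative")
    bait_mean = sum(bait_sc) / len(bait_sc)
    ctrl_mean = sum(control_sc) / len(control_sc)
    if bait_mean == 0:
        return 0.0
    if ctrl_mean == 0:
        return math.inf
    return bait_mean / ctrl_mean


def q1_presence_rule(
    bait_intensities: Sequence[float | None],
    all_observed_intensities: Sequence[float],
    convention: QuartileConvention = QuartileConvention.LINEAR,
) -> bool:
    """True iff at least one observed bait intensity exceeds Q1 of the pooled
    distribution of every observed intensity cell in the experiment."""
    if len(all_observed_intensities) == 0:
        raise ValueError("pooled intensity distribution is empty")
    q1, _ = quartiles(list(all_observed_intensities), QuartileConvention(convention))
    return any(v > q1 for v in _observed(bait_intensities))


@dataclass
class CallingResult(Sequence):
    """Sequence of :class:`InteractorCall` plus run-level statistics."""

    calls: list[InteractorCall]
    log2_ratio_threshold: float
    pooled_q1_intensity: float
    route_counts: dict[str, int]

    def __len__(self) -> int:
        return len(self.calls)

    def __getitem__(self, i):
        return self.calls[i]

    def __iter__(self) -> Iterator[InteractorCall]:
        return iter(self.calls)

    def interactor_ids(self) -> set[str]:
        return {c.protein_id for c in self.calls if c.is_interactor}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": c.protein_id,
                "worst_case_ratio": c.worst_case_ratio,
                "log2_ratio": c.log2_ratio,
                "route": c.route.value,
                "passes_ratio_threshold": c.passes_ratio_threshold,
                "passes_sc_ratio": c.passes_sc_ratio,
                "passes_q1_rule": c.passes_q1_rule,
                "is_interactor": c.is_interactor,
            }
            for c in self.calls
        ]
        return pd.DataFrame(rows).set_index("protein_id")


def call_interactors(
    table: ProteinQuantTable,
    params: CallingParameters | None = None,
) -> CallingResult:
    """Apply the full calling procedure to a bait/control table.

    The fence is computed once from the log2 worst-case ratios of every
    protein quantified on both sides; the pooled Q1 is computed once over all
    observed intensity cells. Output is sorted by descending log2 ratio
    (bait-only calls first, non-evaluable last), ties broken by protein id.
    """
    params = params or CallingParameters()
    bait_cols = table.condition_columns("bait")
    ctrl_cols = table.condition_columns("control")
    if not bait_cols or not ctrl_cols:
        raise ValueError("table must contain both bait and control samples")
    if table.spectral_counts is None:
        raise ValueError("spectral counts are required for interactor calling")

    pooled = table.intensities[bait_cols + ctrl_cols].to_numpy().ravel()
    pooled = pooled[~np.isnan(pooled)]

    bait_mat = table.intensities[bait_cols].to_numpy(dtype=float)
    ctrl_mat = table.intensities[ctrl_cols].to_numpy(dtype=float)
    bait_sc_mat = table.spectral_counts[bait_cols].to_numpy()
    ctrl_sc_mat = table.spectral_counts[ctrl_cols].to_numpy()

    ratios: list[float | None] = [
        worst_case_ratio(bait_mat[i].tolist(), ctrl_mat[i].tolist())
        for i in range(len(table.protein_ids))
    ]

    defined_log2 = [math.log2(r) for r in ratios if r is not None]
    threshold = ratio_fence_threshold(
        defined_log2, params.fence_multiplier, params.quartile_convention
    )
    q1_pooled, _ = quartiles(pooled.tolist(), params.quartile_convention)

    calls: list[InteractorCall] = []
    route_counts = {r.value: 0 for r in Route}
    for i, pid in enumerate(table.protein_ids):
        bait = bait_mat[i].tolist()
        bait_sc = bait_sc_mat[i].tolist()
        ctrl_sc = ctrl_sc_mat[i].tolist()
        n_bait_obs = len(_observed(bait))
        n_ctrl_obs = int((~np.isnan(ctrl_mat[i])).sum())

        wcr = ratios[i]
        sc_ratio = spectral_count_ratio(bait_sc, ctrl_sc)
        passes_sc = sc_ratio >= params.sc_min_ratio

        if n_bait_obs == 0:
            route = Route.NOT_EVALUABLE
            log2_ratio = None
            passes_ratio = False
            passes_q1: bool | None = None
            called = False
        elif n_ctrl_obs == 0:
            route = Route.BAIT_ONLY
            log2_ratio = None
            passes_ratio = False
            passes_q1 = any(v > q1_pooled for v in _observed(bait))
            called = passes_q1 and passes_sc
        else:
            route = Route.RATIO_BASED
            log2_ratio = math.log2(wcr)
            if params.threshold_comparison is ThresholdComparison.GE:
                passes_ratio = log2_ratio >= threshold
            else:
                passes_ratio = log2_ratio > threshold
            passes_q1 = None
            called = passes_ratio and passes_sc

        route_counts[route.value] += 1
        calls.append(
            InteractorCall(
                protein_id=pid,
                worst_case_ratio=wcr,
                log2_ratio=log2_ratio,
                route=route,
                passes_ratio_threshold=passes_ratio,
                passes_sc_ratio=passes_sc,
                passes_q1_rule=passes_q1,
                is_interactor=called,
            )
        )

    def sort_key(c: InteractorCall) -> tuple[float, str]:
        if c.route is Route.BAIT_ONLY:
            lr = math.inf
        elif c.route is Route.NOT_EVALUABLE:
            lr = -math.inf
        else:
            lr = c.log2_ratio  # type: ignore[assignment]
        return (-lr, c.protein_id)

    calls.sort(key=sort_key)
    return CallingResult(
        calls=calls,
        log2_ratio_threshold=threshold,
        pooled_q1_intensity=float(q1_pooled),
        route_counts=route_counts,
    )
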