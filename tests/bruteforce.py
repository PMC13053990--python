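"""Independent brute-force reimplementation of the interactor-calling rules.

Pure Python, no numpy/pandas and no imports from the package's calling module
beyond the table container. Used as the oracle in equivalence tests; it must
stay an independent re-derivation of the rules, not a refactor of the
implementation.
"""

from __future__ import annotations

import math


def bf_quantile_linear(sorted_vals: list[float], q: float) -> float:
    """Linear-interpolation quantile on a pre-sorted list."""
    n = len(sorted_vals)
    h = (n - 1) * q
    lo = math.floor(h)
    if lo + 1 >= n:
        return sorted_vals[-1]
    return sorted_vals[lo] + (h - lo) * (sorted_vals[lo + 1] - sorted_vals[lo])


def bf_call(
    ids: list[str],
    bait: dict[str, list[float | None]],
    ctrl: dict[str, list[float | None]],
    bait_sc: dict[str, list[int]],
    ctrl_sc: dict[str, list[int]],
    fence_multiplier: float = 1.5,
    sc_min_ratio: float = 2.0,
) -> tuple[set[str], float]:
    """Return (called interactor ids, log2 fence) by direct rule application.

    Missing intensities are None. Linear-interpolation quartiles; inclusive
    (>=) fence comparison; bait-only rescue via strict > pooled Q1.
    """

    def obs(vals):
        return [v for v in vals if v is not None]

    # fence over log2 worst-case ratios of proteins observed on both sides
    log2_ratios = []
    for pid in ids:
        b, c = obs(bait[pid]), obs(ctrl[pid])
        if b and c:
            log2_ratios.append(math.log2(min(b) / max(c)))
    if len(log2_ratios) < 4:
        raise ValueError("need >= 4 defined ratios")
    sr = sorted(log2_ratios)
    q1, q3 = bf_quantile_linear(sr, 0.25), bf_quantile_linear(sr, 0.75)
    fence = q3 + fence_multiplier * (q3 - q1)

    # pooled Q1 over every observed intensity cell
    pooled = sorted(
        v for pid in ids for v in obs(bait[pid]) + obs(ctrl[pid])
    )
    pooled_q1 = bf_quantile_linear(pooled, 0.25)

    called = set()
    for pid in ids:
        b, c = obs(bait[pid]), obs(ctrl[pid])
        mb = sum(bait_sc[pid]) / len(bait_sc[pid])
        mc = sum(ctrl_sc[pid]) / len(ctrl_sc[pid])
        if mb == 0:
            sc_ok = False
        elif mc == 0:
            sc_ok = True
        else:
            sc_ok = mb / mc >= sc_min_ratio
        if not b:
            continue
        if not c:
            if sc_ok and any(v > pooled_q1 for v in b):
                called.add(pid)
            continue
        if sc_ok and math.log2(min(b) / max(c)) >= fence:
            called.add(pid)
    return called, fence
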