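"""Independent oracles used across the test suite.

These are deliberately naive implementations (explicit loops, hand
tabulation) kept separate from the package's own code paths.
"""

from __future__ import annotations

import numpy as np


def sort_average_ranks(values) -> np.ndarray:
    """Brute-force ascending ranks with tie averaging via sort positions."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=float)
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pairwise_enumeration_score(values, panel_mask) -> float:
    """Explicit U-statistic: 1 per win, 0.5 per tie, over all pairs."""
    values = np.asarray(values, dtype=float)
    panel_mask = np.asarray(panel_mask, dtype=bool)
    panel = values[panel_mask]
    background = values[~panel_mask]
    u = 0.0
    for p in panel:
        for b in background:
            if p > b:
                u += 1.0
            elif p == b:
                u += 0.5
    return u / (panel.size * background.size)


def manual_product_limit(times, events) -> dict[float, float]:
    """Hand Kaplan-Meier: product over event times of (1 - d/n), censored
    subjects at tied times counted at risk (events first)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    surv = {}
    s = 1.0
    for t in sorted(set(times[events])):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / at_risk
        surv[t] = s
    return surv


def manual_logrank_statistic(times_a, events_a, times_b, events_b) -> float:
    """Observed-minus-expected log-rank chi-square over the pooled risk table."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(all_t[all_e])):
        n = int((all_t >= t).sum())
        n_a = int((ta >= t).sum())
        d = int(((all_t == t) & all_e).sum())
        d_a = int(((ta == t) & ea).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def hscore_binning_loop(cell_values, thresholds) -> float:
    """Per-cell binning loop: <=t1 -> 0, (t1,t2] -> 1, (t2,t3] -> 2, >t3 -> 3."""
    t1, t2, t3 = thresholds
    counts = [0, 0, 0, 0]
    for v in cell_values:
        if v <= t1:
            counts[0] += 1
        elif v <= t2:
            counts[1] += 1
        elif v <= t3:
            counts[2] += 1
        else:
            counts[3] += 1
    n = len(cell_values)
    return sum(i * 100.0 * c / n for i, c in enumerate(counts))


def iou(a, b) -> float:
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0
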