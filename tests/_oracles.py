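"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (grids, pair enumeration, hand
formulas) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np


def min_rect_bruteforce(points: np.ndarray, step_deg: float = 0.01):
    """Minimum-area enclosing rectangle by a dense rotation sweep.

    Returns (area, side_a, side_b) with side_a >= side_b.
    """
    pts = np.asarray(points, dtype=float)
    thetas = np.radians(np.arange(0.0, 90.0, step_deg))
    c, s = np.cos(thetas), np.sin(thetas)
    u = pts @ np.vstack([c, s])          # (n, n_angles)
    v = pts @ np.vstack([-s, c])
    w = u.max(axis=0) - u.min(axis=0)
    h = v.max(axis=0) - v.min(axis=0)
    areas = w * h
    i = int(np.argmin(areas))
    sa, sb = max(w[i], h[i]), min(w[i], h[i])
    return float(areas[i]), float(sa), float(sb)


def concordance_bruteforce(risk, times, events) -> float:
    """Harrell's C by explicit enumeration of all ordered pairs."""
    r = np.asarray(risk, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    num = den = 0.0
    for i in range(len(t)):
        for j in range(len(t)):
            if i == j:
                continue
            if t[i] < t[j] and e[i] == 1:  # i dies first, pair usable
                den += 1
                if r[i] > r[j]:
                    num += 1
                elif r[i] == r[j]:
                    num += 0.5
    if den == 0:
        raise ZeroDivisionError("no usable pairs")
    return num / den


def auc_mannwhitney(y, score) -> float:
    """AUC via the Mann-Whitney pair count."""
    y = np.asarray(y, int)
    s = np.asarray(score, float)
    cases, ctrls = s[y == 1], s[y == 0]
    num = 0.0
    for a in cases:
        for b in ctrls:
            num += 1.0 if a > b else (0.5 if a == b else 0.0)
    return num / (len(cases) * len(ctrls))


def km_by_hand(times, events):
    """Product-limit estimate computed step by step.

    Returns (event_times, survival) at the distinct event times only.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    out_t, out_s = [], []
    s = 1.0
    for u in sorted(set(t[e == 1])):
        n_at_risk = (t >= u).sum()
        d = ((t == u) & (e == 1)).sum()
        s *= 1.0 - d / n_at_risk
        out_t.append(u)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_two_group(times, events, group) -> float:
    """Two-group log-rank chi-square via observed-minus-expected sums."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(group, int)
    O_minus_E = 0.0
    V = 0.0
    for u in sorted(set(t[e == 1])):
        at_risk = t >= u
        n = at_risk.sum()
        n1 = (at_risk & (g == 1)).sum()
        d = ((t == u) & (e == 1)).sum()
        d1 = ((t == u) & (e == 1) & (g == 1)).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(O_minus_E**2 / V)


def cox_score_statistic(times, events, x) -> float:
    """Cox partial-likelihood score test statistic at beta = 0.

    For a single covariate with no tied event times this equals the
    two-group log-rank chi-square (classical identity).
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    x = np.asarray(x, float)
    U = 0.0
    info = 0.0
    for i in np.flatnonzero(e == 1):
        at_risk = t >= t[i]
        xr = x[at_risk]
        U += x[i] - xr.mean()
        info += xr.var()
    return float(U**2 / info)
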