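"""Independent oracles used by the tests.

Everything here recomputes quantities by brute force or direct formula,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity_direct(W: np.ndarray, blocks) -> float:
    """Newman-Girvan modularity of a node partition, direct double sum."""
    two_m = W.sum()
    deg = W.sum(axis=1)
    q = 0.0
    for block in blocks:
        idx = np.array(block)
        q += W[np.ix_(idx, idx)].sum() / two_m - (deg[idx].sum() / two_m) ** 2
    return q


def exhaustive_best_modularity(W: np.ndarray) -> float:
    """Optimal modularity over every partition of the nodes (n <= 8)."""
    n = W.shape[0]
    return max(modularity_direct(W, p) for p in set_partitions(list(range(n))))


def daily_dose_oracle(records, subject):
    """Day-by-day supply-consumption reconstruction of the dose series.

    For each day and drug class the active dispense is the latest dispense on
    or before that day whose supply has not run out and that has not been
    superseded by a newer dispense of the same class; stimulant doses sum
    across classes.
    """
    from stimtraj.io import STIMULANT_CLASSES

    n_days = (subject.followup_date - subject.birth_date).days + 1
    dose = np.zeros(n_days)
    by_class = {}
    for r in sorted(records, key=lambda r: r.dispense_date):
        by_class.setdefault(r.drug_class, []).append(r)
    for cls, recs in by_class.items():
        for i, r in enumerate(recs):
            start = (r.dispense_date - subject.birth_date).days
            supply = max(1, int(round(r.units_dispensed / r.daily_units)))
            end = start + supply
            if i + 1 < len(recs):
                nxt = (recs[i + 1].dispense_date - subject.birth_date).days
                end = min(end, nxt)
            end = min(end, n_days)
            if cls in STIMULANT_CLASSES:
                dose[start:end] += r.unit_strength * r.daily_units
    return dose


def cox_loglik_direct(beta: float, times, events, x) -> float:
    """Explicit Breslow partial log-likelihood for one binary covariate."""
    ll = 0.0
    times = np.asarray(times, float)
    x = np.asarray(x, float)
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_grid_oracle(times, events, x, lo=-5.0, hi=5.0, step=1e-4) -> float:
    """Grid-search maximizer of the explicit partial likelihood."""
    grid = np.arange(lo, hi + step, step)
    lls = [cox_loglik_direct(b, times, events, x) for b in grid]
    return float(grid[int(np.argmax(lls))])
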