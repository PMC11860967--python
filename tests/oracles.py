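"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's own algorithms: the burst oracle works
on boolean ISI masks and run-length segments with a literal fixed-point merge
loop, and the synchrony oracle evaluates the instantaneous dissimilarity
profile on a dense time grid instead of integrating it piecewise.
"""

from __future__ import annotations

import numpy as np


def brute_force_bursts(times, params):
    """Exhaustive max-interval burst search over index windows.

    Returns a list of ``(first_index, last_index)`` spike-index pairs after
    applying the start/extend, merge and size/duration rules.
    """
    t = np.asarray(times, dtype=float)
    n = t.size
    if n < 2:
        return []
    eps = 1e-9  # same boundary convention as the detector; the search differs
    isi = np.diff(t)
    can_begin = isi <= params.max_begin_isi + eps
    can_extend = isi <= params.max_end_isi + eps

    # maximal runs of extendable ISIs; a candidate occupies the tail of a run
    # from its first begin-capable ISI onward
    candidates = []
    k = 0
    while k < n - 1:
        if not can_extend[k]:
            k += 1
            continue
        run_end = k
        while run_end < n - 1 and can_extend[run_end]:
            run_end += 1
        begin_idxs = [i for i in range(k, run_end) if can_begin[i]]
        if begin_idxs:
            candidates.append((begin_idxs[0], run_end))
        k = run_end + 1

    # literal fixed-point merging on the (first, last) windows
    changed = True
    while changed:
        changed = False
        for a in range(len(candidates) - 1):
            (f1, l1), (f2, l2) = candidates[a], candidates[a + 1]
            if t[f2] - t[l1] < params.min_ibi - eps:
                candidates[a : a + 2] = [(f1, l2)]
                changed = True
                break

    return [
        (f, l)
        for f, l in candidates
        if (t[l] - t[f]) >= params.min_duration - eps and (l - f + 1) >= params.min_spikes
    ]


def grid_spike_distance(ta, tb, t0, t1, dt=1e-4):
    """Dense-grid numeric integration of the SPIKE-distance profile.

    Evaluates the instantaneous dissimilarity S(t) at midpoints of a regular
    grid of step ``dt`` and averages — the sampling-based counterpart of the
    package's exact piecewise integration.
    """
    def augment(t):
        t = list(np.asarray(t, dtype=float))
        if not t or t[0] > t0:
            t = [t0] + t
        if t[-1] < t1:
            t = t + [t1]
        return np.asarray(t)

    aug_a, aug_b = augment(ta), augment(tb)
    ts = np.arange(t0 + dt / 2, t1, dt)

    def train_terms(self_t, other_t):
        ip = np.searchsorted(self_t, ts, side="right") - 1
        tP = self_t[ip]
        tF = self_t[np.minimum(ip + 1, self_t.size - 1)]
        xisi = tF - tP

        def nearest(x):
            idx = np.searchsorted(other_t, x)
            left = other_t[np.clip(idx - 1, 0, other_t.size - 1)]
            right = other_t[np.clip(idx, 0, other_t.size - 1)]
            return np.minimum(np.abs(x - left), np.abs(right - x))

        s = (nearest(tP) * (tF - ts) + nearest(tF) * (ts - tP)) / xisi
        return xisi, s

    x1, s1 = train_terms(aug_a, aug_b)
    x2, s2 = train_terms(aug_b, aug_a)
    s = (s1 * x2 + s2 * x1) / (2 * ((x1 + x2) / 2) ** 2)
    return float(s.mean())


def random_mixed_train(rng, max_spikes=50):
    """Random spike train mixing regimes that exercise all burst rules."""
    pieces = []
    t = 0.0
    n_target = rng.integers(0, max_spikes + 1)
    while sum(p.size for p in pieces) < n_target:
        kind = rng.integers(0, 3)
        if kind == 0:  # tight cluster
            k = rng.integers(2, 9)
            isi = rng.uniform(0.005, 0.25, size=k - 1)
            pieces.append(t + np.concatenate([[0], np.cumsum(isi)]))
            t = pieces[-1][-1]
        elif kind == 1:  # lone spike
            pieces.append(np.array([t]))
        else:  # boundary-value ISIs around the detector thresholds
            k = rng.integers(2, 6)
            isi = rng.choice([0.05, 0.1, 0.15, 0.2, 0.25, 0.5], size=k - 1)
            pieces.append(t + np.concatenate([[0], np.cumsum(isi)]))
            t = pieces[-1][-1]
        t += rng.uniform(0.05, 2.0)
    times = np.unique(np.concatenate(pieces)) if pieces else np.empty(0)
    return times[:max_spikes]
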