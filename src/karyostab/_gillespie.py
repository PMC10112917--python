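"""Numba kernel for the exact two-class birth/conversion process.

State is (n_xx, n_xo); events are XX division, XX→XO conversion and XO
division, each with a rate linear in the class count, so classic Gillespie
applies: exponential waiting time at the total rate, then a categorical draw.
Record times and passage bottlenecks are deterministic checkpoints; the
memorylessness of the exponential clock lets us discard the pending event
when a checkpoint comes first.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _kernel(n_xx0, n_xo0, rate_xx, rate_xo, conv, record_times,
            passage_interval, passage_survival, guard, seed):
    np.random.seed(seed)
    n_xx = n_xx0
    n_xo = n_xo0
    m = record_times.shape[0]
    out_xx = np.zeros(m, np.int64)
    out_xo = np.zeros(m, np.int64)
    t = 0.0
    i = 0
    next_pass = passage_interval if passage_interval > 0 else np.inf
    while i < m:
        total = n_xx * (rate_xx + conv) + n_xo * rate_xo
        if total > 0.0:
            t_event = t + np.random.exponential(1.0 / total)
        else:
            t_event = np.inf
        t_next = min(record_times[i], next_pass)
        if t_event >= t_next:
            t = t_next
            if record_times[i] <= next_pass:
                # record before any coinciding passage (pre-bottleneck state)
                out_xx[i] = n_xx
                out_xo[i] = n_xo
                i += 1
            else:
                n_xx = np.random.binomial(n_xx, passage_survival)
                n_xo = np.random.binomial(n_xo, passage_survival)
                next_pass += passage_interval
            continue
        t = t_event
        u = np.random.random() * total
        if u < n_xx * rate_xx:
            n_xx += 1
        elif u < n_xx * (rate_xx + conv):
            n_xx -= 1
            n_xo += 1
        else:
            n_xo += 1
        if n_xx + n_xo > guard:
            return out_xx, out_xo, 1
    return out_xx, out_xo, 0


def run_birth_conversion(n_xx0, n_xo0, rate_xx, rate_xo, conv, record_times,
                         passage_interval, passage_survival, guard, seed):
    """Run the jitted kernel; returns (counts_xx, counts_xo, status)."""
    return _kernel(
        np.int64(n_xx0), np.int64(n_xo0), float(rate_xx), float(rate_xo),
        float(conv), np.ascontiguousarray(record_times, dtype=np.float64),
        float(passage_interval), float(passage_survival), np.int64(guard),
        np.int64(seed),
    )
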