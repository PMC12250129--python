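"""Independent brute-force oracles shared by the test modules."""

import itertools


def brute_force_logrank(a, b):
    """Two-group log-rank statistic with the hypergeometric moments at each
    event time computed by exhaustive enumeration of which at-risk subjects
    die — feasible only for a handful of subjects, and entirely independent
    of the closed-form implementation it checks."""
    records = [(r.time_days, r.event, 0) for r in a] + [
        (r.time_days, r.event, 1) for r in b
    ]
    event_times = sorted({t for t, e, _ in records if e})
    u = 0.0
    v = 0.0
    for t in event_times:
        at_risk = [g for tt, _, g in records if tt >= t]
        d = sum(1 for tt, e, _ in records if tt == t and e)
        d_a = sum(1 for tt, e, g in records if tt == t and e and g == 0)
        n = len(at_risk)
        picks = list(itertools.combinations(range(n), d))
        counts = [sum(1 for i in pick if at_risk[i] == 0) for pick in picks]
        e_da = sum(counts) / len(picks)
        var_da = sum((c - e_da) ** 2 for c in counts) / len(picks)
        u += d_a - e_da
        v += var_da
    if v == 0:
        return 0.0
    return u * u / v
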