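"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive each rule by direct enumeration or a month-by-
month walk, sharing no code with the package.
"""

import numpy as np

TWO_TIER_WINDOW = 24


def censor_month_walk(screenings, baseline, cadence_months, bandwidth,
                      grace=None, horizon=2000):
    """Month-by-month application of the two protocol-deviation rules."""
    K, b = cadence_months, bandwidth
    if grace is None:
        grace = K + b
    scr = sorted(set(int(s) for s in screenings))
    prior = [s for s in scr if s <= baseline]
    last = prior[-1] if prior else baseline
    have_prev = bool(prior)
    future = set(s for s in scr if s > baseline)
    m = baseline
    while m < baseline + horizon:
        m += 1
        allowed = (K + b) if have_prev else grace
        if m - last > allowed:
            return m                      # rule (a): observed too long unscreened
        if m in future:
            if have_prev and m - last < K - b:
                return m                  # rule (b): screened again too soon
            last, have_prev = m, True
    raise AssertionError("horizon too short for month walk")


def diagnose_scan(claims, rule="two_tier"):
    """Exhaustive singleton/pair scan; claims = list of (month, setting)."""
    months = sorted(m for m, _ in claims)
    if not months:
        return None
    if rule == "single":
        return months[0]
    candidates = [m for m, s in claims if s == "IP"]
    op = sorted(m for m, s in claims if s == "OP")
    for i in range(len(op)):
        for j in range(i + 1, len(op)):
            if op[j] - op[i] <= TWO_TIER_WINDOW:
                candidates.append(op[i])
    return min(candidates) if candidates else None


def screening_scan(months, washout):
    """Direct restatement of the washout rule for screening classification."""
    out, last = [], None
    for m in sorted(set(months)):
        if last is None or m - last > washout:
            out.append(m)
        last = m
    return out


def aalen_johansen_by_hand(entry_bin, exit_bin, code, weights=None, n_bins=60):
    """Tiny direct competing-risks estimator with delayed entry.

    code: 1 = event of interest, 3 = competing event, anything else = censored
    at the exit bin (still in that bin's risk set).
    """
    entry_bin = np.asarray(entry_bin)
    exit_bin = np.asarray(exit_bin)
    code = np.asarray(code)
    w = np.ones(len(code)) if weights is None else np.asarray(weights, float)
    surv = 1.0
    cif1 = np.zeros(n_bins)
    cif3 = np.zeros(n_bins)
    survs = np.zeros(n_bins)
    c1 = c3 = 0.0
    for t in range(n_bins):
        at = (entry_bin <= t) & (t <= exit_bin)
        denom = w[at].sum()
        if denom > 0:
            h1 = w[at & (exit_bin == t) & (code == 1)].sum() / denom
            h3 = w[at & (exit_bin == t) & (code == 3)].sum() / denom
        else:
            h1 = h3 = 0.0
        c1 += surv * h1
        c3 += surv * h3
        surv *= (1 - h1 - h3)
        cif1[t], cif3[t], survs[t] = c1, c3, surv
    return cif1, cif3, survs
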