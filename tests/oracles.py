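"""Independent oracles for the test suite.

Everything here is written from scratch, term by term, without importing
the package's scoring internals, so tests compare two independent paths:
the vectorised implementation vs these literal transcriptions and brute
-force enumerations.
"""

import math

import numpy as np


# ---------------------------------------------------------------------------
# Literal term-by-term risk equations (scalar profiles)
# ---------------------------------------------------------------------------

def ukpds_risk_literal(age, female, afro, smoker, hba1c, sbp, tc, hdl, T, t):
    log_q = (-4.4918 + 0.0573 * (age - 55) - 0.6444 * female - 0.9416 * afro
             + 0.3001 * smoker + 0.1681 * (hba1c - 6.72)
             + 0.0843 * (sbp - 135.7) / 10
             + 1.3468 * (math.log(tc / hdl) - 1.59))
    q = math.exp(log_q)
    d = 1.078
    return 1 - math.exp(-q * d ** T * (1 - d ** t) / (1 - d))


def _bp_cat_literal(sbp, dbp):
    def s_cat(v, cuts):
        for i, c in enumerate(cuts):
            if v < c:
                return i
        return len(cuts)
    return max(s_cat(sbp, (120, 130, 140, 160)), s_cat(dbp, (80, 85, 90, 100)))


def fram_initial_risk_literal(sex, age, tc, hdl, sbp, dbp, diabetes, smoker, t):
    bp = _bp_cat_literal(sbp, dbp)  # 0 optimal .. 4 stage2-4
    if sex == "male":
        m = 0.0483 * age - 3.0975
        m += [-0.6595, 0.0, 0.1769, 0.5054, 0.6571][_tc_idx(tc)]
        m += [0.4974, 0.2431, 0.0, -0.0511, -0.4866][_hdl_idx(hdl)]
        m += [-0.0023, 0.0, 0.2832, 0.5217, 0.6186][bp]
        m += 0.4284 * diabetes + 0.5234 * smoker
        s0 = [0.9946, 0.9850, 0.9770, 0.9622, 0.95592][int(t) - 1]
    else:
        m = 0.3377 * age - 0.0027 * age ** 2 - 9.9255
        m += [-0.2614, 0.0, 0.2077, 0.2439, 0.5351][_tc_idx(tc)]
        m += [0.8431, 0.3780, 0.1979, 0.0, -0.4295][_hdl_idx(hdl)]
        m += [-0.5336, 0.0, -0.0677, 0.2629, 0.4657][bp]
        m += 0.5963 * diabetes + 0.2925 * smoker
        s0 = [0.9984, 0.9933, 0.9909, 0.9858, 0.98297][int(t) - 1]
    return 1 - s0 ** math.exp(m)


def _tc_idx(tc):
    for i, c in enumerate((160, 200, 240, 280)):
        if tc < c:
            return i
    return 4


def _hdl_idx(hdl):
    for i, c in enumerate((35, 45, 50, 60)):
        if hdl < c:
            return i
    return 4


def fram_secondary_risk_literal(sex, age, tc, hdl, sbp, diabetes, smoker, t):
    if sex == "male":
        m = 4.995 - 0.0145 * age - 0.6738 * math.log(tc / hdl) - 0.3042 * diabetes
        sigma = 0.9994
    else:
        m = (13.537 - 0.0225 * age - 0.834 * math.log(tc / hdl)
             - 1.3713 * math.log(sbp) - 0.7829 * diabetes - 0.3669 * smoker)
        sigma = 1.0313
    return 1 - math.exp(-math.exp((math.log(t) - m) / sigma))


# ---------------------------------------------------------------------------
# Exhaustive O(n^2) concordance enumeration
# ---------------------------------------------------------------------------

def concordance_brute(scores, times, events):
    """Enumerate every pair; returns (concordant, discordant, score-tied)."""
    conc = disc = tied = 0
    n = len(scores)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = i, j
            if times[a] > times[b]:
                a, b = b, a
            if times[a] < times[b]:
                if not events[a]:
                    continue          # shorter time censored: order unknown
            else:
                if events[a] + events[b] != 1:
                    continue          # tied times need exactly one event
                if events[b]:
                    a, b = b, a       # the event subject is the shorter-lived
            if scores[a] > scores[b]:
                conc += 1
            elif scores[a] < scores[b]:
                disc += 1
            else:
                tied += 1
    return conc, disc, tied


# ---------------------------------------------------------------------------
# Independent Efron log partial likelihood (for finite-difference checks)
# ---------------------------------------------------------------------------

def efron_loglik_direct(X, times, events, beta):
    """Plain-python Efron log partial likelihood, value only."""
    X = np.asarray(X, dtype=float)
    r = np.exp(X @ beta)
    ll = 0.0
    for tau in sorted(set(times[events == 1])):
        D = np.where((times == tau) & (events == 1))[0]
        R = np.where(times >= tau)[0]
        d = len(D)
        s0r = r[R].sum()
        s0d = r[D].sum()
        ll += float((X[D] @ beta).sum())
        for l in range(d):
            ll -= math.log(s0r - (l / d) * s0d)
    return ll


def km_risk_brute(times, events, t_star):
    """Hand product-limit estimate of cumulative incidence at t_star."""
    s = 1.0
    for tau in sorted(set(times[events == 1])):
        if tau > t_star:
            break
        d = int(((times == tau) & (events == 1)).sum())
        n_at = int((times >= tau).sum())
        s *= 1 - d / n_at
    return 1 - s
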