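"""Discrimination and calibration of risk scores under right censoring.

* :func:`harrell_c_index` — Harrell's concordance index computed from the
  exact pair counts (concordant / discordant / score-tied) over all usable
  pairs, with a subject-level bootstrap CI by default.
* :func:`kaplan_meier_risk` — cumulative incidence ``1 - S_KM(t*)`` with a
  Greenwood-variance CI on the survival scale.
* :func:`calibration_table` — subjects ranked by predicted risk, cut into
  G near-equal groups, observed group risk estimated by within-group
  Kaplan-Meier at a common horizon.
* :func:`gof_chi_square` — Hosmer-Lemeshow-type statistic
  ``sum n_d (O_d - p_d)^2 / (p_d (1 - p_d))`` against a fixed cutoff of
  23.2, the 99th percentile of chi-square with 10 df.  The 10-df cutoff is
  applied regardless of G, matching the convention this package validates
  against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import (DegenerateGroupingError, InvalidInputError,
                     UndefinedResultError)

GOF_CUTOFF = 23.2
GOF_DF = 10


@dataclass(frozen=True)
class ConcordanceResult:
    c_index: float
    usable_pairs: int
    concordant: int
    discordant: int
    tied: int
    ci_low: float
    ci_high: float
    ci_method: str


@dataclass(frozen=True)
class KMRiskResult:
    risk: float
    ci_low: float
    ci_high: float
    se: float
    n: int
    events_by_t: int


@dataclass(frozen=True)
class CalibrationGroup:
    group: int
    n: int
    mean_predicted: float
    km_observed: float
    contribution: float


@dataclass(frozen=True)
class GOFResult:
    statistic: float
    df: int
    threshold: float
    calibrated: bool
    groups: tuple  # of CalibrationGroup


class _Fenwick:
    """Binary indexed tree over score ranks; supports prefix counts."""

    def __init__(self, size: int):
        self.tree = np.zeros(size + 1, dtype=np.int64)
        self.total = 0

    def add(self, i: int):
        i += 1
        while i < len(self.tree):
            self.tree[i] += 1
            i += i & (-i)
        self.total += 1

    def prefix(self, i: int) -> int:
        """Count of inserted ranks <= i."""
        s = 0
        i += 1
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return int(s)


def concordance_counts(scores, times, events):
    """Exact Harrell pair counts under right censoring.

    A pair is usable when the ordering of event times is determinable: the
    subject with the shorter observed time had an event, or the times are
    tied with exactly one event (the censored subject is known to survive
    longer).  Pairs of tied event times are unusable.  A pair is
    concordant when the shorter-lived subject carries the higher score;
    score ties count 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (len(scores) == len(times) == len(events)):
        raise InvalidInputError("scores, times and events must have equal length")
    if (times < 0).any():
        raise InvalidInputError("times must be >= 0")
    if not np.isin(events, (0, 1)).all():
        raise InvalidInputError("events must be 0/1")

    ranks = np.searchsorted(np.unique(scores), scores)
    n_ranks = int(ranks.max()) + 1 if len(ranks) else 0
    order = np.argsort(times, kind="stable")
    conc = disc = tied = 0
    tree = _Fenwick(n_ranks)
    # walk distinct times in decreasing order; tree holds subjects with
    # strictly larger observed time
    i = len(order) - 1
    while i >= 0:
        j = i
        t = times[order[i]]
        while j >= 0 and times[order[j]] == t:
            j -= 1
        group = order[j + 1:i + 1]
        ev_idx = group[events[group] == 1]
        cen_idx = group[events[group] == 0]
        for k in ev_idx:
            r = ranks[k]
            le = tree.prefix(r)
            lt = tree.prefix(r - 1) if r > 0 else 0
            conc += lt
            tied += le - lt
            disc += tree.total - le
            # censored subjects at the same observed time survived past t
            for c in cen_idx:
                if ranks[k] > ranks[c]:
                    conc += 1
                elif ranks[k] < ranks[c]:
                    disc += 1
                else:
                    tied += 1
        for k in group:
            tree.add(ranks[k])
        i = j
    return conc, disc, tied


def harrell_c_index(scores, times, events, n_bootstrap: int = 1000,
                    seed: int | None = None, ci_method: str = "bootstrap",
                    alpha: float = 0.05) -> ConcordanceResult:
    """Harrell's c for censored data, with a 95% CI.

    ``ci_method='bootstrap'`` resamples subjects (default 1000 draws,
    seeded); ``'noether'`` uses the crude large-sample approximation
    ``sqrt(c (1-c) / usable)``.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    conc, disc, tied = concordance_counts(scores, times, events)
    usable = conc + disc + tied
    if usable == 0:
        raise UndefinedResultError("no usable pairs: c-index undefined")
    c = (conc + 0.5 * tied) / usable
    z = stats.norm.ppf(1 - alpha / 2)
    if ci_method == "noether":
        se = float(np.sqrt(c * (1 - c) / usable))
        lo, hi = max(0.0, c - z * se), min(1.0, c + z * se)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(scores)
        reps = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            bc, bd, bt = concordance_counts(scores[idx], times[idx], events[idx])
            if bc + bd + bt > 0:
                reps.append((bc + 0.5 * bt) / (bc + bd + bt))
        lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        raise InvalidInputError(f"unknown ci_method {ci_method!r}")
    return ConcordanceResult(float(c), int(usable), int(conc), int(disc),
                             int(tied), float(lo), float(hi), ci_method)


def kaplan_meier_risk(times, events, t_star: float, alpha: float = 0.05
                      ) -> KMRiskResult:
    """Kaplan-Meier cumulative incidence at ``t_star`` with Greenwood CI.

    The CI is formed on the survival scale, ``S +/- z * se_Greenwood``,
    then mapped to the risk scale.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise InvalidInputError("empty input")
    if t_star < 0:
        raise InvalidInputError("t_star must be >= 0")
    kmf = KaplanMeierFitter().fit(times, events)
    s = float(kmf.predict(t_star))
    tbl = kmf.event_table
    mask = (tbl.index <= t_star) & (tbl["observed"] > 0)
    d = tbl.loc[mask, "observed"].to_numpy(dtype=float)
    n_at = tbl.loc[mask, "at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        gsum = np.where(n_at > d, d / (n_at * (n_at - d)), np.inf).sum()
    se = float(s * np.sqrt(gsum)) if np.isfinite(gsum) else 0.0 if s == 0 else np.nan
    z = stats.norm.ppf(1 - alpha / 2)
    if np.isnan(se):
        lo_s, hi_s, se = 0.0, 1.0, np.nan
    else:
        lo_s, hi_s = max(0.0, s - z * se), min(1.0, s + z * se)
    return KMRiskResult(risk=1.0 - s, ci_low=1.0 - hi_s, ci_high=1.0 - lo_s,
                        se=se, n=len(times), events_by_t=int(d.sum()))


def calibration_table(predicted, times, events, t_star: float, G: int = 10
                      ) -> list[CalibrationGroup]:
    """Decile-style calibration groups: mean predicted vs KM observed risk.

    Subjects are ranked by predicted risk (ties broken by stable input
    order) and cut into G near-equal groups; within each group the
    observed risk is the Kaplan-Meier cumulative incidence at ``t_star``.
    """
    predicted = np.asarray(predicted, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if G < 2:
        raise InvalidInputError("G must be >= 2")
    if ((predicted < 0) | (predicted > 1)).any():
        raise InvalidInputError("predicted risks must lie in [0,1]")
    if len(np.unique(predicted)) < G:
        raise DegenerateGroupingError(
            f"only {len(np.unique(predicted))} distinct predictions; "
            f"lower G below that count")
    order = np.argsort(predicted, kind="stable")
    groups = []
    for g, idx in enumerate(np.array_split(order, G), start=1):
        p_bar = float(predicted[idx].mean())
        km = kaplan_meier_risk(times[idx], events[idx], t_star)
        if 0 < p_bar < 1:
            contrib = len(idx) * (km.risk - p_bar) ** 2 / (p_bar * (1 - p_bar))
        else:
            contrib = np.nan
        groups.append(CalibrationGroup(group=g, n=len(idx), mean_predicted=p_bar,
                                       km_observed=km.risk, contribution=float(contrib)))
    return groups


def gof_chi_square(table: Sequence[CalibrationGroup], threshold: float = GOF_CUTOFF,
                   df: int = GOF_DF) -> GOFResult:
    """Hosmer-Lemeshow-type statistic over calibration groups.

    Declares lack of calibration when the statistic exceeds ``threshold``
    (default 23.2 = 99th percentile of chi-square with 10 df).
    """
    for g in table:
        if not 0 < g.mean_predicted < 1:
            raise DegenerateGroupingError(
                f"group {g.group} has mean predicted risk {g.mean_predicted}; "
                "statistic undefined")
    stat = float(sum(g.contribution for g in table))
    return GOFResult(statistic=stat, df=df, threshold=threshold,
                     calibrated=stat <= threshold, groups=tuple(table))


def calibration_to_records(table: Sequence[CalibrationGroup]) -> list[dict]:
    """Plot-ready paired-bar records (one dict per group)."""
    return [{"group": g.group, "n": g.n, "mean_predicted": g.mean_predicted,
             "km_observed": g.km_observed, "contribution": g.contribution}
            for g in table]
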