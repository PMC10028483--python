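"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (day-by-day scans, exhaustive pair
checks, literal step-by-step matching) and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import numpy as np


def day_scan_episodes(fills, gap_days=90):
    """Day-by-day coverage scan.

    fills: list of (person_id, drug_class, fill_date, days_supply).
    Returns a sorted list of (person_id, drug_class, start, end, covered).
    """
    out = []
    keys = sorted({(p, c) for p, c, _, _ in fills})
    for person, cls in keys:
        covered_days = set()
        for p, c, d, s in fills:
            if (p, c) == (person, cls):
                covered_days.update(range(d, d + s))
        days = sorted(covered_days)
        episodes = []
        start = prev = days[0]
        for d in days[1:]:
            if d - prev - 1 >= gap_days:  # uncovered run [prev+1, d)
                episodes.append((start, prev + 1))
                start = d
            prev = d
        episodes.append((start, prev + 1))
        for s, e in episodes:
            covered = sum(1 for d in days if s <= d < e)
            out.append((person, cls, s, e, covered))
    return sorted(out)


def brute_two_code_date(dates, separation=14):
    """Earliest code belonging to any pair >= separation apart, else None."""
    dates = sorted(dates)
    best = None
    for i, a in enumerate(dates):
        for b in dates[i + 1:]:
            if b - a >= separation:
                best = a if best is None else min(best, a)
    return best


def person_time_daycount(starts, ends):
    """Total person-years by counting individual at-risk days."""
    total_days = 0
    for s, e in zip(starts, ends):
        for _d in range(int(s), int(e)):
            total_days += 1
    return total_days / 365.25


def greedy_match_oracle(sets, su_scores, met_scores, met_dates, met_persons):
    """Literal chronological greedy matching.

    sets: list of (su_score_index, candidate_position_list) in chronological
    order.  Returns list of (set_index, chosen_candidate_position).
    """
    used = set()
    pairs = []
    for s, (su_idx, cands) in enumerate(sets):
        best = None
        for c in cands:
            if c in used:
                continue
            d = abs(met_scores[c] - su_scores[su_idx])
            key = (d, met_dates[c], met_persons[c])
            if best is None or key < best[0]:
                best = (key, c)
        if best is None:
            continue
        used.add(best[1])
        pairs.append((s, best[1]))
    return pairs


def caliper_match_oracle(su_logits, met_logits, caliper, met_dates, met_persons):
    """Literal greedy nearest-neighbour caliper matching (su order as given)."""
    used = set()
    pairs = []
    for s, ls in enumerate(su_logits):
        best = None
        for c, lc in enumerate(met_logits):
            if c in used:
                continue
            d = abs(lc - ls)
            key = (d, met_dates[c], met_persons[c])
            if best is None or key < best[0]:
                best = (key, c)
        if best is None or best[0][0] > caliper:
            continue
        used.add(best[1])
        pairs.append((s, best[1]))
    return pairs


def condlogit_loglik(beta, strata):
    """Conditional-logistic log-likelihood; strata = [(x_case, [x_all])]."""
    ll = 0.0
    for x_case, members in strata:
        etas = [float(np.dot(beta, x)) for x in members]
        ll += float(np.dot(beta, x_case)) - np.log(np.sum(np.exp(etas)))
    return ll


def km_hand(times, events):
    """Product-limit table computed row by row; returns (times, survival)."""
    order = np.argsort(times)
    t_sorted = np.asarray(times)[order]
    e_sorted = np.asarray(events)[order]
    s = 1.0
    out_t, out_s = [], []
    n_at_risk = len(t_sorted)
    i = 0
    while i < len(t_sorted):
        t = t_sorted[i]
        d = sum(
            1 for j in range(len(t_sorted)) if t_sorted[j] == t and e_sorted[j]
        )
        c = sum(
            1 for j in range(len(t_sorted)) if t_sorted[j] == t and not e_sorted[j]
        )
        if d:
            s *= 1.0 - d / n_at_risk
            out_t.append(t)
            out_s.append(s)
        n_at_risk -= d + c
        i += d + c
    return out_t, out_s
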