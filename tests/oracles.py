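"""Independent naive-loop oracles used to cross-check the metric engine.

Everything here is deliberately written as plain Python loops over lists,
with no shared code with the package: trailing sums by explicit iteration,
sample statistics via the statistics module, the EWMA by its closed-form
weighted sum, and AUC by brute-force pair counting.
"""

import math
import statistics

ACUTE = 7
COUPLED_WEEKS = 4
UNCOUPLED_WEEKS = 3
EWMA_N = 5
REDI_WINDOW = 5


def week_sum(w, end, nback=0):
    """Sum of the 7-day block ending `nback` weeks before day `end`."""
    hi = end - nback * ACUTE
    return sum(w[hi - ACUTE + 1: hi + 1])


def acute_load(w, day, window=ACUTE):
    if day < window - 1:
        return None
    return sum(w[day - window + 1: day + 1])


def coupled_acwr(w, day):
    if day < ACUTE * COUPLED_WEEKS - 1:
        return None
    blocks = [week_sum(w, day, k) for k in range(COUPLED_WEEKS)]
    chronic = sum(blocks) / COUPLED_WEEKS
    if chronic == 0:
        return None
    return blocks[0] / chronic


def uncoupled_acwr(w, day):
    if day < ACUTE * (UNCOUPLED_WEEKS + 1) - 1:
        return None
    acute = week_sum(w, day, 0)
    prior = [week_sum(w, day, k) for k in range(1, UNCOUPLED_WEEKS + 1)]
    chronic = sum(prior) / UNCOUPLED_WEEKS
    if chronic == 0:
        return None
    return acute / chronic


def weekly_change_ratio(w, day):
    if day < 2 * ACUTE - 1:
        return None
    prev = week_sum(w, day, 1)
    if prev == 0:
        return None
    return week_sum(w, day, 0) / prev


def monotony(w, day):
    if day < ACUTE - 1:
        return None
    daily = list(w[day - ACUTE + 1: day + 1])
    sd = statistics.stdev(daily)
    if sd == 0:
        return None
    return statistics.mean(daily) / sd


def sd_delta(w, day, denominator="sd"):
    if day < ACUTE * COUPLED_WEEKS - 1:
        return None
    blocks = [week_sum(w, day, k) for k in range(COUPLED_WEEKS)]
    num = blocks[0] - statistics.mean(blocks)
    if num == 0:
        return 0.0
    sd = statistics.stdev(blocks)
    if sd == 0:
        return None
    return num / (sd if denominator == "sd" else sd * sd)


def ewma_closed_form(w, t, lam=2.0 / (EWMA_N + 1)):
    """E_t as the explicit weighted sum, initialization mass on W_0."""
    total = (1 - lam) ** t * w[0]
    for k in range(t):
        total += lam * (1 - lam) ** k * w[t - k]
    return total


def ewma_acwr(w, day, lam=2.0 / (EWMA_N + 1)):
    if day < ACUTE * COUPLED_WEEKS - 1:
        return None
    window = ACUTE * COUPLED_WEEKS
    e = [ewma_closed_form(w, t, lam) for t in range(day - window + 1, day + 1)]
    acute = statistics.mean(e[-ACUTE:])
    chronic = statistics.mean(e)
    if chronic == 0:
        return None
    return acute / chronic


def redi_value(w, t, missing=None, window=REDI_WINDOW):
    """Weighted mean of the trailing `window` loads, e^-i weights, gaps zeroed."""
    if missing is None:
        missing = [x == 0 for x in w]
    num = den = 0.0
    for i in range(min(window, t + 1)):
        if not missing[t - i]:
            a = math.exp(-i)
            num += a * w[t - i]
            den += a
    if den == 0:
        return None
    return num / den


def redi_acwr(w, day, missing=None):
    if day < ACUTE * COUPLED_WEEKS - 1:
        return None
    window = ACUTE * COUPLED_WEEKS
    r = [redi_value(w, t, missing) for t in range(day - window + 1, day + 1)]
    acute = [v for v in r[-ACUTE:] if v is not None]
    chronic = [v for v in r if v is not None]
    if not acute or not chronic:
        return None
    c = statistics.mean(chronic)
    if c == 0:
        return None
    return statistics.mean(acute) / c


#: oracle per package metric name
METRIC_ORACLES = {
    "acwr_coupled": coupled_acwr,
    "acwr_uncoupled": uncoupled_acwr,
    "diff": weekly_change_ratio,
    "monotony": monotony,
    "sd_delta": sd_delta,
    "ewma_acwr": ewma_acwr,
    "redi_acwr": redi_acwr,
}


def auc_mann_whitney(scores, labels):
    """AUC as the normalized Mann-Whitney U by brute-force pair counting."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        return None
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
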