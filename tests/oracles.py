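"""Independent naive-loop oracles used to cross-check the vectorized code.

Everything here is deliberately written as plain Python loops over
scalars, sharing no code path with the package implementation.
"""

import math


def naive_time_domain(rr):
    n = len(rr)
    mean_nn = sum(rr) / n
    sdnn = math.sqrt(sum((x - mean_nn) ** 2 for x in rr) / n)
    diffs = [rr[i + 1] - rr[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    pnn50 = 100.0 * sum(1 for d in diffs if abs(d) > 50.0) / n
    return mean_nn, sdnn, rmssd, pnn50


def naive_poincare(rr):
    n = len(rr)
    d = [rr[i] - rr[i + 1] for i in range(n - 1)]
    dbar = sum(d) / len(d)
    var_d = sum((x - dbar) ** 2 for x in d) / len(d)
    sd1 = math.sqrt(var_d / 2.0)
    mean_nn = sum(rr) / n
    sdnn_sq = sum((x - mean_nn) ** 2 for x in rr) / n
    sd2 = math.sqrt(max(2.0 * sdnn_sq - sd1 ** 2, 0.0))
    return sd1, sd2, (sd1 / sd2 if sd2 > 0 else float("nan"))


def naive_qrs_stats(areas, amps):
    n = len(areas)
    abs_areas = [abs(a) for a in areas]
    qrsam = sum(abs_areas) / n
    qrsasd = math.sqrt(sum((a - qrsam) ** 2 for a in abs_areas) / n)
    rpampm = sum(amps) / n
    rpampsd = math.sqrt(sum((a - rpampm) ** 2 for a in amps) / n)
    return qrsam, qrsasd, rpampm, rpampsd


def rank_auc(scores, labels):
    """AUC as the Mann-Whitney pair statistic (ties count one half)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def welch_t(x, y):
    """Welch's t and its degrees of freedom, from the textbook formulas."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se_sq = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se_sq)
    df = se_sq ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


def oneway_f(groups):
    """One-way ANOVA F from between/within mean squares, by hand."""
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / n
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    return (ss_between / (k - 1)) / (ss_within / (n - k))
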