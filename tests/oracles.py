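"""Independent brute-force oracles used to cross-check the package.

Everything here is written from first-principles textbook formulas with
plain loops and math functions, deliberately not sharing code paths with
the package implementation.
"""

from __future__ import annotations

import math

from scipy.stats import norm, t as t_dist

from hrvcohort.io_formats import RRInterval


# -- time-domain HRV ---------------------------------------------------------

def sdnn_direct(nn):
    n = len(nn)
    mean = math.fsum(nn) / n
    return math.sqrt(math.fsum((x - mean) ** 2 for x in nn) / (n - 1))


def rmssd_direct(nn):
    diffs = [nn[i + 1] - nn[i] for i in range(len(nn) - 1)]
    return math.sqrt(math.fsum(d * d for d in diffs) / len(diffs))


def nn50_direct(nn):
    return sum(
        1 for i in range(len(nn) - 1) if abs(nn[i + 1] - nn[i]) > 50.0
    )


def pnn50_direct(nn):
    return 100.0 * nn50_direct(nn) / (len(nn) - 1)


def poincare_direct(nn):
    sd1 = rmssd_direct(nn) / math.sqrt(2.0)
    sd2sq = 2.0 * sdnn_direct(nn) ** 2 - sd1 * sd1
    sd2 = math.sqrt(sd2sq) if sd2sq > 0 else 0.0
    return sd1, sd2


def sdann_asdnn_direct(pairs, window_start_ms, bin_ms=300_000.0):
    """pairs: (onset_ms, rr_ms); returns (sdann, asdnn) or None."""
    bins = {}
    for onset, rr in pairs:
        bins.setdefault(int((onset - window_start_ms) // bin_ms), []).append(rr)
    means, sds = [], []
    for k in sorted(bins):
        vals = bins[k]
        if len(vals) < 2:
            continue
        means.append(math.fsum(vals) / len(vals))
        sds.append(sdnn_direct(vals))
    if len(means) < 2:
        return None
    return sdnn_direct(means), math.fsum(sds) / len(sds)


# -- NN cleaning -------------------------------------------------------------

def clean_segments_direct(intervals: list[RRInterval], allowable_change=0.15,
                          min_run=6):
    """Sequential re-derivation of the cleaning rule: N/N endpoints only,
    strict relative-change bound against the last accepted interval, the
    violating interval discarded and the next interval seeding afresh,
    runs below min_run dropped."""
    segments = []
    run: list[RRInterval] = []

    def close():
        if len(run) >= min_run:
            segments.append([iv.rr_ms for iv in run])

    for iv in intervals:
        if iv.start_label != "N" or iv.end_label != "N":
            close()
            run = []
            continue
        if run:
            prev = run[-1].rr_ms
            lo = prev * (1 - allowable_change)
            hi = prev * (1 + allowable_change)
            if not lo < iv.rr_ms < hi:
                close()
                run = []
                continue  # offending interval discarded entirely
        run.append(iv)
    close()
    return segments


def validate_segments(intervals, segments, allowable_change=0.15, min_run=6):
    """O(n^2) check that every emitted segment satisfies all three rules and
    appears as a contiguous N/N sub-run of the input."""
    rr = [iv.rr_ms for iv in intervals]
    for seg in segments:
        vals = seg.rr_ms if hasattr(seg, "rr_ms") else seg
        assert len(vals) >= min_run
        for prev, cur in zip(vals, vals[1:]):
            assert prev * (1 - allowable_change) < cur < prev * (1 + allowable_change)
        # locate as contiguous subsequence with N/N labels
        found = False
        for s in range(len(rr) - len(vals) + 1):
            if all(abs(rr[s + k] - vals[k]) < 1e-9 for k in range(len(vals))):
                if all(
                    intervals[s + k].start_label == "N"
                    and intervals[s + k].end_label == "N"
                    for k in range(len(vals))
                ):
                    found = True
                    break
        assert found, "segment is not a contiguous N/N sub-run of the input"


# -- statistics --------------------------------------------------------------

def pearson_direct(x, y):
    n = len(x)
    mx = math.fsum(x) / n
    my = math.fsum(y) / n
    sxy = math.fsum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = math.fsum((a - mx) ** 2 for a in x)
    syy = math.fsum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * t_dist.sf(abs(t), n - 2)
    return r, p


def midranks(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_direct(x, y):
    return pearson_direct(midranks(x), midranks(y))


def welch_t_direct(a, b):
    na, nb = len(a), len(b)
    ma, mb = math.fsum(a) / na, math.fsum(b) / nb
    va = math.fsum((v - ma) ** 2 for v in a) / (na - 1)
    vb = math.fsum((v - mb) ** 2 for v in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, p


def mannwhitney_direct(a, b):
    """U of the first sample; asymptotic two-sided p with tie and
    continuity corrections."""
    n1, n2 = len(a), len(b)
    pooled = list(a) + list(b)
    ranks = midranks(pooled)
    r1 = math.fsum(ranks[:n1])
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    mu = n1 * n2 / 2.0
    n = n1 + n2
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = math.fsum(c**3 - c for c in counts.values())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    sigma = math.sqrt(sigma2)
    z = (max(u1, u2) - mu - 0.5) / sigma
    p = min(1.0, 2.0 * norm.sf(z))
    return u1, p


def ks_statistic_direct(a, b):
    """Max ECDF gap by brute force over all pooled points."""
    pts = sorted(set(list(a) + list(b)))
    d = 0.0
    for x in pts:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d


def auc_pairs_direct(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# -- fixtures ----------------------------------------------------------------

def intervals_from_rr(rr_list, labels=None, t0=0.0):
    """Build RRInterval list from interval lengths and per-beat labels
    (labels has len(rr_list)+1 entries; default all N)."""
    if labels is None:
        labels = ["N"] * (len(rr_list) + 1)
    out = []
    t = t0
    for k, rr in enumerate(rr_list):
        out.append(RRInterval(float(rr), labels[k], labels[k + 1], t))
        t += rr
    return out
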