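"""Independent brute-force reference implementation of short-term DFA.

Deliberately written with plain Python loops and no shared code with
the package: integrate the mean-removed series, walk forward over
non-overlapping boxes at each scale, fit a line per box by the
closed-form normal equations, pool squared residuals over boxes
normalising by the per-box residual degrees of freedom (n - 1), and
take the least-squares slope of log F(n) on log n.  Used as the oracle
the fast implementation is compared against.
"""

import math


def dfa_alpha1_bruteforce(x, scale_min=4, scale_max=16):
    n_total = len(x)
    mean = sum(x) / n_total
    y = []
    acc = 0.0
    for v in x:
        acc += v - mean
        y.append(acc)

    log_n = []
    log_f = []
    for n in range(scale_min, scale_max + 1):
        m = n_total // n
        ssr = 0.0
        for b in range(m):
            box = y[b * n : (b + 1) * n]
            # closed-form OLS of box values on 0..n-1
            st = sum(range(n))
            stt = sum(t * t for t in range(n))
            sy = sum(box)
            sty = sum(t * box[t] for t in range(n))
            denom = n * stt - st * st
            slope = (n * sty - st * sy) / denom
            intercept = (sy - slope * st) / n
            for t in range(n):
                r = box[t] - (intercept + slope * t)
                ssr += r * r
        f = math.sqrt(ssr / (m * (n - 1)))
        log_n.append(math.log(n))
        log_f.append(math.log(f))

    k = len(log_n)
    sx = sum(log_n)
    sxx = sum(v * v for v in log_n)
    sy = sum(log_f)
    sxy = sum(a * b for a, b in zip(log_n, log_f))
    return (k * sxy - sx * sy) / (k * sxx - sx * sx)
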