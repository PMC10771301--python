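"""Independent, deliberately naive reference implementations.

These are coded directly from the printed formulas with scalar ``math``
operations and simple loops, kept free of any import from the package's
computational path, so they can serve as oracles for the vectorised
implementations.
"""

from __future__ import annotations

import math


def ror_oracle(a, b, c, d):
    if min(a, b, c, d) == 0:
        return math.nan, math.nan, math.nan
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, math.exp(math.log(ror) - 1.96 * se), math.exp(math.log(ror) + 1.96 * se)


def prr_oracle(a, b, c, d):
    n = a + b + c + d
    prr = math.nan
    if c > 0 and a + b > 0 and c + d > 0:
        prr = (a * (c + d)) / (c * (a + b))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = math.nan if denom == 0 else (a * d - b * c) ** 2 * n / denom
    return prr, chi2


def bcpnn_oracle(a, b, c, d):
    """Observed IC and the Bate closed-form moments with unit margin priors."""
    n = a + b + c + d
    ab, ac = a + b, a + c
    if ab == 0 or ac == 0 or n == 0:
        return math.nan, math.nan, math.nan, math.nan
    ic = -math.inf if a == 0 else math.log2(a * n / (ac * ab))
    a1 = b1 = g11 = 1.0
    al = be = 2.0
    gamma = g11 * (n + al) * (n + be) / ((ab + a1) * (ac + b1))
    e_ic = (math.log((a + g11) / (n + gamma))
            - math.log((ab + a1) / (n + al))
            - math.log((ac + b1) / (n + be))) / math.log(2)
    v_ic = ((n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
            + (n - ab + al - a1) / ((ab + a1) * (1 + n + al))
            + (n - ac + be - b1) / ((ac + b1) * (1 + n + be))) / math.log(2) ** 2
    return ic, e_ic, v_ic, e_ic - 2 * math.sqrt(v_ic)


def mgps_oracle(a, b, c, d):
    n = a + b + c + d
    ab, ac = a + b, a + c
    ebgm = math.nan if ab == 0 or ac == 0 else a * n / (ac * ab)
    ebgm05 = math.nan
    if min(a, b, c, d) > 0:
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ebgm05 = math.exp(math.log(ebgm) - 1.96 * se)
    return ebgm, ebgm05


def bh_oracle(pvals):
    """Benjamini-Hochberg by sort / scale / cumulative-min / unsort."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    scaled = [pvals[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = [0.0] * m
    for i, idx in enumerate(order):
        out[idx] = min(1.0, scaled[i])
    return out


def contingency_oracle(events, target_ids, label):
    """Brute-force 2x2 recount over unique (report, label) pairs."""
    pairs = {(p, lab) for p, lab in events}
    a = b = c = d = 0
    for p, lab in pairs:
        tgt = p in target_ids
        if lab == label:
            if tgt:
                a += 1
            else:
                c += 1
        else:
            if tgt:
                b += 1
            else:
                d += 1
    return a, b, c, d
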