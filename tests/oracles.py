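"""Naive brute-force reference implementations used only by tests.

Each oracle follows the textbook definition with explicit Python loops and
no shared code with the package, so agreement is evidence of correctness
rather than repetition.
"""

from __future__ import annotations

import math

import numpy as np


def _cheb(a, b) -> float:
    return max(abs(float(u) - float(v)) for u, v in zip(a, b))


def naive_approximate_entropy(x, m=2, r_factor=0.7) -> float:
    x = list(map(float, x))
    n = len(x)
    r = r_factor * float(np.std(x))

    def phi(mm):
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for ti in templates:
            c = sum(1 for tj in templates if _cheb(ti, tj) <= r)
            total += math.log(c / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def naive_sample_entropy(x, m=2, r_factor=0.7) -> float:
    x = list(map(float, x))
    n = len(x)
    r = r_factor * float(np.std(x))
    tm = [x[i:i + m] for i in range(n - m)]
    tm1 = [x[i:i + m + 1] for i in range(n - m)]
    b = sum(1 for i in range(len(tm)) for j in range(len(tm))
            if i != j and _cheb(tm[i], tm[j]) <= r)
    a = sum(1 for i in range(len(tm1)) for j in range(len(tm1))
            if i != j and _cheb(tm1[i], tm1[j]) <= r)
    return -math.log(a / b)


def naive_fuzzy_entropy(x, m=2, r_factor=0.7, n_grad=2.0) -> float:
    x = list(map(float, x))
    n = len(x)
    r = r_factor * float(np.std(x))

    def phi(mm):
        raw = [x[i:i + mm] for i in range(n - m)]
        templates = [[v - sum(t) / len(t) for v in t] for t in raw]
        total = 0.0
        k = len(templates)
        for i in range(k):
            for j in range(k):
                if i != j:
                    d = _cheb(templates[i], templates[j])
                    total += math.exp(-((d / r) ** n_grad))
        return total / (k * (k - 1))

    return math.log(phi(m)) - math.log(phi(m + 1))


def naive_permutation_entropy(x, m=5, tau=4, scale=2) -> float:
    x = list(map(float, x))
    nc = len(x) // scale
    y = [sum(x[i * scale:(i + 1) * scale]) / scale for i in range(nc)]
    span = (m - 1) * tau
    counts: dict[tuple, int] = {}
    for i in range(len(y) - span):
        window = [y[i + k * tau] for k in range(m)]
        pattern = tuple(sorted(range(m), key=window.__getitem__))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    h = -sum(c / total * math.log(c / total) for c in counts.values())
    return h / math.log(math.factorial(m))


def naive_symbolic_transfer_entropy(source, target, k=1) -> float:
    s = [1 if source[i + 1] > source[i] else 0 for i in range(len(source) - 1)]
    t = [1 if target[i + 1] > target[i] else 0 for i in range(len(target) - 1)]
    joint: dict[tuple, int] = {}
    n = 0
    for i in range(k, len(t)):
        key = (t[i], tuple(t[i - k:i]), tuple(s[i - k:i]))
        joint[key] = joint.get(key, 0) + 1
        n += 1
    p_joint = {key: c / n for key, c in joint.items()}
    p_yh: dict[tuple, float] = {}
    p_yh_xh: dict[tuple, float] = {}
    p_ynext_yh: dict[tuple, float] = {}
    for (ynext, yh, xh), p in p_joint.items():
        p_yh[yh] = p_yh.get(yh, 0.0) + p
        p_yh_xh[(yh, xh)] = p_yh_xh.get((yh, xh), 0.0) + p
        p_ynext_yh[(ynext, yh)] = p_ynext_yh.get((ynext, yh), 0.0) + p
    te = 0.0
    for (ynext, yh, xh), p in p_joint.items():
        num = p * p_yh[yh]
        den = p_yh_xh[(yh, xh)] * p_ynext_yh[(ynext, yh)]
        te += p * math.log2(num / den)
    return te


def naive_auc(labels, scores) -> float:
    """All-pairs Mann-Whitney AUC: P(s+ > s-) + 0.5 P(s+ == s-)."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
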