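"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (brute force, closed form, exact
simulation) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import numpy as np


def lz76_brute(s: str) -> int:
    """Exhaustive-history LZ76 word count by explicit nested-loop matching."""
    n = len(s)
    words = 0
    i = 0
    while i < n:
        length = 1
        while i + length <= n:
            candidate = s[i : i + length]
            history = s[: i + length - 1]
            found = False
            for start in range(len(history) - length + 1):
                if history[start : start + length] == candidate:
                    found = True
                    break
            if not found:
                break
            length += 1
        words += 1
        i += length
    return words


def auc_concordance(scores, labels) -> float:
    """Mann-Whitney concordance: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (pos.size * neg.size)


def quartile_count_oracle(counts) -> int:
    """Sort-and-interpolate first quartile, rounded half up, floored at 1."""
    v = sorted(float(c) for c in counts)
    n = len(v)
    pos = 0.25 * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    q = v[lo] + (pos - lo) * (v[hi] - v[lo])
    return max(1, int(np.floor(q + 0.5)))


def student_t_oracle(a, b):
    """Textbook equal-variance two-sample t statistic and two-sided p."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_stat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * t_dist.sf(abs(t_stat), na + nb - 2)
    return t_stat, p


def davies_harte_fgn(h: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact-spectrum fractional Gaussian noise via circulant embedding."""
    k = np.arange(n + 1)
    gamma = 0.5 * (
        np.abs(k - 1) ** (2 * h) - 2 * np.abs(k) ** (2 * h) + np.abs(k + 1) ** (2 * h)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.fft(row).real
    if eig.min() < 0:
        raise ValueError("circulant embedding failed for this (h, n)")
    m = row.size
    w = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    f = np.fft.fft(np.sqrt(eig / (2 * m)) * w)
    return f.real[:n]


def binomial_cascade(p: float, levels: int, rng: np.random.Generator) -> np.ndarray:
    """Random binomial multiplicative cascade measure of 2**levels points.

    At each refinement the mass of an interval splits p/(1-p) between its
    halves, the favored side chosen at random; the analytic singularity
    spectrum spans alpha in [-log2(max(p,1-p)), -log2(min(p,1-p))].
    """
    m = np.ones(1)
    for _ in range(levels):
        left = np.where(rng.random(m.size) < 0.5, p, 1 - p)
        m = np.column_stack([m * left, m * (1 - left)]).ravel()
    return m


def bayes_accuracy_mc(
    effect_sizes, correlation: float, n_samples: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo Bayes accuracy of the two-class Gaussian cohort model.

    Classes share the covariance (equicorrelated if requested), class
    means differ by ``effect_sizes``; the Bayes rule is the linear LLR
    threshold, evaluated on fresh draws from both classes.
    """
    d = np.asarray(effect_sizes, dtype=float)
    p = d.size
    if correlation > 0:
        cov = np.full((p, p), correlation) + np.diag(np.full(p, 1 - correlation))
    else:
        cov = np.eye(p)
    inv = np.linalg.inv(cov)
    w = inv @ d  # LLR direction
    thresh = 0.5 * d @ inv @ d
    chol = np.linalg.cholesky(cov)
    half = n_samples // 2
    z0 = rng.standard_normal((half, p)) @ chol.T
    z1 = rng.standard_normal((half, p)) @ chol.T + d
    correct = np.sum(z0 @ w < thresh) + np.sum(z1 @ w >= thresh)
    return correct / (2 * half)
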