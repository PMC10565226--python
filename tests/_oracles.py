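"""Independent brute-force oracles used by the test suite.

These deliberately re-implement, in the most literal style possible, the
operations they check, and stay independent of the package's code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_fixation_groups(x, y, valid, radius, min_run=2):
    """Literal re-scan of the lead-sample dispersion rule.

    Within every maximal run of valid samples: the first remaining sample is
    the lead; consecutive samples join while within ``radius`` of the lead's
    position; the first sample beyond closes the group and starts the next.
    Returns the list of member-index tuples of groups with >= min_run members.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    valid = list(map(bool, valid))
    n = len(x)
    groups = []
    run_start = 0
    while run_start < n:
        if not valid[run_start]:
            run_start += 1
            continue
        run_end = run_start
        while run_end + 1 < n and valid[run_end + 1]:
            run_end += 1
        i = run_start
        while i <= run_end:
            j = i + 1
            while j <= run_end and math.hypot(x[j] - x[i], y[j] - y[i]) <= radius:
                j += 1
            if j - i >= min_run:
                groups.append(tuple(range(i, j)))
            i = j
        run_start = run_end + 1
    return groups


def dense_loglik(X, y, group_codes, g, w, lam, delta, method):
    """Dense multivariate-normal evaluation of the profiled log-likelihood."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    Z = (np.asarray(group_codes)[:, None]
         == np.unique(group_codes)[None, :]).astype(float)
    V = lam * Z @ Z.T + np.diag(np.exp(2.0 * delta * np.asarray(g, float))
                                / np.asarray(w, float))
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    q = float(r @ Vi @ r)
    sld_v = np.linalg.slogdet(V)[1]
    if method.upper() == "ML":
        s2 = q / n
        return -0.5 * (n * np.log(2 * np.pi * s2) + sld_v + n)
    s2 = q / (n - p)
    return -0.5 * (
        (n - p) * np.log(2 * np.pi * s2)
        + sld_v
        + np.linalg.slogdet(XtVX)[1]
        + (n - p)
    )


def mann_whitney_exact_p(a, b):
    """Two-sided exact permutation p-value for the Mann-Whitney U statistic.

    Enumerates every assignment of the pooled values to the two groups and
    counts assignments whose |U - mean U| is at least as extreme as observed.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1 = len(a)
    mu = n1 * len(b) / 2.0

    def u_stat(sample_a, sample_b):
        u = 0.0
        for va in sample_a:
            for vb in sample_b:
                if va > vb:
                    u += 1.0
                elif va == vb:
                    u += 0.5
        return u

    obs = abs(u_stat(a, b) - mu)
    count = 0
    total = 0
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, n1):
        sa = [pooled[i] for i in comb]
        sb = [pooled[i] for i in idx if i not in comb]
        total += 1
        if abs(u_stat(sa, sb) - mu) >= obs - 1e-12:
            count += 1
    return count / total


def random_lmm_dataset(rng, n_groups=None, max_obs=50):
    """A small random dataset in the model's layout for oracle comparisons."""
    import pandas as pd

    n_groups = n_groups or int(rng.integers(3, 8))
    rows = []
    total = 0
    for gidx in range(n_groups):
        m = int(rng.integers(2, 6))
        if total + m > max_obs:
            m = max(2, max_obs - total)
        total += m
        nat = "somali" if gidx % 2 else "czech"
        b = rng.normal(0, 1.0)
        for j in range(m):
            morph = ["cobra", "viper", "other"][int(rng.integers(3))]
            w = int(rng.integers(1, 3))
            rows.append(
                dict(
                    participant_id=f"P{gidx:02d}",
                    nationality=nat,
                    morphotype=morph,
                    weight=w,
                    y=b + rng.normal(0, 1.0) + (morph == "cobra"),
                )
            )
        if total >= max_obs:
            break
    return pd.DataFrame(rows)
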