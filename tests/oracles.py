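"""Independent brute-force oracles used only by the tests.

Deliberately literal transcriptions (explicit loops, no shared code with
the package) so they can stand as independent references.
"""

from __future__ import annotations

import numpy as np


def brute_force_score_model(X: np.ndarray):
    """Correlation-PCA loadings and scores by explicit construction.

    ``X`` is genes × samples. Returns (loadings_pc1, loadings_pc2, scores,
    explained_variance_ratio) under the positive-loading-sum sign rule.
    """
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=1)
    sds = X.std(axis=1, ddof=1)
    Z = (X - means[:, None]) / sds[:, None]
    C = np.corrcoef(X)
    vals, vecs = np.linalg.eig(C)
    vals, vecs = np.real(vals), np.real(vecs)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    out = []
    for j in range(2):
        v = vecs[:, j].copy()
        s = v.sum()
        if s < 0 or (s == 0 and v[0] < 0):
            v = -v
        out.append(v)
    w1, w2 = out
    scores = Z.T @ (w1 + w2)
    return w1, w2, scores, np.clip(vals, 0, None) / np.clip(vals, 0, None).sum()


def literal_ssgsea(values: np.ndarray, gene_names: list, set_genes: list, alpha: float) -> float:
    """Literal running-sum transcription of the single-sample statistic.

    ``values`` is one sample's expression over ``gene_names``. Ascending
    average ranks; walk in descending expression (ties by row order);
    accumulate weighted in-set ECDF minus unweighted out-of-set ECDF.
    """
    n = len(values)
    # average ranks, ascending
    ranks = [0.0] * n
    for i in range(n):
        less = sum(1 for j in range(n) if values[j] < values[i])
        equal = sum(1 for j in range(n) if values[j] == values[i])
        ranks[i] = less + (equal + 1) / 2.0
    order = sorted(range(n), key=lambda i: (-values[i], i))
    in_set = [gene_names[i] in set(set_genes) for i in range(n)]
    n_in = sum(in_set)
    n_out = n - n_in
    if n_out == 0:
        return 0.0
    total_w = sum(abs(ranks[i]) ** alpha for i in order if in_set[i])
    es = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for i in order:
        if in_set[i]:
            if total_w > 0:
                cum_in += abs(ranks[i]) ** alpha / total_w
            else:
                cum_in += 1.0 / n_in
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


def newton_raphson_cox(times, events, x, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Single-covariate Cox partial-likelihood maximizer (Breslow risk sets).

    Valid as an exact reference on untied event times, where Breslow and
    Efron coincide.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    beta = 0.0
    for _ in range(max_iter):
        U = 0.0
        I = 0.0
        for i in np.flatnonzero(events == 1):
            risk = times >= times[i]
            w = np.exp(beta * x[risk])
            s0 = w.sum()
            s1 = (w * x[risk]).sum()
            s2 = (w * x[risk] ** 2).sum()
            U += x[i] - s1 / s0
            I += s2 / s0 - (s1 / s0) ** 2
        step = U / I
        beta += step
        if abs(step) < tol:
            break
    return beta


def hand_logrank_chi2(times, events, labels) -> float:
    """Observed-vs-expected two-group log-rank chi-square by table walk."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    assert len(groups) == 2
    O1 = E1 = V = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n_all = at_risk.sum()
        n1 = (at_risk & (labels == groups[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (labels == groups[0])).sum()
        O1 += d1
        E1 += d * n1 / n_all
        if n_all > 1:
            V += d * (n1 / n_all) * (1 - n1 / n_all) * (n_all - d) / (n_all - 1)
    return (O1 - E1) ** 2 / V


def allpairs_cindex(times, events, risk) -> tuple[float, int]:
    """Harrell's C by explicit enumeration of all pairs."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    risk = np.asarray(risk, float)
    n = len(times)
    num = 0.0
    pairs = 0
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                pairs += 1
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
    if pairs == 0:
        raise ValueError("no comparable pairs")
    return num / pairs, pairs


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's.
    """
    import math

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(aa):
        return (
            math.comb(r1, aa) * math.comb(r2, c1 - aa) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(aa) for aa in range(lo, hi + 1) if prob(aa) <= p_obs * (1 + 1e-9))
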