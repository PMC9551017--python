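"""Independent straight-line oracles used to cross-check the package.

Everything here is written with plain Python loops and the standard
library's math module, sharing no code with the implementation under
test: the grey-association oracle re-derives the whole chain (first
differences, softmax entropy, entropy-ratio window schedule, relational
coefficients, window averaging) literally, and the ranking-metric
oracles enumerate positive/negative pairs and walk the ranking by hand.
"""

import math


# ---------------------------------------------------------------------------
# grey-association chain, literal and loop-based
# ---------------------------------------------------------------------------


def oracle_entropy(segment):
    """Softmax of |values| then Shannon entropy in bits."""
    absvals = [abs(v) for v in segment]
    mx = max(absvals)
    exps = [math.exp(v - mx) for v in absvals]
    total = sum(exps)
    ps = [e / total for e in exps]
    ent = 0.0
    for p in ps:
        if p > 0:
            ent -= p * math.log2(p)
    return max(ent, 0.0)


def oracle_schedule(series, L_init, L_min, L_max):
    """Step-by-step window schedule on the difference axis of a series."""
    diffs = [series[i + 1] - series[i] for i in range(len(series) - 1)]
    n = len(diffs)
    assert n >= L_init, "series too short"
    windows = []
    E_prev = math.log2(L_init)
    L = L_init
    start = 0
    while n - start >= L_min:
        take = min(L, n - start)
        windows.append((start, take))
        E_curr = oracle_entropy(diffs[start : start + take])
        if E_prev <= 0:
            L_next = take
        else:
            L_next = round(E_curr / E_prev * take)  # python round: half-to-even
        L = min(max(L_next, L_min), L_max)
        E_prev = E_curr
        start += take
    rem = n - start
    if rem >= 2:
        windows.append((start, rem))
    elif rem == 1:
        s, l = windows[-1]
        windows[-1] = (s, l + 1)
    return windows


def _oracle_normalize(row, method):
    if method == "none":
        return list(row)
    if method == "zscore":
        mu = sum(row) / len(row)
        var = sum((v - mu) ** 2 for v in row) / len(row)
        sd = math.sqrt(var)
        if sd == 0:
            return [0.0 for _ in row]
        return [(v - mu) / sd for v in row]
    if method == "minmax":
        lo, hi = min(row), max(row)
        if hi == lo:
            return [0.0 for _ in row]
        return [(v - lo) / (hi - lo) for v in row]
    raise ValueError(method)


def oracle_dga(blocks, rho=0.5, L_init=None, L_min=2, L_max=None, norm="zscore"):
    """Full m x m dynamic grey association matrix, computed literally.

    ``blocks`` is a list of per-replicate matrices given as lists of
    per-gene rows.  A window (s, L) on the difference axis samples the
    normalised expression values at timepoints s+1 .. s+L.
    """
    m = len(blocks[0])
    scores = [[0.0] * m for _ in range(m)]
    for block in blocks:
        n = len(block[0])
        li = L_init if L_init is not None else max(3, round((n - 1) / 5))
        lx = L_max if L_max is not None else n - 1
        li = min(max(li, L_min), lx)
        normed = [_oracle_normalize(row, norm) for row in block]
        for j in range(m):
            windows = oracle_schedule(normed[j], li, L_min, lx)
            comp = [k for k in range(m) if k != j]
            sums = {k: 0.0 for k in comp}
            for (s, L) in windows:
                idx = list(range(s + 1, s + 1 + L))
                resid = {
                    k: [abs(normed[j][i] - normed[k][i]) for i in idx] for k in comp
                }
                all_res = [r for rs in resid.values() for r in rs]
                lo, hi = min(all_res), max(all_res)
                for k in comp:
                    if hi <= 0:
                        xis = [1.0] * L
                    else:
                        xis = [(lo + rho * hi) / (r + rho * hi) for r in resid[k]]
                    sums[k] += sum(xis) / L
            for k in comp:
                scores[k][j] += sums[k] / len(windows)
    nb = len(blocks)
    for k in range(m):
        for j in range(m):
            scores[k][j] /= nb
        scores[k][k] = 0.0
    return scores


# ---------------------------------------------------------------------------
# ranking metrics, brute force
# ---------------------------------------------------------------------------


def oracle_auroc(labels, scores):
    """Pairwise Mann-Whitney enumeration with half-credit for ties."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_auprc(labels, scores):
    """Average precision: walk the ranking from the best score down,
    adding precision at each recall increment; tied scores are handled
    as a single group (precision evaluated at the group boundary)."""
    order = sorted(range(len(labels)), key=lambda i: -scores[i])
    n_pos = sum(labels)
    ap = 0.0
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        g_tp = g_fp = 0
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            if labels[order[j]] == 1:
                g_tp += 1
            else:
                g_fp += 1
            j += 1
        prev_tp = tp
        tp += g_tp
        fp += g_fp
        if g_tp:
            precision = tp / (tp + fp)
            ap += precision * (tp - prev_tp) / n_pos
        i = j
    return ap


def oracle_wilcoxon_exact_greater(diffs):
    """One-sided exact signed-rank p-value by enumerating all 2^n sign
    assignments (no zeros, no tied |diffs| expected)."""
    n = len(diffs)
    absd = sorted(range(n), key=lambda i: abs(diffs[i]))
    ranks = [0] * n
    for r, i in enumerate(absd, start=1):
        ranks[i] = r
    w_obs = sum(r for d, r in zip(diffs, ranks) if d > 0)
    count = 0
    for mask in range(2**n):
        w = sum(ranks[i] for i in range(n) if (mask >> i) & 1)
        if w >= w_obs:
            count += 1
    return count / 2**n
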