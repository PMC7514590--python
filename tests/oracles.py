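"""Independent brute-force reference implementations used only by tests.

These are deliberately written as plain double loops, separate from the
vectorised package code, so agreement between the two routes is a real
check and not a tautology.
"""

import math


def apen_bruteforce(u, m, r):
    """ApEn(m, r, N) by literal enumeration of template-vector matches.

    Chebyshev distance, self-matches included, natural log; Phi at each
    dimension is normalised by that dimension's own vector count.
    """
    u = [float(v) for v in u]
    n = len(u)

    def phi(mm):
        nv = n - mm + 1
        total = 0.0
        for i in range(nv):
            count = 0
            for j in range(nv):
                d = 0.0
                for k in range(mm):
                    ad = abs(u[i + k] - u[j + k])
                    if ad > d:
                        d = ad
                if d <= r:
                    count += 1
            total += math.log(count / nv)
        return total / nv

    return phi(m) - phi(m + 1)


def match_counts_bruteforce(u, m, r):
    """Raw template-match counts #{j : d[x(i), x(j)] <= r} for each i."""
    u = [float(v) for v in u]
    n = len(u)
    nv = n - m + 1
    counts = []
    for i in range(nv):
        c = 0
        for j in range(nv):
            d = max(abs(u[i + k] - u[j + k]) for k in range(m))
            if d <= r:
                c += 1
        counts.append(c)
    return counts


def knn_bruteforce(x_train, y_train, x_test, k):
    """knn by exhaustive distance sort with the documented tie rules:
    equidistant neighbours by training-row order, vote ties by smaller
    summed neighbour distance, then by lower class index."""
    preds = []
    for q in x_test:
        dists = []
        for row_idx, (p, label) in enumerate(zip(x_train, y_train)):
            d = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))
            dists.append((d, row_idx, int(label)))
        dists.sort(key=lambda t: (t[0], t[1]))
        nbrs = dists[:k]
        votes = {}
        sums = {}
        for d, _, label in nbrs:
            votes[label] = votes.get(label, 0) + 1
            sums[label] = sums.get(label, 0.0) + d
        top = max(votes.values())
        tied = [c for c, v in votes.items() if v == top]
        tied.sort(key=lambda c: (sums[c], c))
        preds.append(tied[0])
    return preds


def mean_sd_bruteforce(list_of_values, ddof=1):
    """Naive accumulation mean/SD over aligned sequences."""
    n = len(list_of_values)
    length = len(list_of_values[0])
    means, sds = [], []
    for j in range(length):
        s = sum(vals[j] for vals in list_of_values)
        mean = s / n
        if n > ddof:
            var = sum((vals[j] - mean) ** 2 for vals in list_of_values) / (n - ddof)
        else:
            var = 0.0
        means.append(mean)
        sds.append(math.sqrt(var))
    return means, sds


def metrics_bruteforce(y_true, y_pred, fold_ids, labels):
    """Tally-based overall and fold-averaged per-class accuracy."""
    n = len(y_true)
    overall = sum(1 for a, b in zip(y_true, y_pred) if a == b) / n
    folds = sorted(set(fold_ids))
    per_class = {}
    for c in labels:
        accs = []
        for f in folds:
            idx = [i for i in range(n) if fold_ids[i] == f and y_true[i] == c]
            if idx:
                accs.append(sum(1 for i in idx if y_pred[i] == c) / len(idx))
        per_class[c] = sum(accs) / len(accs) if accs else float("nan")
    return overall, per_class
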