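"""Independent brute-force oracles used to check the package's vectorized
implementations.  Everything here is plain double loops and scalar math on
purpose — no shared code with the package internals."""

import math

import numpy as np

EPS = 1e-8


def oracle_ce(p, y):
    total = 0.0
    for b in range(len(y)):
        total += -math.log(p[b][y[b]])
    return total / len(y)


def _pearson(x, y, eps=EPS):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((x[i] - mx) * (y[i] - my) for i in range(n)) / n
    sx = math.sqrt(sum((x[i] - mx) ** 2 for i in range(n)) / n)
    sy = math.sqrt(sum((y[i] - my) ** 2 for i in range(n)) / n)
    return cov / (sx * sy + eps)


def oracle_pr(dq, dr, eps=EPS):
    nq, m = dq.shape
    nr = dr.shape[0]
    qbar = [sum(dq[b][j] for b in range(nq)) / nq for j in range(m)]
    rbar = [sum(dr[b][j] for b in range(nr)) / nr for j in range(m)]
    dev = sum(sum(abs(dq[b][j] - qbar[j]) for j in range(m)) for b in range(nq)) / nq
    term1 = 1.0 / (dev + eps)
    corr_q = sum(
        abs(_pearson([dq[b][i] for b in range(nq)], [dq[b][j] for b in range(nq)]))
        for i in range(m) for j in range(m) if i != j
    ) / (m * m)
    corr_r = sum(
        abs(_pearson([dr[b][i] for b in range(nr)], [dr[b][j] for b in range(nr)]))
        for i in range(m) for j in range(m) if i != j
    ) / (m * m)
    mean_q = sum(abs(v) for v in qbar) / m
    mean_r = sum(abs(v) for v in rbar) / m
    return term1 + corr_q + corr_r + mean_q + mean_r


def _cos(x, y, eps=EPS):
    nx = math.sqrt(sum(v * v for v in x))
    ny = math.sqrt(sum(v * v for v in y))
    return sum(a / (nx + eps) * (b / (ny + eps)) for a, b in zip(x, y))


def oracle_cl(dq, dpos, tau):
    n = dq.shape[0]
    total = 0.0
    for i in range(n):
        num = math.exp(_cos(dq[i], dpos[i]) / tau)
        den = num
        for j in range(n):
            if j != i:
                den += math.exp(_cos(dq[i], dq[j]) / tau)
        total += -math.log(num / den)
    return total / n


def oracle_fa(dq, dr, p_frac):
    nq = dq.shape[0]
    best = []
    for b in range(nq):
        best.append(max(_cos(dq[b], dr[i]) for i in range(dr.shape[0])))
    n_sel = max(1, int(math.floor(p_frac * nq + 1e-9)))
    chosen = sorted(range(nq), key=lambda b: (-best[b], b))[:n_sel]
    return -sum(best[b] for b in chosen) / n_sel


def oracle_sc(d, labels, a, centers):
    n, m = d.shape
    total = 0.0
    for i in range(n):
        for j in range(m):
            total += a[i][j] * (d[i][j] - centers[labels[i]][j]) ** 2
    return total / n


def oracle_knn(x, k):
    """Brute-force kNN on rows of x, self excluded, ties by index."""
    n = x.shape[0]
    out = []
    for i in range(n):
        dists = []
        for j in range(n):
            if j == i:
                continue
            dists.append((math.sqrt(sum((x[i][f] - x[j][f]) ** 2 for f in range(x.shape[1]))), j))
        dists.sort()
        out.append([j for _, j in dists[: min(k, n - 1)]])
    return np.array(out)


def oracle_confusion_metrics(true_labels, predicted_labels):
    """(accuracy, macro_f1 over classes present in truth) by direct counting."""
    n = len(true_labels)
    acc = sum(t == p for t, p in zip(true_labels, predicted_labels)) / n
    classes = sorted(set(true_labels))
    f1s = []
    for c in classes:
        tp = sum(t == c and p == c for t, p in zip(true_labels, predicted_labels))
        fp = sum(t != c and p == c for t, p in zip(true_labels, predicted_labels))
        fn = sum(t == c and p != c for t, p in zip(true_labels, predicted_labels))
        f1s.append(0.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn))
    return acc, sum(f1s) / len(f1s)


def oracle_auroc(is_novel, scores):
    """Pairwise comparison AUROC with midrank tie handling."""
    pos = [s for s, v in zip(scores, is_novel) if v]
    neg = [s for s, v in zip(scores, is_novel) if not v]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_oscr(true_labels, predicted_labels, confidence, novel_mask):
    """Threshold sweep at every distinct confidence, trapezoid area."""
    n_known = sum(not v for v in novel_mask)
    n_novel = sum(bool(v) for v in novel_mask)
    points = [(0.0, 0.0)]
    for theta in sorted(set(confidence), reverse=True):
        ccr = sum(
            (not novel_mask[i]) and predicted_labels[i] == true_labels[i] and confidence[i] >= theta
            for i in range(len(true_labels))
        ) / n_known
        fpr = sum(novel_mask[i] and confidence[i] >= theta for i in range(len(true_labels))) / n_novel
        points.append((fpr, ccr))
    full_ccr = sum((not novel_mask[i]) and predicted_labels[i] == true_labels[i] for i in range(len(true_labels))) / n_known
    points.append((1.0, full_ccr))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area
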