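"""Brute-force KNN oracle, written independently of the package implementation.

Plain-loop arithmetic only: no shared distance/vote helpers.  Conventions
match the documented contract: stable index order for neighbour ties, and
vote ties go to the smaller label.
"""

import math


def oracle_snr(train, labels):
    n_feat = len(train[0])
    classes = sorted(set(labels))
    groups = {c: [row for row, l in zip(train, labels) if l == c] for c in classes}
    w = []
    for f in range(n_feat):
        a = [row[f] for row in groups[classes[0]]]
        b = [row[f] for row in groups[classes[1]]]
        ma, mb = sum(a) / len(a), sum(b) / len(b)
        sa = math.sqrt(sum((x - ma) ** 2 for x in a) / (len(a) - 1))
        sb = math.sqrt(sum((x - mb) ** 2 for x in b) / (len(b) - 1))
        num, den = abs(ma - mb), sa + sb
        if den > 0:
            w.append(num / den)
        elif num > 0:
            w.append(num / 1e-12)
        else:
            w.append(0.0)
    s = sum(w)
    if s > 0:
        return [x / s for x in w]
    return [1.0 / n_feat] * n_feat


def oracle_predict(train, labels, test, k, k_scope, metric, feature_weighting,
                   vote_weighting):
    if feature_weighting == "snr":
        fw = oracle_snr(train, labels)
    else:
        fw = [1.0] * len(test)
    dists = []
    for row in train:
        if metric == "manhattan":
            d = sum(wf * abs(x - t) for wf, x, t in zip(fw, row, test))
        else:
            d = math.sqrt(sum((wf * abs(x - t)) ** 2 for wf, x, t in zip(fw, row, test)))
        dists.append(d)
    order = sorted(range(len(train)), key=lambda i: (dists[i], i))
    classes = sorted(set(labels))
    if k_scope == "all_neighbors":
        nb = order[:k]
    else:
        nb = []
        for c in classes:
            nb.extend([i for i in order if labels[i] == c][:k])
    nd = [dists[i] for i in nb]
    if vote_weighting == "uniform":
        vw = [1.0] * len(nb)
    elif vote_weighting == "inverse_distance":
        vw = [1.0 / max(d, 1e-12) for d in nd]
    else:
        dmax, dmin = max(nd), min(nd)
        if dmax <= 0:
            vw = [1.0] * len(nb)
        else:
            vw = [(dmax - (d - dmin)) / dmax for d in nd]
    votes = {c: 0.0 for c in classes}
    for i, wv in zip(nb, vw):
        votes[labels[i]] += wv
    top = max(votes.values())
    return min(c for c in classes if votes[c] == top)
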