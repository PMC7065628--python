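"""Independent brute-force oracles shared across test modules."""

import numpy as np


def exhaustive_metrics(scores, labels, threshold=0.5):
    """Brute-force oracle: confusion by direct counting; AUC by pairwise
    rank comparison; AP by the stepwise precision sum over unique scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    auc = wins / (len(pos) * len(neg))
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    ap, recall_prev, tp_c = 0.0, 0.0, 0
    for thr in np.unique(s):  # ascending; iterate descending
        pass
    for thr in sorted(set(s), reverse=True):
        sel = s >= thr
        tp_c = int(l[sel].sum())
        prec = tp_c / sel.sum()
        rec = tp_c / len(pos)
        ap += (rec - recall_prev) * prec
        recall_prev = rec
    return dict(tp=tp, fp=fp, tn=tn, fn=fn,
                accuracy=(tp + tn) / len(labels),
                precision=tp / (tp + fp) if tp + fp else 0.0,
                recall=tp / (tp + fn) if tp + fn else 0.0,
                auc=auc, average_precision=ap)


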