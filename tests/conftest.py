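import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_prob_maps(rng, s, k, h, w, n=1):
    """A list of S random normalized probability maps of shape (n,k,h,w)."""
    maps = []
    for _ in range(s):
        x = rng.random((n, k, h, w)).astype(np.float32) + 0.05
        maps.append(x / x.sum(axis=1, keepdims=True))
    return maps


# ---------------------------------------------------------------------------
# explicit loop oracles (kept deliberately naive and independent of dcseg)
# ---------------------------------------------------------------------------

def oracle_avg(maps):
    acc = np.zeros_like(maps[0], dtype=np.float64)
    for m in maps:
        acc += m
    return acc / len(maps)


def oracle_hc(maps):
    """Mean over levels of (mean over batch+pixels of per-pixel squared L2)."""
    avg = oracle_avg(maps)
    total = 0.0
    for m in maps:
        n, k, h, w = m.shape
        acc = 0.0
        for b in range(n):
            for i in range(h):
                for j in range(w):
                    d = 0.0
                    for c in range(k):
                        d += (m[b, c, i, j] - avg[b, c, i, j]) ** 2
                    acc += d
        total += acc / (n * h * w)
    return total / len(maps)


def oracle_kl(maps, eps=1e-8):
    avg = oracle_avg(maps)
    s = len(maps)
    n, k, h, w = maps[0].shape
    d = np.zeros((s, n, h, w))
    for si, m in enumerate(maps):
        for b in range(n):
            for i in range(h):
                for j in range(w):
                    acc = 0.0
                    for c in range(k):
                        p = max(m[b, c, i, j], eps)
                        q = max(avg[b, c, i, j], eps)
                        acc += p * np.log(p / q)
                    d[si, b, i, j] = max(acc, 0.0)
    return d


def oracle_urc(maps):
    avg = oracle_avg(maps)
    d = oracle_kl(maps)
    w_ = np.exp(-d)
    total = 0.0
    for si, m in enumerate(maps):
        n, k, h, wd = m.shape
        num = den = 0.0
        for b in range(n):
            for i in range(h):
                for j in range(wd):
                    sq = 0.0
                    for c in range(k):
                        sq += (m[b, c, i, j] - avg[b, c, i, j]) ** 2
                    num += sq * w_[si, b, i, j]
                    den += w_[si, b, i, j]
        total += num / den
    return total / len(maps)


def oracle_cr(p0, p1):
    n, k, h, w = p0.shape
    acc = 0.0
    for b in range(n):
        for i in range(h):
            for j in range(w):
                for c in range(k):
                    acc += (p0[b, c, i, j] - p1[b, c, i, j]) ** 2
    return acc / (n * h * w)


def oracle_sup(maps, mask, eps=1e-8, smooth=1e-5):
    """Sum over levels of 0.5*CE + 0.5*Dice, unit level weights."""
    total = 0.0
    for m in maps:
        n, k, h, w = m.shape
        ce = 0.0
        for b in range(n):
            for i in range(h):
                for j in range(w):
                    ce -= np.log(max(m[b, mask[b, i, j], i, j], eps))
        ce /= n * h * w
        dice = 0.0
        for c in range(k):
            inter = denom = 0.0
            for b in range(n):
                for i in range(h):
                    for j in range(w):
                        g = 1.0 if mask[b, i, j] == c else 0.0
                        inter += m[b, c, i, j] * g
                        denom += m[b, c, i, j] + g
            dice += 1.0 - (2 * inter + smooth) / (denom + smooth)
        dice /= k
        total += 0.5 * ce + 0.5 * dice
    return total


def oracle_confusion(pred, gt, n_classes):
    h, w = pred.shape
    tp = np.zeros(n_classes, int)
    fp = np.zeros(n_classes, int)
    fn = np.zeros(n_classes, int)
    tn = np.zeros(n_classes, int)
    for c in range(n_classes):
        for i in range(h):
            for j in range(w):
                p, g = pred[i, j] == c, gt[i, j] == c
                if p and g:
                    tp[c] += 1
                elif p:
                    fp[c] += 1
                elif g:
                    fn[c] += 1
                else:
                    tn[c] += 1
    return tp, fp, fn, tn
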