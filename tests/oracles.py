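"""Independent brute-force reference implementations used by the tests.

Everything here is written as plain scalar loops (or direct formula
transcriptions) so it shares no code path with the vectorized package
implementations it checks.
"""

import math

import numpy as np


def point_in_polygon(px, py, poly):
    """Even-odd rule for a single point; points on an edge count inside."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # on-segment check
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if (
            abs(cross) < 1e-9
            and min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9
            and min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9
        ):
            return True
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def rasterize_scan(shapes, height, width):
    """Per-pixel scan rasterizer; LA=2 first, MR=1 painted on top."""
    label_of = {"LA": 2, "MR": 1}
    mask = np.zeros((height, width), dtype=np.int64)
    for want in (2, 1):
        for shape in shapes:
            if label_of[shape["label"]] != want:
                continue
            poly = shape["points"]
            for r in range(height):
                for c in range(width):
                    if point_in_polygon(c + 0.5, r + 0.5, poly):
                        mask[r, c] = want
    return mask


def confusion_loops(pred, truth, k):
    cm = np.zeros((k, k), dtype=np.int64)
    for p, t in zip(np.asarray(pred).ravel(), np.asarray(truth).ravel()):
        cm[int(t), int(p)] += 1
    return cm


def one_vs_rest_counts(cm, c):
    k = cm.shape[0]
    tp = fp = fn = tn = 0
    for i in range(k):
        for j in range(k):
            if i == c and j == c:
                tp += cm[i, j]
            elif j == c:
                fp += cm[i, j]
            elif i == c:
                fn += cm[i, j]
            else:
                tn += cm[i, j]
    return tp, fp, fn, tn


def directional_pool_loops(x):
    n, c, h, w = x.shape
    ph = np.zeros((n, c, h, 1))
    pw = np.zeros((n, c, 1, w))
    for ni in range(n):
        for ci in range(c):
            for i in range(h):
                ph[ni, ci, i, 0] = sum(x[ni, ci, i, j] for j in range(w)) / w
            for j in range(w):
                pw[ni, ci, 0, j] = sum(x[ni, ci, i, j] for i in range(h)) / h
    return ph, pw


def dice_per_class_loops(probs, labels, classes, smooth):
    """One-vs-rest Dice loss per class, averaged, with explicit loops."""
    total = 0.0
    b, k, h, w = probs.shape
    for c in classes:
        num = 0.0
        den = 0.0
        for bi in range(b):
            for i in range(h):
                for j in range(w):
                    p = probs[bi, c, i, j]
                    g = 1.0 if labels[bi, i, j] == c else 0.0
                    num += p * g
                    den += p * p + g * g
        total += 1.0 - (2.0 * num + smooth) / (den + smooth)
    return total / len(classes)


def focal_loops(p_true, alpha, gamma):
    vals = []
    for p in np.asarray(p_true, dtype=np.float64).ravel():
        p = min(max(p, 1e-7), 1 - 1e-7)
        vals.append(-alpha * (1 - p) ** gamma * math.log(p))
    return sum(vals) / len(vals)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _spatial_softmax(z):
    e = np.exp(z - z.max())
    return e / e.sum()


def ema_forward_loops(module, x):
    """Re-evaluate an EMA module with per-group scalar/loop arithmetic in
    float64 using the module's own weights."""
    cfg = module.cfg
    b, C, H, W = x.shape
    g = cfg.groups
    c = C // g
    xr = x.astype(np.float64).reshape(b * g, c, H, W)
    out = np.zeros_like(xr)
    w1 = module.conv1x1.weight.data.astype(np.float64)[:, :, 0, 0]
    b1 = module.conv1x1.bias.data.astype(np.float64)
    w3 = module.conv3x3.weight.data.astype(np.float64)
    b3 = module.conv3x3.bias.data.astype(np.float64)
    gnw = module.gn.weight.data.astype(np.float64)
    gnb = module.gn.bias.data.astype(np.float64)
    for ni in range(b * g):
        xg = xr[ni]
        ph = xg.mean(axis=2)  # c, H
        pw = xg.mean(axis=1)  # c, W
        prof = np.concatenate([ph, pw], axis=1)  # c, H+W
        a = w1 @ prof + b1[:, None]
        sh = _sigmoid(a[:, :H])
        sw = _sigmoid(a[:, H:])
        gated = xg * sh[:, :, None] * sw[:, None, :]
        mu = gated.mean(axis=(1, 2), keepdims=True)
        var = gated.var(axis=(1, 2), keepdims=True)
        g1 = (gated - mu) / np.sqrt(var + module.gn.eps)
        g1 = g1 * gnw[:, None, None] + gnb[:, None, None]
        xp = np.pad(xg, ((0, 0), (1, 1), (1, 1)))
        g3 = np.zeros_like(xg)
        for o in range(c):
            for i in range(H):
                for j in range(W):
                    g3[o, i, j] = (w3[o] * xp[:, i : i + 3, j : j + 3]).sum() + b3[o]

        def cross(A, B):
            desc = A.mean(axis=(1, 2))
            return _spatial_softmax(desc @ B.reshape(c, H * W))

        pre = cross(g1, g3) + cross(g3, g1)
        if cfg.variant == "improved":
            wn = module.conv1x1_new.weight.data.astype(np.float64)[:, :, 0, 0]
            bn = module.conv1x1_new.bias.data.astype(np.float64)
            xn = np.einsum("oc,chw->ohw", wn, xg) + bn[:, None, None]
            pre = pre + cross(g1, xn) + cross(xn, g3)
            if cfg.prenorm:
                fw = float(module.fuse_norm.weight.data[0])
                fb = float(module.fuse_norm.bias.data[0])
                pre = (pre - pre.mean()) / np.sqrt(pre.var() + module.fuse_norm.eps)
                pre = pre * fw + fb
        wmap = _sigmoid(pre).reshape(H, W)
        out[ni] = xg * wmap
    return out.reshape(b, C, H, W)
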