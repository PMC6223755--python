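"""Independent nested-loop reference implementations used as oracles.

These deliberately share no code with the package: plain Python loops over
array entries, so agreement with the vectorized implementations is a real
cross-check.
"""

import numpy as np


def sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def conv_sigmoid_pool(x, w, b):
    """Same-zero-padded conv + sigmoid + 2x2 max pool, scalar loops."""
    H, W, C = x.shape
    f, _, _, F = w.shape
    pl = (f - 1) // 2
    a = np.zeros((H, W, F))
    for i in range(H):
        for j in range(W):
            for o in range(F):
                acc = b[o]
                for u in range(f):
                    for v in range(f):
                        ii, jj = i + u - pl, j + v - pl
                        if 0 <= ii < H and 0 <= jj < W:
                            for c in range(C):
                                acc += x[ii, jj, c] * w[u, v, c, o]
                a[i, j, o] = sigmoid(acc)
    out = np.zeros((H // 2, W // 2, F))
    for i in range(H // 2):
        for j in range(W // 2):
            for o in range(F):
                out[i, j, o] = a[2 * i : 2 * i + 2, 2 * j : 2 * j + 2, o].max()
    return out


def unpool_deconv(z, w, b):
    """2x2 copy-unpool + same-zero-padded conv + sigmoid, scalar loops."""
    h, wd, F = z.shape
    f, _, _, C = w.shape
    pl = (f - 1) // 2
    u_map = np.zeros((2 * h, 2 * wd, F))
    for i in range(h):
        for j in range(wd):
            u_map[2 * i : 2 * i + 2, 2 * j : 2 * j + 2, :] = z[i, j, :]
    H, W = 2 * h, 2 * wd
    y = np.zeros((H, W, C))
    for i in range(H):
        for j in range(W):
            for c in range(C):
                acc = b[c]
                for u in range(f):
                    for v in range(f):
                        ii, jj = i + u - pl, j + v - pl
                        if 0 <= ii < H and 0 <= jj < W:
                            for o in range(F):
                                acc += u_map[ii, jj, o] * w[u, v, o, c]
                y[i, j, c] = sigmoid(acc)
    return y


def sum_squared_diff(a, b):
    total = 0.0
    for x, y in zip(a.ravel(), b.ravel()):
        total += (y - x) ** 2
    return total


def position_entropy(z):
    total = 0.0
    H, W, F = z.shape
    for i in range(H):
        for j in range(W):
            t = float(z[i, j].sum())
            if t <= 0:
                continue
            for f in range(F):
                r = z[i, j, f] / t
                if r > 0:
                    total -= r * np.log(r)
    return total


def risa_p(x, C, H):
    k, n = C.shape
    s = [sum(C[m, j] * x[j] for j in range(n)) for m in range(k)]
    return np.array([
        np.sqrt(sum(H[i, m] * s[m] ** 2 for m in range(k)))
        for i in range(H.shape[0])
    ])


def risa_obj(batch, C, H, lam):
    N = len(batch)
    total = 0.0
    for x in batch:
        y = C.T @ (C @ x) - x
        total += float(y @ y) / N
        total += lam * float(risa_p(x, C, H).sum())
    return total


def subpane_dense(z, G, W, b):
    """Shared dense map over one G x G subpane grid, scalar loops."""
    Hz, Wz, F = z.shape
    h, w = Hz // G, Wz // G
    d_r = b.shape[0]
    out = np.zeros((G, G, d_r))
    for gr in range(G):
        for gc in range(G):
            flat = z[gr * h : (gr + 1) * h, gc * w : (gc + 1) * w, :].ravel()
            for o in range(d_r):
                acc = b[o]
                for i, v in enumerate(flat):
                    acc += v * W[i, o]
                out[gr, gc, o] = sigmoid(acc)
    return out
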