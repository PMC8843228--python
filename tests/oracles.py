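"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written from the textbook definitions
with explicit loops/sums, sharing no code path with the package.
"""

import itertools
import math

import numpy as np


def brute_glcm(window, G):
    """Eight-direction symmetric co-occurrence matrix by pair counting."""
    window = np.asarray(window)
    nx, ny = window.shape
    C = np.zeros((G, G))
    dirs = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1),
            (-1, -1)]
    for i in range(nx):
        for j in range(ny):
            for dx, dy in dirs:
                x, y = i + dx, j + dy
                if 0 <= x < nx and 0 <= y < ny:
                    C[window[i, j] - 1, window[x, y] - 1] += 1
    total = C.sum()
    if total == 0:
        g = window[0, 0] - 1
        C[g, g] = 1.0
        total = 1.0
    return C / total


def brute_haralick(P):
    """The 19 texture statistics from explicit double sums.

    Conventions match the package's documented choices: natural logs,
    0 log 0 = 0, difference variance = variance of the difference
    histogram, sum of squares = marginal variance, degenerate
    correlation / information measures = 0.
    """
    P = np.asarray(P, dtype=float)
    G = P.shape[0]
    lv = np.arange(1, G + 1, dtype=float)

    px = np.array([P[i, :].sum() for i in range(G)])
    py = np.array([P[:, j].sum() for j in range(G)])
    mux = sum(lv[i] * px[i] for i in range(G))
    muy = sum(lv[j] * py[j] for j in range(G))
    varx = sum((lv[i] - mux) ** 2 * px[i] for i in range(G))
    vary = sum((lv[j] - muy) ** 2 * py[j] for j in range(G))

    autoc = contrast = dissim = homog = invdiff = 0.0
    energy = entropy = 0.0
    maxprob = 0.0
    for i in range(G):
        for j in range(G):
            p = P[i, j]
            d = lv[i] - lv[j]
            autoc += p * lv[i] * lv[j]
            contrast += p * d * d
            dissim += p * abs(d)
            homog += p / (1 + d * d)
            invdiff += p / (1 + abs(d))
            energy += p * p
            if p > 0:
                entropy -= p * math.log(p)
            maxprob = max(maxprob, p)

    psum = {}
    pdiff = {}
    for i in range(G):
        for j in range(G):
            if P[i, j] > 0:
                psum[int(lv[i] + lv[j])] = psum.get(int(lv[i] + lv[j]),
                                                    0.0) + P[i, j]
                d = int(abs(lv[i] - lv[j]))
                pdiff[d] = pdiff.get(d, 0.0) + P[i, j]
    sum_avg = sum(k * v for k, v in psum.items())
    sum_ent = -sum(v * math.log(v) for v in psum.values() if v > 0)
    sum_var = sum((k - sum_avg) ** 2 * v for k, v in psum.items())
    mu2 = mux + muy
    shade = sum((k - mu2) ** 3 * v for k, v in psum.items())
    prom = sum((k - mu2) ** 4 * v for k, v in psum.items())
    dmean = sum(k * v for k, v in pdiff.items())
    diff_var = sum((k - dmean) ** 2 * v for k, v in pdiff.items())
    diff_ent = -sum(v * math.log(v) for v in pdiff.values() if v > 0)

    sig = math.sqrt(varx * vary)
    corr = (autoc - mux * muy) / sig if sig > 1e-12 else 0.0

    hx = -sum(p * math.log(p) for p in px if p > 0)
    hy = -sum(p * math.log(p) for p in py if p > 0)
    hxy1 = 0.0
    hxy2 = 0.0
    for i in range(G):
        for j in range(G):
            pipj = px[i] * py[j]
            if pipj > 0:
                hxy2 -= pipj * math.log(pipj)
                if P[i, j] > 0:
                    hxy1 -= P[i, j] * math.log(pipj)
    hmax = max(hx, hy)
    imc1 = (entropy - hxy1) / hmax if hmax > 1e-12 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))

    return np.array([
        autoc, prom, shade, contrast, corr, diff_ent, diff_var, dissim,
        energy, entropy, homog, imc1, imc2, invdiff, maxprob,
        sum_avg, sum_ent, varx, sum_var,
    ])


def compositions(total, parts):
    """All tuples of `parts` nonnegative ints summing to `total`."""
    if parts == 1:
        yield (total,)
        return
    for z in range(total + 1):
        for rest in compositions(total - z, parts - 1):
            yield (z,) + rest


def stars_and_bars(total, parts):
    return math.comb(total + parts - 1, parts - 1)


def exhaustive_weight_search(U_list, truths, t, objective):
    """Plain-loop brute force over the weight simplex."""
    s = U_list[0].shape[1]
    M = round(1.0 / t)
    best = None
    for comp in compositions(M, s):
        w = np.array(comp, dtype=float) * t
        errs = []
        for U, truth in zip(U_list, truths):
            score = U @ w
            n = 100.0 * np.sum(score > 0.5) / U.shape[0]
            errs.append(abs(n - truth))
        val = (sum(errs) / len(errs)) if objective == "min_avg" \
            else max(errs)
        if best is None or val < best[1] - 1e-15:
            best = (w, val)
    return best


def discrete_tofts(t, cp, ktrans_per_min, ve, refine=200):
    """Tissue curve by fine-grid numerical convolution of the AIF."""
    t = np.asarray(t, dtype=float)
    cp = np.asarray(cp, dtype=float)
    tf = np.linspace(t[0], t[-1], (len(t) - 1) * refine + 1)
    cpf = np.interp(tf, t, cp)
    kt = ktrans_per_min / 60.0
    kep = kt / ve
    dt = tf[1] - tf[0]
    out = np.zeros_like(t)
    for m, tm in enumerate(t):
        mask = tf <= tm + 1e-12
        tau = tf[mask]
        integrand = cpf[mask] * np.exp(-kep * (tm - tau))
        out[m] = kt * np.trapezoid(integrand, tau)
    return out
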