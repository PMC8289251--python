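"""Independent brute-force oracles used by the test suite.

Everything here is written straight from the definitions, with plain Python
loops and no reuse of the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_bruteforce(levels: np.ndarray, delta, n_levels: int) -> np.ndarray:
    """Enumerate every in-mask voxel pair separated by delta, both orders."""
    counts = np.zeros((n_levels, n_levels))
    nz, ny, nx = levels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                a = levels[z, y, x]
                if a == 0:
                    continue
                z2, y2, x2 = z + delta[0], y + delta[1], x + delta[2]
                if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                    continue
                b = levels[z2, y2, x2]
                if b == 0:
                    continue
                counts[a - 1, b - 1] += 1
                counts[b - 1, a - 1] += 1
    return counts


def glrlm_bruteforce(levels: np.ndarray, delta, n_levels: int) -> np.ndarray:
    """Walk every lattice line along delta and record maximal runs."""
    shape = levels.shape
    runs: list[tuple[int, int]] = []
    # starting points: voxels with no in-bounds predecessor along delta
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                pz, py, px = z - delta[0], y - delta[1], x - delta[2]
                if (0 <= pz < shape[0] and 0 <= py < shape[1]
                        and 0 <= px < shape[2]):
                    continue
                # walk the full line
                cz, cy, cx = z, y, x
                current_level, length = 0, 0
                while (0 <= cz < shape[0] and 0 <= cy < shape[1]
                       and 0 <= cx < shape[2]):
                    lv = levels[cz, cy, cx]
                    if lv == current_level and lv != 0:
                        length += 1
                    else:
                        if current_level != 0:
                            runs.append((current_level, length))
                        current_level, length = lv, (1 if lv != 0 else 0)
                    cz, cy, cx = cz + delta[0], cy + delta[1], cx + delta[2]
                if current_level != 0:
                    runs.append((current_level, length))
    lmax = max((l for _, l in runs), default=1)
    counts = np.zeros((n_levels, lmax), dtype=int)
    for g, l in runs:
        counts[g - 1, l - 1] += 1
    return counts


def glcm_features_reference(p: np.ndarray) -> dict[str, float]:
    """Scalar GLCM features evaluated term by term from the formula sheet."""
    g = p.shape[0]
    px = [sum(p[i, j] for j in range(g)) for i in range(g)]
    mu = sum((i + 1) * px[i] for i in range(g))
    sig2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(g))

    def xlog2(v):
        return v * math.log2(v) if v > 0 else 0.0

    p_diff = [0.0] * g
    p_sum = [0.0] * (2 * g - 1)
    for i in range(g):
        for j in range(g):
            p_diff[abs(i - j)] += p[i, j]
            p_sum[i + j] += p[i, j]

    out: dict[str, float] = {}
    out["autocorrelation"] = sum(
        (i + 1) * (j + 1) * p[i, j] for i in range(g) for j in range(g)
    )
    out["cluster_shade"] = sum(
        ((i + 1) + (j + 1) - 2 * mu) ** 3 * p[i, j]
        for i in range(g) for j in range(g)
    )
    out["cluster_prominence"] = sum(
        ((i + 1) + (j + 1) - 2 * mu) ** 4 * p[i, j]
        for i in range(g) for j in range(g)
    )
    out["contrast"] = sum(
        (i - j) ** 2 * p[i, j] for i in range(g) for j in range(g)
    )
    out["correlation"] = (
        (out["autocorrelation"] - mu * mu) / sig2 if sig2 > 0 else 1.0
    )
    out["variance"] = sum(
        (i + 1 - mu) ** 2 * p[i, j] for i in range(g) for j in range(g)
    )
    out["dissimilarity"] = sum(
        abs(i - j) * p[i, j] for i in range(g) for j in range(g)
    )
    out["diff_entropy"] = -sum(xlog2(q) for q in p_diff)
    mu_d = sum(k * p_diff[k] for k in range(g))
    out["diff_variance"] = sum((k - mu_d) ** 2 * p_diff[k] for k in range(g))
    out["energy"] = sum(p[i, j] ** 2 for i in range(g) for j in range(g))
    out["entropy"] = -sum(
        xlog2(p[i, j]) for i in range(g) for j in range(g)
    )
    out["homogeneity1"] = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(g) for j in range(g)
    )
    out["homogeneity2"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(g) for j in range(g)
    )
    hxy = out["entropy"]
    hx = -sum(xlog2(q) for q in px)
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * px[j])
        for i in range(g) for j in range(g)
        if p[i, j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = -sum(
        xlog2(px[i] * px[j]) for i in range(g) for j in range(g)
    )
    out["imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = -2.0 * (hxy2 - hxy)
    out["imc2"] = math.sqrt(1.0 - math.exp(arg)) if arg < 0 else 0.0
    out["max_prob"] = max(p[i, j] for i in range(g) for j in range(g))
    sa = sum((k + 2) * p_sum[k] for k in range(2 * g - 1))
    out["sum_average"] = sa
    out["sum_entropy"] = -sum(xlog2(q) for q in p_sum)
    out["sum_variance"] = sum(
        (k + 2 - sa) ** 2 * p_sum[k] for k in range(2 * g - 1)
    )
    return out


def glrlm_features_reference(r: np.ndarray) -> dict[str, float]:
    """Scalar run-length features evaluated straight from the formulas."""
    ng, nl = r.shape
    nr = float(r.sum())
    npix = sum(r[i, j] * (j + 1) for i in range(ng) for j in range(nl))

    def s(term):
        return sum(
            term(i + 1, j + 1) * r[i, j] for i in range(ng) for j in range(nl)
        )

    return {
        "sre": s(lambda g, l: 1 / l**2) / nr,
        "lre": s(lambda g, l: l**2) / nr,
        "gln": sum(r[i, :].sum() ** 2 for i in range(ng)) / nr,
        "rln": sum(r[:, j].sum() ** 2 for j in range(nl)) / nr,
        "rp": nr / npix,
        "lglre": s(lambda g, l: 1 / g**2) / nr,
        "hglre": s(lambda g, l: g**2) / nr,
        "srlgle": s(lambda g, l: 1 / (g**2 * l**2)) / nr,
        "srhgle": s(lambda g, l: g**2 / l**2) / nr,
        "lrlgle": s(lambda g, l: l**2 / g**2) / nr,
        "lrhgle": s(lambda g, l: g**2 * l**2) / nr,
    }


def auc_bruteforce(scores, labels) -> float:
    """Concordant pairs plus half ties over all cross-class pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))
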