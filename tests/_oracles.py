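"""Independent brute-force oracles for the numerical acceptance checks.

Deliberately naive implementations, written straight from the definitions:

* a double-loop masked symmetric GLCM accumulator plus literal-formula
  second-order features (explicit sums over matrix cells), and
* a least-squares projection-matrix factorial ANOVA (Type-III partial sums
  of squares via model comparison on an explicitly built sum-coded design
  matrix).

They share no code with the package beyond numpy/scipy primitives.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats

DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))


# ---------------------------------------------------------------------------
# GLCM oracle
# ---------------------------------------------------------------------------

def oracle_glcm(
    pixels: np.ndarray,
    mask: np.ndarray,
    levels: int = 256,
    displacement: int = 1,
    directions=DIRECTIONS,
) -> np.ndarray:
    """Masked symmetric GLCM by explicit pixel-pair enumeration."""
    g = pixels.astype(np.int64)
    if levels != 256:
        g = (g * levels) // 256
    h, w = g.shape
    counts = np.zeros((levels, levels), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in directions:
                for s in (1, -1):
                    rr = r + s * dr * displacement
                    cc = c + s * dc * displacement
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                        counts[g[r, c], g[rr, cc]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs")
    return counts / total


def oracle_features(p: np.ndarray) -> dict[str, float]:
    """The 15 second-order variables by literal formula sums (fsum)."""
    L = p.shape[0]
    p_x = [math.fsum(p[i, j] for j in range(L)) for i in range(L)]
    p_y = [math.fsum(p[i, j] for i in range(L)) for j in range(L)]
    mu_x = math.fsum(i * p_x[i] for i in range(L))
    mu_y = math.fsum(j * p_y[j] for j in range(L))
    var_x = math.fsum((i - mu_x) ** 2 * p_x[i] for i in range(L))
    var_y = math.fsum((j - mu_y) ** 2 * p_y[j] for j in range(L))
    sd = math.sqrt(var_x * var_y)

    cells = [(i, j) for i in range(L) for j in range(L)]

    p_sum = [0.0] * (2 * L - 1)
    p_diff = [0.0] * L
    for i, j in cells:
        p_sum[i + j] += p[i, j]
        p_diff[abs(i - j)] += p[i, j]
    mu_sum = math.fsum(k * p_sum[k] for k in range(2 * L - 1))

    def xlogx(v: float) -> float:
        return v * math.log(v) if v > 0 else 0.0

    p0 = math.fsum(p[i, i] for i in range(L))
    pe = math.fsum(p_x[k] * p_y[k] for k in range(L))
    kappa = 1.0 if pe == 1.0 else (p0 - pe) / (1.0 - pe)
    if sd == 0:
        correlation = 0.0
    else:
        correlation = math.fsum(
            (i - mu_x) * (j - mu_y) * p[i, j] for i, j in cells
        ) / sd

    return {
        "cluster_prominence": math.fsum(
            (i + j - mu_x - mu_y) ** 4 * p[i, j] for i, j in cells
        ),
        "cluster_shade": math.fsum(
            (i + j - mu_x - mu_y) ** 3 * p[i, j] for i, j in cells
        ),
        "correlation": correlation,
        "diagonal_moment": math.fsum(
            math.sqrt(abs(i - j)) * (i + j - mu_x - mu_y) * p[i, j]
            for i, j in cells
        ),
        "difference_energy": math.fsum(v * v for v in p_diff),
        "difference_entropy": -math.fsum(xlogx(v) for v in p_diff),
        "energy": math.fsum(p[i, j] ** 2 for i, j in cells),
        "entropy": -math.fsum(xlogx(p[i, j]) for i, j in cells),
        "inertia": math.fsum((i - j) ** 2 * p[i, j] for i, j in cells),
        "inverse_different_moment": math.fsum(
            p[i, j] / (1.0 + (i - j) ** 2) for i, j in cells
        ),
        "kappa": kappa,
        "maximum_probability": max(p[i, j] for i, j in cells),
        "sum_energy": math.fsum(v * v for v in p_sum),
        "sum_entropy": -math.fsum(xlogx(v) for v in p_sum),
        "sum_variance": math.fsum(
            (k - mu_sum) ** 2 * p_sum[k] for k in range(2 * L - 1)
        ),
    }


# ---------------------------------------------------------------------------
# Factorial ANOVA oracle
# ---------------------------------------------------------------------------

def _sum_coded_columns(values: np.ndarray) -> np.ndarray:
    """Sum (deviation) coding: one column per non-reference level."""
    levels = sorted(set(values.tolist()))
    ref = levels[-1]
    cols = []
    for lv in levels[:-1]:
        col = np.where(values == lv, 1.0, np.where(values == ref, -1.0, 0.0))
        cols.append(col)
    return np.column_stack(cols)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def oracle_anova(data, response: str, factors: list[str]) -> dict[str, dict]:
    """Type-III factorial ANOVA by explicit model comparison.

    Builds the sum-coded design matrix column block per effect (main effects
    and all interactions), fits the full model by least squares, and for
    each effect refits without that effect's block.  Returns per-effect
    df, sum_sq, F and p plus the residual df/SS.
    """
    y = data[response].to_numpy(float)
    n = len(y)
    blocks: dict[str, np.ndarray] = {}
    mains = {f: _sum_coded_columns(data[f].to_numpy()) for f in factors}
    names = []
    for k in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, k):
            name = ":".join(combo)
            names.append(name)
            block = mains[combo[0]]
            for f in combo[1:]:
                block = np.concatenate(
                    [block[:, [i]] * mains[f] for i in range(block.shape[1])],
                    axis=1,
                )
            blocks[name] = block

    X_full = np.concatenate([np.ones((n, 1))] + [blocks[nm] for nm in names], axis=1)
    rss_full = _rss(X_full, y)
    df_res = n - X_full.shape[1]
    ms_res = rss_full / df_res

    out: dict[str, dict] = {}
    for nm in names:
        X_red = np.concatenate(
            [np.ones((n, 1))] + [blocks[o] for o in names if o != nm], axis=1
        )
        ss = _rss(X_red, y) - rss_full
        df = blocks[nm].shape[1]
        F = (ss / df) / ms_res
        out[nm] = dict(df=df, sum_sq=ss, F=F, p=float(stats.f.sf(F, df, df_res)))
    out["Residual"] = dict(df=df_res, sum_sq=rss_full)
    return out
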