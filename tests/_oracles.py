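"""Independent oracle implementations used by the test suite.

Everything here is deliberately written by a different route than the
package code it checks: straight loops instead of vectorized windows,
exhaustive enumeration instead of closed forms, breadth-first search
instead of library labeling.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

# ---------------------------------------------------------------------------
# rank-sum p-value by exhaustive enumeration


def enumeration_ranksum_pvalue(x1: np.ndarray, x2: np.ndarray) -> float:
    """Exact two-sided rank-sum p-value by enumerating all rank assignments.

    Two-sided p = min(1, 2 * min(P(U <= u), P(U >= u))) over the exact
    null distribution of the Mann-Whitney U statistic of group 1.
    Assumes no ties.
    """
    pooled = np.concatenate([x1, x2])
    ranks = np.argsort(np.argsort(pooled)) + 1
    n1 = len(x1)
    r1 = ranks[:n1].sum()
    u_obs = r1 - n1 * (n1 + 1) / 2
    n = len(pooled)
    us = []
    for comb in combinations(range(1, n + 1), n1):
        us.append(sum(comb) - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# connected-component labeling by BFS flood fill (8-connectivity)


def flood_fill_components(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    mask = np.asarray(mask) > 0
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                queue = [(r, c)]
                seen[r, c] = True
                comp = []
                while queue:
                    rr, cc = queue.pop()
                    comp.append((rr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = rr + dr, cc + dc
                            if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2] \
                                    and not seen[r2, c2]:
                                seen[r2, c2] = True
                                queue.append((r2, c2))
                comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# straight-loop evaluation of the conv/ReLU/LRN/pool chain


def direct_conv(x: np.ndarray, weights: np.ndarray, bias: np.ndarray,
                stride: int, pad: int) -> np.ndarray:
    """Per-output-position convolution: loops over positions, dots per patch."""
    if pad:
        x = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    k = weights.shape[1]
    n = (x.shape[0] - k) // stride + 1
    out = np.empty((n, n, weights.shape[0]))
    for i in range(n):
        for j in range(n):
            patch = x[i * stride : i * stride + k, j * stride : j * stride + k, :]
            for ch in range(weights.shape[0]):
                out[i, j, ch] = np.sum(patch * weights[ch]) + bias[ch]
    return out


def direct_lrn(x: np.ndarray, depth: int = 5, alpha: float = 1e-4,
               beta: float = 0.75, k: float = 2.0) -> np.ndarray:
    half = depth // 2
    out = np.empty_like(x)
    n_ch = x.shape[2]
    for ch in range(n_ch):
        lo, hi = max(0, ch - half), min(n_ch, ch + half + 1)
        s = (x[:, :, lo:hi] ** 2).sum(axis=2)
        out[:, :, ch] = x[:, :, ch] / (k + alpha * s) ** beta
    return out


def direct_maxpool(x: np.ndarray, k: int = 3, stride: int = 2) -> np.ndarray:
    n = (x.shape[0] - k) // stride + 1
    out = np.empty((n, n, x.shape[2]))
    for i in range(n):
        for j in range(n):
            out[i, j, :] = x[i * stride : i * stride + k,
                             j * stride : j * stride + k, :].max(axis=(0, 1))
    return out


def direct_pool2_features(roi: np.ndarray, backend) -> np.ndarray:
    """Full chain by the direct route, flattened channel-major."""
    x = backend.prepare_input(roi)
    x = direct_conv(x, backend.conv1_weights, backend.conv1_bias, 4, 0)
    x = np.maximum(x, 0.0)
    x = direct_lrn(x)
    x = direct_maxpool(x)
    x = direct_conv(x, backend.conv2_weights, backend.conv2_bias, 1, 2)
    x = np.maximum(x, 0.0)
    x = direct_lrn(x)
    x = direct_maxpool(x)
    out = np.empty(x.shape[2] * x.shape[0] * x.shape[1])
    pos = 0
    for ch in range(x.shape[2]):
        for i in range(x.shape[0]):
            for j in range(x.shape[1]):
                out[pos] = x[i, j, ch]
                pos += 1
    return out


def receptive_field_recurrence(chain) -> tuple[int, int, float]:
    """(size, jump, start) by the standard receptive-field recurrence."""
    r, j, start = 1, 1, 0.0
    for k, s, p in chain:
        r = r + (k - 1) * j
        start = start + ((k - 1) / 2 - p) * j
        j = j * s
    return r, j, start
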