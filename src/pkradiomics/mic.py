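"""Maximal information coefficient (MIC).

MIC scans two-dimensional grids with nx * ny <= n**alpha cells and reports
the largest grid-normalized mutual information

    MIC = max_{nx*ny <= B} max_G I_G(x, y) / log(min(nx, ny)).

Key computational fact: with the partition of one axis fixed, maximizing
mutual information over partitions of the other axis is an additive
segmentation problem (I = H(Y) - sum_bins p_bin H(Y|bin)) solved exactly by
dynamic programming.  Two modes are provided:

* ``exact`` — enumerate every admissible partition of the y-axis (cuts only
  between distinct values) and DP-optimize the x-axis for each; this is the
  full maximization and is feasible for small samples;
* ``approx`` — the standard equipartition heuristic: equipartition one axis,
  DP-optimize the other, take the better of the two orientations.

``mode="auto"`` (default) uses ``exact`` for n <= 25 and ``approx`` above.
The statistic is deterministic given its inputs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

__all__ = ["mic"]

_EXACT_N_MAX = 25


def _distinct_boundaries(sorted_vals: np.ndarray) -> np.ndarray:
    """Positions p where a cut between sorted_vals[p-1] and sorted_vals[p]
    separates distinct values (admissible cut positions, 1..n-1)."""
    return np.nonzero(np.diff(sorted_vals) > 0)[0] + 1


def _entropy_cost_matrix(cum: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """W[a, b] = n_ab * H(Y | x-segment (pos[a], pos[b]]) in nats.

    cum is (n+1, ny) prefix counts of y-bin membership in x-sorted order;
    pos the admissible segment endpoints (including 0 and n).
    """
    seg = cum[pos][:, None, :] - cum[pos][None, :, :]       # (P, P, ny), b-a
    seg = np.swapaxes(seg, 0, 1)                            # [a, b]
    tot = seg.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = seg * (np.log(tot)[:, :, None] - np.log(seg))
    term[~np.isfinite(term)] = 0.0
    W = term.sum(axis=2)
    W[np.tril_indices_from(W)] = np.inf          # only forward segments a < b
    W[np.diag_indices_from(W)] = np.inf
    return W


def _max_mi_dp(cum: np.ndarray, pos: np.ndarray, nx: int, n: int,
               h_y: float) -> float:
    """Max mutual information (nats) over x-partitions into <= nx segments
    with the y-binning fixed, by exact dynamic programming."""
    W = _entropy_cost_matrix(cum, pos)
    P = len(pos)
    # dp[b] = min cost of partitioning (0, pos[b]] into k segments
    dp = W[0, :].copy()
    for _ in range(nx - 1):
        dp = np.minimum(dp, np.min(dp[:, None] + W, axis=0))
    min_cost = dp[P - 1]
    return h_y - min_cost / n


def _ybin_entropy(cum: np.ndarray, n: int) -> float:
    counts = cum[-1]
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _prep(xs: np.ndarray, ny: int, ybins: np.ndarray):
    """Prefix counts of y-bin membership in x-sorted order."""
    order = np.argsort(xs, kind="stable")
    yb = ybins[order]
    n = xs.size
    cum = np.zeros((n + 1, ny))
    onehot = np.zeros((n, ny))
    onehot[np.arange(n), yb] = 1.0
    cum[1:] = np.cumsum(onehot, axis=0)
    pos = np.concatenate(([0], _distinct_boundaries(xs[order]), [n]))
    return cum, pos


def _equipartition_bins(v: np.ndarray, ny: int) -> np.ndarray:
    """Rank equipartition into <= ny bins, ties kept together."""
    order = np.argsort(v, kind="stable")
    sorted_v = v[order]
    n = v.size
    bounds = _distinct_boundaries(sorted_v)
    targets = n * (np.arange(1, ny) / ny)
    cuts = []
    for t in targets:
        if bounds.size == 0:
            break
        b = bounds[np.argmin(np.abs(bounds - t))]
        if not cuts or b > cuts[-1]:
            cuts.append(int(b))
    ybins_sorted = np.zeros(n, dtype=int)
    for c in cuts:
        ybins_sorted[c:] += 1
    out = np.empty(n, dtype=int)
    out[order] = ybins_sorted
    return out


def _bins_from_cuts(v_sorted_order: np.ndarray, n: int, cuts) -> np.ndarray:
    b = np.zeros(n, dtype=int)
    for c in cuts:
        b[c:] += 1
    out = np.empty(n, dtype=int)
    out[v_sorted_order] = b
    return out


def _grid_sizes(n: int, alpha: float) -> list[tuple[int, int]]:
    B = n ** alpha
    out = []
    ny = 2
    while 2 * ny <= B:
        nx = int(B // ny)
        if nx >= 2:
            out.append((nx, ny))
        ny += 1
    return out


def mic(x, y, alpha: float = 0.6, c: float = 15, mode: str = "auto") -> float:
    """Maximal information coefficient of two paired samples, in [0, 1].

    ``alpha`` bounds the grid size (nx * ny <= n**alpha); ``c`` caps the
    number of candidate cut positions per axis at c * nbins in approx mode.
    Constant inputs carry no information and return 0.
    """
    xs = np.asarray(x, dtype=np.float64)
    ys = np.asarray(y, dtype=np.float64)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    n = xs.size
    if n < 10:
        raise ValueError("MIC needs at least 10 paired values")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return 0.0
    if mode == "auto":
        mode = "exact" if n <= _EXACT_N_MAX else "approx"
    if mode not in ("exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")

    best = 0.0
    for nx, ny in _grid_sizes(n, alpha):
        for a, b, na, nb in ((xs, ys, nx, ny), (ys, xs, ny, nx)):
            # partition b-axis into nb bins, DP-optimize a-axis into na
            if mode == "approx":
                val = _one_orientation_approx(a, b, na, nb, n, c)
            else:
                val = _one_orientation_exact(a, b, na, nb, n)
            norm = np.log(min(nx, ny))
            best = max(best, val / norm)
    return float(min(best, 1.0))


def _one_orientation_approx(a, b, na, nb, n, c) -> float:
    bbins = _equipartition_bins(b, nb)
    cum, pos = _prep(a, nb, bbins)
    if c is not None and len(pos) - 2 > int(c * na):
        # cap candidate cuts: keep the c*na admissible positions closest to
        # an equipartition of the a-axis
        interior = pos[1:-1]
        targets = n * (np.arange(1, int(c * na) + 1) / (int(c * na) + 1))
        keep = np.unique([interior[np.argmin(np.abs(interior - t))]
                          for t in targets])
        pos = np.concatenate(([0], keep, [n]))
    h = _ybin_entropy(cum, n)
    return _max_mi_dp(cum, pos, na, n, h)


def _one_orientation_exact(a, b, na, nb, n) -> float:
    order_b = np.argsort(b, kind="stable")
    bounds = _distinct_boundaries(b[order_b])
    best = 0.0
    for k in range(1, nb):                       # k cuts -> k+1 bins
        for cuts in combinations(bounds, k):
            bbins = _bins_from_cuts(order_b, n, cuts)
            cum, pos = _prep(a, k + 1, bbins)
            h = _ybin_entropy(cum, n)
            best = max(best, _max_mi_dp(cum, pos, na, n, h))
    return best
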