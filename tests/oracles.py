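"""Independent brute-force oracles used to cross-check package numerics.

These deliberately avoid the package's own code paths: plain Python loops,
closed forms, or third-party routines (statsmodels, scikit-learn).
"""

from __future__ import annotations

import cmath
import math

import numpy as np


def mi_oracle(phase, amplitude, n_bins=18):
    """Tort modulation index by explicit binning loops."""
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for ph, am in zip(phase, amplitude):
        frac = (ph + math.pi) / (2 * math.pi)
        j = min(max(int(frac * n_bins), 0), n_bins - 1)
        sums[j] += am
        counts[j] += 1
    means = [s / c if c else 0.0 for s, c in zip(sums, counts)]
    total = sum(means)
    if total <= 0:
        return float("nan")
    p = [m / total for m in means]
    h = -sum(pi * math.log(pi) for pi in p if pi > 0)
    return (math.log(n_bins) - h) / math.log(n_bins)


def sampen_oracle(x, m=2, r=0.2):
    """Sample entropy via O(n^2) template-pair counting with plain loops."""
    x = list(map(float, x))
    n = len(x)
    n_templates = n - m
    b = a = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if a == 0 or b == 0:
        return 0.0 if a == b else float("nan")
    return -math.log(a / b)


def ispc_oracle(phase_a, phase_b):
    """Resultant length of phase differences by explicit complex summation."""
    acc = 0j
    for pa, pb in zip(phase_a, phase_b):
        acc += cmath.exp(1j * (pa - pb))
    return abs(acc) / len(phase_a)


def eta2_type3_oracle(y, design_full: np.ndarray, term_columns: list[int]):
    """Partial eta² by drop-term RSS with QR-based projections (no lstsq).

    Uses an orthogonal-projection route distinct from the package's
    least-squares solver.
    """
    y = np.asarray(y, dtype=float)

    def rss(x):
        q, _ = np.linalg.qr(x)
        fitted = q @ (q.T @ y)
        return float(np.sum((y - fitted) ** 2))

    keep = [j for j in range(design_full.shape[1]) if j not in set(term_columns)]
    rss_full = rss(design_full)
    rss_red = rss(design_full[:, keep])
    ss = rss_red - rss_full
    return ss / (ss + rss_full)


def nmi_oracle(a, b):
    """NMI (arithmetic-mean normalization) via scikit-learn."""
    from sklearn.metrics import normalized_mutual_info_score

    return normalized_mutual_info_score(
        np.asarray(a).astype(int), np.asarray(b).astype(int), average_method="arithmetic"
    )


def legendre_poly(n, x):
    """P_n(x) via the Bonnet recurrence (independent of scipy)."""
    if n == 0:
        return np.ones_like(np.asarray(x, dtype=float))
    p_prev = np.ones_like(np.asarray(x, dtype=float))
    p = np.asarray(x, dtype=float).copy()
    for k in range(1, n):
        p_next = ((2 * k + 1) * x * p - k * p_prev) / (k + 1)
        p_prev, p = p, p_next
    return p


def laplacian_oracle(data_2d, positions, m=4, n_terms=10, reg=1e-5):
    """Spherical-spline Laplacian of (channels, samples) by direct solves.

    Solves the constrained spline system per time sample with
    np.linalg.solve rather than a precomputed operator.
    """
    pos = np.asarray(positions, dtype=float)
    n_ch = pos.shape[0]
    cosang = np.clip(pos @ pos.T, -1, 1)
    g = np.zeros((n_ch, n_ch))
    h = np.zeros((n_ch, n_ch))
    for n in range(1, n_terms + 1):
        pn = legendre_poly(n, cosang)
        g += (2 * n + 1) / (n * (n + 1)) ** m * pn
        h += -(2 * n + 1) / (n * (n + 1)) ** (m - 1) * pn
    g /= 4 * np.pi
    h /= 4 * np.pi
    gs = g + reg * np.eye(n_ch)

    out = np.zeros_like(np.asarray(data_2d, dtype=float))
    # augmented system: [[Gs, 1], [1', 0]] [c; c0] = [v; 0]
    aug = np.zeros((n_ch + 1, n_ch + 1))
    aug[:n_ch, :n_ch] = gs
    aug[:n_ch, n_ch] = 1.0
    aug[n_ch, :n_ch] = 1.0
    for t in range(out.shape[1]):
        rhs = np.concatenate([np.asarray(data_2d)[:, t], [0.0]])
        sol = np.linalg.solve(aug, rhs)
        out[:, t] = h @ sol[:n_ch]
    return out


def greedy_match_oracle(demo_rows, age_tol=5.0, iq_tol=10.0):
    """Re-implementation of the greedy matching rule with plain dict/loops.

    demo_rows: list of dicts with participant_id, age_months, sex, iq,
    diagnosis.  Returns list of (case_id, control_id).
    """
    cases = [r for r in demo_rows if r["diagnosis"] in ("AD", "ASD")]
    cases.sort(key=lambda r: (r["age_months"], r["participant_id"]))
    controls = {r["participant_id"]: r for r in demo_rows if r["diagnosis"] == "CON"}
    pairs = []
    for case in cases:
        best = None
        for cid in sorted(controls):
            ctl = controls[cid]
            if ctl["sex"] != case["sex"]:
                continue
            da = abs(ctl["age_months"] - case["age_months"])
            di = abs(ctl["iq"] - case["iq"])
            if da > age_tol or di > iq_tol:
                continue
            key = (da, di, cid)
            if best is None or key < best[0]:
                best = (key, cid)
        if best is not None:
            pairs.append((case["participant_id"], best[1]))
            del controls[best[1]]
    return pairs
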