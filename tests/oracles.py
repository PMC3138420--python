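"""Brute-force reference solvers used only to cross-check the package.

The cubic-spline oracle assembles the full dense linear system in the
per-interval polynomial coefficients — interpolation, derivative-continuity
and boundary equations, 4(L-1) in total — and solves it with a generic
dense solver.  It shares no code with the tridiagonal/cyclic solvers in
``aainterp.interpolate``.
"""

import numpy as np


def dense_spline_coefficients(y, boundary):
    """Solve for (a, b, c, d) of S_i(t) = a + b t + c t^2 + d t^3 on each
    unit interval i = 1..L-1 (t local in [0, 1])."""
    y = np.asarray(y, dtype=float)
    L = len(y)
    n = L - 1
    A = np.zeros((4 * n, 4 * n))
    rhs = np.zeros(4 * n)

    def idx(i, k):  # interval i (0-based), coefficient k in (a,b,c,d)
        return 4 * i + k

    row = 0
    for i in range(n):
        A[row, idx(i, 0)] = 1.0  # S_i(0) = y_i
        rhs[row] = y[i]
        row += 1
        A[row, idx(i, 0)] = A[row, idx(i, 1)] = A[row, idx(i, 2)] = A[row, idx(i, 3)] = 1.0
        rhs[row] = y[i + 1]  # S_i(1) = y_{i+1}
        row += 1
    for i in range(n - 1):
        # S_i'(1) = S_{i+1}'(0)
        A[row, idx(i, 1)] = 1.0
        A[row, idx(i, 2)] = 2.0
        A[row, idx(i, 3)] = 3.0
        A[row, idx(i + 1, 1)] = -1.0
        row += 1
        # S_i''(1) = S_{i+1}''(0)
        A[row, idx(i, 2)] = 2.0
        A[row, idx(i, 3)] = 6.0
        A[row, idx(i + 1, 2)] = -2.0
        row += 1

    if boundary == "natural":
        A[row, idx(0, 2)] = 2.0
        row += 1
        A[row, idx(n - 1, 2)] = 2.0
        A[row, idx(n - 1, 3)] = 6.0
        row += 1
    elif boundary == "periodic":
        # S'(x_1) = S'(x_L)
        A[row, idx(0, 1)] = 1.0
        A[row, idx(n - 1, 1)] = -1.0
        A[row, idx(n - 1, 2)] = -2.0
        A[row, idx(n - 1, 3)] = -3.0
        row += 1
        # S''(x_1) = S''(x_L)
        A[row, idx(0, 2)] = 2.0
        A[row, idx(n - 1, 2)] = -2.0
        A[row, idx(n - 1, 3)] = -6.0
        row += 1
    elif boundary == "fmm":
        # S''' on each end interval equals the third derivative of the
        # exact cubic through the outermost four points (6 x the third
        # divided difference; unit spacing).
        A[row, idx(0, 3)] = 6.0
        rhs[row] = y[3] - 3 * y[2] + 3 * y[1] - y[0]
        row += 1
        A[row, idx(n - 1, 3)] = 6.0
        rhs[row] = y[L - 1] - 3 * y[L - 2] + 3 * y[L - 3] - y[L - 4]
        row += 1
    else:
        raise ValueError(boundary)
    return np.linalg.solve(A, rhs).reshape(n, 4)


def dense_spline_eval(y, boundary, x):
    """Evaluate the dense-solve spline at position(s) x in [1, L]."""
    coef = dense_spline_coefficients(y, boundary)
    L = len(y)
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    i = np.clip(np.floor(xa).astype(int), 1, L - 1) - 1
    t = xa - (i + 1)
    a, b, c, d = coef[i, 0], coef[i, 1], coef[i, 2], coef[i, 3]
    return a + b * t + c * t**2 + d * t**3


def rank_auc(scores, labels):
    """Mann-Whitney rank AUC, independent of sklearn's ROC construction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores), dtype=float)
    ranks[order] = np.arange(1, len(scores) + 1)
    # midranks for ties
    s_sorted = scores[order]
    start = 0
    for end in range(1, len(scores) + 1):
        if end == len(scores) or s_sorted[end] != s_sorted[start]:
            ranks[order[start:end]] = 0.5 * (start + 1 + end)
            start = end
    n1 = labels.sum()
    n0 = len(labels) - n1
    return (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1)
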