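"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's vectorized code paths: plain
nested loops, explicit window scans, BFS connectivity, and a generic
gradient-based MAP solver, so agreement with the package is informative.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.optimize import minimize

N = 7


def brute_force_violations(grid: np.ndarray) -> set[tuple]:
    """All topographic-constraint violations of a 7x7 grid, as hashable
    (kind, coords) tuples, found by exhaustive scanning."""
    grid = np.asarray(grid, dtype=bool)
    found: set[tuple] = set()
    if not grid.any():
        return {("NO_PATH", ())}

    def is_path(r, c):
        return 0 <= r < N and 0 <= c < N and bool(grid[r, c])

    for r in range(N):
        for c in range(N):
            if not grid[r, c]:
                continue
            nbrs = sum(is_path(r + dr, c + dc)
                       for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)))
            if nbrs <= 1:
                found.add(("DEAD_END", ((r, c),)))
            elif nbrs == 4:
                found.add(("CROSS_ROAD", ((r, c),)))

    for r in range(N - 1):
        for c in range(N - 1):
            cells = ((r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1))
            vals = [bool(grid[rc]) for rc in cells]
            if all(vals):
                found.add(("WHITE_PATCH", cells))
            elif not any(vals):
                found.add(("BLACK_PATCH", cells))
            elif vals[0] == vals[3] and vals[1] == vals[2] and vals[0] != vals[1]:
                found.add(("CHECKER", cells))

    # BFS from the first path cell
    start = None
    for r in range(N):
        for c in range(N):
            if grid[r, c]:
                start = (r, c)
                break
        if start:
            break
    seen = {start}
    queue = deque([start])
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            if is_path(r + dr, c + dc) and (r + dr, c + dc) not in seen:
                seen.add((r + dr, c + dc))
                queue.append((r + dr, c + dc))
    stranded = tuple(
        (r, c) for r in range(N) for c in range(N) if grid[r, c] and (r, c) not in seen
    )
    if stranded:
        found.add(("DISCONNECTED", stranded))
    return found


def map_logistic_weights(
    X: np.ndarray, y: np.ndarray, alpha: float, bias_alpha: float = 1e-8
) -> np.ndarray:
    """Ridge-penalized logistic MAP via generic gradient-based optimization.

    Returns the weight vector with the bias appended.
    """
    n, p = X.shape
    Xw = np.hstack([X, np.ones((n, 1))])
    a = np.append(np.full(p, alpha), bias_alpha)

    def nlp(w):
        z = Xw @ w
        return np.sum(np.logaddexp(0.0, z) - y * z) + 0.5 * np.sum(a * w * w)

    def grad(w):
        z = Xw @ w
        return Xw.T @ (1.0 / (1.0 + np.exp(-z)) - y) + a * w

    res = minimize(nlp, np.zeros(p + 1), jac=grad, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 5000})
    return res.x


def quadratic_residual_normal_equations(y: np.ndarray) -> np.ndarray:
    """Residual of a quadratic fit in the sample index, solved through the
    normal equations directly (independent of lstsq/vander)."""
    n = len(y)
    t = np.arange(n, dtype=float)
    B = np.stack([np.ones(n), t, t * t], axis=1)
    coef = np.linalg.solve(B.T @ B, B.T @ y)
    return y - B @ coef
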