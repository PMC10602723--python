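"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths of the package (no scipy ranking,
no power iteration): concordance is evaluated straight from its defining
formula with a hand-rolled midrank, and eigen quantities come from the
characteristic polynomial's roots.
"""

from __future__ import annotations

import numpy as np


def midranks(values) -> list[float]:
    """Average-rank transform computed by explicit position averaging."""
    order = sorted(range(len(values)), key=lambda k: values[k])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kendalls_w_definition(score_rows) -> float:
    """W from the definition: 12 S / (m^2 (n^3 - n) - m sum T_e)."""
    rows = [midranks(r) for r in score_rows]
    m, n = len(rows), len(rows[0])
    rank_sums = [sum(r[j] for r in rows) for j in range(n)]
    mean_sum = sum(rank_sums) / n
    s = sum((rs - mean_sum) ** 2 for rs in rank_sums)
    tie = 0.0
    for raw in score_rows:
        seen: dict = {}
        for v in raw:
            seen[v] = seen.get(v, 0) + 1
        tie += sum(t**3 - t for t in seen.values())
    return 12.0 * s / (m**2 * (n**3 - n) - m * tie)


def principal_eigen_3x3(a: np.ndarray) -> tuple[np.ndarray, float]:
    """Principal eigenpair of a positive 3x3 matrix via the characteristic
    polynomial lambda^3 - tr*lambda^2 + M2*lambda - det = 0."""
    tr = a[0, 0] + a[1, 1] + a[2, 2]
    m2 = (
        a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
        + a[0, 0] * a[2, 2] - a[0, 2] * a[2, 0]
        + a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1]
    )
    det = np.linalg.det(a)
    roots = np.roots([1.0, -tr, m2, -det])
    lam = max(roots, key=lambda z: z.real).real
    # eigenvector by solving (A - lam I) v = 0 via the null space
    b = a - lam * np.eye(3)
    _, _, vh = np.linalg.svd(b)
    v = np.abs(vh[-1])
    return v / v.sum(), float(lam)
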