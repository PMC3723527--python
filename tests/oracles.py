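"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by the most literal method available —
base-by-base enumeration, explicit loops, the textbook formula — so the
implementation under test is checked against a genuinely separate path.
"""

from __future__ import annotations

import numpy as np


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up recursion."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top            # 1-based rank of this p-value
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def median_polish_loops(x, max_iter=20, tol=1e-6):
    """Tukey median polish with explicit Python loops (row sweep, re-centre
    row effects, column sweep, re-centre column effects)."""
    resid = [list(map(float, row)) for row in np.asarray(x)]
    nr, nc = len(resid), len(resid[0])
    overall, row, col = 0.0, [0.0] * nr, [0.0] * nc
    for _ in range(max_iter):
        rmeds = []
        for i in range(nr):
            med = float(np.median(resid[i]))
            rmeds.append(med)
            for j in range(nc):
                resid[i][j] -= med
            row[i] += med
        m = float(np.median(row))
        row = [r - m for r in row]
        overall += m
        cmeds = []
        for j in range(nc):
            colvals = [resid[i][j] for i in range(nr)]
            med = float(np.median(colvals))
            cmeds.append(med)
            for i in range(nr):
                resid[i][j] -= med
            col[j] += med
        m = float(np.median(col))
        col = [c - m for c in col]
        overall += m
        if max(max(abs(v) for v in rmeds), max(abs(v) for v in cmeds)) < tol:
            break
    return overall, np.array(row), np.array(col), np.array(resid)


def spliced_positions(model):
    """All exonic genomic base positions of a transcript in 5'->3' order,
    enumerated one base at a time (the interval-arithmetic oracle)."""
    out = []
    exons = model.exons if model.strand == "+" else reversed(model.exons)
    for a, b in exons:
        rng = range(a, b) if model.strand == "+" else range(b - 1, a - 1, -1)
        out.extend(rng)
    return out


def ptc_distance_enumerated(model) -> int | None:
    """Stop-to-final-junction distance by base enumeration (None if 1 exon)."""
    if len(model.exons) < 2 or not model.cds:
        return None
    bases = spliced_positions(model)
    cds_bases = set()
    for a, b in model.cds:
        cds_bases.update(range(a, b))
    stop_end = max(i for i, g in enumerate(bases) if g in cds_bases) + 1
    last_exon = model.exons[-1] if model.strand == "+" else model.exons[0]
    junction = len(bases) - (last_exon[1] - last_exon[0])
    return junction - stop_end
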