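"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the package's
implementation path: brute-force agglomeration for clustering, a dense grid
search with analytic linear solve for 4PL midpoints, and an all-pairs scan
for direct-target calling.
"""

from __future__ import annotations

import numpy as np


def complete_linkage_bruteforce(X: np.ndarray) -> list[float]:
    """Merge heights of complete-linkage agglomeration, recomputed from the
    raw points at every step (O(n^3); no Lance-Williams shortcut)."""
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    float(np.linalg.norm(X[a] - X[b]))
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


def grid_fit_ec50(doses: np.ndarray, viability: np.ndarray, n_refine: int = 4) -> float:
    """4PL midpoint by dense (ec50, hill) grid search with an analytic
    least-squares solve for (bottom, span) at each grid point."""
    doses = np.asarray(doses, float)
    v = np.asarray(viability, float)
    lo, hi = np.log10(doses.min()) - 3, np.log10(doses.max()) + 3
    h_lo, h_hi = np.log(0.2), np.log(5.0)
    best = None
    for _ in range(n_refine):
        ec_grid = np.logspace(lo, hi, 80)
        h_grid = np.exp(np.linspace(h_lo, h_hi, 40))
        for ec in ec_grid:
            for h in h_grid:
                g = 1.0 / (1.0 + (doses / ec) ** h)
                A = np.column_stack([np.ones_like(g), g])
                coef, *_ = np.linalg.lstsq(A, v, rcond=None)
                rss = float(np.sum((A @ coef - v) ** 2))
                if best is None or rss < best[0]:
                    best = (rss, ec, h)
        _, ec, h = best
        span_ec = (hi - lo) / 79
        lo, hi = np.log10(ec) - 5 * span_ec, np.log10(ec) + 5 * span_ec
        span_h = (h_hi - h_lo) / 39
        h_lo, h_hi = np.log(h) - 5 * span_h, np.log(h) + 5 * span_h
    return float(best[1])


def direct_targets_bruteforce(
    peaks, tss_table, degs, max_dist: int = 10_000, min_abs_lfc: float = 1.5
) -> set[str]:
    """All-peaks x all-genes scan applying the calling rule literally."""
    kept = [
        p
        for p in peaks.to_dict("records")
        if p["fold_enrichment"] >= 5.0 and p["pileup"] >= 25 and p["q_value"] < 0.01
    ]
    tss_by_gene = {r["gene_id"]: r for r in tss_table.to_dict("records")}
    called = set()
    for rec in degs.to_dict("records"):
        gene = rec["gene_id"]
        if gene not in tss_by_gene or not abs(rec["log2_fold_change"]) > min_abs_lfc:
            continue
        g = tss_by_gene[gene]
        for p in kept:
            if p["chrom"] != g["chrom"]:
                continue
            pos = g["tss"]
            if p["start"] <= pos < p["end"]:
                d = 0
            else:
                d = min(abs(pos - p["start"]), abs(pos - (p["end"] - 1)))
            if d < max_dist:
                called.add(gene)
                break
    return called
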