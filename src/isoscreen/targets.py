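"""Direct-target calling: TSS-proximal binding peaks x differential expression.

A gene is called a direct target when (a) a shortlisted binding peak —
enrichment over background >= 5-fold, pileup >= 25 reads and q < 0.01 — lies
strictly within 10 kb of its transcription start site, and (b) its absolute
log2 fold-change strictly exceeds 1.5. Coordinates follow the BED
convention (0-based, half-open); distance is measured from the TSS to the
nearest peak boundary, 0 when the TSS falls inside the peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PEAK_COLUMNS",
    "shortlist_peaks",
    "peak_tss_distance",
    "call_direct_targets",
    "read_peaks",
    "write_peaks",
    "read_tss",
    "write_tss",
    "read_deg",
    "write_deg",
]

PEAK_COLUMNS = ["chrom", "start", "end", "fold_enrichment", "pileup", "q_value"]
TSS_COLUMNS = ["gene_id", "chrom", "tss", "strand"]
DEG_COLUMNS = ["gene_id", "log2_fold_change"]


def _validate_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak table missing column(s): {missing}")
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError("peak with start >= end (coordinates are half-open)")
    if ((peaks["q_value"] < 0) | (peaks["q_value"] > 1)).any():
        raise ValueError("q_value outside [0, 1]")
    if (peaks["fold_enrichment"] < 0).any():
        raise ValueError("negative fold_enrichment")
    return peaks


def shortlist_peaks(
    peaks: pd.DataFrame,
    min_fold: float = 5.0,
    min_pileup: float = 25.0,
    max_q: float = 0.01,
) -> pd.DataFrame:
    """Keep highly enriched, highly significant peaks.

    Inclusive at the enrichment and pileup thresholds (>=), strict on the
    q-value (<).
    """
    _validate_peaks(peaks)
    keep = (
        (peaks["fold_enrichment"] >= min_fold)
        & (peaks["pileup"] >= min_pileup)
        & (peaks["q_value"] < max_q)
    )
    return peaks.loc[keep].reset_index(drop=True)


def peak_tss_distance(peak, tss) -> int:
    """Distance in bp from a TSS to the nearest peak boundary.

    0 when the TSS lies inside [start, end); otherwise
    ``min(|tss - start|, |tss - (end - 1)|)``. Both records must be on the
    same chromosome; strand only determines which coordinate the caller
    used as the TSS, never the distance.
    """
    chrom_p = peak["chrom"] if isinstance(peak, (dict, pd.Series)) else peak.chrom
    start = int(peak["start"] if isinstance(peak, (dict, pd.Series)) else peak.start)
    end = int(peak["end"] if isinstance(peak, (dict, pd.Series)) else peak.end)
    chrom_t = tss["chrom"] if isinstance(tss, (dict, pd.Series)) else tss.chrom
    pos = int(tss["tss"] if isinstance(tss, (dict, pd.Series)) else tss.tss)
    if chrom_p != chrom_t:
        raise ValueError(f"peak on {chrom_p} and TSS on {chrom_t}: distance undefined")
    if start <= pos < end:
        return 0
    return min(abs(pos - start), abs(pos - (end - 1)))


def call_direct_targets(
    peaks: pd.DataFrame,
    tss_table: pd.DataFrame,
    degs: pd.DataFrame,
    max_dist: int = 10_000,
    min_abs_lfc: float = 1.5,
    preshortlisted: bool = False,
) -> pd.DataFrame:
    """Intersect TSS-proximal shortlisted peaks with perturbed genes.

    A gene is called iff a shortlisted peak lies at distance strictly below
    ``max_dist`` from its TSS and |log2FC| strictly exceeds ``min_abs_lfc``.
    The nearest peak is reported per gene; output is sorted by |log2FC|
    descending (gene id breaking ties) and is invariant to the input order
    of both tables. Genes present in the DEG table but absent from the TSS
    table are skipped with a warning. Set ``preshortlisted=True`` when the
    peak table already passed :func:`shortlist_peaks`.
    """
    if not preshortlisted:
        peaks = shortlist_peaks(peaks)
    else:
        _validate_peaks(peaks)

    tss_by_gene = tss_table.set_index("gene_id")
    if tss_by_gene.index.has_duplicates:
        raise ValueError("duplicate gene_id in TSS table")

    # per-chromosome sorted boundary arrays for binary search
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in peaks.groupby("chrom", sort=False):
        order = np.argsort(grp["start"].to_numpy(), kind="mergesort")
        by_chrom[chrom] = (grp["start"].to_numpy()[order], grp["end"].to_numpy()[order])

    rows = []
    for rec in degs.itertuples(index=False):
        gene, lfc = rec.gene_id, float(rec.log2_fold_change)
        if gene not in tss_by_gene.index:
            warnings.warn(f"gene {gene!r} in DEG table missing from TSS table; skipped")
            continue
        if not abs(lfc) > min_abs_lfc:
            continue
        g = tss_by_gene.loc[gene]
        if g["chrom"] not in by_chrom:
            continue
        starts, ends = by_chrom[g["chrom"]]
        pos = int(g["tss"])
        # vectorized boundary distance over the chromosome's sorted peaks;
        # peaks may overlap, so containment is checked before boundaries
        dist = np.where(
            (starts <= pos) & (pos < ends),
            0,
            np.minimum(np.abs(pos - starts), np.abs(pos - (ends - 1))),
        )
        j = int(np.argmin(dist))
        if dist[j] < max_dist:
            rows.append(
                {
                    "gene_id": gene,
                    "log2_fold_change": lfc,
                    "distance_bp": int(dist[j]),
                    "chrom": g["chrom"],
                    "peak_start": int(starts[j]),
                    "peak_end": int(ends[j]),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "log2_fold_change", "distance_bp", "chrom", "peak_start", "peak_end"],
    )
    out["_abs"] = out["log2_fold_change"].abs()
    out = out.sort_values(["_abs", "gene_id"], ascending=[False, True], kind="mergesort")
    return out.drop(columns="_abs").reset_index(drop=True)


# ---------------------------------------------------------------------------
# plain-text I/O: peaks TSV, TSS BED6, DEG TSV
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return _validate_peaks(df[PEAK_COLUMNS])


def write_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    _validate_peaks(peaks)[PEAK_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tss(path: str | Path) -> pd.DataFrame:
    """Read a TSS table from BED6 (chrom, start, end, name, score, strand).

    The TSS is the interval start for + strand entries and end - 1 for -
    strand entries, matching the half-open convention.
    """
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    tss = np.where(bed["strand"] == "+", bed["start"], bed["end"] - 1)
    return pd.DataFrame(
        {"gene_id": bed["name"], "chrom": bed["chrom"], "tss": tss, "strand": bed["strand"]}
    )


def write_tss(tss_table: pd.DataFrame, path: str | Path) -> None:
    """Write a TSS table as BED6 with 1-bp intervals at the TSS."""
    bed = pd.DataFrame(
        {
            "chrom": tss_table["chrom"],
            "start": tss_table["tss"],
            "end": tss_table["tss"] + 1,
            "name": tss_table["gene_id"],
            "score": 0,
            "strand": tss_table["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False, lineterminator="\n")


def read_deg(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DEG table missing column(s): {missing}")
    if not np.all(np.isfinite(df["log2_fold_change"])):
        raise ValueError("non-finite log2_fold_change")
    return df[DEG_COLUMNS]


def write_deg(degs: pd.DataFrame, path: str | Path) -> None:
    degs[DEG_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")
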