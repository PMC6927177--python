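"""Peak assembly and BED12 export.

Adjacent significant bins of the same gene are merged into peaks on the
transcript, then mapped back through the exon structure to genome
coordinates; intron-spanning peaks become multi-block BED12 records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .genemodel import GeneModel

logger = logging.getLogger(__name__)


@dataclass
class Peak:
    """A merged run of significant bins on one gene's transcript."""

    gene_id: str
    tx_start: int
    tx_end: int
    score: float       # min padj over member bins
    logfc: float       # inverse-variance-weighted mean beta0
    n_bins: int


def merge_significant_bins(results: pd.DataFrame, fdr_cutoff: float = 0.1) -> list[Peak]:
    """Merge adjacent significant bins (padj < cutoff) into peaks.

    Bins are adjacent when they belong to the same gene and have
    consecutive bin indices.  The peak effect size is the
    inverse-variance-weighted mean of member ``beta0`` (weights 1/se^2);
    the peak score is the minimum member ``padj``.
    """
    sig = results[(results["padj"] < fdr_cutoff) & results["padj"].notna()]
    peaks: list[Peak] = []
    for gene_id, sub in sig.groupby("gene_id", sort=True):
        sub = sub.sort_values("bin_index")
        run: list[pd.Series] = []
        prev = None
        for _, row in sub.iterrows():
            if prev is not None and row["bin_index"] != prev + 1:
                peaks.append(_finalize(gene_id, run))
                run = []
            run.append(row)
            prev = row["bin_index"]
        if run:
            peaks.append(_finalize(gene_id, run))
    logger.info("merged %d significant bins into %d peaks", len(sig), len(peaks))
    return peaks


def _finalize(gene_id: str, run: list[pd.Series]) -> Peak:
    beta = np.array([r["beta0"] for r in run])
    se = np.array([r["se"] for r in run])
    w = 1.0 / np.maximum(se, 1e-12) ** 2
    return Peak(
        gene_id=str(gene_id),
        tx_start=int(run[0]["tx_start"]),
        tx_end=int(run[-1]["tx_end"]),
        score=float(min(r["padj"] for r in run)),
        logfc=float((w * beta).sum() / w.sum()),
        n_bins=len(run),
    )


def to_bed12(peaks: list[Peak], models: Mapping[str, GeneModel]) -> pd.DataFrame:
    """BED12 records for peaks, mapping transcript intervals to genome blocks.

    Scores are min(1000, round(-10 log10 padj)).  Coordinates are 0-based
    half-open; thickStart/thickEnd mirror chromStart/chromEnd.
    """
    rows = []
    for pk in peaks:
        if pk.gene_id not in models:
            raise KeyError(f"peak references unknown gene {pk.gene_id!r}")
        gm = models[pk.gene_id]
        blocks = gm.tx_interval_to_blocks(pk.tx_start, pk.tx_end)
        if not blocks:
            raise ValueError(f"peak [{pk.tx_start},{pk.tx_end}) maps to no exon of {pk.gene_id}")
        chrom_start = blocks[0][0]
        chrom_end = blocks[-1][1]
        score = int(min(1000, round(-10.0 * np.log10(max(pk.score, 1e-300)))))
        rows.append(
            {
                "chrom": gm.chrom,
                "chromStart": chrom_start,
                "chromEnd": chrom_end,
                "name": f"{pk.gene_id}:{pk.tx_start}-{pk.tx_end}",
                "score": score,
                "strand": gm.strand,
                "thickStart": chrom_start,
                "thickEnd": chrom_end,
                "itemRgb": "0",
                "blockCount": len(blocks),
                "blockSizes": ",".join(str(e - s) for s, e in blocks),
                "blockStarts": ",".join(str(s - chrom_start) for s, e in blocks),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "chromStart", "chromEnd", "name", "score", "strand",
            "thickStart", "thickEnd", "itemRgb", "blockCount",
            "blockSizes", "blockStarts",
        ],
    )


def peak_table(peaks: list[Peak]) -> pd.DataFrame:
    """Companion statistics table (one row per peak)."""
    return pd.DataFrame(
        [
            {
                "gene_id": p.gene_id,
                "tx_start": p.tx_start,
                "tx_end": p.tx_end,
                "n_bins": p.n_bins,
                "logFC": p.logfc,
                "min_padj": p.score,
            }
            for p in peaks
        ]
    )


def write_bed12(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
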