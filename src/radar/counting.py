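"""Bin- and gene-level fragment counting from BAM/SAM alignments.

Fragments (single-end reads, or properly paired mates collapsed to one
fragment spanning leftmost start to rightmost end) are assigned to the
single transcript bin containing the fragment midpoint in transcript
coordinates.  The midpoint rule partitions counted fragments: each
contributes exactly once to exactly one bin of a gene, so gene-level sums
equal fragment counts.  Fragments whose span does not intersect the exon
union of a gene are not counted for that gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .genemodel import GeneModel

logger = logging.getLogger(__name__)

_BIN_KEY = ["gene_id", "bin_index", "tx_start", "tx_end"]


@dataclass
class BinCountTable:
    """Bin x sample fragment counts for the INPUT and IP channels.

    ``bins`` has columns gene_id, bin_index, tx_start, tx_end; row order of
    ``input_counts`` and ``ip_counts`` (integer arrays, bins x samples)
    follows ``bins``; column order follows ``samples`` in both matrices.
    """

    bins: pd.DataFrame
    samples: list[str]
    input_counts: np.ndarray
    ip_counts: np.ndarray

    def __post_init__(self) -> None:
        B = len(self.bins)
        for name, mat in (("input_counts", self.input_counts), ("ip_counts", self.ip_counts)):
            mat = np.asarray(mat)
            if mat.shape != (B, len(self.samples)):
                raise ValueError(f"{name} shape {mat.shape} != ({B}, {len(self.samples)})")
            if (mat < 0).any():
                raise ValueError(f"{name} contains negative counts")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def to_frame(self) -> pd.DataFrame:
        """Flat table with key columns then INPUT and IP columns per sample."""
        out = self.bins.reset_index(drop=True).copy()
        for j, s in enumerate(self.samples):
            out[f"input.{s}"] = self.input_counts[:, j]
        for j, s in enumerate(self.samples):
            out[f"ip.{s}"] = self.ip_counts[:, j]
        return out

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BinCountTable":
        df = pd.read_csv(path, sep="\t")
        samples = [c[len("input."):] for c in df.columns if c.startswith("input.")]
        return cls(
            bins=df[_BIN_KEY].copy(),
            samples=samples,
            input_counts=df[[f"input.{s}" for s in samples]].to_numpy(int),
            ip_counts=df[[f"ip.{s}" for s in samples]].to_numpy(int),
        )


@dataclass
class GeneCountTable:
    """Gene x sample INPUT fragment counts (the *geneSum* expression proxy)."""

    genes: list[str]
    samples: list[str]
    gene_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"gene_id": self.genes})
        for j, s in enumerate(self.samples):
            out[s] = self.gene_counts[:, j]
        return out

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class MissingIndexError(IOError):
    pass


def _iter_fragments(
    path: str | Path,
    paired_end: bool,
    min_mapq: int,
) -> Iterable[tuple[str, int, int, str]]:
    """Yield (chrom, start, end, strand) fragments from an alignment file.

    Secondary/supplementary/unmapped records and records below the mapping
    quality threshold are skipped.  Properly paired mates are collapsed to
    one fragment using the template span, emitted from the leftmost mate.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            strand = "-" if read.is_reverse else "+"
            if paired_end and read.is_paired:
                if not read.is_proper_pair:
                    continue
                tlen = read.template_length
                # emit the fragment once, from the leftmost mate
                if tlen <= 0:
                    continue
                yield read.reference_name, read.reference_start, read.reference_start + tlen, strand
            else:
                if read.reference_end is None:
                    continue
                yield read.reference_name, read.reference_start, read.reference_end, strand


def _count_one_library(
    path: str | Path,
    models: Mapping[str, GeneModel],
    bin_offsets: Mapping[str, int],
    n_bins_total: int,
    paired_end: bool,
    strandness: str,
    min_mapq: int,
) -> np.ndarray:
    """Count fragment midpoints per bin for one library (single pass)."""
    # group fragments per chromosome, sorted by start, for interval queries
    frags: dict[str, list[tuple[int, int, str]]] = {}
    n_frag = 0
    for chrom, s, e, st in _iter_fragments(path, paired_end, min_mapq):
        frags.setdefault(chrom, []).append((s, e, st))
        n_frag += 1
    if n_frag == 0:
        raise ValueError(f"no mapped reads in library {path}")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, lst in frags.items():
        lst.sort()
        starts = np.array([f[0] for f in lst])
        ends = np.array([f[1] for f in lst])
        fwd = np.array([f[2] == "+" for f in lst])
        by_chrom[chrom] = (starts, ends, fwd)

    counts = np.zeros(n_bins_total, dtype=np.int64)
    for gene_id, gm in models.items():
        if gm.chrom not in by_chrom:
            continue
        starts, ends, fwd = by_chrom[gm.chrom]
        gs, ge = gm.exons[0][0], gm.exons[-1][1]
        hi = np.searchsorted(starts, ge)
        sel = np.nonzero(ends[:hi] > gs)[0]
        if sel.size == 0:
            continue
        if strandness == "forward":
            sel = sel[fwd[sel] == (gm.strand == "+")]
        elif strandness == "reverse":
            sel = sel[fwd[sel] == (gm.strand == "-")]
        off = bin_offsets[gene_id]
        for i in sel:
            proj = gm.project_interval(int(starts[i]), int(ends[i]))
            if proj is None:
                continue
            mid = (proj[0] + proj[1]) // 2
            counts[off + mid // gm.bin_size] += 1
    return counts


def make_bin_index(models: Mapping[str, GeneModel]) -> pd.DataFrame:
    """Bin key table (gene_id, bin_index, tx_start, tx_end) over all models."""
    rows = []
    for gene_id in models:
        gm = models[gene_id]
        for k, (a, b) in enumerate(gm.bins):
            rows.append((gene_id, k, a, b))
    return pd.DataFrame(rows, columns=_BIN_KEY)


def count_bins(
    samples: Mapping[str, tuple[str | Path, str | Path]],
    models: Mapping[str, GeneModel],
    paired_end: bool = False,
    strandness: str = "none",
    min_mapq: int = 0,
) -> BinCountTable:
    """Quantify INPUT and IP fragments per transcript bin.

    Parameters
    ----------
    samples : mapping
        Ordered mapping sample name -> (input_path, ip_path).
    models : mapping
        Gene models from :func:`build_gene_models`.
    paired_end : bool
        Collapse properly paired mates into single fragments.
    strandness : {"none", "forward", "reverse"}
        Orientation filter; default unstranded.
    min_mapq : int
        Minimum mapping quality.
    """
    if strandness not in ("none", "forward", "reverse"):
        raise ValueError(f"invalid strandness {strandness!r}")
    bins = make_bin_index(models)
    offsets: dict[str, int] = {}
    off = 0
    for gene_id in models:
        offsets[gene_id] = off
        off += models[gene_id].n_bins

    names = list(samples)
    inp = np.zeros((len(bins), len(names)), dtype=np.int64)
    ip = np.zeros_like(inp)
    for j, name in enumerate(names):
        input_path, ip_path = samples[name]
        try:
            inp[:, j] = _count_one_library(
                input_path, models, offsets, len(bins), paired_end, strandness, min_mapq
            )
            ip[:, j] = _count_one_library(
                ip_path, models, offsets, len(bins), paired_end, strandness, min_mapq
            )
        except ValueError as exc:
            raise ValueError(f"sample {name!r}: {exc}") from exc
        logger.info(
            "sample %s: %d INPUT / %d IP fragments in bins",
            name, inp[:, j].sum(), ip[:, j].sum(),
        )
    return BinCountTable(bins=bins, samples=names, input_counts=inp, ip_counts=ip)


def gene_sum(table: BinCountTable) -> GeneCountTable:
    """Sum bin-level INPUT counts to gene level (*geneSum*)."""
    if table.n_bins == 0:
        raise ValueError("empty BinCountTable")
    df = pd.DataFrame(table.input_counts, copy=False)
    grouped = df.groupby(table.bins["gene_id"].to_numpy(), sort=False).sum()
    return GeneCountTable(
        genes=[str(g) for g in grouped.index],
        samples=list(table.samples),
        gene_counts=grouped.to_numpy(),
    )
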