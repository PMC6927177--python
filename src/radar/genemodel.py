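"""Exon-union gene models with a transcript bin grid.

Each gene is reduced to the union of its annotated exons ("longest
isoform"): overlapping exon records are merged and the disjoint pieces are
concatenated 5'->3' in genome order to form a single transcript coordinate
system.  The transcript is tiled with fixed-width bins (the unit at which
methylation is quantified and tested); the last bin may be shorter.

All internal coordinates are 0-based half-open.  GTF input is parsed as
1-based inclusive and converted on read.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 50


class GtfFormatError(ValueError):
    """Raised when the annotation file cannot be parsed as GTF."""


@dataclass
class GeneModel:
    """Union-exon transcript model of one gene with its bin grid.

    Parameters
    ----------
    gene_id : str
        Gene identifier from the GTF ``gene_id`` attribute.
    chrom : str
        Chromosome name.
    strand : str
        ``+`` or ``-``.
    exons : list of (int, int)
        Disjoint, genome-sorted exon intervals, 0-based half-open.
    bin_size : int
        Bin width in nucleotides.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    bin_size: int = DEFAULT_BIN_SIZE
    # cumulative tx offset at the start of each exon; filled in __post_init__
    _offsets: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
        if any(e <= s for s, e in self.exons):
            raise ValueError(f"{self.gene_id}: empty exon interval")
        offs = [0]
        for s, e in self.exons:
            offs.append(offs[-1] + (e - s))
        self._offsets = offs

    @property
    def tx_length(self) -> int:
        return self._offsets[-1]

    @property
    def n_bins(self) -> int:
        return max(1, -(-self.tx_length // self.bin_size))

    @property
    def bins(self) -> list[tuple[int, int]]:
        """Transcript-coordinate bin intervals tiling ``[0, tx_length)``."""
        L, w = self.tx_length, self.bin_size
        return [(i * w, min((i + 1) * w, L)) for i in range(self.n_bins)]

    # ------------------------------------------------------------------
    # coordinate maps
    # ------------------------------------------------------------------
    def tx_to_genome(self, offset: int) -> int:
        """Map a transcript offset in ``[0, tx_length)`` to a genome position."""
        if not 0 <= offset < self.tx_length:
            raise ValueError(
                f"{self.gene_id}: tx offset {offset} outside [0, {self.tx_length})"
            )
        k = bisect_right(self._offsets, offset) - 1
        start, _ = self.exons[k]
        return start + (offset - self._offsets[k])

    def genome_to_tx(self, pos: int) -> int | None:
        """Map a genome position to a transcript offset; None if intronic."""
        for k, (s, e) in enumerate(self.exons):
            if s <= pos < e:
                return self._offsets[k] + (pos - s)
        return None

    def project_interval(self, start: int, end: int) -> tuple[int, int] | None:
        """Project a genome interval onto transcript coordinates.

        Returns the transcript span covered by the intersection of
        ``[start, end)`` with the exon union, or ``None`` when disjoint.
        """
        lo = hi = None
        for k, (s, e) in enumerate(self.exons):
            a, b = max(start, s), min(end, e)
            if a < b:
                ta = self._offsets[k] + (a - s)
                tb = self._offsets[k] + (b - s)
                lo = ta if lo is None else min(lo, ta)
                hi = tb if hi is None else max(hi, tb)
        if lo is None:
            return None
        return lo, hi

    def tx_interval_to_blocks(self, tx_start: int, tx_end: int) -> list[tuple[int, int]]:
        """Map a transcript interval to disjoint genome blocks (exon pieces)."""
        if not 0 <= tx_start < tx_end <= self.tx_length:
            raise ValueError(
                f"{self.gene_id}: tx interval [{tx_start}, {tx_end}) out of bounds"
            )
        blocks = []
        for k, (s, e) in enumerate(self.exons):
            o0, o1 = self._offsets[k], self._offsets[k + 1]
            a, b = max(tx_start, o0), min(tx_end, o1)
            if a < b:
                blocks.append((s + (a - o0), s + (b - o0)))
        return blocks


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_gene_models(gtf_path: str, bin_size: int = DEFAULT_BIN_SIZE) -> dict[str, GeneModel]:
    """Build union-exon gene models from a GTF annotation.

    Exon records sharing a ``gene_id`` are unioned (overlaps merged) and
    concatenated in genome order; the resulting transcript is tiled with
    ``bin_size``-nt bins.  Genes whose exon records span multiple
    chromosomes or strands are skipped with a warning.

    Returns a dict mapping gene_id to :class:`GeneModel`.
    """
    if bin_size < 10:
        raise ValueError(f"bin_size must be >= 10, got {bin_size}")
    import pyranges

    try:
        df = pyranges.read_gtf(gtf_path).df
    except Exception as exc:  # pragma: no cover - exercised via malformed fixture
        raise GtfFormatError(f"cannot parse GTF {gtf_path!r}: {exc}") from exc
    if df.empty or "Feature" not in df.columns:
        raise GtfFormatError(f"{gtf_path!r}: no GTF features found")
    exons = df[df.Feature == "exon"]
    if "gene_id" not in exons.columns or exons.empty:
        raise GtfFormatError(f"{gtf_path!r}: no exon features with gene_id")

    models: dict[str, GeneModel] = {}
    for gene_id, sub in exons.groupby("gene_id", sort=True):
        chroms = sub.Chromosome.unique()
        if len(chroms) > 1:
            warnings.warn(
                f"gene {gene_id} spans multiple chromosomes; skipped", stacklevel=2
            )
            continue
        strands = sub.Strand.unique() if "Strand" in sub.columns else np.array(["+"])
        strand = str(strands[0]) if len(strands) == 1 and strands[0] in ("+", "-") else "+"
        iv = _merge_intervals(list(zip(sub.Start.astype(int), sub.End.astype(int))))
        models[str(gene_id)] = GeneModel(
            gene_id=str(gene_id),
            chrom=str(chroms[0]),
            strand=strand,
            exons=iv,
            bin_size=bin_size,
        )
    logger.info("built %d gene models (bin size %d)", len(models), bin_size)
    return models
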