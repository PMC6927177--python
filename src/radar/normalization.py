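"""Channel-specific normalization and expression adjustment of IP counts.

INPUT libraries are ordinary RNA-seq, so they are normalized by the
median-of-ratios method on gene-level counts.  IP libraries additionally
differ in immunoprecipitation efficiency, so their size factors are
estimated from the fold enrichment E = IP count / normalized geneSum of
the most enriched bins (library-size normalization alone would conflate
IP efficiency with depth).  Finally, normalized IP counts are divided by
a gene-wise expression factor (normalized gene counts centered to row
mean 1) so the adjusted counts reflect methylation level alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .counting import BinCountTable, GeneCountTable

logger = logging.getLogger(__name__)


@dataclass
class NormalizationResult:
    """Size factors, gene expression factors and adjusted IP counts."""

    samples: list[str]
    input_size_factors: np.ndarray  # (S,)
    ip_size_factors: np.ndarray     # (S,)
    norm_gene_counts: np.ndarray    # genes x S
    gene_factors: np.ndarray        # genes x S, row mean 1
    adjusted_ip: np.ndarray         # bins x S, real-valued
    enrichment: np.ndarray          # bins x S


def input_size_factors(genes: GeneCountTable) -> np.ndarray:
    """Median-of-ratios size factors from gene-level INPUT counts.

    The reference is the per-gene geometric mean across samples over genes
    with positive counts in every sample; each sample's factor is the
    median ratio of its counts to the reference.
    """
    counts = np.asarray(genes.gene_counts, dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("median-of-ratios requires >= 2 samples")
    pos = (counts > 0).all(axis=1)
    if not pos.any():
        raise ValueError(
            "no gene has positive counts in all samples; sequencing depth too low"
        )
    logref = np.log(counts[pos]).mean(axis=1)
    factors = np.exp(np.median(np.log(counts[pos]) - logref[:, None], axis=0))
    return factors


def ip_size_factors(
    table: BinCountTable,
    norm_genes: np.ndarray,
    gene_index: dict[str, int],
    top_frac: float = 0.01,
) -> np.ndarray:
    """IP size factors from the fold enrichment of the top-enriched bins.

    Bins are ranked by mean raw IP count across samples; over the top
    ``top_frac`` fraction the enrichment E[i, j] = t[i, j] / s[gene(i), j]
    is averaged per sample and the factors are rescaled to geometric mean 1.
    Only top bins are used so that non-specific background does not dilute
    the IP-efficiency estimate.
    """
    if not 0 < top_frac <= 0.1:
        raise ValueError(f"top_frac must be in (0, 0.1], got {top_frac}")
    t = np.asarray(table.ip_counts, dtype=float)
    n_top = max(int(round(top_frac * t.shape[0])), 1)
    if n_top < 10:
        raise ValueError(
            f"only {n_top} bins in the top {top_frac:.1%}; too few enriched bins"
        )
    order = np.argsort(-t.mean(axis=1), kind="stable")[:n_top]
    gidx = table.bins["gene_id"].map(gene_index).to_numpy()
    denom = norm_genes[gidx[order], :]
    with np.errstate(divide="ignore", invalid="ignore"):
        E = np.where(denom > 0, t[order] / denom, np.nan)
    raw = np.nanmean(E, axis=0)
    if not np.all(np.isfinite(raw)) or (raw <= 0).any():
        raise ValueError("cannot estimate IP size factors: degenerate enrichment")
    return raw / np.exp(np.mean(np.log(raw)))


def expression_adjust(
    norm_ip: np.ndarray,
    norm_genes: np.ndarray,
    gene_of_bin: np.ndarray,
    eps_frac: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Divide normalized IP counts by gene-wise expression factors.

    gene_factors[g, j] = norm_gene_counts[g, j] / mean_j norm_gene_counts[g, :],
    floored at ``eps_frac`` times the row mean to keep dropout genes from
    producing unbounded adjusted counts.  Returns (adjusted_ip, gene_factors).
    """
    norm_genes = np.asarray(norm_genes, dtype=float)
    row_mean = norm_genes.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(row_mean > 0, norm_genes / row_mean, 1.0)
    floor = eps_frac
    if (factors[row_mean[:, 0] > 0] < floor).any():
        warnings.warn(
            "gene expression factors below the floor were clipped; "
            "adjusted IP counts for dropout genes are approximate",
            stacklevel=2,
        )
    factors = np.maximum(factors, floor)
    adjusted = norm_ip / factors[gene_of_bin, :]
    return adjusted, factors


def enrichment_pca(
    adjusted_ip: np.ndarray,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """First two principal components of log1p adjusted IP, per sample.

    With ``covariates`` (samples x k), each bin's log enrichment is first
    residualized on the covariates by least squares, mirroring the
    diagnostic of regressing out known batch structure before PCA.
    """
    X = np.log1p(np.asarray(adjusted_ip, dtype=float)).T  # samples x bins
    if X.shape[0] < 3:
        raise ValueError("PCA diagnostic requires >= 3 samples")
    if covariates is not None:
        C = np.column_stack([np.ones(X.shape[0]), np.asarray(covariates, float)])
        coef, *_ = np.linalg.lstsq(C, X, rcond=None)
        X = X - C @ coef
    else:
        X = X - X.mean(axis=0)
    if np.allclose(X, 0):
        warnings.warn("constant enrichment matrix; PCA coordinates are zero", stacklevel=2)
        return np.zeros((X.shape[0], 2))
    pca = PCA(n_components=2, svd_solver="full")
    return pca.fit_transform(X)


class EnrichmentNormalizer(BaseEstimator, TransformerMixin):
    """Normalize INPUT/IP channels and adjust IP counts for expression.

    A transformer over a :class:`BinCountTable`: :meth:`fit` estimates
    sample-wise INPUT size factors (median-of-ratios on geneSum), IP size
    factors (top-bin fold enrichment) and gene-wise expression factors;
    :meth:`transform` returns the adjusted IP matrix fed to the DM model.

    Parameters
    ----------
    top_frac : float, default 0.01
        Fraction of bins (ranked by mean raw IP count) used for the IP
        size factors.
    eps_frac : float, default 0.1
        Floor on gene expression factors, as a fraction of the row mean.

    Attributes
    ----------
    input_size_factors_ : ndarray of shape (n_samples,)
    ip_size_factors_ : ndarray of shape (n_samples,)
    norm_gene_counts_ : ndarray, genes x samples
    gene_factors_ : ndarray, genes x samples (row mean 1)
    result_ : NormalizationResult
    """

    def __init__(self, top_frac: float = 0.01, eps_frac: float = 0.1):
        self.top_frac = top_frac
        self.eps_frac = eps_frac

    def fit(self, table: BinCountTable, genes: GeneCountTable | None = None):
        from .counting import gene_sum

        if genes is None:
            genes = gene_sum(table)
        gene_index = {g: i for i, g in enumerate(genes.genes)}
        missing = set(table.bins["gene_id"]) - set(gene_index)
        if missing:
            raise ValueError(f"bins reference genes absent from gene counts: {sorted(missing)[:5]}")

        sf_in = input_size_factors(genes)
        norm_genes = genes.gene_counts / sf_in[None, :]
        sf_ip = ip_size_factors(table, norm_genes, gene_index, self.top_frac)

        gidx = table.bins["gene_id"].map(gene_index).to_numpy()
        norm_ip = table.ip_counts / sf_ip[None, :]
        adjusted, factors = expression_adjust(norm_ip, norm_genes, gidx, self.eps_frac)

        with np.errstate(divide="ignore", invalid="ignore"):
            denom = norm_genes[gidx, :]
            enr = np.where(denom > 0, table.ip_counts / denom, np.inf)

        self.gene_index_ = gene_index
        self.input_size_factors_ = sf_in
        self.ip_size_factors_ = sf_ip
        self.norm_gene_counts_ = norm_genes
        self.gene_factors_ = factors
        self.result_ = NormalizationResult(
            samples=list(table.samples),
            input_size_factors=sf_in,
            ip_size_factors=sf_ip,
            norm_gene_counts=norm_genes,
            gene_factors=factors,
            adjusted_ip=adjusted,
            enrichment=enr,
        )
        logger.info(
            "normalized %d samples: INPUT factors %s, IP factors %s",
            len(table.samples),
            np.round(sf_in, 3), np.round(sf_ip, 3),
        )
        return self

    def transform(self, table: BinCountTable) -> np.ndarray:
        """Adjusted IP matrix (bins x samples, real-valued)."""
        gidx = table.bins["gene_id"].map(self.gene_index_).to_numpy()
        norm_ip = table.ip_counts / self.ip_size_factors_[None, :]
        return norm_ip / self.gene_factors_[gidx, :]

    def fit_transform(self, table: BinCountTable, genes: GeneCountTable | None = None, **kw):
        return self.fit(table, genes).result_.adjusted_ip
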