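"""Bin filtering and the differential methylation test.

Two pre-specified filters remove uninformative bins before testing:
bins with mean raw IP count across samples below ``min_ip`` (too noisy,
likely unmethylated) and IP-depleted bins whose mean fold enrichment is
below ``min_enrichment`` (counts attributable to non-specific binding).
Each retained bin is then fitted with the Poisson-gamma random-effect
regression; the group coefficient is Wald-tested and p-values are
Benjamini-Hochberg adjusted across all tested bins.  Because the filters
do not look at group labels, they do not bias the FDR.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .counting import BinCountTable
from .model import OptimizerConfig, fit_bins, wald_test
from .normalization import NormalizationResult

logger = logging.getLogger(__name__)


def filter_bins(
    table: BinCountTable,
    norm: NormalizationResult,
    min_ip: float = 15,
    min_enrichment: float = 1.0,
) -> np.ndarray:
    """Boolean mask of bins retained for testing.

    A bin is dropped when its mean raw IP count across samples is below
    ``min_ip``, or when its mean fold enrichment across samples is below
    ``min_enrichment`` (IP-depleted).
    """
    mean_ip = np.asarray(table.ip_counts, float).mean(axis=1)
    enr = np.asarray(norm.enrichment, float)
    with np.errstate(invalid="ignore"):
        mean_enr = np.nanmean(np.where(np.isfinite(enr), enr, np.nan), axis=1)
    mask = (mean_ip >= min_ip) & (mean_enr >= min_enrichment)
    if not mask.any():
        raise ValueError(
            "no bins pass the filters; consider lowering min_ip "
            f"(currently {min_ip}) or sequencing deeper"
        )
    logger.info(
        "filtering: %d/%d bins retained (%d low IP, %d IP-depleted)",
        mask.sum(), mask.size, (mean_ip < min_ip).sum(),
        ((mean_ip >= min_ip) & (mean_enr < min_enrichment)).sum(),
    )
    return mask


def make_design(group: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
    """Design matrix [X0 | covariates] with the group indicator first."""
    group = np.asarray(group)
    uniq = np.unique(group)
    if uniq.size != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    x0 = (group == uniq[1]).astype(float)
    if np.minimum((x0 == 0).sum(), (x0 == 1).sum()) < 2:
        raise ValueError("need >= 2 samples per group")
    cols = [x0]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != x0.size:
            C = C.T
        cols.extend(C.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(x0)), X])) < X.shape[1] + 1:
        raise ValueError("design matrix is rank deficient")
    return X


def run_dm_test(
    adjusted_ip: np.ndarray,
    X: np.ndarray,
    bins: pd.DataFrame | None = None,
    mask: np.ndarray | None = None,
    optimizer: OptimizerConfig | None = None,
    keep_nonconverged: bool = False,
) -> pd.DataFrame:
    """Fit every retained bin and return the DM result table.

    Parameters
    ----------
    adjusted_ip : array, bins x samples
        Expression-adjusted IP counts; rounded half-to-even to integers
        at this boundary (the likelihood is a count model).
    X : array, samples x p
        Design matrix (group indicator first; no intercept column).
    bins : DataFrame, optional
        Bin key table aligned with ``adjusted_ip`` rows.
    mask : bool array, optional
        Retained-bin mask from :func:`filter_bins`; default all bins.

    Returns
    -------
    DataFrame with one row per retained bin: bin key columns, ``beta0``
    (log fold change), ``se``, ``z``, ``p``, ``padj``, ``mu``, ``psi``,
    ``converged``.  Non-converged bins are reported but excluded from the
    BH adjustment unless ``keep_nonconverged``.
    """
    Y_all = np.rint(np.asarray(adjusted_ip, float))
    B = Y_all.shape[0]
    if mask is None:
        mask = np.ones(B, dtype=bool)
    idx = np.nonzero(mask)[0]
    Y = Y_all[idx]
    res = fit_bins(Y, X, optimizer)
    z, p, se, ok = wald_test(Y, X, res["mu"], res["beta"], res["psi"], coef_index=0)
    conv = res["converged"] & ok

    out = pd.DataFrame(
        {
            "beta0": res["beta"][:, 0],
            "se": se,
            "z": z,
            "p": p,
            "mu": res["mu"],
            "psi": res["psi"],
            "n_iter": res["n_iter"],
            "converged": conv,
        }
    )
    testable = conv | keep_nonconverged
    padj = np.full(len(out), np.nan)
    if testable.any():
        padj[testable] = multipletests(out.loc[testable, "p"], method="fdr_bh")[1]
    out["padj"] = padj
    if bins is not None:
        key = bins.iloc[idx].reset_index(drop=True)
        out = pd.concat([key, out], axis=1)
        sort_cols = [c for c in ("gene_id", "bin_index") if c in out.columns]
        out = out.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    logger.info(
        "DM test: %d bins fitted, %d converged, %d significant at padj<0.1",
        len(out), int(conv.sum()), int((out["padj"] < 0.1).sum()),
    )
    return out


class DifferentialMethylationTest(BaseEstimator):
    """Per-bin differential methylation caller.

    scikit-learn-style estimator: ``fit(Y, group)`` fits the
    Poisson-gamma regression to each row of the adjusted IP count matrix
    ``Y`` (bins x samples) with a two-group design plus optional
    covariates, Wald-tests the group coefficient and BH-adjusts the
    p-values.

    Parameters
    ----------
    min_ip : float, default 15
        Mean raw IP count threshold used when a :class:`BinCountTable`
        and normalization result are supplied for filtering.
    min_enrichment : float, default 1.0
        IP-depletion threshold on mean fold enrichment.
    fdr_cutoff : float, default 0.1
        BH level used by :meth:`predict`.
    keep_nonconverged : bool, default False
        Include non-converged bins in the BH adjustment.

    Attributes
    ----------
    results_ : DataFrame
        Full per-bin result table (see :func:`run_dm_test`).
    mask_ : ndarray of bool
        Bins retained by filtering.
    """

    def __init__(
        self,
        min_ip: float = 15,
        min_enrichment: float = 1.0,
        fdr_cutoff: float = 0.1,
        keep_nonconverged: bool = False,
        tol: float = 1e-8,
        max_iter: int = 1000,
    ):
        self.min_ip = min_ip
        self.min_enrichment = min_enrichment
        self.fdr_cutoff = fdr_cutoff
        self.keep_nonconverged = keep_nonconverged
        self.tol = tol
        self.max_iter = max_iter

    def fit(
        self,
        Y: np.ndarray,
        group: np.ndarray,
        covariates: np.ndarray | None = None,
        bins: pd.DataFrame | None = None,
        table: BinCountTable | None = None,
        norm: NormalizationResult | None = None,
    ):
        X = make_design(group, covariates)
        if table is not None and norm is not None:
            mask = filter_bins(table, norm, self.min_ip, self.min_enrichment)
        else:
            mask = np.ones(np.atleast_2d(Y).shape[0], dtype=bool)
        cfg = OptimizerConfig(tol=self.tol, max_iter=self.max_iter)
        self.design_ = X
        self.mask_ = mask
        self.results_ = run_dm_test(
            Y, X, bins=bins, mask=mask, optimizer=cfg,
            keep_nonconverged=self.keep_nonconverged,
        )
        return self

    def predict(self, Y=None) -> np.ndarray:
        """Boolean DM call per tested bin at the configured BH level."""
        return (self.results_["padj"] < self.fdr_cutoff).to_numpy()
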