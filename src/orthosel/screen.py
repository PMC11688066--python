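"""Negative-binomial Wald screen for differential expression between tissues.

A transparent, moment-based stand-in for heavyweight DE engines: its role
in the selection pipeline is only to reduce the gene universe to the
tissue-discriminating genes before the PLS stages. Externally computed
screens can be substituted through the DEG table format in :mod:`.io`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .expression import validate_counts

#: pseudocount added to class means before log2 ratios
PSEUDOCOUNT = 0.5


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    ``factor_s = median_g (count_gs / geomean_g)`` over genes whose
    geometric mean across samples is positive (i.e. genes expressed in
    every sample).
    """
    counts = validate_counts(counts)
    values = counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; size factors "
            "undefined (consider a pseudo-reference fallback)"
        )
    log_vals = np.log(values[all_positive])
    log_geomean = log_vals.mean(axis=1)
    ratios = np.exp(log_vals - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_screen(
    counts: pd.DataFrame,
    labels,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test between two classes.

    ``labels`` is a binary vector over samples; positive entries are class
    A and the reported ``log2_fc`` is A over B. Class means are computed
    on size-factor-normalized counts; a common moment-based dispersion
    ``alpha = max(0, (s^2 - m) / m^2)`` is estimated from the pooled
    within-class mean and variance, and the Wald statistic propagates the
    NB variance of each class mean through the (pseudocounted) log ratio.

    Returns a DataFrame indexed by gene with columns ``log2_fc``,
    ``p_value``, ``p_adj``, ``base_mean``.
    """
    counts = validate_counts(counts)
    labels = np.asarray(labels)
    if labels.dtype == bool:
        mask_a = labels
    else:
        mask_a = labels.astype(float) > 0
    n_a, n_b = int(mask_a.sum()), int((~mask_a).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("both classes need at least 2 samples")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    norm = counts.to_numpy(dtype=float) / size_factors.to_numpy(dtype=float)[None, :]

    a, b = norm[:, mask_a], norm[:, ~mask_a]
    m_a, m_b = a.mean(axis=1), b.mean(axis=1)
    v_a, v_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)

    pooled_var = ((n_a - 1) * v_a + (n_b - 1) * v_b) / (n_a + n_b - 2)
    pooled_mean = (n_a * m_a + n_b * m_b) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(
            pooled_mean > 0,
            np.maximum(0.0, (pooled_var - pooled_mean) / pooled_mean**2),
            0.0,
        )

    var_mean_a = (m_a + alpha * m_a**2) / n_a
    var_mean_b = (m_b + alpha * m_b**2) / n_b
    lfc = np.log2((m_a + PSEUDOCOUNT) / (m_b + PSEUDOCOUNT))
    se = np.sqrt(
        var_mean_a / (m_a + PSEUDOCOUNT) ** 2 + var_mean_b / (m_b + PSEUDOCOUNT) ** 2
    ) / np.log(2)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    # degenerate genes (both classes constant): no evidence either way
    p = np.where(se > 0, p, 1.0)
    lfc = np.where((m_a == 0) & (m_b == 0), 0.0, lfc)
    return pd.DataFrame(
        {
            "log2_fc": lfc,
            "p_value": p,
            "p_adj": bh_adjust(p),
            "base_mean": norm.mean(axis=1),
        },
        index=counts.index,
    )


def screen_genes(deg: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.01) -> set[str]:
    """Genes with ``|log2_fc| > lfc_min`` and ``p_adj < fdr_max`` (strict)."""
    if lfc_min <= 0 or fdr_max <= 0:
        raise ValueError("thresholds must be positive")
    keep = (deg["log2_fc"].abs() > lfc_min) & (deg["p_adj"] < fdr_max)
    return set(deg.index[keep])


class DifferentialExpressionScreen(SelectorMixin, BaseEstimator):
    """Feature selector keeping tissue-discriminating genes by NB Wald test.

    Parameters
    ----------
    lfc_min : float, default 1.0
        Minimum absolute log2 fold change (strict).
    fdr_max : float, default 0.01
        Maximum BH-adjusted p-value (strict).

    Attributes
    ----------
    results_ : DataFrame with log2_fc / p_value / p_adj / base_mean per gene.
    size_factors_ : Series of per-sample normalization factors.
    support_ : boolean mask of selected genes.
    """

    def __init__(self, lfc_min: float = 1.0, fdr_max: float = 0.01):
        self.lfc_min = lfc_min
        self.fdr_max = fdr_max

    def fit(self, X, y):
        """Fit on samples x genes counts ``X`` and binary tissue labels ``y``."""
        if isinstance(X, pd.DataFrame):
            counts = X.T
        else:
            X = np.asarray(X)
            counts = pd.DataFrame(
                X.T,
                index=[f"g{i}" for i in range(X.shape[1])],
                columns=[f"s{j}" for j in range(X.shape[0])],
            )
        self.n_features_in_ = counts.shape[0]
        self.size_factors_ = estimate_size_factors(counts)
        self.results_ = nb_wald_screen(counts, y, self.size_factors_)
        selected = screen_genes(self.results_, self.lfc_min, self.fdr_max)
        self.support_ = self.results_.index.isin(sorted(selected))
        self.selected_genes_ = set(selected)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
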