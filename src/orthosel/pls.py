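"""First-component PLS-DA weights on tumor samples and weight-based selection.

For a single mean-centered response the first PLS weight vector is, in
closed form, proportional to ``X_c^T y_c`` — the per-gene covariance of
expression with class membership. Genes with large first-component weight
discriminate the two tumor types.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted


def _centered(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (samples x genes)")
    if len(y) != X.shape[0]:
        raise ValueError("label length does not match sample count")
    if np.ptp(y) == 0:
        raise ValueError("labels are constant; discrimination undefined")
    return X - X.mean(axis=0), y - y.mean()


def plsda_first_component(X, y, normalization: str = "unit_norm"):
    """First PLS-DA weight vector for samples x genes ``X`` and labels ``y``.

    ``X`` and ``y`` are mean-centered; the weight vector is
    ``w = X_c^T y_c``, returned raw or scaled to unit Euclidean norm.
    Sign convention: the entry of largest magnitude is made positive.
    Returns a Series when ``X`` is a DataFrame, else an ndarray.
    """
    if normalization not in ("unit_norm", "raw"):
        raise ValueError(f"unknown normalization {normalization!r}")
    columns = X.columns if isinstance(X, pd.DataFrame) else None
    Xc, yc = _centered(X, y)
    w = Xc.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("all genes are constant; PLS weights undefined")
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    if normalization == "unit_norm":
        w = w / norm
    if columns is not None:
        return pd.Series(w, index=columns, name="weight")
    return w


def select_by_weight(weights, threshold: float, mode: str = "absolute"):
    """Genes whose first-component weight passes ``threshold`` (strict).

    ``absolute`` compares ``|weight| > threshold`` (a gene strongly
    enriched in either tumor type is discriminative regardless of sign);
    ``signed`` compares ``weight > threshold`` literally.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if mode == "absolute":
        mask = np.abs(np.asarray(weights, dtype=float)) > threshold
    elif mode == "signed":
        mask = np.asarray(weights, dtype=float) > threshold
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    if isinstance(weights, pd.Series):
        return set(weights.index[mask])
    return set(np.flatnonzero(mask))


class TumorPLSSelector(SelectorMixin, BaseEstimator):
    """Select tumor-type-discriminating genes by first PLS-DA weight.

    Parameters
    ----------
    mode : {"permutation", "quantile", "absolute", "signed"}
        How the weight cutoff is set. ``permutation`` (default)
        standardizes each gene's raw covariance weight by its own
        permutation-null standard deviation and keeps genes with
        ``|z| > perm_z``; the calibration is per gene and scale-free, so
        selection tracks signal content rather than the size of the gene
        universe or per-gene expression scale. ``quantile`` keeps the top
        fraction of genes by |weight|. ``absolute``/``signed`` use a
        fixed ``threshold`` (strict inequality) on the chosen
        normalization scale.
    threshold : float, optional — required for absolute/signed modes.
    quantile : float, default 0.16
        Fraction kept in quantile mode (roughly the selection ratio a
        full-scale two-tumor screen of ~4000 genes yields).
    n_permutations : int, default 30
        Label permutations in permutation mode.
    perm_z : float, default 4.0
        Null-standardized |weight| cutoff in permutation mode.
    normalization : {"unit_norm", "raw"}, default "unit_norm"
    random_state : int or None

    Attributes
    ----------
    weights_ : Series (or ndarray) of first-component weights.
    threshold_ : resolved weight cutoff actually applied.
    support_ : boolean selection mask.
    """

    def __init__(
        self,
        mode: str = "permutation",
        threshold: float | None = None,
        quantile: float = 0.16,
        n_permutations: int = 30,
        perm_z: float = 4.0,
        normalization: str = "unit_norm",
        random_state=None,
    ):
        self.mode = mode
        self.threshold = threshold
        self.quantile = quantile
        self.n_permutations = n_permutations
        self.perm_z = perm_z
        self.normalization = normalization
        self.random_state = random_state

    def fit(self, X, y):
        self.n_features_in_ = np.shape(X)[1]
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        w = plsda_first_component(X, y, normalization=self.normalization)
        self.weights_ = w
        abs_w = np.abs(np.asarray(w, dtype=float))
        if self.mode in ("absolute", "signed"):
            if self.threshold is None:
                raise ValueError(f"mode {self.mode!r} requires a threshold")
            self.threshold_ = float(self.threshold)
        elif self.mode == "quantile":
            if not 0 < self.quantile <= 1:
                raise ValueError("quantile must lie in (0, 1]")
            self.threshold_ = float(np.quantile(abs_w, 1.0 - self.quantile))
        elif self.mode == "permutation":
            rng = np.random.default_rng(self.random_state)
            y_arr = np.asarray(y, dtype=float)
            # null distribution of the *raw* covariance weight, per gene
            raw = np.asarray(
                plsda_first_component(X, y, normalization="raw"), dtype=float
            )
            null = np.empty((self.n_permutations, len(raw)))
            for b in range(self.n_permutations):
                perm = rng.permutation(y_arr)
                null[b] = np.asarray(
                    plsda_first_component(X, perm, normalization="raw"), dtype=float
                )
            null_sd = null.std(axis=0, ddof=1)
            null_sd[null_sd == 0] = np.inf
            self.null_sd_ = null_sd
            self.z_scores_ = np.abs(raw) / null_sd
            self.threshold_ = float(self.perm_z)
        else:
            raise ValueError(f"unknown selection mode {self.mode!r}")

        values = np.asarray(w, dtype=float)
        if self.mode == "signed":
            self.support_ = values > self.threshold_
        elif self.mode == "permutation":
            self.support_ = self.z_scores_ > self.threshold_
        else:
            self.support_ = abs_w > self.threshold_
        if isinstance(w, pd.Series):
            self.selected_genes_ = set(w.index[self.support_])
        else:
            self.selected_genes_ = set(np.flatnonzero(self.support_))
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
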