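"""Combining the two selection procedures, baselines and cluster validation.

The final gene list is the intersection of the tumor-derived
(PLS-DA-discriminating) and normal-derived (tissue-invariant) sets:
genes that separate the two tumor types while staying flat across the
corresponding normal tissues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as hierarchy
from sklearn.base import BaseEstimator
from sklearn.metrics import adjusted_rand_score

from .expression import LabeledSplit, split_and_label
from .invariance import NormalInvarianceSelector
from .pls import TumorPLSSelector
from .screen import DifferentialExpressionScreen

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Tumor-derived, normal-derived and intersected gene sets."""

    tumor_selected: tuple
    normal_invariant: tuple
    final: tuple
    thresholds: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        with open(path) as fh:
            data = json.load(fh)
        for key in ("tumor_selected", "normal_invariant", "final"):
            data[key] = tuple(data[key])
        return cls(**data)


def intersect_selections(tumor, invariant, thresholds=None, provenance=None) -> SelectionResult:
    """Intersect the two procedures' gene sets (sorted, deterministic)."""
    tumor, invariant = set(tumor), set(invariant)
    final = tumor & invariant
    if not final:
        logger.warning("tumor-derived and invariant gene sets are disjoint")
    return SelectionResult(
        tumor_selected=tuple(sorted(tumor, key=str)),
        normal_invariant=tuple(sorted(invariant, key=str)),
        final=tuple(sorted(final, key=str)),
        thresholds=thresholds or {},
        provenance=provenance or {},
    )


def baseline_de_selection(
    deg_normal: pd.DataFrame, lfc_max: float = 0.5, padj_min: float = 0.6
) -> set[str]:
    """Naive 'invariant by DE' baseline: small fold change AND large p_adj.

    The contrast the selection method is evaluated against: genes called
    non-differential between the two normal tissues by an ordinary DE
    screen (|log2_fc| < lfc_max and p_adj > padj_min, both strict).
    """
    if lfc_max <= 0 or not 0 <= padj_min <= 1:
        raise ValueError("invalid baseline thresholds")
    keep = (deg_normal["log2_fc"].abs() < lfc_max) & (deg_normal["p_adj"] > padj_min)
    return set(deg_normal.index[keep])


def cluster_purity(expr: pd.DataFrame, labels, return_ari: bool = False):
    """Two-cluster purity of samples under average-linkage clustering.

    ``expr`` is genes x samples restricted to the selected genes; each
    gene is standardized (z-score across samples) before computing
    Euclidean distances between samples. Purity is the fraction of
    samples whose 2-way cluster's majority tissue matches their own —
    1 for perfect separation, ~max class fraction for label-independent
    expression.
    """
    labels = np.asarray(labels)
    if expr.shape[0] < 2:
        raise ValueError("cluster purity needs at least 2 genes")
    if min(np.sum(labels == c) for c in np.unique(labels)) < 2 or len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 samples per class")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (values - values.mean(axis=1)[:, None]) / sd[:, None]
    link = hierarchy.linkage(z.T, method="average", metric="euclidean")
    assign = hierarchy.fcluster(link, t=2, criterion="maxclust")
    purity = sum(
        pd.Series(labels[assign == c]).value_counts().iloc[0]
        for c in np.unique(assign)
    ) / len(labels)
    if return_ari:
        return float(purity), float(adjusted_rand_score(labels, assign))
    return float(purity)


def evaluate_selection(selected, truth: pd.Series, target_class: str = "CANCER_INVARIANT") -> dict:
    """Precision/recall of a gene set against planted truth classes.

    Also reports the contamination fraction per class (fraction of the
    selection belonging to each non-target class). An empty selection
    yields recall 0 and NaN precision.
    """
    selected = set(selected)
    missing = selected - set(truth.index)
    if missing:
        raise ValueError(f"selected gene(s) absent from truth: {sorted(missing)[:5]}")
    target = set(truth.index[truth == target_class])
    tp = len(selected & target)
    recall = tp / len(target) if target else float("nan")
    precision = tp / len(selected) if selected else float("nan")
    contamination = {}
    for cls in truth.unique():
        if cls == target_class:
            continue
        members = set(truth.index[truth == cls])
        contamination[cls] = len(selected & members) / len(selected) if selected else float("nan")
    return {
        "n_selected": len(selected),
        "n_target": len(target),
        "recall": recall,
        "precision": precision,
        "contamination": contamination,
    }


class CancerInvariantGeneSelector(BaseEstimator):
    """End-to-end selection of cancer-specific, normal-invariant genes.

    Pipeline: (1) NB Wald screen between the two tumor types restricts
    the gene universe to tissue-discriminating genes; (2) PLS-DA on tumor
    samples keeps genes with large first-component weight; (3) the
    normal-invariance filter keeps genes whose normal-tissue coefficient
    stays below ``tau``; the final list is the intersection of (2) and
    (3) within the screened universe.

    ``fit`` consumes the four-group dataset directly: a genes x samples
    count matrix, the matching TPM matrix and the sample metadata table.
    """

    def __init__(
        self,
        screen_lfc_min: float = 1.0,
        screen_fdr_max: float = 0.01,
        tumor_mode: str = "permutation",
        tumor_threshold: float | None = None,
        tumor_quantile: float = 0.16,
        tau: float = 0.9,
        scaling: str = "correlation",
        invariance_method: str = "coef_shortcut",
        sampler: str = "gaussian",
        n_draws: int = 20_000,
        log_tpm: bool = False,
        random_state=None,
    ):
        self.screen_lfc_min = screen_lfc_min
        self.screen_fdr_max = screen_fdr_max
        self.tumor_mode = tumor_mode
        self.tumor_threshold = tumor_threshold
        self.tumor_quantile = tumor_quantile
        self.tau = tau
        self.scaling = scaling
        self.invariance_method = invariance_method
        self.sampler = sampler
        self.n_draws = n_draws
        self.log_tpm = log_tpm
        self.random_state = random_state

    def fit(self, counts: pd.DataFrame, tpm: pd.DataFrame, meta: pd.DataFrame):
        """Run the full selection on a four-group dataset.

        Parameters
        ----------
        counts : genes x samples integer counts (screen stage).
        tpm : genes x samples TPM matrix (PLS stages).
        meta : sample metadata with tissue and condition columns.
        """
        if self.log_tpm:
            tpm = np.log2(tpm + 1.0)
        split: LabeledSplit = split_and_label(tpm, meta)

        tumor_ids = split.X_tumor.columns
        self.screen_ = DifferentialExpressionScreen(
            lfc_min=self.screen_lfc_min, fdr_max=self.screen_fdr_max
        ).fit(counts[tumor_ids].T, split.y_tumor.to_numpy())
        screened = sorted(self.screen_.selected_genes_)
        self.screened_genes_ = set(screened)
        if len(screened) < 2:
            raise ValueError("screen kept fewer than 2 genes; nothing to select from")

        X_T = split.X_tumor.loc[screened].T  # samples x genes
        self.tumor_selector_ = TumorPLSSelector(
            mode=self.tumor_mode,
            threshold=self.tumor_threshold,
            quantile=self.tumor_quantile,
            random_state=self.random_state,
        ).fit(X_T, split.y_tumor.to_numpy())

        X_N = split.X_normal.loc[screened].T
        self.invariance_selector_ = NormalInvarianceSelector(
            tau=self.tau,
            scaling=self.scaling,
            method=self.invariance_method,
            sampler=self.sampler,
            n_draws=self.n_draws,
            random_state=self.random_state,
        ).fit(X_N, split.y_normal.to_numpy())

        self.result_ = intersect_selections(
            self.tumor_selector_.selected_genes_,
            self.invariance_selector_.selected_genes_,
            thresholds={
                "screen_lfc_min": self.screen_lfc_min,
                "screen_fdr_max": self.screen_fdr_max,
                "tumor_mode": self.tumor_mode,
                "tumor_weight_threshold": self.tumor_selector_.threshold_,
                "tau": self.tau,
                "scaling": self.scaling,
            },
            provenance={
                "n_genes_input": counts.shape[0],
                "n_genes_screened": len(screened),
                "invariance_method": self.invariance_method,
                "sampler": self.sampler,
                "n_draws": self.n_draws,
                "random_state": self.random_state,
            },
        )
        self.tumor_selected_ = set(self.result_.tumor_selected)
        self.normal_invariant_ = set(self.result_.normal_invariant)
        self.final_ = set(self.result_.final)
        logger.info(
            "selection funnel: %d genes -> %d screened -> %d tumor / %d invariant -> %d final",
            counts.shape[0],
            len(screened),
            len(self.tumor_selected_),
            len(self.normal_invariant_),
            len(self.final_),
        )
        return self

    def transform(self, tpm: pd.DataFrame) -> pd.DataFrame:
        """Restrict a genes x samples matrix to the final gene list."""
        if not hasattr(self, "final_"):
            raise ValueError("selector is not fitted")
        return tpm.loc[sorted(self.final_)]
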