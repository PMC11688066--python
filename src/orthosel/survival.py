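"""Per-gene survival validation: median dichotomization, KM curves, log-rank.

Each selected gene is tested within each tumor cohort (tissue A and B
separately): samples are split at the median expression into low/high
groups and overall survival is compared with the two-sample log-rank
test. Kaplan–Meier estimation and the log-rank statistic are delegated
to lifelines.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .screen import bh_adjust

logger = logging.getLogger(__name__)


def dichotomize_expression(values, method: str = "median") -> np.ndarray:
    """Median split: strictly above the median -> 1 (high), else 0 (low).

    Ties at the median fall to the low group by this fixed rule, so the
    split is reproducible; group sizes then differ by at most the number
    of median ties.
    """
    if method != "median":
        raise ValueError(f"unknown dichotomization method {method!r}")
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 samples to dichotomize")
    if np.ptp(values) == 0:
        raise ValueError("all expression values identical; no split exists")
    return (values > np.median(values)).astype(int)


def km_estimate(times, events) -> pd.Series:
    """Kaplan–Meier product-limit survival curve.

    Returns a right-continuous step function as a Series of survival
    probabilities indexed by time (starting at S(0) = 1).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if (times < 0).any():
        raise ValueError("negative survival time")
    if len(times) != len(events):
        raise ValueError("times and events must have equal length")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    curve = kmf.survival_function_["KM_estimate"]
    curve.index.name = "time"
    return curve


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi2, p).

    Observed-minus-expected event counts over distinct event times with
    hypergeometric variance; chi2 is referred to a chi-square with 1 df.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if (times < 0).any():
        raise ValueError("negative survival time")
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two non-empty groups required")
    if events.sum() == 0:
        raise ValueError("no events observed; log-rank undefined")
    mask = groups == labels[0]
    res = _lifelines_logrank(
        times[mask], times[~mask], event_observed_A=events[mask], event_observed_B=events[~mask]
    )
    return float(res.test_statistic), float(res.p_value)


def survival_screen(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    genes,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dichotomize + log-rank for every (gene, tumor cohort) pair.

    One test per gene per tissue cohort, flagged significant at
    ``p < alpha`` without multiplicity correction (per-gene reporting); a
    BH-adjusted column ``p_bh`` is emitted alongside for the stricter
    view. Gene/cohort pairs without usable survival data are skipped with
    a warning; genes absent from ``expr`` are skipped and counted.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if "time" not in meta.columns or "event" not in meta.columns:
        raise ValueError("metadata lacks survival columns 'time'/'event'")
    genes = list(genes)
    present = [g for g in genes if g in expr.index]
    n_missing = len(genes) - len(present)
    if n_missing:
        logger.warning("%d gene(s) absent from expression matrix; skipped", n_missing)

    rows = []
    tumor = meta[meta["condition"] == "tumor"]
    for tissue in sorted(tumor["tissue"].unique()):
        cohort = tumor[tumor["tissue"] == tissue]
        usable = cohort.index[cohort["time"].notna() & cohort["event"].notna()]
        usable = usable.intersection(expr.columns)
        for gene in present:
            values = expr.loc[gene, usable].to_numpy(dtype=float)
            try:
                groups = dichotomize_expression(values)
                times = cohort.loc[usable, "time"].to_numpy(dtype=float)
                events = cohort.loc[usable, "event"].to_numpy(dtype=int)
                chi2, p = logrank_test(times, events, groups)
            except ValueError as exc:
                logger.warning("skipping gene %s cohort %s: %s", gene, tissue, exc)
                continue
            rows.append(
                {
                    "gene_id": gene,
                    "cohort": tissue,
                    "cutpoint": float(np.median(values)),
                    "n_low": int((groups == 0).sum()),
                    "n_high": int((groups == 1).sum()),
                    "chi2": chi2,
                    "p": p,
                }
            )
    result = pd.DataFrame(
        rows, columns=["gene_id", "cohort", "cutpoint", "n_low", "n_high", "chi2", "p"]
    )
    if len(result):
        result["p_bh"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["p"] < alpha
    else:
        result["p_bh"] = []
        result["significant"] = []
    result.attrs["n_missing_genes"] = n_missing
    return result
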