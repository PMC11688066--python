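"""Synthetic four-group RNA-seq count generator with planted gene classes.

The generator emulates the study design the selection method targets: two
tissues (A, B), each with tumor and normal samples, and four gene classes

* ``TISSUE`` — tissue-specific in both conditions (the confounders the
  method is built to reject),
* ``CANCER_INVARIANT`` — tissue-discriminating in tumors only, flat in
  normals (the selection target),
* ``CANCER_SHARED`` — a tumor-vs-normal effect identical in both tissues
  (cancer genes that do not discriminate tumor type),
* ``SHARED_NULL`` — no effect anywhere.

Counts are negative binomial with mean ``mu_gs = base_g * L_s * f_gs``
(gene baseline x sample library size x class fold) and variance
``mu + dispersion * mu^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import validate_metadata

GENE_CLASSES = ("TISSUE", "CANCER_INVARIANT", "CANCER_SHARED", "SHARED_NULL")


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic cohort.

    Defaults are a desk-scale rendition of a two-tissue tumor/normal
    RNA-seq design: 400 genes, 30/30 tumor and 60/60 normal samples, and
    4-fold planted effects. ``dispersion`` is the NB overdispersion
    (variance ``mu + dispersion * mu^2``); the default 0.02 reflects
    uniformly processed bulk RNA-seq and keeps planted effects carrying
    information comparable to the much larger cohorts the design mimics.
    """

    n_genes: int = 400
    group_sizes: tuple[int, int, int, int] = (30, 30, 60, 60)  # tumorA, tumorB, normalA, normalB
    class_fractions: dict = field(
        default_factory=lambda: {
            "TISSUE": 0.25,
            "CANCER_INVARIANT": 0.10,
            "CANCER_SHARED": 0.10,
            "SHARED_NULL": 0.55,
        }
    )
    fold_tissue: float = 4.0
    fold_cancer: float = 4.0
    base_mean_log_range: tuple[float, float] = (1.5, 3.0)  # log10 of baseline mean
    dispersion: float = 0.02
    lib_size_sigma: float = 0.3
    length_range_bp: tuple[int, int] = (500, 10_000)
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_fractions.get(c, 0.0) for c in GENE_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1 (got {total})")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene class(es): {sorted(unknown)}")
        if any(s < 2 for s in self.group_sizes):
            raise ValueError("every group needs at least 2 samples")
        if self.fold_tissue <= 1 or self.fold_cancer <= 1:
            raise ValueError("fold changes must exceed 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.lib_size_sigma < 0:
            raise ValueError("lib_size_sigma must be non-negative")


def _assign_classes(n_genes: int, fractions: dict) -> np.ndarray:
    # largest-remainder apportionment so counts sum exactly to n_genes
    quotas = np.array([fractions.get(c, 0.0) * n_genes for c in GENE_CLASSES])
    counts = np.floor(quotas).astype(int)
    remainder = n_genes - counts.sum()
    order = np.argsort(-(quotas - counts))
    counts[order[:remainder]] += 1
    return np.repeat(np.array(GENE_CLASSES, dtype=object), counts)


def generate_dataset(cfg: SyntheticConfig | None = None):
    """Generate (counts, metadata, gene lengths, truth) for a config.

    Returns
    -------
    counts : DataFrame, genes x samples, integer NB draws.
    meta : DataFrame indexed by sample id (tissue, condition).
    lengths : Series of gene lengths in bp.
    truth : Series mapping gene id -> planted class.
    """
    cfg = cfg or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    gene_ids = np.array([f"G{i:04d}" for i in range(cfg.n_genes)])
    classes = _assign_classes(cfg.n_genes, cfg.class_fractions)
    truth = pd.Series(classes, index=gene_ids, name="class")

    groups = [("tumor", "A"), ("tumor", "B"), ("normal", "A"), ("normal", "B")]
    sample_ids, tissues, conditions = [], [], []
    for (condition, tissue), size in zip(groups, cfg.group_sizes):
        for i in range(size):
            sample_ids.append(f"{condition[0].upper()}{tissue}_{i:03d}")
            tissues.append(tissue)
            conditions.append(condition)
    meta = pd.DataFrame(
        {"tissue": tissues, "condition": conditions}, index=pd.Index(sample_ids, name="sample_id")
    )

    lo, hi = cfg.base_mean_log_range
    base = 10.0 ** rng.uniform(lo, hi, size=cfg.n_genes)
    lib = np.exp(rng.normal(0.0, cfg.lib_size_sigma, size=len(sample_ids)))
    direction = rng.choice([-1.0, 1.0], size=cfg.n_genes)

    tissue_sign = np.where(np.array(tissues) == "A", 1.0, -1.0)  # per sample
    is_tumor = np.array(conditions) == "tumor"

    # log2 fold matrix, genes x samples
    log2f = np.zeros((cfg.n_genes, len(sample_ids)))
    l2t = np.log2(cfg.fold_tissue)
    l2c = np.log2(cfg.fold_cancer)
    for g in range(cfg.n_genes):
        cls = classes[g]
        d = direction[g]
        if cls == "TISSUE":
            # symmetric split keeps the baseline the geometric group mean
            log2f[g] = d * tissue_sign * l2t / 2.0
        elif cls == "CANCER_INVARIANT":
            log2f[g] = np.where(is_tumor, d * tissue_sign * l2c / 2.0, 0.0)
        elif cls == "CANCER_SHARED":
            log2f[g] = np.where(is_tumor, d * l2c, 0.0)
        # SHARED_NULL: zeros

    mu = base[:, None] * lib[None, :] * (2.0 ** log2f)
    r = 1.0 / cfg.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    # generator diagnostics (not part of the on-disk formats)
    counts_df.attrs["base_mean"] = pd.Series(base, index=gene_ids)
    counts_df.attrs["lib_size"] = pd.Series(lib, index=sample_ids)
    counts_df.attrs["mu"] = pd.DataFrame(mu, index=gene_ids, columns=sample_ids)

    lengths = pd.Series(
        rng.integers(cfg.length_range_bp[0], cfg.length_range_bp[1] + 1, size=cfg.n_genes),
        index=gene_ids,
        name="length_bp",
    )
    return counts_df, meta, lengths, truth


def generate_survival(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    effect_genes,
    hazard_ratio: float,
    censor_rate: float = 0.3,
    baseline_hazard: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach exponential survival outcomes to the tumor samples.

    For every effect gene, samples in the upper expression half of their
    tumor cohort (per tissue) have their log-hazard shifted by
    ``log(hazard_ratio)``; shifts accumulate over effect genes. Censoring
    is independent exponential with rate ``censor_rate`` (0 disables it).
    Normal samples keep missing time/event.

    Returns a copy of ``meta`` with ``time`` and ``event`` columns.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if censor_rate < 0:
        raise ValueError("censor_rate must be non-negative")
    effect_genes = list(effect_genes)
    missing = set(effect_genes) - set(expr.index)
    if missing:
        raise ValueError(f"effect gene(s) absent from expression: {sorted(missing)}")
    meta = validate_metadata(meta.copy(), sample_ids=expr.columns)
    rng = np.random.default_rng(seed)

    tumor_ids = meta.index[meta["condition"] == "tumor"]
    log_hr = np.zeros(len(tumor_ids))
    for tissue in ("A", "B"):
        cohort = tumor_ids[meta.loc[tumor_ids, "tissue"] == tissue]
        pos = np.isin(tumor_ids, cohort)
        for gene in effect_genes:
            values = expr.loc[gene, cohort].to_numpy(dtype=float)
            high = values > np.median(values)
            log_hr[pos] += np.where(high, np.log(hazard_ratio), 0.0)

    hazard = baseline_hazard * np.exp(log_hr)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=len(tumor_ids))
    else:
        censor_time = np.full(len(tumor_ids), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    meta["time"] = np.nan
    meta["event"] = np.nan
    meta.loc[tumor_ids, "time"] = time
    meta.loc[tumor_ids, "event"] = event
    return meta
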