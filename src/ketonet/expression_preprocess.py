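"""TPM computation, expression/variability filtering, and VST normalization.

The MAD filter operates on log2(TPM + 1) without the 1.4826 consistency
constant; genes pass when their MAD exceeds both the absolute floor and the
empirical quantile among expression-passing genes (strict inequalities).
The variance-stabilizing step uses median-of-ratios size factors followed by
log2(x + 1); it targets approximate homoskedasticity only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, GeneAnnotation

logger = logging.getLogger("ketonet")

TPM_TOTAL = 1e6


@dataclass
class ExpressionMatrix:
    """Real-valued gene × sample expression on a declared scale."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str  # 'TPM' | 'log_tpm' | 'vst'

    VALID_SCALES = ("TPM", "log_tpm", "vst")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in self.VALID_SCALES:
            raise ValueError(f"scale must be one of {self.VALID_SCALES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression shape inconsistent with ids")
        if self.scale == "TPM":
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, TPM_TOTAL, rtol=1e-6):
                raise ValueError("TPM columns must sum to 1e6")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows], self.scale)


@dataclass
class FilterReport:
    n_input_genes: int
    n_pass_expression: int
    n_pass_mad: int
    mad_values: pd.Series  # per input gene, MAD of log2(TPM+1)
    min_tpm: float
    min_samples: int
    mad_floor: float
    mad_quantile: float
    mad_quantile_value: float
    notes: str = "MAD on log2(TPM+1), no 1.4826 consistency constant"

    def __post_init__(self) -> None:
        if not (self.n_pass_mad <= self.n_pass_expression <= self.n_input_genes):
            raise ValueError("filter counts violate n_pass_mad <= n_pass_expression <= n_input")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.mad_values.index,
                "mad_log2_tpm": self.mad_values.to_numpy(),
            }
        )


def compute_tpm(counts: CountMatrix, annot: GeneAnnotation) -> ExpressionMatrix:
    """Transcripts per million: RPK per gene, scaled so each column sums to 1e6.

    TPM_gs = (count_gs / (length_g / 1000)) / Σ_g (count_gs / (length_g / 1000)) × 1e6
    """
    lengths = annot.lengths_for(counts.gene_ids)
    rpk = counts.counts / (lengths[:, None] / 1000.0)
    depth = rpk.sum(axis=0)
    zero = np.flatnonzero(depth <= 0)
    if zero.size:
        raise ValueError(f"zero-depth sample(s): {[counts.sample_ids[i] for i in zero]}")
    tpm = rpk / depth[None, :] * TPM_TOTAL
    return ExpressionMatrix(list(counts.gene_ids), list(counts.sample_ids), tpm, "TPM")


def mad(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Median absolute deviation from the median (no consistency constant)."""
    med = np.median(values, axis=axis, keepdims=True)
    return np.median(np.abs(values - med), axis=axis)


def filter_genes(
    tpm: ExpressionMatrix,
    min_tpm: float = 1.0,
    min_samples: int = 1,
    mad_floor: float = 0.01,
    mad_quantile: float = 0.25,
) -> tuple[list[str], FilterReport]:
    """Keep genes expressed above ``min_tpm`` in ≥ ``min_samples`` samples and
    with MAD of log2(TPM+1) strictly above both ``mad_floor`` and the
    ``mad_quantile`` empirical quantile among expression-passing genes."""
    if tpm.scale != "TPM":
        raise ValueError("filter_genes expects a TPM-scale matrix")
    expressed = (tpm.values > min_tpm).sum(axis=1) >= min_samples
    log_tpm = np.log2(tpm.values + 1.0)
    mads = mad(log_tpm, axis=1)
    mad_series = pd.Series(mads, index=tpm.gene_ids)

    if not expressed.any():
        raise ValueError(
            f"no gene passes TPM > {min_tpm} in >= {min_samples} samples; lower thresholds"
        )
    q = float(np.quantile(mads[expressed], mad_quantile))
    keep = expressed & (mads > mad_floor) & (mads > q)
    kept = [g for g, k in zip(tpm.gene_ids, keep) if k]
    if not kept:
        raise ValueError("all genes removed by MAD filter; lower mad_floor/mad_quantile")

    report = FilterReport(
        n_input_genes=tpm.n_genes,
        n_pass_expression=int(expressed.sum()),
        n_pass_mad=int(keep.sum()),
        mad_values=mad_series,
        min_tpm=min_tpm,
        min_samples=min_samples,
        mad_floor=mad_floor,
        mad_quantile=mad_quantile,
        mad_quantile_value=q,
    )
    return kept, report


def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style size factors: median per sample of count / geometric-mean
    reference, over genes with all-positive counts.  Falls back to relative
    total counts (with a warning) when no gene is positive everywhere."""
    counts = np.asarray(counts, dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        logger.warning("no gene with all-positive counts; using total-count size factors")
        totals = counts.sum(axis=0)
        return totals / np.exp(np.mean(np.log(totals)))
    sub = counts[all_pos]
    log_ref = np.mean(np.log(sub), axis=1)
    sf = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return sf


def vst_normalize(counts: CountMatrix, kept_genes=None) -> ExpressionMatrix:
    """Variance-stabilizing normalization: size-factor scaling then log2(x+1)."""
    if counts.n_samples < 2:
        raise ValueError("vst_normalize needs at least 2 samples")
    cm = counts if kept_genes is None else counts.subset_genes(kept_genes)
    sf = median_of_ratios_size_factors(cm.counts)
    vst = np.log2(cm.counts / sf[None, :] + 1.0)
    return ExpressionMatrix(list(cm.gene_ids), list(cm.sample_ids), vst, "vst")


def mean_sd_trend_slope(values: np.ndarray) -> float:
    """Slope of per-gene SD against rank of per-gene mean.

    A homoskedastic matrix has slope near 0; used to verify VST reduces the
    mean–variance trend relative to raw log counts.
    """
    values = np.asarray(values, dtype=float)
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    ranks = np.argsort(np.argsort(means)) / max(len(means) - 1, 1)
    x = ranks - ranks.mean()
    return float(np.dot(x, sds - sds.mean()) / np.dot(x, x))
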