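"""Module eigengene vs. trait association and gene-level group tests."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression_network import EigengeneMatrix
from .expression_preprocess import ExpressionMatrix
from .io_formats import SampleInfo

logger = logging.getLogger("ketonet")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up: q_(i) = min_{j>=i} p_(j)·m/j, clipped to 1.

    NaN inputs yield NaN outputs and are excluded from m.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    q[ok] = out
    return q


def pearson_with_p(x: np.ndarray, y: np.ndarray, min_n: int = 4) -> tuple[float, float]:
    """Pearson r and two-sided p from t = r·sqrt(n−2)/sqrt(1−r²), df = n−2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < max(min_n, 3):
        raise ValueError(f"need at least {max(min_n, 3)} samples")
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def associate(eigengenes: EigengeneMatrix, sampleinfo: SampleInfo) -> pd.DataFrame:
    """Correlate each module eigengene with each state indicator and
    bio-indicator; BH FDR pooled across the full module × trait grid.

    States are encoded one-vs-rest (target state 1, others 0).  Samples in
    ``sampleinfo`` are aligned to the eigengene columns.  Note: the two
    samples per animal are treated as independent observations.
    """
    info = sampleinfo.aligned_to(eigengenes.values.columns.tolist())
    traits = info.state_indicators()
    for col in info.indicator_columns:
        traits[col] = info.table[col].to_numpy(dtype=float)

    rows = []
    for mod in eigengenes.modules:
        e = eigengenes.values.loc[mod].to_numpy()
        for trait in traits.columns:
            tv = traits[trait].to_numpy()
            if np.nanstd(tv) == 0:
                logger.warning("trait %r is constant; reporting NA", trait)
                r, p = np.nan, np.nan
            else:
                mask = np.isfinite(tv)
                r, p = pearson_with_p(e[mask], tv[mask])
            rows.append(
                {"module": mod, "trait": trait, "r": r, "pvalue": p, "n_samples": int(np.isfinite(tv).sum())}
            )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
    out["significance"] = np.select(
        [out["fdr"] < 0.05, out["fdr"] < 0.1], ["*", "."], default=""
    )
    return out


def gene_group_ttest(
    expr: ExpressionMatrix,
    sampleinfo: SampleInfo,
    gene: str,
    group_a: str,
    group_b: str,
) -> tuple[float, float]:
    """Welch two-sided t-test of one gene's expression between two states."""
    info = sampleinfo.aligned_to(expr.sample_ids)
    states = info.table["state"].to_numpy()
    gi = expr.gene_ids.index(gene)
    x = expr.values[gi]
    a = x[states == group_a]
    b = x[states == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if np.var(a) == 0 and np.var(b) == 0:
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
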