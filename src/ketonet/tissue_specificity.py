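"""Tissue-specificity t-statistics, top-fraction sets, and hypergeometric
gene-set enrichment (also the generic engine for GO-style user sets)."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("ketonet")


@dataclass
class TissuePanel:
    """Gene × sample expression with a sample → tissue label map."""

    expression: pd.DataFrame  # index gene ids, columns sample ids
    labels: pd.Series  # index sample ids, values tissue names

    def __post_init__(self) -> None:
        missing = [s for s in self.expression.columns if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples without tissue label: {missing[:5]}")
        self.labels = self.labels.loc[self.expression.columns]
        counts = self.labels.value_counts()
        if len(counts) < 2:
            raise ValueError("need at least 2 tissues")
        if (counts < 2).any():
            small = counts.index[counts < 2].tolist()
            raise ValueError(f"tissues with fewer than 2 samples: {small}")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.labels.unique())


def tissue_t_statistics(panel: TissuePanel, tissue: str) -> pd.Series:
    """Slope t-statistic of expression regressed on the ±1 tissue code, for
    every gene at once; equals the pooled-variance two-sample t of target
    tissue vs. the rest.  Zero residual variance yields ±inf; a gene that is
    constant everywhere yields 0.
    """
    if tissue not in set(panel.labels):
        raise ValueError(f"unknown tissue {tissue!r}")
    x = np.where(panel.labels.to_numpy() == tissue, 1.0, -1.0)
    y = panel.expression.to_numpy(dtype=float)
    n = x.size
    xc = x - x.mean()
    sxx = np.dot(xc, xc)
    yc = y - y.mean(axis=1, keepdims=True)
    slope = yc @ xc / sxx
    resid = yc - slope[:, None] * xc[None, :]
    ss_res = np.sum(resid**2, axis=1)
    ss_tot = np.sum(yc**2, axis=1)
    # relative threshold: a perfect two-group separation leaves only float dust
    zero_resid = ss_res <= 1e-12 * np.maximum(ss_tot, 1e-300)
    ss_res = np.where(zero_resid, 0.0, ss_res)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(ss_res / (n - 2) / sxx)
        t = slope / se
    const = ss_tot == 0
    t[const] = 0.0
    degenerate = (~const) & zero_resid
    if degenerate.any():
        logger.warning("%d genes with zero residual variance; t set to ±inf", int(degenerate.sum()))
        t[degenerate] = np.sign(slope[degenerate]) * np.inf
    return pd.Series(t, index=panel.expression.index, name=tissue)


def tissue_t_statistic(panel: TissuePanel, gene: str, tissue: str) -> float:
    return float(tissue_t_statistics(panel, tissue).loc[gene])


def top_fraction_sets(panel: TissuePanel, fraction: float = 0.05) -> dict[str, list[str]]:
    """Per tissue, the top ceil(fraction·n_genes) genes by t-statistic.

    Ties (and non-finite t, ranked last) are broken by gene id for
    determinism.  Set sizes are exactly ceil(fraction·n).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    n = panel.expression.shape[0]
    k = math.ceil(fraction * n)
    out: dict[str, list[str]] = {}
    for tissue in panel.tissues:
        t = tissue_t_statistics(panel, tissue)
        rank_t = np.where(np.isnan(t.to_numpy()), -np.inf, t.to_numpy())
        # lexsort: primary key t descending (+inf first, NaN treated as -inf
        # so it lands last), ties broken by gene id ascending
        order = np.lexsort((t.index.to_numpy(), -rank_t))
        out[tissue] = sorted(t.index.to_numpy()[order][:k].tolist())
    return out


def hypergeom_enrichment(
    module_genes, set_genes, universe
) -> tuple[int, float]:
    """Upper-tail hypergeometric test of module/set overlap.

    p = P(X ≥ overlap) with population |universe|, successes |set ∩ universe|,
    draws |module ∩ universe|.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes) & universe
    geneset = set(set_genes) & universe
    if len(module) < len(set(module_genes)) or len(geneset) < len(set(set_genes)):
        logger.warning("genes outside the universe were dropped from the test")
    overlap = len(module & geneset)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(geneset), len(module)))
    return overlap, min(p, 1.0)


def module_tissue_enrichment(
    partition_labels: pd.Series,
    tissue_sets: dict[str, list[str]],
    universe,
) -> pd.DataFrame:
    """Hypergeometric enrichment for every module × tissue pair with BH FDR."""
    from .io_formats import UNASSIGNED
    from .module_trait import bh_fdr

    universe = sorted(set(universe))
    modules = sorted(set(partition_labels) - {UNASSIGNED})
    rows = []
    for mod in modules:
        genes = partition_labels.index[partition_labels == mod]
        for tissue in sorted(tissue_sets):
            ov, p = hypergeom_enrichment(genes, tissue_sets[tissue], universe)
            rows.append({"module": mod, "tissue": tissue, "overlap": ov, "pvalue": p})
    out = pd.DataFrame(rows, columns=["module", "tissue", "overlap", "pvalue"])
    if len(out):
        out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
    else:
        out["fdr"] = []
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
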