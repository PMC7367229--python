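"""Weighted co-expression network: adjacency, TOM, modules, eigengenes, hubs.

The network is unsigned: a_ij = |cor(x_i, x_j)|^β.  Module detection uses
average-linkage clustering of 1 − TOM with a static height cut, dissolution
of undersized branches into the reserved ``unassigned`` label, and a final
eigengene-correlation reassignment pass — a deterministic variant of the
dynamic hybrid cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression_preprocess import ExpressionMatrix
from .io_formats import UNASSIGNED

logger = logging.getLogger("ketonet")

# WGCNA-style color labels, assigned to detected modules by decreasing size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
]


@dataclass
class NetworkParams:
    soft_power: int | str = "auto"  # integer >= 1 or 'auto'
    min_module_size: int = 30
    merge_cor_threshold: float = 0.9
    # cut at 0.92 of the max merge height: at 0.99 the branches absorb
    # uncorrelated background genes and module recovery degrades badly
    cut_height: float = 0.92
    scale_free_target_r2: float = 0.8
    # with ~24 samples the null SD of a correlation is ~0.21, so a 0.2
    # reassignment threshold admits background genes at a ~50% rate per
    # module; 0.5 keeps reassignment conservative
    reassign_cor_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.merge_cor_threshold <= 1):
            raise ValueError("merge_cor_threshold must lie in (0, 1]")
        if self.soft_power != "auto":
            beta = int(self.soft_power)
            if not (1 <= beta <= 20):
                raise ValueError("soft_power must be in [1, 20] or 'auto'")


@dataclass
class ModulePartition:
    """Gene → module label map with a reserved 'unassigned' label."""

    labels: pd.Series  # index gene_id, values module label strings

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)

    @property
    def modules(self) -> list[str]:
        mods = sorted(set(self.labels) - {UNASSIGNED})
        return mods

    def genes_in(self, module: str) -> list[str]:
        return self.labels.index[self.labels == module].tolist()

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("module").rename_axis("gene_id").reset_index()


@dataclass
class EigengeneMatrix:
    """Module × sample first-principal-component profiles (unit norm)."""

    values: pd.DataFrame  # index module, columns sample ids
    variance_explained: pd.Series  # per module

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.values.to_numpy(), axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("eigengenes must have unit norm over samples")

    @property
    def modules(self) -> list[str]:
        return self.values.index.tolist()


def correlation_matrix(expr: ExpressionMatrix) -> np.ndarray:
    x = expr.values
    sd = x.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance gene(s): {[expr.gene_ids[i] for i in zero[:5]]}")
    return np.corrcoef(x)


def adjacency(expr: ExpressionMatrix, beta: int) -> np.ndarray:
    """Unsigned soft-thresholded adjacency |cor|^β with zero diagonal."""
    a = np.abs(correlation_matrix(expr)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R² of log10(frequency) on log10(mean connectivity) over bins; the fit
    counts only when the slope is negative (scale-free topology criterion)."""
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 3:
        raise ValueError("too few positive-connectivity genes to assess fit")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 4:
        raise ValueError("fewer than 3 populated connectivity bins")
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        raise ValueError("fewer than 3 populated connectivity bins")
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        return 0.0
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return float(1.0 - np.sum(resid**2) / ss_tot)


def select_soft_power(expr: ExpressionMatrix, params: NetworkParams) -> int:
    """Smallest β in 1..20 reaching the scale-free fit target, else 6."""
    if params.soft_power != "auto":
        return int(params.soft_power)
    if len(expr.sample_ids) < 8:
        logger.warning("fewer than 8 samples; soft-power selection is unreliable")
    abs_cor = np.abs(correlation_matrix(expr))
    np.fill_diagonal(abs_cor, 0.0)
    for beta in range(1, 21):
        k = (abs_cor**beta).sum(axis=1)
        r2 = scale_free_fit_r2(k)
        if r2 >= params.scale_free_target_r2:
            logger.info("selected soft power beta=%d (R^2=%.3f)", beta, r2)
            return beta
    logger.warning(
        "no beta in 1..20 reached scale-free R^2 >= %.2f; falling back to 6",
        params.scale_free_target_r2,
    )
    return 6


def build_tom(expr: ExpressionMatrix, beta: int) -> np.ndarray:
    """Topological overlap: TOM_ij = (Σ_u a_iu·a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)."""
    a = adjacency(expr, beta)
    k = a.sum(axis=1)
    shared = a @ a  # diagonal of a is 0, so u ranges over u != i and u != j
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def tom_linkage(tom: np.ndarray) -> np.ndarray:
    """Average-linkage clustering of the 1 − TOM dissimilarity."""
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(np.clip((dissim + dissim.T) / 2.0, 0.0, None), checks=False)
    return hierarchy.linkage(condensed, method="average")


def detect_modules(
    tom: np.ndarray,
    params: NetworkParams,
    expr: ExpressionMatrix | None = None,
) -> ModulePartition:
    """Cluster 1 − TOM (average linkage), cut, dissolve small branches, then
    reassign unassigned genes whose eigengene correlation exceeds the
    reassignment threshold (requires ``expr``; skipped when omitted).
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    gene_ids = list(expr.gene_ids) if expr is not None else [f"g{i}" for i in range(n)]
    if n < params.min_module_size:
        logger.warning("fewer genes than min_module_size; returning all-unassigned")
        return ModulePartition(pd.Series(UNASSIGNED, index=gene_ids))

    link = tom_linkage(tom)
    cut = params.cut_height * link[:, 2].max()
    cluster_ids = hierarchy.fcluster(link, t=cut, criterion="distance")

    labels = np.full(n, UNASSIGNED, dtype=object)
    sizes = pd.Series(cluster_ids).value_counts()
    big = sizes.index[sizes >= params.min_module_size]
    # deterministic color order: by size desc, ties by smallest member index
    order = sorted(
        big,
        key=lambda c: (-int(sizes[c]), int(np.flatnonzero(cluster_ids == c)[0])),
    )
    for rank, c in enumerate(order):
        color = MODULE_COLORS[rank % len(MODULE_COLORS)]
        if rank >= len(MODULE_COLORS):
            color = f"{color}{rank // len(MODULE_COLORS)}"
        labels[cluster_ids == c] = color

    part = ModulePartition(pd.Series(labels, index=gene_ids))
    if expr is not None and part.modules:
        part = _reassign_by_eigengene(expr, part, params.reassign_cor_threshold)
    return part


def _reassign_by_eigengene(
    expr: ExpressionMatrix, part: ModulePartition, threshold: float
) -> ModulePartition:
    labels = part.labels.copy()
    for _ in range(10):  # iterate to fixed point, bounded
        mods = sorted(set(labels) - {UNASSIGNED})
        if not mods:
            break
        eg = compute_eigengenes(expr, ModulePartition(labels))
        un = labels.index[labels == UNASSIGNED]
        if len(un) == 0:
            break
        x = expr.subset_genes(list(un)).values
        cors = _cor_rows_vs_rows(x, eg.values.to_numpy())
        best = np.argmax(cors, axis=1)
        best_cor = cors[np.arange(len(un)), best]
        move = best_cor > threshold
        if not move.any():
            break
        labels.loc[np.asarray(un)[move]] = [eg.modules[j] for j in best[move]]
    return ModulePartition(labels)


def _cor_rows_vs_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    return az @ bz.T / a.shape[1]


def compute_eigengenes(expr: ExpressionMatrix, part: ModulePartition) -> EigengeneMatrix:
    """First principal component over samples of each module's z-scored
    expression, sign-oriented so mean member correlation is non-negative."""
    rows, ve = {}, {}
    for mod in part.modules:
        genes = part.genes_in(mod)
        if len(genes) < 2:
            raise ValueError(f"module {mod!r} has fewer than 2 genes")
        x = expr.subset_genes(genes).values
        sd = x.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError(f"zero-variance gene in module {mod!r}")
        z = (x - x.mean(axis=1, keepdims=True)) / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        mean_cor = _cor_rows_vs_rows(x, eig[None, :]).mean()
        if mean_cor < 0:
            eig = -eig
        rows[mod] = eig
        ve[mod] = float(s[0] ** 2 / np.sum(s**2))
    values = pd.DataFrame(rows, index=expr.sample_ids).T
    values = values.loc[sorted(values.index)]
    return EigengeneMatrix(values, pd.Series(ve).loc[values.index])


def merge_modules(
    expr: ExpressionMatrix,
    part: ModulePartition,
    merge_cor_threshold: float = 0.9,
) -> ModulePartition:
    """Greedily merge the module pair with the highest eigengene correlation
    while it exceeds the threshold, recomputing eigengenes after each merge.
    The merged module keeps the larger member's label (ties: lexicographic)."""
    labels = part.labels.copy()
    while True:
        mods = sorted(set(labels) - {UNASSIGNED})
        if len(mods) < 2:
            break
        eg = compute_eigengenes(expr, ModulePartition(labels))
        e = eg.values.to_numpy()
        cors = _cor_rows_vs_rows(e, e)
        np.fill_diagonal(cors, -np.inf)
        i, j = np.unravel_index(np.argmax(cors), cors.shape)
        if not cors[i, j] > merge_cor_threshold:
            break
        a, b = sorted((eg.modules[i], eg.modules[j]))  # lexicographic tie-break
        sizes = labels.value_counts()
        keep, drop = (a, b) if sizes[a] >= sizes[b] else (b, a)
        labels[labels == drop] = keep
    return ModulePartition(labels)


def gene_significance(expr: ExpressionMatrix, trait: np.ndarray) -> np.ndarray:
    """GS_i = |cor(x_i, trait)|; constant traits yield zeros."""
    t = np.asarray(trait, dtype=float)
    if t.std() == 0:
        return np.zeros(expr.n_genes)
    return np.abs(_cor_rows_vs_rows(expr.values, t[None, :]))[:, 0]


def intramodular_connectivity(
    expr: ExpressionMatrix, part: ModulePartition, beta: int
) -> pd.Series:
    """kIM_i = Σ_{j in same module, j≠i} a_ij (unassigned genes get 0)."""
    a = adjacency(expr, beta)
    k = np.zeros(expr.n_genes)
    gi = {g: i for i, g in enumerate(expr.gene_ids)}
    for mod in part.modules:
        idx = [gi[g] for g in part.genes_in(mod)]
        sub = a[np.ix_(idx, idx)]
        k[idx] = sub.sum(axis=1)
    return pd.Series(k, index=expr.gene_ids)


def call_hub_genes(
    expr: ExpressionMatrix,
    part: ModulePartition,
    traits: pd.DataFrame,
    beta: int,
    k_threshold: float = 30.0,
    gs_threshold: float = 0.2,
) -> pd.DataFrame:
    """Genes with kIM > k_threshold and GS > gs_threshold for any trait.

    ``traits`` is a sample × trait numeric frame aligned to expr samples.
    """
    kim = intramodular_connectivity(expr, part, beta)
    gs = {}
    for trait in traits.columns:
        gs[trait] = gene_significance(expr, traits[trait].to_numpy())
    gs_df = pd.DataFrame(gs, index=expr.gene_ids)

    rows = []
    for gene in expr.gene_ids:
        mod = part.labels.get(gene, UNASSIGNED)
        if mod == UNASSIGNED:
            continue
        if kim[gene] > k_threshold and (gs_df.loc[gene] > gs_threshold).any():
            best_trait = gs_df.loc[gene].idxmax()
            rows.append(
                {
                    "gene_id": gene,
                    "module": mod,
                    "kIM": kim[gene],
                    "best_trait": best_trait,
                    "best_GS": gs_df.loc[gene, best_trait],
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "module", "kIM", "best_trait", "best_GS"])
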