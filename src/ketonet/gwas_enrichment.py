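"""Sum-based GWAS signal enrichment of gene modules.

The statistic is T_sum = Σ b² over SNPs falling in a module's gene bodies
extended by ±20 kb.  The null distribution comes from circular permutation:
all SNPs are placed on one genome-ordered circle (chromosomes concatenated
in sorted name order) and the effect vector is rotated by a random non-zero
offset, preserving the local ordering structure of effects while decoupling
them from module membership.  Empirical p uses the add-one estimator
(1 + #{T_perm ≥ T_obs}) / (1 + n_perm) so p is never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coexpression_network import ModulePartition
from .io_formats import GeneAnnotation, GwasSummary
from .module_trait import bh_fdr

logger = logging.getLogger("ketonet")

DEFAULT_FLANK = 20_000


@dataclass
class EnrichmentResult:
    module: str
    trait: str
    n_snps_in_module: int
    t_obs: float
    n_perm: int
    n_greater_equal: int
    empirical_p: float
    seed: int | None

    def __post_init__(self) -> None:
        if self.t_obs < 0:
            raise ValueError("T_obs must be non-negative")
        if np.isfinite(self.empirical_p) and not (0 < self.empirical_p <= 1):
            raise ValueError("empirical p must lie in (0, 1]")


def module_windows(
    annot: GeneAnnotation,
    partition: ModulePartition,
    flank: int = DEFAULT_FLANK,
    modules: list[str] | None = None,
) -> pd.DataFrame:
    """Per-module genomic windows: gene bodies ±flank, clipped at 0, merged
    when overlapping within a module.  Columns: module, chrom, start, end."""
    tab = annot.table.set_index("gene_id")
    mods = modules if modules is not None else partition.modules + _maybe_unassigned(partition)
    rows = []
    for mod in mods:
        genes = [g for g in partition.genes_in(mod) if g in tab.index]
        if not genes:
            continue
        sub = tab.loc[genes]
        for chrom, grp in sub.groupby("chrom", sort=True):
            starts = np.maximum(grp["start"].to_numpy() - flank, 0)
            ends = grp["end"].to_numpy() + flank
            order = np.argsort(starts, kind="mergesort")
            cur_s, cur_e = None, None
            for s, e in zip(starts[order], ends[order]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:  # overlap or abut: merge
                    cur_e = max(cur_e, e)
                else:
                    rows.append({"module": mod, "chrom": chrom, "start": int(cur_s), "end": int(cur_e)})
                    cur_s, cur_e = s, e
            if cur_s is not None:
                rows.append({"module": mod, "chrom": chrom, "start": int(cur_s), "end": int(cur_e)})
    return pd.DataFrame(rows, columns=["module", "chrom", "start", "end"])


def _maybe_unassigned(partition: ModulePartition) -> list[str]:
    from .io_formats import UNASSIGNED

    return [UNASSIGNED] if (partition.labels == UNASSIGNED).any() else []


def _check_chroms(gwas: GwasSummary, annot: GeneAnnotation) -> None:
    unmatched = gwas.chroms.symmetric_difference(annot.chroms)
    if unmatched and not (gwas.chroms & annot.chroms):
        raise ValueError(f"chromosome names do not match between files: {sorted(unmatched)}")
    only_gwas = gwas.chroms - annot.chroms
    if only_gwas:
        logger.warning("chromosomes only in GWAS summary: %s", sorted(only_gwas))


def map_snps_to_modules(
    gwas: GwasSummary,
    annot: GeneAnnotation,
    partition: ModulePartition,
    flank: int = DEFAULT_FLANK,
    modules: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Per-module sorted indices (into the genome-ordered SNP table) of SNPs
    overlapping any module window; a SNP may belong to several modules."""
    _check_chroms(gwas, annot)
    windows = module_windows(annot, partition, flank=flank, modules=modules)
    gt = gwas.table
    chrom_arr = gt["chrom"].to_numpy()
    pos = gt["pos"].to_numpy()
    out: dict[str, np.ndarray] = {}
    for mod, wsub in windows.groupby("module", sort=True):
        hits: list[np.ndarray] = []
        for chrom, csub in wsub.groupby("chrom", sort=True):
            on_c = np.flatnonzero(chrom_arr == chrom)
            if on_c.size == 0:
                continue
            p = pos[on_c]  # sorted within chromosome by construction
            for s, e in zip(csub["start"], csub["end"]):
                lo = np.searchsorted(p, s, side="left")
                hi = np.searchsorted(p, e, side="left")
                if hi > lo:
                    hits.append(on_c[lo:hi])
        out[mod] = np.unique(np.concatenate(hits)) if hits else np.array([], dtype=int)
    mods = modules if modules is not None else partition.modules + _maybe_unassigned(partition)
    for mod in mods:
        out.setdefault(mod, np.array([], dtype=int))
    return out


def t_sum(effects_b: np.ndarray, snp_index_set: np.ndarray) -> float:
    """Σ b² over the SNP index set."""
    b = np.asarray(effects_b, dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("effect estimates must be finite")
    idx = np.asarray(snp_index_set, dtype=int)
    return float(np.sum(b[idx] ** 2))


def circular_permutation_test(
    gwas: GwasSummary,
    snp_index_set: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool = False,
    module: str = "",
    trait: str | None = None,
) -> EnrichmentResult:
    """Rotate the genome-ordered effect vector; T_perm on the fixed index set.

    Offsets are uniform on {1, …, m−1} (k = 0 excluded); exhaustive mode
    enumerates every offset once.  empirical_p = (1 + #{T_perm ≥ T_obs}) /
    (1 + n_offsets).
    """
    b2 = gwas.effects**2
    m = b2.size
    if m < 2:
        raise ValueError("need at least 2 SNPs genome-wide")
    idx = np.asarray(snp_index_set, dtype=int)
    trait_name = trait if trait is not None else gwas.trait
    if idx.size == 0:
        logger.info("module %r has no SNPs; p = NA", module)
        return EnrichmentResult(module, trait_name, 0, 0.0, 0, 0, np.nan, seed)

    t_obs = float(b2[idx].sum())
    if exhaustive:
        offsets = np.arange(1, m)
    else:
        rng = np.random.default_rng(seed)
        offsets = rng.integers(1, m, size=n_perm)
    # T_perm[k] = Σ_{i∈set} b²[(i+k) mod m]
    if idx.size * offsets.size <= 50_000_000:
        t_perm = b2[(idx[:, None] + offsets[None, :]) % m].sum(axis=0)
    else:  # chunk offsets to bound memory on very large problems
        t_perm = np.empty(offsets.size)
        step = max(1, 50_000_000 // max(idx.size, 1))
        for j0 in range(0, offsets.size, step):
            ks = offsets[j0 : j0 + step]
            t_perm[j0 : j0 + ks.size] = b2[(idx[:, None] + ks[None, :]) % m].sum(axis=0)
    # tolerance absorbs summation-order float noise so a full-genome module
    # (every rotation an exact tie) yields p = 1
    tol = 1e-9 * max(1.0, abs(t_obs))
    n_ge = int(np.sum(t_perm >= t_obs - tol))
    p = (1.0 + n_ge) / (1.0 + offsets.size)
    return EnrichmentResult(module, trait_name, int(idx.size), t_obs, int(offsets.size), n_ge, p, seed)


def enrich_all(
    gwas_by_trait: dict[str, GwasSummary],
    partition: ModulePartition,
    annot: GeneAnnotation,
    n_perm: int = 10_000,
    seed: int = 0,
    flank: int = DEFAULT_FLANK,
    include_unassigned: bool = True,
) -> pd.DataFrame:
    """One circular test per (module, trait) with BH FDR pooled over the grid."""
    from .io_formats import UNASSIGNED

    mods = partition.modules
    if include_unassigned and (partition.labels == UNASSIGNED).any():
        mods = mods + [UNASSIGNED]
    rows = []
    for ti, (trait, gwas) in enumerate(sorted(gwas_by_trait.items())):
        index_sets = map_snps_to_modules(gwas, annot, partition, flank=flank, modules=mods)
        for mi, mod in enumerate(mods):
            # deterministic per-cell seed, independent of iteration order
            sub_seed = seed * 1_000_003 + ti * 1009 + mi
            res = circular_permutation_test(
                gwas, index_sets[mod], n_perm=n_perm, seed=sub_seed, module=mod, trait=trait
            )
            rows.append(
                {
                    "module": res.module,
                    "trait": res.trait,
                    "n_snps": res.n_snps_in_module,
                    "t_obs": res.t_obs,
                    "n_perm": res.n_perm,
                    "n_greater_equal": res.n_greater_equal,
                    "empirical_p": res.empirical_p,
                    "seed": res.seed,
                }
            )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["empirical_p"].to_numpy())
    out["significant"] = out["fdr"] < 0.05
    return out


def call_candidate_genes(
    gwas_by_trait: dict[str, GwasSummary],
    annot: GeneAnnotation,
    partition: ModulePartition,
    significant_modules: dict[str, list[str]],
    p_threshold: float = 1e-5,
    cross_trait_p: float = 0.05,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Per gene in a significant module: top SNP = minimum p in the gene's
    ±flank window; report the gene when top p < p_threshold.  Cross-trait
    support lists other traits where the gene's top SNP has p < cross_trait_p.
    """
    tab = annot.table.set_index("gene_id")
    rows = []
    for trait, modules in sorted(significant_modules.items()):
        gwas = gwas_by_trait[trait]
        gt = gwas.table
        for mod in sorted(modules):
            for gene in sorted(partition.genes_in(mod)):
                if gene not in tab.index:
                    continue
                rec = tab.loc[gene]
                hit = _window_snps(gt, rec["chrom"], max(int(rec["start"]) - flank, 0), int(rec["end"]) + flank)
                if hit.empty:
                    continue
                top = hit.loc[hit["pvalue"].idxmin()]
                if top["pvalue"] >= p_threshold:
                    continue
                support = []
                for other, og in sorted(gwas_by_trait.items()):
                    if other == trait:
                        continue
                    oh = _window_snps(
                        og.table, rec["chrom"], max(int(rec["start"]) - flank, 0), int(rec["end"]) + flank
                    )
                    if not oh.empty and oh["pvalue"].min() < cross_trait_p:
                        support.append(other)
                rows.append(
                    {
                        "gene_id": gene,
                        "module": mod,
                        "trait": trait,
                        "top_snp": top["snp_id"],
                        "top_snp_pos": int(top["pos"]) + 1,  # report 1-based
                        "top_snp_effect": top["effect_b"],
                        "top_snp_pvalue": top["pvalue"],
                        "cross_trait_support": ",".join(support),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "module", "trait", "top_snp", "top_snp_pos",
            "top_snp_effect", "top_snp_pvalue", "cross_trait_support",
        ],
    )


def _window_snps(gt: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    sub = gt[gt["chrom"] == chrom]
    p = sub["pos"].to_numpy()
    lo = np.searchsorted(p, start, side="left")
    hi = np.searchsorted(p, end, side="left")
    return sub.iloc[lo:hi]
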