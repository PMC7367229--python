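"""Synthetic inputs with planted structure for parameter-recovery tests.

Every generator is a pure function of (config, seed): the expression layer
plants co-expression modules driven by latent factors that may be coupled
to physiological states or bio-indicators; the GWAS layer inflates squared
marker effects inside ±20 kb windows of chosen modules; the tissue panel
plants tissue-specific gene sets.  The emitted :class:`GroundTruth` is
sufficient to score module recovery, enrichment detection, and tissue-set
recovery downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    BIO_INDICATORS,
    STATES,
    UNASSIGNED,
    CountMatrix,
    GeneAnnotation,
    GwasSummary,
    SampleInfo,
    write_table,
)

# natural-log-scale biological SD of gene expression; observation noise is
# added on top of this, so it bounds the attainable within-module correlation
_SIGMA_BIO = 1.0


@dataclass
class TraitDriver:
    """Couples one module's latent factor to a state or bio-indicator.

    ``kind='state'``: the factor gets a mean shift of ``effect`` (in SD
    units, before re-standardisation) in samples of ``target`` state.
    ``kind='bio'``: the generated ``target`` indicator correlates ``effect``
    (in (-1, 1)) with the factor.
    """

    kind: str  # 'state' | 'bio'
    target: str
    effect: float

    def __post_init__(self) -> None:
        if self.kind not in ("state", "bio"):
            raise ValueError(f"driver kind must be 'state' or 'bio', got {self.kind!r}")
        if self.kind == "state" and self.target not in STATES:
            raise ValueError(f"unknown state {self.target!r}")
        if self.kind == "bio" and self.target not in BIO_INDICATORS:
            raise ValueError(f"unknown bio-indicator {self.target!r}")
        if self.kind == "bio" and not (-1 < self.effect < 1):
            raise ValueError("bio coupling must lie in (-1, 1)")


@dataclass
class SyntheticConfig:
    seed: int
    n_samples: int = 24
    n_genes: int = 2000
    module_sizes: list[int] = field(default_factory=lambda: [150, 120, 100, 80, 60])
    within_module_cor: float = 0.7
    trait_drivers: dict[str, TraitDriver] = field(default_factory=dict)
    n_snps: int = 20_000
    n_chroms: int = 5
    enriched_modules: dict[str, float] = field(default_factory=dict)
    baseline_effect_sd: float = 0.1
    count_depth: float = 2e6
    dispersion: float = 0.1
    libsize_cv: float = 0.2
    gene_spacing: int = 44_000
    gene_length_range: tuple[int, int] = (1_000, 3_000)
    flank: int = 20_000
    # tissue panel
    n_tissues: int = 8
    samples_per_tissue: int = 5
    tissue_specific_fraction: float = 0.02
    tissue_shift: float = 5.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if not (0 < self.within_module_cor < 1):
            raise ValueError("within_module_cor must lie in (0, 1)")
        if any(v < 1 for v in self.enriched_modules.values()):
            raise ValueError("inflation factors must be >= 1")
        if self.n_samples % len(STATES):
            raise ValueError(f"n_samples must be divisible by {len(STATES)}")

    @property
    def module_labels(self) -> list[str]:
        return [f"M{i + 1}" for i in range(len(self.module_sizes))]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trait_drivers"] = {k: asdict(v) for k, v in self.trait_drivers.items()}
        return d


@dataclass
class GroundTruth:
    """Planted structure, sufficient to score every downstream stage."""

    module_labels: pd.Series  # gene_id -> planted module label (or unassigned)
    factors: pd.DataFrame  # module × sample latent factor values
    enriched_modules: dict[str, float]
    snp_effect_sd: pd.Series | None = None  # snp_id -> generative effect SD
    tissue_specific_sets: dict[str, list[str]] | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lbl = self.module_labels.rename_axis("gene_id").rename("module").reset_index()
        write_table(lbl, outdir / "ground_truth.tsv")
        fac = self.factors.rename_axis("module").reset_index()
        write_table(fac, outdir / "ground_truth_factors.tsv")
        meta: dict = {"enriched_modules": self.enriched_modules}
        if self.tissue_specific_sets is not None:
            meta["tissue_specific_sets"] = self.tissue_specific_sets
        (outdir / "ground_truth_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        if self.snp_effect_sd is not None:
            sd = self.snp_effect_sd.rename_axis("snp_id").rename("effect_sd").reset_index()
            write_table(sd, outdir / "ground_truth_snp_sd.tsv")


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(stream,)))


def _latent_factors(cfg: SyntheticConfig, states: np.ndarray, rng: np.random.Generator):
    """One unit-variance latent factor per module; drivers tilt it toward a trait.

    Returns (factors array modules × samples, bio-indicator table).
    """
    n = cfg.n_samples
    factors = np.empty((len(cfg.module_sizes), n))
    bio = {name: None for name in BIO_INDICATORS}
    for mi, label in enumerate(cfg.module_labels):
        base = rng.standard_normal(n)
        driver = cfg.trait_drivers.get(label)
        if driver is None:
            factors[mi] = base
            continue
        if driver.kind == "state":
            ind = (states == driver.target).astype(float)
            ind = (ind - ind.mean()) / ind.std()
            f = driver.effect * ind + base
            factors[mi] = f / np.sqrt(1.0 + driver.effect**2)
        else:  # bio: indicator built from the factor afterwards
            factors[mi] = base
            rho = driver.effect
            noise = rng.standard_normal(n)
            bio[driver.target] = rho * base + np.sqrt(1 - rho**2) * noise
    for name in BIO_INDICATORS:
        if bio[name] is None:
            bio[name] = rng.standard_normal(n)
    return factors, pd.DataFrame(bio)


def simulate_expression(
    cfg: SyntheticConfig,
) -> tuple[CountMatrix, SampleInfo, GeneAnnotation, GroundTruth]:
    """Generate counts, sample metadata, annotation, and ground truth.

    Module genes load on their module's latent factor with a loading
    calibrated so the expected pairwise Pearson correlation of observed
    log-expression equals ``within_module_cor``; the calibration inverts
    cor = loading² · σ_bio² / (σ_bio² + v_obs) with v_obs ≈ 1/µ + dispersion
    (delta-method variance of log NB counts).
    """
    rng = _rng(cfg, 0)
    n, g = cfg.n_samples, cfg.n_genes
    per_state = n // len(STATES)
    states = np.repeat(STATES, per_state)
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    gene_ids = [f"G{i + 1:05d}" for i in range(g)]

    factors, bio = _latent_factors(cfg, states, rng)

    # planted module labels: first genes in config order, rest unassigned
    labels = np.full(g, UNASSIGNED, dtype=object)
    pos = 0
    for label, size in zip(cfg.module_labels, cfg.module_sizes):
        labels[pos : pos + size] = label
        pos += size

    annot = _make_annotation(cfg, gene_ids, rng)
    lengths = annot.table["length_bp"].to_numpy(dtype=float)

    base_expr = rng.uniform(np.log(20.0), np.log(500.0), size=g)
    mu_ref = np.exp(base_expr)  # reference-scale mean counts per gene
    v_obs = 1.0 / mu_ref + cfg.dispersion
    load_sq = cfg.within_module_cor * (_SIGMA_BIO**2 + v_obs) / _SIGMA_BIO**2
    if np.any(load_sq >= 1.0):
        worst = float(np.max(cfg.within_module_cor * (_SIGMA_BIO**2 + v_obs) / _SIGMA_BIO**2))
        raise ValueError(
            f"within_module_cor={cfg.within_module_cor} infeasible: required "
            f"squared loading {worst:.3f} >= 1 given observation noise"
        )
    loading = np.sqrt(load_sq)

    z = rng.standard_normal((g, n))
    for mi, label in enumerate(cfg.module_labels):
        member = labels == label
        a = loading[member][:, None]
        z[member] = a * factors[mi][None, :] + np.sqrt(1 - a**2) * z[member]

    lib = np.exp(rng.normal(0.0, cfg.libsize_cv, size=n))
    lib *= cfg.count_depth / (lib.mean() * mu_ref.sum())
    mu = np.exp(base_expr[:, None] + _SIGMA_BIO * z) * (lengths[:, None] / 2000.0) * lib[None, :]
    if cfg.dispersion > 0:
        nb_n = 1.0 / cfg.dispersion
        counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
    else:
        counts = rng.poisson(mu)

    cm = CountMatrix(gene_ids, sample_ids, counts.astype(np.int64))
    info = SampleInfo(
        pd.concat(
            [pd.DataFrame({"sample_id": sample_ids, "state": states}), bio.reset_index(drop=True)],
            axis=1,
        )
    )
    truth = GroundTruth(
        module_labels=pd.Series(labels, index=gene_ids),
        factors=pd.DataFrame(factors, index=cfg.module_labels, columns=sample_ids),
        enriched_modules=dict(cfg.enriched_modules),
    )
    return cm, info, annot, truth


def _make_annotation(cfg: SyntheticConfig, gene_ids: list[str], rng: np.random.Generator) -> GeneAnnotation:
    g = len(gene_ids)
    per_chrom = -(-g // cfg.n_chroms)  # ceil
    lo, hi = cfg.gene_length_range
    chroms, starts = [], []
    for i in range(g):
        ci, j = divmod(i, per_chrom)
        chroms.append(f"chr{ci + 1}")
        starts.append(cfg.gene_spacing // 2 + j * cfg.gene_spacing)
    lengths = rng.integers(lo, hi + 1, size=g)
    tab = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chroms,
            "start": starts,
            "end": np.asarray(starts) + lengths,
            "length_bp": lengths,
        }
    )
    return GeneAnnotation(tab)


def simulate_gwas(
    cfg: SyntheticConfig,
    annot: GeneAnnotation,
    truth: GroundTruth,
    trait: str = "KETO",
) -> GwasSummary:
    """Genome-ordered marker effects with inflated variance near enriched modules.

    effect_b ~ Normal(0, σ²) with σ² = baseline² × inflation inside ±flank of
    genes belonging to an enriched module; p-values from z = b / baseline_sd.
    """
    rng = _rng(cfg, 1)
    chrom_tab = annot.table.groupby("chrom")["end"].max() + cfg.gene_spacing
    chrom_names = sorted(chrom_tab.index)
    n_per = np.full(len(chrom_names), cfg.n_snps // len(chrom_names))
    n_per[: cfg.n_snps % len(chrom_names)] += 1

    rows = []
    for cname, n_c in zip(chrom_names, n_per):
        pos = np.sort(rng.choice(int(chrom_tab[cname]), size=n_c, replace=False))
        rows.append(pd.DataFrame({"chrom": cname, "pos": pos}))
    snps = pd.concat(rows, ignore_index=True)
    snps["snp_id"] = [f"snp{i + 1:06d}" for i in range(len(snps))]

    sd = np.full(len(snps), cfg.baseline_effect_sd)
    labels = truth.module_labels
    for mod, inflation in truth.enriched_modules.items():
        genes = labels.index[labels == mod]
        sub = annot.table[annot.table["gene_id"].isin(genes)]
        in_window = np.zeros(len(snps), dtype=bool)
        for cname, grp in sub.groupby("chrom"):
            lo = np.maximum(grp["start"].to_numpy() - cfg.flank, 0)
            hi = grp["end"].to_numpy() + cfg.flank
            on_c = snps["chrom"].to_numpy() == cname
            p = snps.loc[on_c, "pos"].to_numpy()
            hit = ((p[:, None] >= lo[None, :]) & (p[:, None] < hi[None, :])).any(axis=1)
            in_window[np.flatnonzero(on_c)[hit]] = True
        if not in_window.any():
            raise ValueError(
                f"no SNP falls in any window of enriched module {mod!r}; increase n_snps"
            )
        sd[in_window] = np.maximum(sd[in_window], cfg.baseline_effect_sd * np.sqrt(inflation))

    b = rng.normal(0.0, 1.0, size=len(snps)) * sd
    se = cfg.baseline_effect_sd if cfg.baseline_effect_sd > 0 else 1.0
    pvals = 2.0 * stats.norm.sf(np.abs(b) / se)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "snp_id": snps["snp_id"],
            "chrom": snps["chrom"],
            "pos": snps["pos"],
            "effect_b": b,
            "pvalue": pvals,
        }
    )
    gwas = GwasSummary(table, trait=trait)
    truth.snp_effect_sd = pd.Series(sd, index=snps["snp_id"].to_numpy())
    return gwas


def simulate_tissue_panel(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Tissue panel with planted tissue-specific sets.

    Returns (gene × sample expression, sample→tissue labels, planted sets).
    """
    if cfg.n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    rng = _rng(cfg, 2)
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    n_spec = int(round(cfg.tissue_specific_fraction * cfg.n_genes))
    if n_spec * cfg.n_tissues > cfg.n_genes:
        raise ValueError("tissue_specific_fraction too large for disjoint planted sets")

    tissues = [f"T{i + 1}" for i in range(cfg.n_tissues)]
    sample_ids, labels = [], []
    for t in tissues:
        for k in range(cfg.samples_per_tissue):
            sample_ids.append(f"{t}_s{k + 1}")
            labels.append(t)
    label_s = pd.Series(labels, index=sample_ids, name="tissue")

    base = rng.normal(5.0, 1.0, size=cfg.n_genes)
    expr = base[:, None] + rng.normal(0.0, 1.0, size=(cfg.n_genes, len(sample_ids)))

    order = rng.permutation(cfg.n_genes)
    planted: dict[str, list[str]] = {}
    for ti, t in enumerate(tissues):
        idx = order[ti * n_spec : (ti + 1) * n_spec]
        cols = np.asarray(labels) == t
        expr[np.ix_(idx, np.flatnonzero(cols))] += cfg.tissue_shift
        planted[t] = sorted(gene_ids[i] for i in idx)

    panel = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
    return panel, label_s, planted
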