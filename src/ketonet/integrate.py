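"""Cross-stage integration: correlate per-module GWAS enrichment evidence
with module–trait association evidence, and assemble the final report."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .module_trait import pearson_with_p

logger = logging.getLogger("ketonet")


@dataclass
class IntegrationResult:
    trait: str  # GWAS trait
    state: str  # physiological state / bio-indicator
    r: float
    pvalue: float
    spearman_r: float
    spearman_p: float
    n_modules: int
    transform: str


def correlate_enrichment_association(
    enrich: pd.DataFrame,
    modtrait: pd.DataFrame,
    trait: str,
    state: str,
    transform: str = "neglog10_p",
) -> IntegrationResult:
    """Across modules, correlate GWAS-enrichment evidence for ``trait`` with
    association evidence for ``state``.

    ``transform='neglog10_p'`` uses x = −log10(empirical p), y = −log10(p);
    ``transform='association_r'`` uses y = association r instead.  A
    rank-based (Spearman) correlation is reported alongside.
    """
    e = enrich[enrich["trait"] == trait].set_index("module")
    a = modtrait[modtrait["trait"] == state].set_index("module")
    common = sorted(set(e.index) & set(a.index))
    if len(common) < 3:
        raise ValueError(f"need >= 3 shared modules, got {len(common)}")
    x = -np.log10(e.loc[common, "empirical_p"].to_numpy(dtype=float))
    if transform == "neglog10_p":
        y = -np.log10(a.loc[common, "pvalue"].to_numpy(dtype=float))
    elif transform == "association_r":
        y = a.loc[common, "r"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        logger.warning("degenerate integration inputs for (%s, %s); returning NA", trait, state)
        return IntegrationResult(trait, state, np.nan, np.nan, np.nan, np.nan, int(ok.sum()), transform)
    r, p = pearson_with_p(x, y, min_n=3)
    sr, sp = stats.spearmanr(x, y)
    return IntegrationResult(trait, state, r, p, float(sr), float(sp), int(ok.sum()), transform)


def integrate_all(
    enrich: pd.DataFrame,
    modtrait: pd.DataFrame,
    transform: str = "neglog10_p",
) -> pd.DataFrame:
    """All (GWAS trait, state/bio-indicator) pairs as one table."""
    rows = []
    for trait in sorted(enrich["trait"].unique()):
        for state in sorted(modtrait["trait"].unique()):
            try:
                res = correlate_enrichment_association(enrich, modtrait, trait, state, transform)
            except ValueError:
                continue
            rows.append(vars(res))
    return pd.DataFrame(rows)


def build_report(
    partition_frame: pd.DataFrame,
    modtrait: pd.DataFrame,
    enrich: pd.DataFrame,
    integration: pd.DataFrame,
    hub_genes: pd.DataFrame | None = None,
    candidates: pd.DataFrame | None = None,
    tissue_enrichment: pd.DataFrame | None = None,
    meta: dict | None = None,
) -> tuple[pd.DataFrame, str]:
    """Per-module dossier table plus a markdown run summary.

    Numbers are taken verbatim from the stage tables so the report can be
    cross-checked programmatically against them.
    """
    sizes = partition_frame.groupby("module").size().rename("n_genes")
    modules = sizes.index.tolist()

    best_assoc = (
        modtrait.loc[modtrait.groupby("module")["pvalue"].idxmin().dropna()]
        .set_index("module")[["trait", "r", "pvalue", "fdr"]]
        .rename(columns=lambda c: f"assoc_{c}")
        if len(modtrait)
        else pd.DataFrame()
    )
    best_enrich = (
        enrich.loc[enrich.groupby("module")["empirical_p"].idxmin().dropna()]
        .set_index("module")[["trait", "t_obs", "empirical_p", "fdr"]]
        .rename(columns=lambda c: f"gwas_{c}")
        if len(enrich)
        else pd.DataFrame()
    )
    dossier = pd.DataFrame(index=pd.Index(modules, name="module")).join([sizes, best_assoc, best_enrich])
    if hub_genes is not None and len(hub_genes):
        dossier = dossier.join(hub_genes.groupby("module").size().rename("n_hub_genes"))
    if candidates is not None and len(candidates):
        dossier = dossier.join(candidates.groupby("module").size().rename("n_candidate_genes"))
    if tissue_enrichment is not None and len(tissue_enrichment):
        top_tissue = tissue_enrichment.loc[
            tissue_enrichment.groupby("module")["pvalue"].idxmin().dropna()
        ].set_index("module")[["tissue", "pvalue"]].rename(columns=lambda c: f"tissue_{c}")
        dossier = dossier.join(top_tissue)
    dossier = dossier.reset_index()

    lines = ["# ketonet run report", ""]
    if meta:
        lines.append("## Reproducibility")
        for k in sorted(meta):
            lines.append(f"- {k}: {meta[k]}")
        lines.append("")
    lines.append(f"## Modules ({len(modules)})")
    for _, row in dossier.iterrows():
        lines.append(f"- **{row['module']}** — {int(row['n_genes'])} genes")
    lines.append("")
    if len(integration):
        lines.append("## Integration (enrichment vs. association across modules)")
        for _, row in integration.iterrows():
            lines.append(
                f"- {row['trait']} × {row['state']}: r = {row['r']:.3f}, p = {row['pvalue']:.3g}"
                f" (n = {int(row['n_modules'])} modules)"
            )
        lines.append("")
    return dossier, "\n".join(lines)
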