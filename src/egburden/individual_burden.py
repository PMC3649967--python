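"""Per-individual mutational-load accounting over gene sets and strata.

A variant counts towards a sample's load iff the sample carries at least one
alternate allele at the site (site-level counting; a homozygous-alt genotype
counts the variant once). Heterozygous and homozygous LoF carriage is
tallied separately for the het/hom ratio. Loads are computed per gene set
(EG / NLG / ALL) and per frequency stratum (all variants, or rare <1%).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .constraint_stats import wilcoxon_compare
from .types import LOF, SYNONYMOUS, TestResult, is_broad_missense
from .variant_annotation import GenotypeMatrix

logger = logging.getLogger(__name__)

LOAD_COLUMNS = [
    "sample_id",
    "gene_set",
    "stratum",
    "n_missense_broad",
    "n_synonymous",
    "ns_ratio",
    "n_damaging",
    "n_lof",
    "lof_fraction",
    "n_lof_het",
    "n_lof_hom",
    "genes_hit",
]


def per_sample_load(
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    genes: pd.DataFrame,
    gene_set: str = "ALL",
    stratum: str = "all",
    exclude_chr_y: bool = True,
) -> pd.DataFrame:
    """Per-sample mutational load restricted to a gene set and AF stratum.

    ``gene_set`` is an essentiality class name (``EG``/``NLG``/``OTHER``) or
    ``ALL``; ``stratum`` is ``all`` or ``rare``. Undefined ratios (zero
    denominator) are reported as NaN. Y-linked genes are excluded by default
    (call sets without Y genotypes).
    """
    if len(variants) != genotypes.codes.shape[0]:
        raise ValueError("genotype matrix not aligned with variant list")
    if stratum not in ("all", "rare"):
        raise ValueError(f"unknown stratum {stratum!r}")

    keep_genes = genes
    if exclude_chr_y:
        chrom_up = genes["chrom"].astype(str).str.upper()
        keep_genes = genes[~chrom_up.isin(["Y", "CHRY"])]
    if gene_set == "ALL":
        set_ids = set(keep_genes["gene_id"])
    else:
        set_ids = set(keep_genes.loc[keep_genes["ess_class"] == gene_set, "gene_id"])

    v_mask = variants["gene_id"].isin(set_ids).to_numpy()
    if stratum == "rare":
        v_mask &= variants["rare"].to_numpy(dtype=bool)

    eff = variants["effect_class"].to_numpy()
    broad = np.array([is_broad_missense(e) for e in eff]) & v_mask
    syn = (eff == SYNONYMOUS) & v_mask
    lof = (eff == LOF) & v_mask
    damaging = variants["damaging_consensus"].to_numpy(dtype=bool) & broad

    G = genotypes.codes
    carrier = G > 0  # (n_sites, n_samples)

    def count(site_mask: np.ndarray) -> np.ndarray:
        return carrier[site_mask].sum(axis=0).astype(int)

    n_broad = count(broad)
    n_syn = count(syn)
    n_lof = count(lof)
    n_dam = count(damaging)
    n_lof_het = (G[lof] == 1).sum(axis=0).astype(int)
    n_lof_hom = (G[lof] == 2).sum(axis=0).astype(int)

    gene_codes, _ = pd.factorize(variants["gene_id"])
    qual = v_mask
    genes_hit = np.zeros(len(genotypes.sample_ids), dtype=int)
    if qual.any():
        gc = gene_codes[qual]
        sub = carrier[qual]
        for s in range(sub.shape[1]):
            genes_hit[s] = len(np.unique(gc[sub[:, s]]))

    with np.errstate(divide="ignore", invalid="ignore"):
        ns_ratio = np.where(n_syn > 0, n_broad / np.maximum(n_syn, 1), np.nan)
        lof_fraction = np.where(n_broad > 0, n_lof / np.maximum(n_broad, 1), np.nan)

    return pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "gene_set": gene_set,
            "stratum": stratum,
            "n_missense_broad": n_broad,
            "n_synonymous": n_syn,
            "ns_ratio": ns_ratio,
            "n_damaging": n_dam,
            "n_lof": n_lof,
            "lof_fraction": lof_fraction,
            "n_lof_het": n_lof_het,
            "n_lof_hom": n_lof_hom,
            "genes_hit": genes_hit,
        }
    )


def all_loads(
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    genes: pd.DataFrame,
    gene_sets: Iterable[str] = ("EG", "NLG", "ALL"),
    strata: Iterable[str] = ("all", "rare"),
    exclude_chr_y: bool = True,
) -> pd.DataFrame:
    """Stacked per-sample loads over every (gene set, stratum) combination."""
    frames = [
        per_sample_load(variants, genotypes, genes, gs, st, exclude_chr_y)
        for gs in gene_sets
        for st in strata
    ]
    return pd.concat(frames, ignore_index=True)


_FILTER_COLUMN = {
    "missense": "n_missense_broad",
    "damaging": "n_damaging",
    "lof": "n_lof",
    "ns_ratio": "ns_ratio",
    "lof_fraction": "lof_fraction",
}


def cohort_summary(
    loads: pd.DataFrame,
    variant_filter: str = "missense",
    compare: tuple[str, str] = ("EG", "NLG"),
    alternative: str = "less",
) -> tuple[pd.DataFrame, dict[str, TestResult]]:
    """Mean/SD of a load metric per (gene set, stratum) + paired comparisons.

    The EG-vs-NLG comparison pairs values within samples (two properties of
    the same individual), using the one-sided signed-rank test by default
    (``less``: the first set's loads are smaller). Samples with an undefined
    metric in either set are excluded from the paired test. Requires >= 2
    samples per cell.
    """
    col = _FILTER_COLUMN[variant_filter]
    grouped = loads.groupby(["gene_set", "stratum"])[col]
    if (grouped.count() < 2).any():
        raise ValueError("need >= 2 samples with defined values per cell")
    summary = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()

    tests: dict[str, TestResult] = {}
    for stratum in loads["stratum"].unique():
        sub = loads[loads["stratum"] == stratum]
        wide = sub.pivot(index="sample_id", columns="gene_set", values=col)
        if compare[0] in wide.columns and compare[1] in wide.columns:
            pair = wide[[compare[0], compare[1]]].dropna()
            if len(pair) >= 2:
                tests[stratum] = wilcoxon_compare(
                    pair[compare[0]], pair[compare[1]],
                    alternative=alternative, paired=True,
                )
    return summary, tests


def fraction_samples_with_lof(loads: pd.DataFrame) -> pd.DataFrame:
    """Fraction of samples carrying >= 1 LoF variant, per gene set and stratum."""
    out = (
        loads.assign(has_lof=loads["n_lof"] >= 1)
        .groupby(["gene_set", "stratum"])["has_lof"]
        .agg(fraction="mean", n_samples="count")
        .reset_index()
    )
    return out
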