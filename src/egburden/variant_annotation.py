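"""Typed variant records from effect-annotated VCF.

Effect classes follow the SnpEff v2 token vocabulary: seven tokens form the
*broad exonic missense* class, of which the stop-codon and splice-site tokens
are loss-of-function (LoF); ``SYNONYMOUS_CODING`` is synonymous; anything
else is OTHER. Putatively damaging variants require a consensus of both
PolyPhen2 and SIFT calls. Allele frequencies are alt-allele counts over
2 × called diploid samples; *rare* means strictly below 1%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    BROAD_MISSENSE_TOKENS,
    LOF,
    LOF_TOKENS,
    MISSENSE_BROAD,
    OTHER,
    SYNONYMOUS,
    SYNONYMOUS_TOKEN,
)

logger = logging.getLogger(__name__)

RARE_AF_THRESHOLD = 0.01

_warned_tokens: set[str] = set()


class VcfParseError(ValueError):
    """Malformed VCF content."""


@dataclass
class GenotypeMatrix:
    """Per-site alt-allele dosages for every sample (-1 = missing call)."""

    sample_ids: list[str]
    codes: np.ndarray  # int8, shape (n_sites, n_samples)

    def __post_init__(self) -> None:
        if self.codes.ndim != 2 or self.codes.shape[1] != len(self.sample_ids):
            raise ValueError("genotype matrix shape inconsistent with sample list")


def classify_effect(raw_effect: str) -> str:
    """Map an annotation token to an effect class.

    LoF tokens are a subset of the broad missense class and are returned as
    ``LOF``; callers tallying "exonic missense" must include both (see
    :func:`egburden.types.is_broad_missense`). Unknown tokens map to OTHER
    and are logged once per token.
    """
    if not raw_effect:
        raise ValueError("empty effect token")
    if raw_effect in LOF_TOKENS:
        return LOF
    if raw_effect in BROAD_MISSENSE_TOKENS:
        return MISSENSE_BROAD
    if raw_effect == SYNONYMOUS_TOKEN:
        return SYNONYMOUS
    if raw_effect not in _warned_tokens:
        logger.warning("unknown effect token %r mapped to OTHER", raw_effect)
        _warned_tokens.add(raw_effect)
    return OTHER


def consensus_damaging(polyphen: str, sift: str) -> bool:
    """True iff both predictors call the variant damaging.

    A missing call on either side yields False (conservative policy).
    """
    return polyphen == "damaging" and sift == "damaging"


def compute_af(
    genotypes: np.ndarray, rare_threshold: float = RARE_AF_THRESHOLD
) -> tuple[float, bool]:
    """Allele frequency and rare flag for one site's genotype codes.

    ``af = alt allele count / (2 × called samples)``; missing genotypes (-1)
    shrink the denominator. Rare means af strictly below the threshold.
    """
    g = np.asarray(genotypes)
    called = g >= 0
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError("no called genotypes at site")
    af = float(g[called].sum()) / (2.0 * n_called)
    return af, af < rare_threshold


def _parse_eff(eff: Optional[str]) -> tuple[Optional[str], Optional[str]]:
    """Extract (token, gene_id) from a SnpEff-style EFF value."""
    if not eff:
        return None, None
    token, _, rest = eff.partition("(")
    gene = None
    if rest:
        fields = rest.rstrip(")").split("|")
        if len(fields) >= 5 and fields[4]:
            gene = fields[4]
    return token or None, gene


def parse_vcf(
    path: str, rare_threshold: float = RARE_AF_THRESHOLD
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Parse an effect-annotated VCF into a variant table and genotype matrix.

    One output record per biallelic SNV with a gene assignment; multi-allelic
    rows are split per alt allele (each alt's dosage counted separately).
    Records with no gene assignment in the EFF annotation are dropped with a
    logged count. Returns (variants, GenotypeMatrix) where variants carries
    ``chrom, pos, ref, alt, gene_id, raw_effect, effect_class, polyphen,
    sift, damaging_consensus, af, rare, quality_avgpost``.
    """
    from cyvcf2 import VCF  # deferred: htslib import is comparatively heavy

    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 error surface
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    rows: list[dict] = []
    geno_rows: list[np.ndarray] = []
    n_dropped_no_gene = 0

    for rec in vcf:
        token, gene = _parse_eff(rec.INFO.get("EFF"))
        if gene is None:
            n_dropped_no_gene += 1
            continue
        pp2 = rec.INFO.get("PP2") or "missing"
        sift = rec.INFO.get("SIFT") or "missing"
        avgpost = rec.INFO.get("AVGPOST")
        gts = rec.genotypes  # [[a0, a1, phased], ...]

        for alt_idx, alt in enumerate(rec.ALT, start=1):
            codes = np.full(len(sample_ids), -1, dtype=np.int8)
            for s, gt in enumerate(gts):
                alleles = [a for a in gt[:-1] if a is not None and a >= 0]
                if alleles:
                    codes[s] = sum(1 for a in alleles if a == alt_idx)
            if (codes >= 0).sum() == 0:
                logger.warning(
                    "site %s:%d has no called genotypes; skipped", rec.CHROM, rec.POS
                )
                continue
            af, rare = compute_af(codes, rare_threshold)
            eff_class = classify_effect(token) if token else OTHER
            rows.append(
                {
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": alt,
                    "gene_id": gene,
                    "raw_effect": token,
                    "effect_class": eff_class,
                    "polyphen": pp2,
                    "sift": sift,
                    "damaging_consensus": consensus_damaging(pp2, sift),
                    "af": af,
                    "rare": rare,
                    "quality_avgpost": float(avgpost) if avgpost is not None else np.nan,
                }
            )
            geno_rows.append(codes)

    if n_dropped_no_gene:
        logger.info("%d records without gene assignment dropped", n_dropped_no_gene)

    variants = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene_id", "raw_effect", "effect_class",
            "polyphen", "sift", "damaging_consensus", "af", "rare", "quality_avgpost",
        ],
    )
    codes = (
        np.vstack(geno_rows)
        if geno_rows
        else np.zeros((0, len(sample_ids)), dtype=np.int8)
    )
    return variants, GenotypeMatrix(sample_ids, codes)


def intersect_hc_lof(variants: pd.DataFrame, hc_list: pd.DataFrame) -> pd.DataFrame:
    """Flag variants present in a curated high-confidence LoF site list.

    ``hc_list`` needs columns ``chrom, pos, ref, alt``; duplicate keys are
    deduplicated (set semantics). Adds a boolean ``hc_lof`` column.
    """
    keys = set(
        zip(
            hc_list["chrom"].astype(str),
            hc_list["pos"].astype(int),
            hc_list["ref"].astype(str),
            hc_list["alt"].astype(str),
        )
    )
    out = variants.copy()
    out["hc_lof"] = [
        (str(c), int(p), str(r), str(a)) in keys
        for c, p, r, a in zip(out["chrom"], out["pos"], out["ref"], out["alt"])
    ]
    return out


def write_variant_table(variants: pd.DataFrame, path: str) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variant_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
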