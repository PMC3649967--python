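"""Gene-set construction from mouse phenotype annotations.

A gene is *essential* (EG) if its mouse ortholog carries at least one
homozygous annotation with a lethal phenotype code and maps one-to-one to a
human gene. If a gene has both lethal and non-lethal annotations, lethal wins.
Phenotypes observed only in the heterozygous state are disregarded. Genes
with homozygous non-lethal annotations only form the non-lethal set (NLG);
everything else in the universe is OTHER.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FLAG_NAMES = (
    "hgmd",
    "haploinsufficient",
    "ubiquitous_top10",
    "brain_overexpressed",
    "asd_candidate",
)


def load_lethal_codes(path: str) -> set[str]:
    """Read a lethal-phenotype-code config file (one code per line, # comments)."""
    codes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                codes.add(line)
    if not codes:
        raise ValueError(f"lethal-code file {path} is empty")
    return codes


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Expression CV = sample sd / mean (the ubiquitous-expression ranking metric)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs >= 2 expression values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero-mean expression")
    return float(v.std(ddof=1) / mean)


def _one_to_one_map(orthologs: pd.DataFrame) -> dict[str, str]:
    """Mouse→human map restricted to strictly one-to-one rows.

    Rows where the mouse gene maps to more than one human gene, or the human
    gene is hit by more than one mouse gene, are dropped with a warning.
    """
    df = orthologs[["mouse_gene", "human_gene"]].drop_duplicates()
    mouse_multi = df["mouse_gene"].duplicated(keep=False)
    human_multi = df["human_gene"].duplicated(keep=False)
    bad = mouse_multi | human_multi
    if bad.any():
        logger.warning(
            "dropping %d ambiguous ortholog rows (%d mouse genes map to >1 human "
            "gene or vice versa)", int(bad.sum()), df.loc[bad, "mouse_gene"].nunique(),
        )
    df = df[~bad]
    return dict(zip(df["mouse_gene"], df["human_gene"]))


def classify_genes(
    phenotypes: pd.DataFrame,
    lethal_codes: Iterable[str],
    orthologs: pd.DataFrame,
    universe: pd.DataFrame,
) -> pd.DataFrame:
    """Assign EG / NLG / OTHER classes to every gene in the universe.

    Parameters
    ----------
    phenotypes : frame with columns ``mouse_gene, phenotype_code, zygosity``
        (zygosity in {hom, het}).
    lethal_codes : the lethal phenotype code set (nonempty).
    orthologs : frame with columns ``mouse_gene, human_gene``.
    universe : gene table; its ``ess_class`` column is (re)assigned.

    Returns a copy of the universe with ``ess_class`` set. EG and NLG are
    disjoint by construction: any homozygous lethal annotation wins.
    """
    lethal = set(lethal_codes)
    if not lethal:
        raise ValueError("lethal code set must be nonempty")
    bad_zyg = set(phenotypes["zygosity"].unique()) - {"hom", "het"}
    if bad_zyg:
        raise ValueError(f"unknown zygosity values: {sorted(bad_zyg)}")

    m2h = _one_to_one_map(orthologs)

    hom = phenotypes[phenotypes["zygosity"] == "hom"]
    unmapped = set(hom["mouse_gene"]) - set(m2h)
    if unmapped:
        logger.warning(
            "%d phenotype-annotated mouse genes have no usable ortholog and are excluded",
            len(unmapped),
        )

    is_lethal = hom["phenotype_code"].isin(lethal)
    lethal_mouse = set(hom.loc[is_lethal, "mouse_gene"])
    nonlethal_mouse = set(hom.loc[~is_lethal, "mouse_gene"]) - lethal_mouse

    eg_human = {m2h[m] for m in lethal_mouse if m in m2h}
    nlg_human = {m2h[m] for m in nonlethal_mouse if m in m2h} - eg_human

    universe_ids = set(universe["gene_id"])
    for name, s in (("EG", eg_human), ("NLG", nlg_human)):
        missing = s - universe_ids
        if missing:
            logger.warning(
                "%d %s orthologs are absent from the gene universe and ignored",
                len(missing), name,
            )

    out = universe.copy()
    gene_ids = out["gene_id"]
    out["ess_class"] = np.where(
        gene_ids.isin(eg_human), "EG", np.where(gene_ids.isin(nlg_human), "NLG", "OTHER")
    )
    return out


def annotate_flags(
    genes: pd.DataFrame,
    flag_lists: Optional[Mapping[str, Iterable[str]]] = None,
    expression_cv: Optional[pd.DataFrame] = None,
    brain_p: Optional[pd.DataFrame] = None,
    ubiquitous_top_frac: float = 0.10,
    brain_p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Attach boolean annotation flags to the gene table.

    ``flag_lists`` maps a flag name (e.g. ``hgmd``, ``haploinsufficient``,
    ``asd_candidate``) to an iterable of gene IDs; unknown IDs are logged and
    ignored. ``expression_cv`` (columns gene_id, cv) sets ``ubiquitous_top10``
    for genes whose expression coefficient of variation ranks within the
    lowest ``ubiquitous_top_frac`` of ranked genes (low CV = ubiquitously
    expressed). ``brain_p`` (columns gene_id, p_value) sets
    ``brain_overexpressed`` for p <= threshold (inclusive).
    A ``chr_y`` flag is always set from the chromosome column so variant
    analyses can exclude Y-linked genes when a call set carries no Y genotypes.
    """
    out = genes.copy()
    universe_ids = set(out["gene_id"])

    for name, ids in (flag_lists or {}).items():
        ids = set(ids)
        unknown = ids - universe_ids
        if unknown:
            logger.warning("flag %r: %d unknown gene IDs ignored", name, len(unknown))
        out[name] = out["gene_id"].isin(ids & universe_ids)

    if expression_cv is not None:
        ranked = expression_cv.dropna(subset=["cv"]).sort_values(
            ["cv", "gene_id"], kind="stable"
        )
        n_top = int(math.floor(ubiquitous_top_frac * len(ranked)))
        top_ids = set(ranked["gene_id"].iloc[:n_top])
        out["ubiquitous_top10"] = out["gene_id"].isin(top_ids)

    if brain_p is not None:
        hit = set(brain_p.loc[brain_p["p_value"] <= brain_p_threshold, "gene_id"])
        out["brain_overexpressed"] = out["gene_id"].isin(hit)

    out["chr_y"] = out["chrom"].astype(str).str.upper().str.lstrip("CHR") == "Y"
    return out


def set_counts(genes: pd.DataFrame, flag: str) -> dict:
    """Per-class counts and the EG-vs-NLG 2×2 table for a boolean flag.

    Returns ``{"table": [[EG∧F, EG∧¬F], [NLG∧F, NLG∧¬F]], "per_class": {...}}``.
    """
    if flag not in genes.columns:
        raise KeyError(f"flag column {flag!r} not present")
    f = genes[flag].astype(bool)
    per_class = {}
    for cls in ("EG", "NLG", "OTHER"):
        in_cls = genes["ess_class"] == cls
        per_class[cls] = {
            "n": int(in_cls.sum()),
            "with_flag": int((in_cls & f).sum()),
        }
    table = [
        [per_class["EG"]["with_flag"], per_class["EG"]["n"] - per_class["EG"]["with_flag"]],
        [per_class["NLG"]["with_flag"], per_class["NLG"]["n"] - per_class["NLG"]["with_flag"]],
    ]
    return {"table": table, "per_class": per_class}


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_gene_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_gene_table(genes: pd.DataFrame, path: str) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_orthologs(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
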