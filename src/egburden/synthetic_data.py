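"""Synthetic input generators with known ground truth.

Every input the pipeline consumes can be generated here from explicit
distributions: a protein-coding gene universe with essentiality classes,
mouse phenotype annotations plus an ortholog map, a multi-sample
effect-annotated cohort VCF, a per-base conservation track, per-gene
substitution-rate and expression tables, and per-study de novo event lists.

The generators emulate the statistical structure the downstream analysis
assumes rather than any particular genome: essential-gene (EG) orthologs are
longer on average, carry fewer non-synonymous sites per base pair, show an
allele-frequency spectrum shifted towards rare variants, and attract de novo
events in proportion to exon length and GC content, with a tunable true
enrichment odds in case probands.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .types import LOF_TOKENS, SYNONYMOUS_TOKEN

logger = logging.getLogger(__name__)

_BASES = np.array(["A", "C", "G", "T"])
_CHROMS = [str(c) for c in range(1, 23)] + ["X"]

#: Placeholder lethal / non-lethal phenotype code vocabularies (synthetic --
#: real analyses supply the curated lethal-code list as a config file).
DEFAULT_LETHAL_CODES = tuple(f"MP:L{i:04d}" for i in range(1, 47))
DEFAULT_NONLETHAL_CODES = tuple(f"MP:N{i:04d}" for i in range(1, 31))

#: Non-LoF token mix for broad-missense sites.
_MISSENSE_TOKENS = ("NON_SYNONYMOUS_CODING", "START_LOST", "START_GAINED")
_MISSENSE_TOKEN_P = (0.90, 0.05, 0.05)
_LOF_TOKEN_LIST = sorted(LOF_TOKENS)

#: De novo mutation-type mix for coding (non-synonymous) events.
_DENOVO_CODING_MIX = {
    "missense": 0.70,
    "nonsense": 0.10,
    "frameshift": 0.10,
    "splice": 0.05,
    "inframe": 0.03,
    "del_aa": 0.01,
    "stoploss": 0.01,
}


class ConfigError(ValueError):
    """Invalid generator configuration."""


def _as_rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Gene universe
# ---------------------------------------------------------------------------


@dataclass
class UniverseConfig:
    """Distributional description of the protein-coding gene universe.

    ``length_law`` is the (log-scale mean, log-scale sd) of a log-normal over
    total exon length in bp; EG lengths are multiplied by
    ``eg_length_multiplier`` (>1 makes essential genes longer, as observed).
    ``gc_law`` is (mean %, sd %) of a normal truncated to [20, 80].
    """

    n_genes: int = 20_000
    eg_fraction: float = 0.1234      # ~2,472 / 20,029
    nlg_fraction: float = 0.1903     # ~3,811 / 20,029
    length_law: tuple[float, float] = (7.3, 0.8)
    eg_length_multiplier: float = 1.5
    gc_law: tuple[float, float] = (46.0, 8.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        if not (0.0 <= self.eg_fraction <= 1.0 and 0.0 <= self.nlg_fraction <= 1.0):
            raise ConfigError("class fractions must lie in [0, 1]")
        if self.eg_fraction + self.nlg_fraction > 1.0 + 1e-12:
            raise ConfigError("eg_fraction + nlg_fraction must be <= 1")
        if self.eg_length_multiplier <= 0:
            raise ConfigError("eg_length_multiplier must be > 0")
        if self.length_law[1] < 0 or self.gc_law[1] < 0:
            raise ConfigError("scale parameters must be >= 0")


GENE_TABLE_COLUMNS = [
    "gene_id",
    "symbol",
    "chrom",
    "tss",
    "strand",
    "exon_length_bp",
    "gc_pct",
    "ess_class",
]


def generate_gene_universe(cfg: UniverseConfig) -> pd.DataFrame:
    """Draw a gene universe with EG/NLG/OTHER labels in configured proportions.

    Returns a gene table with columns ``gene_id, symbol, chrom, tss, strand,
    exon_length_bp, gc_pct, ess_class`` (one row per gene). Lengths are
    clipped at 100 bp, GC at [20, 80]%.
    """
    cfg.validate()
    n = cfg.n_genes
    rng = _as_rng(cfg.seed)

    if n == 0:
        return pd.DataFrame(columns=GENE_TABLE_COLUMNS)

    n_eg = int(round(n * cfg.eg_fraction))
    n_nlg = int(round(n * cfg.nlg_fraction))
    n_nlg = min(n_nlg, n - n_eg)
    ess = np.array(["EG"] * n_eg + ["NLG"] * n_nlg + ["OTHER"] * (n - n_eg - n_nlg))
    rng.shuffle(ess)

    mu, sigma = cfg.length_law
    lengths = rng.lognormal(mean=mu, sigma=sigma, size=n)
    lengths[ess == "EG"] *= cfg.eg_length_multiplier
    lengths = np.maximum(np.round(lengths), 100).astype(np.int64)

    gc_mu, gc_sd = cfg.gc_law
    if gc_sd == 0:
        gc = np.full(n, float(gc_mu))
    else:
        a, b = (20.0 - gc_mu) / gc_sd, (80.0 - gc_mu) / gc_sd
        gc = stats.truncnorm.rvs(a, b, loc=gc_mu, scale=gc_sd, size=n, random_state=rng)
    gc = np.clip(gc, 20.0, 80.0)

    chrom = rng.choice(_CHROMS, size=n)
    tss = rng.integers(1_000_000, 100_000_000, size=n)
    strand = rng.choice(["+", "-"], size=n)

    idx = np.arange(1, n + 1)
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:06d}" for i in idx],
            "symbol": [f"SYNG{i}" for i in idx],
            "chrom": chrom,
            "tss": tss,
            "strand": strand,
            "exon_length_bp": lengths,
            "gc_pct": np.round(gc, 3),
            "ess_class": ess,
        }
    )


# ---------------------------------------------------------------------------
# Phenotype annotations + ortholog map
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    genes: pd.DataFrame,
    lethal_codes: Sequence[str] = DEFAULT_LETHAL_CODES,
    nonlethal_codes: Sequence[str] = DEFAULT_NONLETHAL_CODES,
    seed: Union[int, np.random.Generator] = 0,
    p_extra_nonlethal: float = 0.3,
    p_het_noise: float = 0.2,
    other_mapped_fraction: float = 0.3,
    n_ambiguous: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a mouse phenotype table and ortholog map consistent with labels.

    EG genes receive at least one homozygous lethal annotation (possibly plus
    non-lethal and heterozygous rows — classification must still call them
    EG). NLG genes receive a homozygous non-lethal annotation, optionally plus
    a heterozygous lethal row which must be disregarded. A fraction of OTHER
    genes are mapped with either no phenotype rows or het-only lethal rows,
    and ``n_ambiguous`` one-to-many ortholog rows are injected on otherwise
    unmapped OTHER genes so that downstream filtering is exercised without
    changing any truth label.

    Returns ``(phenotypes, orthologs)``: phenotype columns
    ``mouse_gene, phenotype_code, zygosity``; ortholog columns
    ``mouse_gene, human_gene``.
    """
    rng = _as_rng(seed)
    lethal = list(lethal_codes)
    nonlethal = list(nonlethal_codes)
    if not lethal or not nonlethal:
        raise ConfigError("code lists must be nonempty")

    pheno_rows: list[tuple[str, str, str]] = []
    ortho_rows: list[tuple[str, str]] = []

    other_ids = genes.loc[genes["ess_class"] == "OTHER", "gene_id"].to_numpy()
    n_other_mapped = int(round(other_mapped_fraction * len(other_ids)))
    mapped_other = set(rng.choice(other_ids, size=n_other_mapped, replace=False)) if n_other_mapped else set()

    for row in genes.itertuples(index=False):
        mouse = f"Mgi{row.gene_id[1:]}"
        if row.ess_class == "EG":
            ortho_rows.append((mouse, row.gene_id))
            pheno_rows.append((mouse, str(rng.choice(lethal)), "hom"))
            if rng.random() < p_extra_nonlethal:
                pheno_rows.append((mouse, str(rng.choice(nonlethal)), "hom"))
            if rng.random() < p_het_noise:
                pheno_rows.append((mouse, str(rng.choice(lethal)), "het"))
        elif row.ess_class == "NLG":
            ortho_rows.append((mouse, row.gene_id))
            pheno_rows.append((mouse, str(rng.choice(nonlethal)), "hom"))
            if rng.random() < p_het_noise:
                pheno_rows.append((mouse, str(rng.choice(lethal)), "het"))
        elif row.gene_id in mapped_other:
            ortho_rows.append((mouse, row.gene_id))
            if rng.random() < p_het_noise:
                # het-only lethal annotation: must not promote to EG
                pheno_rows.append((mouse, str(rng.choice(lethal)), "het"))

    # ambiguous (one mouse -> two human) rows on unmapped OTHER genes; a hom
    # lethal annotation on the ambiguous mouse gene must be discarded
    unmapped = [g for g in other_ids if g not in mapped_other]
    k = min(n_ambiguous, len(unmapped) // 2)
    for j in range(k):
        mouse = f"MgiAMB{j:04d}"
        ortho_rows.append((mouse, unmapped[2 * j]))
        ortho_rows.append((mouse, unmapped[2 * j + 1]))
        pheno_rows.append((mouse, str(rng.choice(lethal)), "hom"))

    pheno = pd.DataFrame(pheno_rows, columns=["mouse_gene", "phenotype_code", "zygosity"])
    ortho = pd.DataFrame(ortho_rows, columns=["mouse_gene", "human_gene"])
    return pheno, ortho


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


MultiplierSpec = Mapping[str, Union[float, Mapping[str, float]]]


@dataclass
class CohortConfig:
    """Distributional description of a diploid cohort call set.

    ``site_rate`` gives unconstrained per-bp site rates per effect class.
    ``constraint_multiplier`` scales the non-synonymous rates per gene class;
    values may be scalars (applied to missense and lof) or per-effect-class
    mappings. Synonymous sites are neutral unless explicitly scaled.

    Allele frequencies are drawn from a discretized law f(x) ∝ x^(−af_alpha)
    on the grid {i/(2N): i = 1..N}; EG non-synonymous sites use exponent
    ``af_alpha + rare_skew_eg`` (a rarer-shifted spectrum).
    """

    n_samples: int = 100
    site_rate: Mapping[str, float] = field(
        default_factory=lambda: {"synonymous": 2e-3, "missense": 2e-3, "lof": 2e-4}
    )
    constraint_multiplier: MultiplierSpec = field(
        default_factory=lambda: {
            "EG": {"synonymous": 1.0, "missense": 0.5, "lof": 0.2},
            "NLG": 1.0,
            "OTHER": 1.0,
        }
    )
    af_alpha: float = 1.0
    rare_skew_eg: float = 1.0
    damaging_prob: float = 0.3
    predictor_concordance: float = 0.9
    predictor_missing_rate: float = 0.02
    avgpost_law: tuple[float, float] = (0.97, 0.02)
    seed: int = 0

    def multiplier(self, gene_class: str, effect_class: str) -> float:
        entry = self.constraint_multiplier.get(gene_class, 1.0)
        if isinstance(entry, Mapping):
            m = float(entry.get(effect_class, 1.0))
        else:
            # scalar applies to the selected (non-synonymous) classes only
            m = float(entry) if effect_class in ("missense", "lof") else 1.0
        if m < 0:
            raise ConfigError("constraint multipliers must be >= 0")
        return m

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if any(r < 0 for r in self.site_rate.values()):
            raise ConfigError("site rates must be >= 0")
        if self.af_alpha < 0 or self.rare_skew_eg < 0:
            raise ConfigError("allele-frequency exponents must be >= 0")
        if not (0.0 <= self.damaging_prob <= 1.0):
            raise ConfigError("damaging_prob must be a probability")


def _af_grid(n_samples: int) -> np.ndarray:
    n_chrom = 2 * n_samples
    return np.arange(1, n_samples + 1) / n_chrom  # up to 0.5


def _af_weights(grid: np.ndarray, alpha: float) -> np.ndarray:
    w = grid.astype(float) ** (-alpha)
    return w / w.sum()


def simulate_cohort(
    genes: pd.DataFrame, cfg: CohortConfig
) -> tuple[pd.DataFrame, np.ndarray, list[str], dict]:
    """Simulate an annotated cohort call set over a gene universe.

    Per gene and effect class the number of sites is Poisson with mean
    ``site_rate × exon_length × multiplier(gene class, effect class)``.
    Each site draws an allele frequency from the configured grid law and
    genotypes under Hardy–Weinberg; sites monomorphic in the sampled cohort
    are dropped (a cohort call set only contains sites observed in it).

    Returns ``(sites, genotypes, sample_ids, truth)`` where ``sites`` has one
    row per retained site (columns ``chrom, pos, ref, alt, gene_id,
    raw_effect, sim_class, true_af, latent_damaging, polyphen, sift,
    avgpost``), ``genotypes`` is an int8 array of alt-allele counts with
    shape (n_sites, n_samples), and ``truth`` records the drawn parameters.
    """
    cfg.validate()
    if genes.empty:
        raise ConfigError("gene table must be nonempty")
    rng = _as_rng(cfg.seed)

    n_samples = cfg.n_samples
    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    grid = _af_grid(n_samples)
    w_base = _af_weights(grid, cfg.af_alpha)
    w_rare = _af_weights(grid, cfg.af_alpha + cfg.rare_skew_eg)

    lengths = genes["exon_length_bp"].to_numpy()
    classes = genes["ess_class"].to_numpy()

    frames: list[pd.DataFrame] = []
    geno_blocks: list[np.ndarray] = []
    truth_counts: dict[str, int] = {}

    for eff in ("synonymous", "missense", "lof"):
        rate = float(cfg.site_rate.get(eff, 0.0))
        mult = np.array([cfg.multiplier(c, eff) for c in classes])
        lam = rate * lengths * mult
        n_sites_per_gene = rng.poisson(lam)
        total = int(n_sites_per_gene.sum())
        truth_counts[eff] = total
        if total == 0:
            continue

        gene_idx = np.repeat(np.arange(len(genes)), n_sites_per_gene)
        is_eg = classes[gene_idx] == "EG"

        # allele frequency: EG non-synonymous sites use the rarer-shifted law
        af = np.empty(total)
        use_rare = is_eg & (eff != "synonymous")
        af[~use_rare] = rng.choice(grid, size=int((~use_rare).sum()), p=w_base)
        af[use_rare] = rng.choice(grid, size=int(use_rare.sum()), p=w_rare)

        genotypes = rng.binomial(2, af[:, None], size=(total, n_samples)).astype(np.int8)
        poly = genotypes.sum(axis=1) > 0

        # positions: unique offsets within each gene's exonic span
        pos = np.empty(total, dtype=np.int64)
        start = 0
        for g, k in zip(*np.unique(gene_idx, return_counts=True)):
            span = int(lengths[g])
            offs = rng.choice(span, size=min(k, span), replace=False)
            if k > span:  # degenerate tiny gene: allow duplicates
                offs = np.concatenate([offs, rng.integers(0, span, size=k - span)])
            pos[start : start + k] = genes["tss"].iat[g] + np.sort(offs)
            start += k

        ref_i = rng.integers(0, 4, size=total)
        alt_i = (ref_i + rng.integers(1, 4, size=total)) % 4

        if eff == "synonymous":
            tokens = np.full(total, SYNONYMOUS_TOKEN, dtype=object)
        elif eff == "missense":
            tokens = rng.choice(_MISSENSE_TOKENS, size=total, p=_MISSENSE_TOKEN_P)
        else:
            tokens = rng.choice(_LOF_TOKEN_LIST, size=total)

        # predictor calls: latent damaging state only for non-LoF missense
        polyphen = np.full(total, "missing", dtype=object)
        sift = np.full(total, "missing", dtype=object)
        latent = np.zeros(total, dtype=bool)
        if eff == "missense":
            latent = rng.random(total) < cfg.damaging_prob
            for arr, (pos_lab, neg_lab) in (
                (polyphen, ("damaging", "benign")),
                (sift, ("damaging", "tolerated")),
            ):
                concordant = rng.random(total) < cfg.predictor_concordance
                call = np.where(latent == concordant, pos_lab, neg_lab)
                miss = rng.random(total) < cfg.predictor_missing_rate
                arr[:] = np.where(miss, "missing", call)

        avgpost = np.clip(
            rng.normal(cfg.avgpost_law[0], cfg.avgpost_law[1], size=total), 0.0, 1.0
        )

        frames.append(
            pd.DataFrame(
                {
                    "chrom": genes["chrom"].to_numpy()[gene_idx],
                    "pos": pos,
                    "ref": _BASES[ref_i],
                    "alt": _BASES[alt_i],
                    "gene_id": genes["gene_id"].to_numpy()[gene_idx],
                    "raw_effect": tokens,
                    "sim_class": eff,
                    "true_af": af,
                    "latent_damaging": latent,
                    "polyphen": polyphen,
                    "sift": sift,
                    "avgpost": np.round(avgpost, 4),
                }
            )[poly]
        )
        geno_blocks.append(genotypes[poly])

    if frames:
        sites = pd.concat(frames, ignore_index=True)
        G = np.concatenate(geno_blocks, axis=0)
        order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
        sites = sites.iloc[order].reset_index(drop=True)
        G = G[order]
    else:
        sites = pd.DataFrame(
            columns=[
                "chrom", "pos", "ref", "alt", "gene_id", "raw_effect", "sim_class",
                "true_af", "latent_damaging", "polyphen", "sift", "avgpost",
            ]
        )
        G = np.zeros((0, n_samples), dtype=np.int8)

    truth = {
        "n_samples": n_samples,
        "site_rate": dict(cfg.site_rate),
        "constraint_multiplier": {
            k: (dict(v) if isinstance(v, Mapping) else float(v))
            for k, v in cfg.constraint_multiplier.items()
        },
        "af_alpha": cfg.af_alpha,
        "rare_skew_eg": cfg.rare_skew_eg,
        "damaging_prob": cfg.damaging_prob,
        "seed": cfg.seed,
        "n_sites_drawn": truth_counts,
        "n_sites_retained": int(len(sites)),
    }
    return sites, G, sample_ids, truth


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_cohort_vcf(
    sites: pd.DataFrame,
    genotypes: np.ndarray,
    sample_ids: Sequence[str],
    path: str,
) -> None:
    """Write the simulated cohort as a VCFv4.1 file.

    The effect annotation goes into ``INFO/EFF`` in a SnpEff-like
    ``TOKEN(...|gene_id|...)`` form; predictor calls into ``PP2`` / ``SIFT``
    (omitted when missing), genotype posterior mean into ``AVGPOST``.
    Genotypes are unphased GT fields.
    """
    chroms = list(dict.fromkeys(sites["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.1\n")
        fh.write("##source=egburden-synthetic\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=EFF,Number=1,Type=String,Description="Effect annotation: TOKEN(||||gene_id|)">\n')
        fh.write('##INFO=<ID=PP2,Number=1,Type=String,Description="PolyPhen2 call">\n')
        fh.write('##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT call">\n')
        fh.write('##INFO=<ID=AVGPOST,Number=1,Type=Float,Description="Mean genotype posterior">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for i, row in enumerate(sites.itertuples(index=False)):
            info = [f"EFF={row.raw_effect}(||||{row.gene_id}|)"]
            if row.polyphen != "missing":
                info.append(f"PP2={row.polyphen}")
            if row.sift != "missing":
                info.append(f"SIFT={row.sift}")
            info.append(f"AVGPOST={row.avgpost:.4f}")
            gts = "\t".join(_GT_STRINGS[int(g)] for g in genotypes[i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                + ";".join(info)
                + f"\tGT\t{gts}\n"
            )


def variants_from_simulation(
    sites: pd.DataFrame,
    genotypes: np.ndarray,
    rare_threshold: float = 0.01,
) -> pd.DataFrame:
    """Typed variant table directly from a simulated cohort (no VCF round trip).

    Produces the same columns :func:`egburden.variant_annotation.parse_vcf`
    yields, with allele frequencies recomputed from the genotype matrix.
    """
    from .variant_annotation import classify_effect, consensus_damaging

    n_called = genotypes.shape[1] - (genotypes < 0).sum(axis=1)
    ac = np.where(genotypes > 0, genotypes, 0).sum(axis=1)
    af = ac / (2.0 * np.maximum(n_called, 1))
    return pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "ref": sites["ref"].to_numpy(),
            "alt": sites["alt"].to_numpy(),
            "gene_id": sites["gene_id"].to_numpy(),
            "raw_effect": sites["raw_effect"].to_numpy(),
            "effect_class": [classify_effect(t) for t in sites["raw_effect"]],
            "polyphen": sites["polyphen"].to_numpy(),
            "sift": sites["sift"].to_numpy(),
            "damaging_consensus": [
                consensus_damaging(p, s)
                for p, s in zip(sites["polyphen"], sites["sift"])
            ],
            "af": af,
            "rare": af < rare_threshold,
            "quality_avgpost": sites["avgpost"].to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# De novo studies
# ---------------------------------------------------------------------------


@dataclass
class DeNovoStudyConfig:
    """One synthetic trio study's de novo event list.

    Event genes are drawn with weight ``exon_length × gc_weight × true_or``
    (the odds multiplier applying only to EG genes in the case arm).
    ``gc_weight = clip(1 + gamma·(GC − mean GC)/sd GC, 0.1, ∞)`` models the
    positive correlation between GC content and de novo event counts.
    """

    study_id: str = "study1"
    n_case_events: int = 200
    n_control_events: int = 150
    true_or: float = 1.0
    synonymous_fraction: float = 0.3
    gc_gamma: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.true_or <= 0:
            raise ConfigError("true_or must be > 0")
        if self.n_case_events < 0 or self.n_control_events < 0:
            raise ConfigError("event counts must be >= 0")
        if not (0.0 <= self.synonymous_fraction <= 1.0):
            raise ConfigError("synonymous_fraction must be a probability")


def gc_weight(gc_pct: np.ndarray, gamma: float = 0.2) -> np.ndarray:
    """De novo sampling weight from GC content, standardized and clipped."""
    gc = np.asarray(gc_pct, dtype=float)
    sd = gc.std()
    if sd == 0 or gamma == 0:
        return np.ones_like(gc)
    return np.clip(1.0 + gamma * (gc - gc.mean()) / sd, 0.1, None)


def simulate_denovo_study(genes: pd.DataFrame, cfg: DeNovoStudyConfig) -> pd.DataFrame:
    """Draw one study's de novo events (columns: study, arm, gene_id, mutation_type)."""
    cfg.validate()
    if genes.empty:
        raise ConfigError("gene table must be nonempty")
    if "ess_class" not in genes.columns:
        raise ConfigError("gene table must carry class labels")
    rng = _as_rng(cfg.seed)

    base_w = genes["exon_length_bp"].to_numpy(dtype=float) * gc_weight(
        genes["gc_pct"].to_numpy(), cfg.gc_gamma
    )
    case_w = base_w * np.where(genes["ess_class"].to_numpy() == "EG", cfg.true_or, 1.0)

    coding_types = list(_DENOVO_CODING_MIX)
    coding_p = np.array(list(_DENOVO_CODING_MIX.values()))
    coding_p = coding_p / coding_p.sum()

    rows = []
    for arm, n_events, w in (
        ("case", cfg.n_case_events, case_w),
        ("control", cfg.n_control_events, base_w),
    ):
        if n_events == 0:
            continue
        p = w / w.sum()
        gene_rows = rng.choice(len(genes), size=n_events, p=p)
        syn = rng.random(n_events) < cfg.synonymous_fraction
        types = np.where(
            syn, "synonymous", rng.choice(coding_types, size=n_events, p=coding_p)
        )
        for gi, t in zip(gene_rows, types):
            rows.append((cfg.study_id, arm, genes["gene_id"].iat[int(gi)], str(t)))
    return pd.DataFrame(rows, columns=["study", "arm", "gene_id", "mutation_type"])


# ---------------------------------------------------------------------------
# Auxiliary per-gene tables (substitution rates, conservation, expression)
# ---------------------------------------------------------------------------


def simulate_gene_metrics(
    genes: pd.DataFrame,
    seed: Union[int, np.random.Generator] = 0,
    species: Sequence[str] = ("rhesus", "chimp", "mouse", "rat"),
    dnds_base: float = 0.25,
    dnds_log_sd: float = 0.5,
    dnds_multiplier: Optional[Mapping[str, float]] = None,
    transcript_lambda: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Per-gene dN/dS per species pair and alternative-transcript counts.

    EG genes draw lower dN/dS (stronger purifying selection) and more
    alternative transcripts by default. Long format: gene_id, metric, value.
    """
    rng = _as_rng(seed)
    dnds_multiplier = dict(dnds_multiplier or {"EG": 0.6, "NLG": 1.0, "OTHER": 1.0})
    transcript_lambda = dict(transcript_lambda or {"EG": 6.0, "NLG": 4.0, "OTHER": 4.0})
    classes = genes["ess_class"].to_numpy()
    mult = np.array([dnds_multiplier.get(c, 1.0) for c in classes])

    frames = []
    for sp in species:
        vals = np.exp(rng.normal(np.log(dnds_base * mult), dnds_log_sd))
        frames.append(
            pd.DataFrame(
                {"gene_id": genes["gene_id"], "metric": f"dnds_{sp}", "value": vals}
            )
        )
    lam = np.array([transcript_lambda.get(c, 4.0) for c in classes])
    frames.append(
        pd.DataFrame(
            {
                "gene_id": genes["gene_id"],
                "metric": "n_transcripts",
                "value": 1 + rng.poisson(lam),
            }
        )
    )
    return pd.concat(frames, ignore_index=True)


def simulate_conservation_track(
    genes: pd.DataFrame,
    seed: Union[int, np.random.Generator] = 0,
    window_bp: int = 120,
    class_shift: Optional[Mapping[str, float]] = None,
    score_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-base conservation scores around each TSS (bedGraph-shaped frame).

    Scores are Normal(shift[class], score_sd) per base, covering
    TSS ± window_bp. Columns: chrom, start (0-based), end, score.
    """
    rng = _as_rng(seed)
    class_shift = dict(class_shift or {"EG": 0.8, "NLG": 0.2, "OTHER": 0.0})
    rows = []
    width = 2 * window_bp + 1
    for row in genes.itertuples(index=False):
        mu = class_shift.get(row.ess_class, 0.0)
        scores = rng.normal(mu, score_sd, size=width)
        start0 = int(row.tss) - window_bp - 1  # 0-based start of (tss - window)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": row.chrom,
                    "start": start0 + np.arange(width),
                    "end": start0 + np.arange(width) + 1,
                    "score": np.round(scores, 4),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "end", "score"]
    )
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def simulate_expression_tables(
    genes: pd.DataFrame,
    seed: Union[int, np.random.Generator] = 0,
    cv_log_mean: Optional[Mapping[str, float]] = None,
    brain_over_prob: Optional[Mapping[str, float]] = None,
    brain_p_threshold: float = 1e-4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene expression CV ranking input and brain over-expression p-values.

    Lower CV = more ubiquitous expression; EG genes draw lower CV on average.
    Brain over-expression p-values are a mixture: with the per-class
    probability the gene is truly over-expressed (p ~ U(0, threshold]),
    otherwise p ~ U(threshold, 1).
    """
    rng = _as_rng(seed)
    cv_log_mean = dict(cv_log_mean or {"EG": -1.0, "NLG": -0.6, "OTHER": -0.5})
    brain_over_prob = dict(brain_over_prob or {"EG": 0.16, "NLG": 0.15, "OTHER": 0.10})
    classes = genes["ess_class"].to_numpy()

    mu = np.array([cv_log_mean.get(c, -0.5) for c in classes])
    cv = np.exp(rng.normal(mu, 0.5))
    cv_tab = pd.DataFrame({"gene_id": genes["gene_id"], "cv": cv})

    over = rng.random(len(genes)) < np.array([brain_over_prob.get(c, 0.1) for c in classes])
    p = np.where(
        over,
        rng.uniform(0.0, brain_p_threshold, size=len(genes)),
        rng.uniform(brain_p_threshold, 1.0, size=len(genes)),
    )
    brain_tab = pd.DataFrame({"gene_id": genes["gene_id"], "p_value": p})
    return cv_tab, brain_tab
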