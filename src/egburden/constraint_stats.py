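"""Gene-set constraint statistics.

Length-corrected variant rates with Z-score / log1p transforms, one-sided
Wilcoxon comparisons (paired within samples, unpaired between gene sets),
two-sided Fisher exact tests with sample odds ratios and Woolf logit
confidence intervals, site-frequency-spectrum excess profiles, and promoter
conservation summaries (mean per-base score in TSS ± 100 bp).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import LOF, MISSENSE_BROAD, SYNONYMOUS, TestResult, is_broad_missense

logger = logging.getLogger(__name__)

#: Default allele-frequency bins (right-closed) for SFS comparisons.
DEFAULT_SFS_BINS = (0.0, 0.001, 0.005, 0.01, 0.05, 0.1, 0.5)


# ---------------------------------------------------------------------------
# Length-corrected rates
# ---------------------------------------------------------------------------


def _effect_mask(variants: pd.DataFrame, effect_filter: Optional[str]) -> pd.Series:
    if effect_filter is None or effect_filter == "all":
        return pd.Series(True, index=variants.index)
    if effect_filter == "missense_broad":
        return variants["effect_class"].map(is_broad_missense)
    if effect_filter == "lof":
        return variants["effect_class"] == LOF
    if effect_filter == "synonymous":
        return variants["effect_class"] == SYNONYMOUS
    if effect_filter == "damaging":
        return variants["effect_class"].map(is_broad_missense) & variants[
            "damaging_consensus"
        ].astype(bool)
    raise ValueError(f"unknown effect filter {effect_filter!r}")


def per_gene_counts(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    effect_filter: Optional[str] = None,
    rare_only: bool = False,
) -> pd.Series:
    """Variant count per universe gene (0 for genes without variants)."""
    mask = _effect_mask(variants, effect_filter)
    if rare_only:
        mask &= variants["rare"].astype(bool)
    counts = variants.loc[mask].groupby("gene_id").size()
    return counts.reindex(genes["gene_id"], fill_value=0)


def zscores(values: np.ndarray) -> np.ndarray:
    """Z-scores with sample sd (ddof=1) relative to the full vector."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def length_corrected_rate(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    class_filter: Optional[str] = None,
    effect_filter: Optional[str] = None,
    transform: str = "rate",
    rare_only: bool = False,
) -> pd.DataFrame:
    """Per-gene, length-corrected variant rates.

    ``transform``:

    * ``rate`` — count / exon_length_bp
    * ``z`` — Z-score of the rate relative to ALL genes (sample sd)
    * ``log1p`` — log(count + 1), the pseudo-count transform
    * ``log1p_z`` — Z-score of log(count + 1) relative to ALL genes

    Z-normalization always uses the full universe; ``class_filter`` then
    restricts the returned rows to one essentiality class.
    """
    lengths = genes["exon_length_bp"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene table contains non-positive exon lengths")
    counts = per_gene_counts(variants, genes, effect_filter, rare_only).to_numpy(float)

    if transform == "rate":
        value = counts / lengths
    elif transform == "z":
        value = zscores(counts / lengths)
    elif transform == "log1p":
        value = np.log(counts + 1.0)
    elif transform == "log1p_z":
        value = zscores(np.log(counts + 1.0))
    else:
        raise ValueError(f"unknown transform {transform!r}")

    out = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "ess_class": genes["ess_class"].to_numpy(),
            "metric": f"{effect_filter or 'all'}_{transform}",
            "value": value,
        }
    )
    if class_filter is not None:
        out = out[out["ess_class"] == class_filter].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------


def wilcoxon_compare(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    paired: bool = False,
) -> TestResult:
    """Wilcoxon comparison of two samples.

    Unpaired: Mann–Whitney rank-sum (exact for small tie-free samples, else
    normal approximation with continuity correction). Paired: signed-rank on
    the within-sample differences. ``alternative`` is relative to ``a``
    (``less`` means a < b). Paired comparisons with all-zero differences
    carry no evidence and return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be nonempty")
    sidedness = "two" if alternative == "two-sided" else "one"
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal-length samples")
        d = a - b
        if np.all(d == 0):
            return TestResult(0.0, 1.0, sidedness, paired=True, method="wilcoxon-signed-rank")
        stat, p = stats.wilcoxon(a, b, alternative=alternative, zero_method="wilcox")
        return TestResult(float(stat), float(p), sidedness, paired=True,
                          method="wilcoxon-signed-rank")
    stat, p = stats.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return TestResult(float(stat), float(min(p, 1.0)), sidedness, paired=False,
                      method="mann-whitney")


def fisher_2x2(
    table: Sequence[Sequence[float]],
    ci_method: str = "woolf",
    or_kind: str = "conditional",
) -> TestResult:
    """Two-sided Fisher's exact test with odds ratio and 95% CI.

    ``or_kind="conditional"`` (default) reports the conditional maximum-
    likelihood odds ratio — what R's ``fisher.test`` prints; ``"sample"``
    reports the cross-product (a·d)/(b·c). With any zero cell a 0.5
    continuity correction is applied to all cells (sample OR, flagged
    ``continuity_corrected``). The default CI is Woolf's logit interval
    exp(ln OR_sample ± 1.96·√(1/a+1/b+1/c+1/d)); ``ci_method="conditional"``
    uses the conditional exact interval instead.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 nonnegative integers")
    a, b = t[0]
    c, d = t[1]
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")

    flags: tuple[str, ...] = ()
    ta, tb, tc, td = a, b, c, d
    if min(a, b, c, d) == 0:
        ta, tb, tc, td = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flags = ("continuity_corrected",)
    or_sample = (ta * td) / (tb * tc)

    if flags or or_kind == "sample":
        or_ = or_sample
    elif or_kind == "conditional":
        or_ = float(
            stats.contingency.odds_ratio(t.astype(int), kind="conditional").statistic
        )
    else:
        raise ValueError(f"unknown or_kind {or_kind!r}")

    if ci_method == "woolf":
        se = np.sqrt(1 / ta + 1 / tb + 1 / tc + 1 / td)
        ci = (
            float(np.exp(np.log(or_sample) - 1.96 * se)),
            float(np.exp(np.log(or_sample) + 1.96 * se)),
        )
    elif ci_method == "conditional":
        res = stats.contingency.odds_ratio(t.astype(int), kind="conditional")
        ci_obj = res.confidence_interval(0.95)
        ci = (float(ci_obj.low), float(ci_obj.high))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    ci = (min(ci[0], or_), max(ci[1], or_))

    return TestResult(
        statistic=float(or_), p_value=float(p), sidedness="two",
        or_=float(or_), ci95=ci, method=f"fisher-exact+{or_kind}+{ci_method}",
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Site frequency spectrum
# ---------------------------------------------------------------------------


def sfs_relative_excess(
    af_set: Sequence[float],
    af_all: Sequence[float],
    bins: Sequence[float] = DEFAULT_SFS_BINS,
) -> tuple[pd.DataFrame, TestResult]:
    """Per-bin relative excess of a set's allele-frequency spectrum.

    excess(bin) = share of the set's variants in the bin − share of the
    comparator's variants in the bin (positive in low bins = rarer-shifted).
    Bins are right-closed intervals over the given edges. The accompanying
    one-sided Wilcoxon tests "set is rarer" on the raw frequencies.
    """
    af_set = np.asarray(af_set, dtype=float)
    af_all = np.asarray(af_all, dtype=float)
    if af_set.size == 0 or af_all.size == 0:
        raise ValueError("both frequency lists must be nonempty")
    edges = np.asarray(bins, dtype=float)

    def shares(x: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(edges, x, side="left") - 1
        idx = np.clip(idx, 0, len(edges) - 2)
        cnt = np.bincount(idx, minlength=len(edges) - 1).astype(float)
        return cnt / cnt.sum()

    s_set, s_all = shares(af_set), shares(af_all)
    table = pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "share_set": s_set,
            "share_all": s_all,
            "excess": s_set - s_all,
        }
    )
    test = wilcoxon_compare(af_set, af_all, alternative="less")
    return table, test


# ---------------------------------------------------------------------------
# Conservation track summaries
# ---------------------------------------------------------------------------


def read_bedgraph(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "score"],
        dtype={"chrom": str}, comment="#",
    )


def promoter_mean_score(
    track: pd.DataFrame, genes: pd.DataFrame, window_bp: int = 100
) -> pd.DataFrame:
    """Mean per-base track score in the promoter window TSS ± window_bp.

    The window is strand-symmetric (1-based inclusive ``[tss − w, tss + w]``).
    Track intervals are bedGraph convention (0-based half-open); bases with
    no coverage are omitted from the mean; genes with no covered base get a
    missing metric and are logged.
    """
    values = []
    for chrom, sub in track.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        scores = sub["score"].to_numpy(dtype=float)
        order = np.argsort(starts, kind="stable")
        values.append((str(chrom), starts[order], ends[order], scores[order]))
    by_chrom = {c: (s, e, v) for c, s, e, v in values}

    out_rows = []
    n_missing = 0
    for row in genes.itertuples(index=False):
        lo = int(row.tss) - window_bp  # 1-based inclusive
        hi = int(row.tss) + window_bp
        entry = by_chrom.get(str(row.chrom))
        mean_val = np.nan
        if entry is not None:
            starts, ends, scores = entry
            # overlap with [lo-1, hi) in 0-based half-open coords
            q_lo, q_hi = lo - 1, hi
            i0 = np.searchsorted(ends, q_lo, side="right")
            i1 = np.searchsorted(starts, q_hi, side="left")
            if i1 > i0:
                ov = np.minimum(ends[i0:i1], q_hi) - np.maximum(starts[i0:i1], q_lo)
                ov = np.clip(ov, 0, None)
                n_bases = ov.sum()
                if n_bases > 0:
                    mean_val = float((scores[i0:i1] * ov).sum() / n_bases)
        if np.isnan(mean_val):
            n_missing += 1
        out_rows.append((row.gene_id, "promoter_mean_score", mean_val))
    if n_missing:
        logger.warning("%d genes had no covered promoter bases", n_missing)
    return pd.DataFrame(out_rows, columns=["gene_id", "metric", "value"])


# ---------------------------------------------------------------------------
# Generic gene-set metric comparison
# ---------------------------------------------------------------------------


def compare_gene_sets(
    metric: pd.DataFrame,
    set_a: Iterable[str],
    set_b: Iterable[str],
    alternative: str = "two-sided",
    metric_name: Optional[str] = None,
) -> dict:
    """Wilcoxon comparison of a per-gene metric between two gene sets.

    ``metric`` is long-format (gene_id, metric, value). Returns the
    TestResult plus per-set sizes and Z-normalized means (Z over all genes
    carrying the metric).
    """
    df = metric
    if metric_name is not None:
        df = df[df["metric"] == metric_name]
    df = df.dropna(subset=["value"])
    set_a, set_b = set(set_a), set(set_b)
    a = df.loc[df["gene_id"].isin(set_a), "value"].to_numpy(dtype=float)
    b = df.loc[df["gene_id"].isin(set_b), "value"].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("metric undefined on one of the gene sets")
    z = zscores(df["value"].to_numpy(dtype=float))
    zs = pd.Series(z, index=df["gene_id"].to_numpy())
    result = wilcoxon_compare(a, b, alternative=alternative)
    return {
        "test": result,
        "n_a": int(a.size),
        "n_b": int(b.size),
        "mean_z_a": float(zs[zs.index.isin(set_a)].mean()),
        "mean_z_b": float(zs[zs.index.isin(set_b)].mean()),
    }
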