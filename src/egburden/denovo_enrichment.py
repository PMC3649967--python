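"""Matched-gene permutation test for de novo mutation enrichment.

Longer and more GC-rich genes attract more de novo events, so a naive
gene-set count is confounded by gene size. The test here exchanges each
event's gene for a random gene with similar total exon length (within
±100 bp) and GC content (within ±2.5 percentage points), with replacement,
and compares the observed number of events falling in the target gene set
against the permutation expectation:

    adjusted OR = [obs / (n − obs)] / [exp / (n − exp)]

with ``n`` the number of events and ``exp`` the permutation mean. The
permutation p-value uses the add-one convention. Per-study log adjusted ORs
are combined by inverse-variance weighted fixed-effects meta-analysis with
Cochran's Q as the heterogeneity check; the study SE is the spread of the
replicate log-odds (a documented design choice).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    DENOVO_CODING_TYPES,
    DENOVO_TYPE_PRECEDENCE,
    MetaResult,
    StudyResult,
)

logger = logging.getLogger(__name__)

DEFAULT_LEN_TOL_BP = 100.0
DEFAULT_GC_TOL_PCT = 2.5

_TYPE_RANK = {t: i for i, t in enumerate(DENOVO_TYPE_PRECEDENCE)}


# ---------------------------------------------------------------------------
# Event filtering
# ---------------------------------------------------------------------------


def _most_damaging(tokens: Iterable[str]) -> str:
    """Resolve multiple annotations: any coding type outranks synonymous."""
    toks = list(tokens)
    unknown = [t for t in toks if t not in _TYPE_RANK]
    if unknown:
        raise ValueError(f"unknown mutation-type token(s): {sorted(set(unknown))}")
    return min(toks, key=lambda t: _TYPE_RANK[t])


def filter_events(
    raw_events: pd.DataFrame,
    universe: pd.DataFrame,
    include_synonymous: bool = True,
) -> pd.DataFrame:
    """Filter and normalise raw de novo event lists.

    ``raw_events`` needs columns ``study, arm, gene_id, mutation_type``; an
    optional ``proband`` column groups multiple annotations of the same gene
    within one proband, which are collapsed to the single most damaging type
    (coding > synonymous). A ``mutation_type`` cell may itself carry several
    comma/semicolon-separated tokens, resolved the same way. Events in genes
    outside the universe are dropped (logged); synonymous events are dropped
    when ``include_synonymous`` is false. Unknown tokens raise.
    """
    ev = raw_events.copy()
    ev["mutation_type"] = [
        _most_damaging(str(cell).replace(";", ",").split(","))
        for cell in ev["mutation_type"]
    ]

    if "proband" in ev.columns:
        key = ["study", "arm", "proband", "gene_id"]
        ev = (
            ev.sort_values("mutation_type", key=lambda s: s.map(_TYPE_RANK), kind="stable")
            .drop_duplicates(subset=key, keep="first")
            .reset_index(drop=True)
        )

    in_universe = ev["gene_id"].isin(set(universe["gene_id"]))
    n_out = int((~in_universe).sum())
    if n_out:
        logger.info("%d events in genes outside the universe dropped", n_out)
    ev = ev[in_universe]

    if not include_synonymous:
        ev = ev[ev["mutation_type"].isin(DENOVO_CODING_TYPES)]

    return ev.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Matched pools
# ---------------------------------------------------------------------------


class MatchedUniverse:
    """Gene universe indexed for fast length/GC-matched pool queries."""

    def __init__(
        self,
        universe: pd.DataFrame,
        len_tol_bp: float = DEFAULT_LEN_TOL_BP,
        gc_tol_pct: float = DEFAULT_GC_TOL_PCT,
    ) -> None:
        self.gene_ids = universe["gene_id"].to_numpy()
        self.lengths = universe["exon_length_bp"].to_numpy(dtype=float)
        self.gc = universe["gc_pct"].to_numpy(dtype=float)
        self.len_tol = float(len_tol_bp)
        self.gc_tol = float(gc_tol_pct)
        self._order = np.argsort(self.lengths, kind="stable")
        self._sorted_len = self.lengths[self._order]
        self._row_of = {g: i for i, g in enumerate(self.gene_ids)}
        self._pool_cache: dict[str, np.ndarray] = {}

    def row(self, gene_id: str) -> int:
        try:
            return self._row_of[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in universe") from None

    def pool_rows(self, gene_id: str) -> np.ndarray:
        """Universe row indices of all genes matching the target's length & GC."""
        cached = self._pool_cache.get(gene_id)
        if cached is not None:
            return cached
        r = self.row(gene_id)
        length, gc = self.lengths[r], self.gc[r]
        i0 = np.searchsorted(self._sorted_len, length - self.len_tol, side="left")
        i1 = np.searchsorted(self._sorted_len, length + self.len_tol, side="right")
        cand = self._order[i0:i1]
        pool = cand[np.abs(self.gc[cand] - gc) <= self.gc_tol]
        self._pool_cache[gene_id] = pool
        return pool


def build_match_pool(
    target_gene_id: str,
    universe: pd.DataFrame,
    len_tol_bp: float = DEFAULT_LEN_TOL_BP,
    gc_tol_pct: float = DEFAULT_GC_TOL_PCT,
) -> list[str]:
    """All universe genes within ±len_tol bp and ±gc_tol %GC of the target.

    The target always matches itself, so the pool is never empty.
    """
    mu = MatchedUniverse(universe, len_tol_bp, gc_tol_pct)
    return [str(g) for g in mu.gene_ids[mu.pool_rows(target_gene_id)]]


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


def _set_rows(universe_ids: np.ndarray, gene_set: Iterable[str]) -> np.ndarray:
    s = set(gene_set)
    if not s:
        raise ValueError("gene set must be nonempty")
    return pd.Index(universe_ids).isin(s)


def _logit_counts(counts: np.ndarray, n: int) -> np.ndarray:
    """Replicate log-odds with 0.5 continuity correction at the boundaries."""
    c = np.clip(counts.astype(float), 0.5, n - 0.5)
    return np.log(c / (n - c))


def permutation_pvalue(counts: np.ndarray, obs: int) -> float:
    """Add-one one-sided (enrichment) permutation p-value.

    p = (1 + #{replicates with count >= obs}) / (1 + n_perm); never exactly 0,
    and monotone non-increasing in ``obs`` for fixed replicate counts.
    """
    counts = np.asarray(counts)
    return float((1 + (counts >= obs).sum()) / (1 + counts.size))


def exact_expectation(
    events: pd.DataFrame, matched: MatchedUniverse, set_mask: np.ndarray
) -> float:
    """Exact permutation expectation Σ_events |pool ∩ set| / |pool|."""
    total = 0.0
    for g in events["gene_id"]:
        pool = matched.pool_rows(g)
        total += float(set_mask[pool].mean())
    return total


def permute_study(
    events: pd.DataFrame,
    universe: pd.DataFrame,
    gene_set: Iterable[str],
    n_perm: int = 2000,
    seed: Union[int, np.random.Generator, None] = 0,
    len_tol_bp: float = DEFAULT_LEN_TOL_BP,
    gc_tol_pct: float = DEFAULT_GC_TOL_PCT,
    per_gene: bool = False,
    exact: bool = False,
    study_id: Optional[str] = None,
    arm: Optional[str] = None,
    matched: Optional[MatchedUniverse] = None,
) -> StudyResult:
    """Matched-permutation enrichment test for one study (one arm).

    Each replicate independently replaces each event's gene by a uniform draw
    (with replacement) from that gene's matched pool (``per_gene=True``
    instead draws once per distinct gene and carries the draw over all its
    events). ``exact=True`` additionally computes the exact expectation
    Σ|pool∩set|/|pool|. Genes whose only match is themselves remain in the
    analysis (self-swap).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if events.empty:
        raise ValueError("event list is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    matched = matched or MatchedUniverse(universe, len_tol_bp, gc_tol_pct)

    set_mask = _set_rows(matched.gene_ids, gene_set)
    n = len(events)
    event_rows = np.array([matched.row(g) for g in events["gene_id"]])
    obs = int(set_mask[event_rows].sum())

    genes_seq, mult = np.unique(events["gene_id"].to_numpy(), return_counts=True)
    pools = [matched.pool_rows(g) for g in genes_seq]
    pool_in_set = np.concatenate([set_mask[p] for p in pools])
    sizes = np.array([len(p) for p in pools], dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])

    counts = np.zeros(n_perm, dtype=np.int64)
    # draw uniform pool positions for every (gene, replicate) in blocks
    block = max(1, int(4_000_000 // max(len(genes_seq), 1)))
    for j0 in range(0, n_perm, block):
        j1 = min(j0 + block, n_perm)
        u = rng.random((len(genes_seq), j1 - j0))
        idx = starts[:, None] + (u * sizes[:, None]).astype(np.int64)
        in_set = pool_in_set[idx]
        if per_gene:
            counts[j0:j1] = (mult[:, None] * in_set).sum(axis=0)
        else:
            # per-event resampling: a gene hit m times needs m independent draws
            counts[j0:j1] = in_set.sum(axis=0)
    if not per_gene and (mult > 1).any():
        # extra independent draws for repeated genes (draw 2..m per gene)
        rep_idx = np.repeat(np.arange(len(genes_seq)), mult - 1)
        for j0 in range(0, n_perm, block):
            j1 = min(j0 + block, n_perm)
            if len(rep_idx):
                u = rng.random((len(rep_idx), j1 - j0))
                idx = starts[rep_idx, None] + (u * sizes[rep_idx, None]).astype(np.int64)
                counts[j0:j1] += pool_in_set[idx].sum(axis=0)

    exp = float(counts.mean())
    # obs = exp = n (every pool inside the set) is handled by the continuity
    # clipping below and yields the identity result OR = 1
    obs_c = min(max(float(obs), 0.5), n - 0.5)
    exp_c = min(max(exp, 0.5), n - 0.5)
    log_adj_or = float(
        np.log(obs_c / (n - obs_c)) - np.log(exp_c / (n - exp_c))
    )

    rep_logodds = _logit_counts(counts, n)
    se = float(rep_logodds.std(ddof=1)) if n_perm > 1 else float("nan")
    if se == 0.0:
        se = float("nan")  # identity permutation: no spread, SE undefined

    p_one = permutation_pvalue(counts, obs)
    p_two = float(min(1.0, 2.0 * p_one))

    mean_rep_or = float(
        np.exp(np.log(obs_c / (n - obs_c)) - rep_logodds).mean()
    )

    return StudyResult(
        study_id=study_id or str(events["study"].iloc[0]) if "study" in events else (study_id or ""),
        arm=arm or (str(events["arm"].iloc[0]) if "arm" in events else ""),
        n_events=n,
        obs_in_set=obs,
        exp_in_set=exp,
        log_adj_or=log_adj_or,
        se_log_or=se,
        perm_p=p_one,
        perm_p_two=p_two,
        n_perm=n_perm,
        exact_exp_in_set=(
            exact_expectation(events, matched, set_mask) if exact else None
        ),
        mean_replicate_or=mean_rep_or,
    )


# ---------------------------------------------------------------------------
# Fixed-effects meta-analysis
# ---------------------------------------------------------------------------


def meta_fixed_effects(
    results: Sequence[Union[StudyResult, tuple[float, float]]]
) -> MetaResult:
    """Inverse-variance weighted fixed-effects combination of log-ORs.

    Accepts StudyResults or raw ``(log_or, se)`` tuples; studies with a
    non-finite SE are skipped. Q is Cochran's heterogeneity statistic on
    k − 1 degrees of freedom (a single study yields Q = 0, q_p = 1).
    """
    thetas, ses = [], []
    for r in results:
        if isinstance(r, StudyResult):
            th, se = r.log_adj_or, r.se_log_or
        else:
            th, se = r
        if np.isfinite(se) and se > 0:
            thetas.append(float(th))
            ses.append(float(se))
    if not thetas:
        raise ValueError("need >= 1 study with finite SE")

    theta = np.array(thetas)
    w = 1.0 / np.array(ses) ** 2
    combined = float((w * theta).sum() / w.sum())
    se_c = float(1.0 / np.sqrt(w.sum()))
    ci = (float(np.exp(combined - 1.96 * se_c)), float(np.exp(combined + 1.96 * se_c)))
    z = combined / se_c
    meta_p = float(2.0 * stats.norm.sf(abs(z)))
    q = float((w * (theta - combined) ** 2).sum())
    df = len(theta) - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return MetaResult(
        combined_or=float(np.exp(combined)),
        ci95=ci,
        meta_p=meta_p,
        cochran_q=q,
        q_df=df,
        q_p=q_p,
        log_combined=combined,
        se_combined=se_c,
        n_studies=len(theta),
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def study_results_frame(results: Sequence[StudyResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        lo, hi = r.ci95
        rows.append(
            {
                "study": r.study_id,
                "arm": r.arm,
                "n_events": r.n_events,
                "obs_in_set": r.obs_in_set,
                "exp_in_set": r.exp_in_set,
                "adjusted_or": r.adjusted_or,
                "ci_low": lo,
                "ci_high": hi,
                "perm_p_one_sided": r.perm_p,
                "perm_p_two_sided": r.perm_p_two,
                "n_perm": r.n_perm,
                "exact_exp_in_set": r.exact_exp_in_set,
            }
        )
    return pd.DataFrame(rows)


def run_denovo_analysis(
    events: pd.DataFrame,
    universe: pd.DataFrame,
    gene_set: Union[str, Iterable[str]],
    include_synonymous: bool = True,
    n_perm: int = 2000,
    seed: int = 0,
    len_tol_bp: float = DEFAULT_LEN_TOL_BP,
    gc_tol_pct: float = DEFAULT_GC_TOL_PCT,
    per_gene: bool = False,
    exact: bool = True,
) -> dict:
    """Filter → permute per study per arm → meta-analyse, per arm.

    ``gene_set`` is a class name (looked up in the universe's ``ess_class``)
    or an explicit iterable of gene IDs. Returns
    ``{arm: {"studies": [StudyResult...], "table": DataFrame, "meta": MetaResult}}``.
    """
    if isinstance(gene_set, str):
        set_ids = universe.loc[universe["ess_class"] == gene_set, "gene_id"]
        set_ids = list(set_ids)
        if not set_ids:
            raise ValueError(f"gene class {gene_set!r} is empty in this universe")
    else:
        set_ids = list(gene_set)

    ev = filter_events(events, universe, include_synonymous=include_synonymous)
    if ev.empty:
        raise ValueError("no events left after filtering")

    matched = MatchedUniverse(universe, len_tol_bp, gc_tol_pct)
    ss = np.random.SeedSequence(seed)

    out: dict = {}
    for arm in sorted(ev["arm"].unique()):
        arm_ev = ev[ev["arm"] == arm]
        results = []
        for study in sorted(arm_ev["study"].unique()):
            sev = arm_ev[arm_ev["study"] == study]
            child = np.random.default_rng(ss.spawn(1)[0])
            results.append(
                permute_study(
                    sev, universe, set_ids, n_perm=n_perm, seed=child,
                    len_tol_bp=len_tol_bp, gc_tol_pct=gc_tol_pct,
                    per_gene=per_gene, exact=exact,
                    study_id=str(study), arm=str(arm), matched=matched,
                )
            )
        out[arm] = {
            "studies": results,
            "table": study_results_frame(results),
            "meta": meta_fixed_effects(results),
        }
    return out


def read_denovo_events(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
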