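"""Statistical tests used across the pipeline.

Contents: a moderated two-sample t for differential expression between
cohort subtypes, Benjamini-Hochberg FDR adjustment, Fisher's exact test on
2x2 tables (probability-mass two-sided rule), a pooled two-proportion
chi-square test, hypergeometric overlap significance, the Cochran-Armitage
trend test for 2xK tables (asymptotic with optional exact conditional
permutation p), per-chromosome differential-expression summaries, and
generic Fisher enrichment over a gene-set collection.

All tests are two-sided. P-values are returned unclipped; use
:func:`format_pvalue` for the conventional "< 2.2e-16" display floor.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import GeneAnnotation, GeneSetCollection, OmicsMatrix, ValidationError

logger = logging.getLogger(__name__)

PVALUE_FLOOR = 2.2e-16


def format_pvalue(p: float) -> str:
    """Report a p-value, flooring the display at '< 2.2e-16'."""
    if p < PVALUE_FLOOR:
        return "< 2.2e-16"
    return f"{p:.3g}"


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class DeResult:
    """Per-gene differential expression between two sample groups.

    ``table`` is indexed by gene with columns ``mean_a``, ``mean_b``,
    ``t``, ``pvalue``, ``p_adj``, ``direction`` ("up_in_a"/"down_in_a") and
    ``significant`` (adjusted p < alpha). ``group_a``/``group_b`` name the
    groups; ``alpha`` records the threshold used.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    alpha: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _resolve_groups(groups, sample_ids) -> pd.Series:
    # accepts a PloidyCallSet, a mapping, or a Series of labels per sample
    if hasattr(groups, "labels"):
        labels = groups.labels
    elif isinstance(groups, pd.Series):
        labels = groups
    else:
        labels = pd.Series(dict(groups))
    missing = [s for s in sample_ids if s not in labels.index]
    if missing:
        raise ValidationError(f"no group label for sample(s) {missing[:3]}")
    return labels.loc[list(sample_ids)]


def differential_expression(
    expr: OmicsMatrix,
    groups,
    alpha: float = 0.05,
    shrinkage: float = 0.5,
) -> DeResult:
    """Moderated two-sample t test per gene with BH correction.

    The per-gene pooled variance is shrunk toward the across-gene median
    pooled variance with weight ``shrinkage`` (default 0.5), and the residual
    degrees of freedom are inflated by the implied prior degrees of freedom
    (d0 = df * w / (1 - w)), the usual empirical-Bayes accounting for the
    information borrowed across genes. With shrinkage 0 this reduces to the
    ordinary pooled-variance t test.

    ``groups`` may be a ploidy call set, a mapping, or a Series of two labels
    over the matrix's samples; both groups need >= 2 samples.
    """
    if not 0 <= shrinkage < 1:
        raise ValidationError("shrinkage weight must be in [0, 1)")
    labels = _resolve_groups(groups, expr.sample_ids)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValidationError(f"need exactly 2 groups, got {uniq}")
    group_a, group_b = uniq
    x = expr.data.to_numpy(dtype=float)
    mask_a = (labels == group_a).to_numpy()
    mask_b = ~mask_a
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < 2 or n_b < 2:
        raise ValidationError(
            f"each group needs >= 2 samples (got {group_a}: {n_a}, {group_b}: {n_b})"
        )
    xa, xb = x[:, mask_a], x[:, mask_b]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    df = n_a + n_b - 2
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    s2_prior = float(np.median(s2))
    s2_mod = (1 - shrinkage) * s2 + shrinkage * s2_prior
    d0 = df * shrinkage / (1 - shrinkage) if shrinkage > 0 else 0.0
    df_mod = df + d0
    denom = np.sqrt(s2_mod * (1 / n_a + 1 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (mean_a - mean_b) / denom, 0.0)
    p = 2 * scipy.stats.t.sf(np.abs(t), df_mod)
    p_adj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "t": t,
            "pvalue": p,
            "p_adj": p_adj,
            "direction": np.where(mean_a >= mean_b, "up_in_a", "down_in_a"),
            "significant": p_adj < alpha,
        },
        index=expr.data.index,
    )
    return DeResult(table=table, group_a=group_a, group_b=group_b, alpha=alpha)


# ---------------------------------------------------------------------------
# exact tests on counts
# ---------------------------------------------------------------------------

class FisherResult(NamedTuple):
    odds_ratio: float
    pvalue: float


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's
    (probability-mass criterion). The odds ratio is the sample (a*d)/(b*c),
    with a Haldane 0.5 correction applied to every cell when any cell is 0.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValidationError("Fisher table cells must be non-negative integers")
    if sum(cells) == 0:
        raise ValidationError("Fisher table is all-zero")
    a, b, c, d = (int(x) for x in cells)
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return FisherResult(odds_ratio=float(odds), pvalue=float(p))


class TwoProportionResult(NamedTuple):
    z: float
    pvalue: float


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> TwoProportionResult:
    """Chi-square homogeneity test of two proportions (no continuity correction).

    Equivalent to the pooled two-sample z test; p from the 1-df chi-square
    (i.e. two-sided normal) tail.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValidationError("need 0 <= x <= n with n > 0 for both proportions")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate margins in two-proportion test; p = 1", stacklevel=2)
        return TwoProportionResult(z=0.0, pvalue=1.0)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return TwoProportionResult(z=float(z), pvalue=float(2 * scipy.stats.norm.sf(abs(z))))


def hypergeometric_overlap(
    query_size: int, set_size: int, overlap: int, universe: int
) -> FisherResult:
    """Significance of the overlap between two gene lists drawn from a universe.

    Builds the 2x2 table (overlap, query-overlap, set-overlap, rest) and
    delegates to :func:`fisher_exact_2x2`.
    """
    if overlap > min(query_size, set_size) or overlap < 0:
        raise ValidationError("overlap must satisfy 0 <= overlap <= min(query, set)")
    rest = universe - query_size - set_size + overlap
    if rest < 0:
        raise ValidationError("universe smaller than the union of the two lists")
    return fisher_exact_2x2(overlap, query_size - overlap, set_size - overlap, rest)


# ---------------------------------------------------------------------------
# trend test
# ---------------------------------------------------------------------------

class TrendResult(NamedTuple):
    z: float
    pvalue: float
    method: str


EXACT_TREND_MAX_TOTAL = 30


def cochran_armitage_trend(
    table,
    scores: Sequence[float] | None = None,
    continuity: bool = True,
    method: str = "auto",
) -> TrendResult:
    """Cochran-Armitage test for trend in proportions across ordered columns.

    ``table`` is a 2xK array of counts (K >= 3); ``scores`` default to
    1..K. The statistic is T = sum_j s_j * x_1j with mean and variance
    conditional on all margins; z = (T - E[T]) / sd.

    ``method="exact"`` enumerates all 2xK tables with the observed margins
    and returns P(|T - E[T]| >= |t_obs - E[T]|) under the multivariate
    hypergeometric — the exact conditional permutation tail, practical for
    total counts up to a few dozen. ``method="asymptotic"`` uses the normal
    tail of z; a half-unit continuity correction (default) keeps it close to
    the exact tail at moderate counts (``continuity=False`` for the plain z).
    The default ``"auto"`` picks the exact test when the total count is
    <= 30, where the normal approximation degrades, and the asymptotic test
    otherwise.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 3:
        raise ValidationError("trend table must be 2 x K with K >= 3")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("trend table must hold non-negative integer counts")
    k = t.shape[1]
    s = np.arange(1, k + 1, dtype=float) if scores is None else np.asarray(scores, float)
    if s.shape != (k,):
        raise ValidationError("scores length must match the number of columns")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    if (row == 0).any():
        raise ValidationError("trend test undefined with a zero row margin")
    t_obs = float((s * t[0]).sum())
    e_t = row[0] / n * float((s * col).sum())
    var = (
        row[0]
        * row[1]
        / (n * n * (n - 1))
        * (n * float((s * s * col).sum()) - float((s * col).sum()) ** 2)
    )
    if var <= 0:
        return TrendResult(z=0.0, pvalue=1.0, method="degenerate")

    if method == "auto":
        method = "exact" if n <= EXACT_TREND_MAX_TOTAL else "asymptotic"
    if method == "exact":
        p = _trend_exact_p(t.astype(int), s, t_obs, e_t)
        z = (t_obs - e_t) / math.sqrt(var)
        return TrendResult(z=float(z), pvalue=float(p), method="exact")
    if method != "asymptotic":
        raise ValidationError(f"unknown method {method!r}")
    z = (t_obs - e_t) / math.sqrt(var)
    dev = abs(t_obs - e_t)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    p = 2 * scipy.stats.norm.sf(dev / math.sqrt(var))
    return TrendResult(z=float(z), pvalue=float(min(p, 1.0)), method="asymptotic")


def _trend_exact_p(t: np.ndarray, scores: np.ndarray, t_obs: float, e_t: float) -> float:
    """Exact conditional tail P(|T - E| >= |t_obs - E|) with fixed margins."""
    col = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(t.sum())
    logfact = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, n + 1)))))

    def log_choose(m, x):
        return logfact[m] - logfact[x] - logfact[m - x]

    log_denom = log_choose(n, r1)
    threshold = abs(t_obs - e_t) - 1e-9
    total = 0.0
    tail = 0.0
    k = len(col)

    def recurse(j, remaining, logp, t_acc):
        nonlocal total, tail
        if j == k - 1:
            x = remaining
            if 0 <= x <= col[j]:
                lp = logp + log_choose(int(col[j]), x)
                pr = math.exp(lp - log_denom)
                total += pr
                if abs(t_acc + scores[j] * x - e_t) >= threshold:
                    tail += pr
            return
        max_rest = int(col[j + 1 :].sum())
        lo = max(0, remaining - max_rest)
        hi = min(int(col[j]), remaining)
        for x in range(lo, hi + 1):
            recurse(
                j + 1,
                remaining - x,
                logp + log_choose(int(col[j]), x),
                t_acc + scores[j] * x,
            )

    recurse(0, r1, 0.0, 0.0)
    return min(tail / total, 1.0)


# ---------------------------------------------------------------------------
# genome-level summaries
# ---------------------------------------------------------------------------

def expressed_gene_flag(expr: OmicsMatrix) -> pd.Series:
    """Flag the expressed half of the transcriptome: genes whose median
    expression is >= the across-gene median of per-gene medians (ties included)."""
    if expr.n_genes < 2:
        raise ValidationError("need >= 2 genes to split by median expression")
    medians = expr.data.median(axis=1)
    return medians >= medians.median()


@dataclass
class ChromosomeDeSummary:
    """Differentially expressed gene counts per chromosome plus trisomy enrichment."""

    counts: pd.DataFrame  # index chromosome; columns n_genes, n_up, n_down
    up_enrichment: FisherResult | None
    down_enrichment: FisherResult | None


def de_by_chromosome(
    de: DeResult,
    annotation: GeneAnnotation,
    trisomy_chromosomes: Iterable[str] = ("3", "5", "7", "9", "11", "15", "19", "21"),
) -> ChromosomeDeSummary:
    """Count up-/down-regulated genes per chromosome and test whether
    up-regulated (resp. down-regulated) genes are enriched on the trisomy
    chromosomes with Fisher's exact test."""
    trisomy = {str(c) for c in trisomy_chromosomes}
    genes = [g for g in de.table.index if g in set(annotation.gene_symbols)]
    sub = de.table.loc[genes]
    chrom = annotation.table.loc[genes, "chromosome"]
    up = sub["significant"] & (sub["direction"] == "up_in_a")
    down = sub["significant"] & (sub["direction"] == "down_in_a")
    counts = (
        pd.DataFrame({"chromosome": chrom, "up": up, "down": down})
        .groupby("chromosome")
        .agg(n_genes=("up", "size"), n_up=("up", "sum"), n_down=("down", "sum"))
    )
    on_tri = chrom.isin(trisomy)

    def _enrich(flag):
        if flag.sum() == 0:
            logger.info("de_by_chromosome: no significant genes; enrichment skipped")
            return None
        return fisher_exact_2x2(
            int((flag & on_tri).sum()),
            int((flag & ~on_tri).sum()),
            int((~flag & on_tri).sum()),
            int((~flag & ~on_tri).sum()),
        )

    return ChromosomeDeSummary(
        counts=counts, up_enrichment=_enrich(up), down_enrichment=_enrich(down)
    )


def gene_set_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Fisher enrichment of a query gene list against each set in a collection.

    Sets are intersected with the universe before testing; BH adjustment is
    applied across sets. Returns a DataFrame indexed by set name with columns
    overlap, set_size, query_size, universe_size, odds_ratio, pvalue, p_adj.
    """
    universe = set(universe)
    query = set(query) & universe
    if not query:
        raise ValidationError("query is empty after intersecting with the universe")
    rows = []
    for name in collection.names():
        members = set(collection[name]) & universe
        if not members:
            continue
        overlap = len(query & members)
        res = hypergeometric_overlap(len(query), len(members), overlap, len(universe))
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": len(members),
                "query_size": len(query),
                "universe_size": len(universe),
                "odds_ratio": res.odds_ratio,
                "pvalue": res.pvalue,
            }
        )
    if not rows:
        raise ValidationError("no gene set overlaps the universe")
    out = pd.DataFrame(rows).set_index("set")
    out["p_adj"] = bh_adjust(out["pvalue"])
    return out.sort_values("pvalue")
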