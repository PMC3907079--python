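"""Gene-wise dosage effect scoring.

The dosage effect score (DES) of a gene measures how often a copy-number
alteration (CNA) at the gene is accompanied by a concordant change of its own
expression across a tumor cohort. Per gene:

1. Samples are split by copy number into loss (CN < 1.7), neutral
   (1.7 <= CN <= 2.3) and gain (CN > 2.3); the neutral band absorbs signal
   noise and normal-cell contamination.
2. The copy-neutral samples define the gene's reference expression:
   normal_mean and normal_sd (sample sd, n-1 denominator).
3. A CNA sample is concordant when its expression moves beyond the reference
   band in the direction of its CNA: above normal_mean + k*normal_sd for a
   gain, below normal_mean - k*normal_sd for a loss (strict inequalities,
   k = 1 by default).
4. DES = concordant count / CNA count, in [0, 1]. The score is left
   undefined unless CNAs occur in more than 10% of samples, at least 5
   copy-neutral samples exist, and the reference sd is positive.

Genes are categorized as low (DES < 0.2), medium (0.2 <= DES <= 0.4) or high
(DES > 0.4, "dosage sensitive"). Dosage-resistant genes are the highly
expressed genes (top 20% by median expression) whose DES stays below 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import GeneAnnotation, ValidationError
from .preprocess import PairedDataset
from .stats import TrendResult, cochran_armitage_trend

logger = logging.getLogger(__name__)

LOSS, NEUTRAL, GAIN, MISSING = "loss", "neutral", "gain", "missing"
CAT_LOW, CAT_MEDIUM, CAT_HIGH, CAT_UNDEFINED = "low", "medium", "high", "undefined"


@dataclass
class DesParams:
    """Thresholds governing the dosage effect score.

    loss_threshold, gain_threshold : CNA calls on the linear CN scale
        (loss strictly below 1.7, gain strictly above 2.3; the closed
        interval between them is copy-neutral).
    sd_multiplier : k in the normal_mean +/- k*normal_sd concordance band.
    min_cna_fraction : DES is defined only when the CNA count strictly
        exceeds this fraction of all samples (default 10%).
    min_neutral_samples : minimum copy-neutral samples for a usable
        reference (default 5).
    low_max, high_min : category boundaries (low < 0.2 <= medium <= 0.4 < high).
    resistant_expr_quantile : expression-median quantile defining "highly
        expressed" (default 0.80, i.e. the top quintile).
    resistant_des_max : DES ceiling for dosage-resistant genes (default 0.2).
    """

    loss_threshold: float = 1.7
    gain_threshold: float = 2.3
    sd_multiplier: float = 1.0
    min_cna_fraction: float = 0.10
    min_neutral_samples: int = 5
    low_max: float = 0.2
    high_min: float = 0.4
    resistant_expr_quantile: float = 0.80
    resistant_des_max: float = 0.2

    def __post_init__(self):
        if not 0 < self.loss_threshold < self.gain_threshold:
            raise ValidationError("need 0 < loss_threshold < gain_threshold")
        if not 0 <= self.min_cna_fraction <= 1:
            raise ValidationError("min_cna_fraction must be in [0, 1]")
        if self.low_max > self.high_min:
            raise ValidationError("low_max must be <= high_min")
        if self.sd_multiplier <= 0:
            raise ValidationError("sd_multiplier must be > 0")


@dataclass
class DesTable:
    """Per-gene DES records plus the parameters that produced them.

    ``table`` is indexed by gene with columns n_samples, gain_count,
    loss_count, cna_count, neutral_count, neutral_mean, neutral_sd,
    concordant_count, des (NaN when undefined), category and
    undefined_reason.
    """

    table: pd.DataFrame
    params: DesParams

    def defined(self) -> pd.DataFrame:
        return self.table[self.table["des"].notna()]

    @property
    def des(self) -> pd.Series:
        return self.table["des"]

    def category_fractions(self, among_defined: bool = True) -> pd.Series:
        """Share of genes per category, over defined-DES genes (default) or all."""
        denom = len(self.defined()) if among_defined else len(self.table)
        counts = self.defined()["category"].value_counts()
        return (counts / denom).reindex([CAT_LOW, CAT_MEDIUM, CAT_HIGH]).fillna(0.0)


def cna_status(cn_value, params: DesParams | None = None):
    """Classify a linear copy number as loss / neutral / gain / missing.

    Boundaries are neutral-inclusive: CN equal to either threshold is
    neutral. Accepts scalars or arrays (arrays return an object array)."""
    params = params or DesParams()
    arr = np.asarray(cn_value, dtype=float)
    out = np.full(arr.shape, NEUTRAL, dtype=object)
    out[np.isnan(arr)] = MISSING
    out[arr < params.loss_threshold] = LOSS
    out[arr > params.gain_threshold] = GAIN
    out[np.isnan(arr)] = MISSING
    if out.shape == ():
        return out.item()
    return out


def categorize_des(des: float, params: DesParams | None = None) -> str:
    """Map a DES value to low / medium / high (NaN -> undefined)."""
    params = params or DesParams()
    if des is None or (isinstance(des, float) and np.isnan(des)):
        return CAT_UNDEFINED
    if des < params.low_max:
        return CAT_LOW
    if des <= params.high_min:
        return CAT_MEDIUM
    return CAT_HIGH


class DosageEffectScorer(BaseEstimator):
    """Compute per-gene dosage effect scores from an aligned paired cohort.

    scikit-learn estimator conventions: constructor stores parameters only,
    ``fit`` computes, fitted attributes carry a trailing underscore.

    Parameters mirror :class:`DesParams`.

    Attributes
    ----------
    des_table_ : DesTable with one record per gene.
    n_samples_ : cohort size used for the frequency guard.
    """

    def __init__(
        self,
        loss_threshold: float = 1.7,
        gain_threshold: float = 2.3,
        sd_multiplier: float = 1.0,
        min_cna_fraction: float = 0.10,
        min_neutral_samples: int = 5,
        low_max: float = 0.2,
        high_min: float = 0.4,
        resistant_expr_quantile: float = 0.80,
        resistant_des_max: float = 0.2,
    ):
        self.loss_threshold = loss_threshold
        self.gain_threshold = gain_threshold
        self.sd_multiplier = sd_multiplier
        self.min_cna_fraction = min_cna_fraction
        self.min_neutral_samples = min_neutral_samples
        self.low_max = low_max
        self.high_min = high_min
        self.resistant_expr_quantile = resistant_expr_quantile
        self.resistant_des_max = resistant_des_max

    def _des_params(self) -> DesParams:
        return DesParams(**{k: getattr(self, k) for k in DesParams.__dataclass_fields__})

    def fit(self, dataset: PairedDataset, y=None) -> "DosageEffectScorer":
        params = self._des_params()
        cn = dataset.copy_number.data.to_numpy(dtype=float)
        ex = dataset.expression.data.to_numpy(dtype=float)
        n = cn.shape[1]
        with np.errstate(invalid="ignore"):
            gain = cn > params.gain_threshold
            loss = cn < params.loss_threshold
            neutral = (cn >= params.loss_threshold) & (cn <= params.gain_threshold)

        neutral_count = neutral.sum(axis=1)
        gain_count = gain.sum(axis=1)
        loss_count = loss.sum(axis=1)
        cna_count = gain_count + loss_count

        # reference expression from copy-neutral samples (sample sd, n-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            nm = np.where(neutral_count > 0, (ex * neutral).sum(axis=1) / neutral_count, np.nan)
            resid2 = ((ex - nm[:, None]) ** 2) * neutral
            nsd = np.where(
                neutral_count > 1,
                np.sqrt(resid2.sum(axis=1) / np.maximum(neutral_count - 1, 1)),
                np.nan,
            )
            upper = nm + params.sd_multiplier * nsd
            lower = nm - params.sd_multiplier * nsd
            concordant = (
                (gain & (ex > upper[:, None])) | (loss & (ex < lower[:, None]))
            ).sum(axis=1)

        freq_ok = cna_count > params.min_cna_fraction * n
        neutral_ok = neutral_count >= params.min_neutral_samples
        sd_ok = np.nan_to_num(nsd, nan=0.0) > 0
        defined = freq_ok & neutral_ok & sd_ok
        with np.errstate(invalid="ignore", divide="ignore"):
            des = np.where(defined, concordant / np.maximum(cna_count, 1), np.nan)

        reasons = np.full(len(des), "", dtype=object)
        reasons[~freq_ok] = "low_cna_fraction"
        reasons[freq_ok & ~neutral_ok] = "few_neutral_samples"
        reasons[freq_ok & neutral_ok & ~sd_ok] = "zero_neutral_sd"

        categories = np.array([categorize_des(v, params) for v in des], dtype=object)
        table = pd.DataFrame(
            {
                "n_samples": n,
                "gain_count": gain_count,
                "loss_count": loss_count,
                "cna_count": cna_count,
                "neutral_count": neutral_count,
                "neutral_mean": nm,
                "neutral_sd": nsd,
                "concordant_count": concordant,
                "des": des,
                "category": categories,
                "undefined_reason": reasons,
            },
            index=dataset.expression.data.index,
        )
        self.des_table_ = DesTable(table=table, params=params)
        self.n_samples_ = n
        logger.info(
            "DES: %d/%d genes defined; category split %s",
            int(defined.sum()),
            len(des),
            self.des_table_.category_fractions().round(3).to_dict(),
        )
        return self

    def fit_transform(self, dataset: PairedDataset, y=None) -> pd.DataFrame:
        return self.fit(dataset).des_table_.table


def compute_des(dataset: PairedDataset, params: DesParams | None = None) -> DesTable:
    """Functional wrapper over :class:`DosageEffectScorer`."""
    params = params or DesParams()
    return DosageEffectScorer(**asdict(params)).fit(dataset).des_table_


def identify_dosage_resistant(
    dataset: PairedDataset, des: DesTable, params: DesParams | None = None
) -> list[str]:
    """Highly expressed genes whose expression ignores their copy number.

    Genes whose median expression is at or above the
    ``resistant_expr_quantile`` quantile of all genes' medians, and whose DES
    is defined and below ``resistant_des_max``."""
    params = params or des.params
    medians = dataset.expression.data.median(axis=1)
    threshold = medians.quantile(params.resistant_expr_quantile)
    top = medians >= threshold
    d = des.table["des"]
    resistant = top & d.notna() & (d < params.resistant_des_max)
    return sorted(des.table.index[resistant])


def expression_group_trend(
    dataset: PairedDataset,
    des: DesTable,
    n_groups: int = 5,
) -> tuple[pd.DataFrame, TrendResult]:
    """Does high dosage sensitivity concentrate in highly expressed genes?

    Genes with defined DES are ranked by median expression (ties broken by
    gene symbol), split into ``n_groups`` groups as equal as possible
    (remainders go to the lower-expression groups), and the per-group counts
    of high-DES vs other genes are tested for a monotone trend with the
    Cochran-Armitage test (group indices as scores). A table in which every
    gene, or no gene, is high-DES carries no gradient and returns p = 1.
    """
    defined = des.defined()
    if len(defined) < n_groups:
        raise ValidationError(f"need >= {n_groups} genes with defined DES")
    medians = dataset.expression.data.loc[defined.index].median(axis=1)
    # stable sort after ordering by symbol => ties broken lexicographically
    genes = list(medians.sort_index().sort_values(kind="mergesort").index)
    m, r = divmod(len(genes), n_groups)
    sizes = [m + 1 if g < r else m for g in range(n_groups)]
    counts = np.zeros((2, n_groups), dtype=int)
    start = 0
    rows = []
    for g, size in enumerate(sizes, start=1):
        members = genes[start : start + size]
        start += size
        high = int((defined.loc[members, "category"] == CAT_HIGH).sum())
        counts[0, g - 1] = high
        counts[1, g - 1] = size - high
        rows.append({"group": g, "n_genes": size, "n_high": high, "n_other": size - high})
    table = pd.DataFrame(rows).set_index("group")
    if counts[0].sum() == 0 or counts[1].sum() == 0:
        trend = TrendResult(z=0.0, pvalue=1.0, method="degenerate")
    else:
        trend = cochran_armitage_trend(counts)
    return table, trend


def chromosome_summary(
    des: DesTable,
    annotation: GeneAnnotation,
    dataset: PairedDataset,
) -> pd.DataFrame:
    """Per-chromosome dosage sensitivity and CNA burden.

    For each chromosome: gene counts, the proportion of defined-DES genes in
    each category (NaN when no gene has a defined DES, which is logged), and
    the mean over genes of each gene's CNA sample fraction."""
    t = des.table
    chrom = annotation.table.loc[t.index, "chromosome"]
    cna_fraction = t["cna_count"] / t["n_samples"]
    rows = []
    for c, idx in t.groupby(chrom).groups.items():
        sub = t.loc[idx]
        d = sub[sub["des"].notna()]
        rec = {
            "chromosome": c,
            "n_genes": len(sub),
            "n_defined": len(d),
            "mean_cna_fraction": float(cna_fraction.loc[idx].mean()),
        }
        for cat in (CAT_LOW, CAT_MEDIUM, CAT_HIGH):
            rec[f"prop_{cat}"] = (
                float((d["category"] == cat).mean()) if len(d) else np.nan
            )
        if not len(d):
            logger.info("chromosome %s has no defined-DES genes", c)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("chromosome")
    # natural chromosome order where labels are numeric
    key = {c: (0, int(c)) if str(c).isdigit() else (1, str(c)) for c in out.index}
    return out.loc[sorted(out.index, key=key.get)]
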