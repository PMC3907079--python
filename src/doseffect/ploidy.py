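"""Hyperdiploidy subtyping from gene-level copy numbers.

Hyperdiploid myeloma (HMM) carries trisomies of chromosomes 3, 5, 7, 9, 11,
15, 19 and 21. Because tumor purity and array normalization attenuate the
signal, a trisomy appears as a copy number near 2.6 rather than 3, so the
per-sample median copy number over trisomy-chromosome genes is bimodal with
peaks near 2 (non-hyperdiploid, NHMM) and 2.6 (HMM). Samples are called HMM
when that median exceeds a cutoff — by default 2.3, the midpoint between the
peaks — or a cutoff re-estimated from the cohort's own bimodal density.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator

from .io import GeneAnnotation, OmicsMatrix, ValidationError
from .preprocess import PairedDataset

logger = logging.getLogger(__name__)

HMM = "HMM"
NHMM = "NHMM"
DEFAULT_TRISOMY_CHROMOSOMES = frozenset({"3", "5", "7", "9", "11", "15", "19", "21"})
DEFAULT_CUTOFF = 2.3


@dataclass
class PloidyParams:
    """Settings for the hyperdiploidy call.

    trisomy_chromosomes : chromosome labels whose median CN defines the call.
    cutoff : median trisomy CN above which (strictly) a sample is HMM.
    auto_cutoff : re-estimate the cutoff from the cohort's bimodal density
        (requires >= 20 samples; falls back to the default on unimodal input).
    """

    trisomy_chromosomes: frozenset = field(default_factory=lambda: DEFAULT_TRISOMY_CHROMOSOMES)
    cutoff: float = DEFAULT_CUTOFF
    auto_cutoff: bool = False

    def __post_init__(self):
        self.trisomy_chromosomes = frozenset(str(c) for c in self.trisomy_chromosomes)
        if not self.trisomy_chromosomes:
            raise ValidationError("trisomy chromosome set must be non-empty")
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be > 0")


@dataclass
class PloidyCallSet:
    """Per-sample hyperdiploidy calls.

    ``calls`` is indexed by sample with columns ``median_trisomy_cn`` and
    ``label`` (HMM/NHMM); ``cutoff_used`` records the decision threshold.
    """

    calls: pd.DataFrame
    cutoff_used: float

    def __post_init__(self):
        expected = self.calls["median_trisomy_cn"] > self.cutoff_used
        actual = self.calls["label"] == HMM
        if not (expected == actual).all():
            raise ValidationError("labels inconsistent with median CN and cutoff")

    @property
    def labels(self) -> pd.Series:
        return self.calls["label"]

    def counts(self) -> dict:
        return self.calls["label"].value_counts().to_dict()


def _trisomy_medians(
    copy_number: OmicsMatrix,
    annotation: GeneAnnotation,
    trisomy_chromosomes,
) -> pd.Series:
    chroms = annotation.table["chromosome"]
    genes = [
        g
        for g in copy_number.gene_ids
        if g in chroms.index and chroms[g] in trisomy_chromosomes
    ]
    if not genes:
        raise ValidationError("no genes located on the trisomy chromosomes")
    sub = copy_number.data.loc[genes]
    n_usable = sub.notna().sum(axis=0)
    empty = list(n_usable.index[n_usable == 0])
    if empty:
        raise ValidationError(
            f"sample(s) with no usable trisomy-chromosome copy numbers: {empty[:5]}"
        )
    return sub.median(axis=0, skipna=True).rename("median_trisomy_cn")


def median_trisomy_cn(
    dataset: PairedDataset, params: PloidyParams | None = None
) -> pd.Series:
    """Per-sample median of gene-level CN over trisomy-chromosome genes
    (missing values skipped; even counts give the midpoint)."""
    params = params or PloidyParams()
    return _trisomy_medians(dataset.copy_number, dataset.annotation, params.trisomy_chromosomes)


def estimate_cutoff(
    medians,
    min_samples: int = 20,
    min_peak_separation: float = 0.2,
    fallback: float = DEFAULT_CUTOFF,
) -> float:
    """Data-driven HMM/NHMM cutoff: midpoint of the two highest modes of a
    Gaussian KDE (Silverman bandwidth) of the per-sample medians.

    Local density maxima closer than ``min_peak_separation`` CN units are
    merged (highest kept). If the density is unimodal the ``fallback`` cutoff
    is returned with a warning. Fewer than ``min_samples`` values is an error:
    use a fixed cutoff on small cohorts.
    """
    x = np.asarray(pd.Series(medians).dropna(), dtype=float)
    if x.size < min_samples:
        raise ValidationError(
            f"cutoff estimation needs >= {min_samples} samples (got {x.size}); "
            "use the fixed default cutoff instead"
        )
    kde = scipy.stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min() - 0.3, x.max() + 0.3, 1024)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1
    # merge maxima closer than the separation floor, keeping the denser one
    peaks: list[int] = []
    for i in sorted(interior, key=lambda j: -dens[j]):
        if all(abs(grid[i] - grid[j]) >= min_peak_separation for j in peaks):
            peaks.append(i)
    if len(peaks) < 2:
        warnings.warn(
            "median copy-number density looks unimodal; "
            f"falling back to cutoff {fallback}",
            stacklevel=2,
        )
        return float(fallback)
    top_two = sorted(peaks, key=lambda j: -dens[j])[:2]
    return float((grid[top_two[0]] + grid[top_two[1]]) / 2)


class PloidyClassifier(BaseEstimator):
    """Call hyperdiploid (HMM) vs non-hyperdiploid (NHMM) status per sample.

    A sample is HMM iff its median copy number over trisomy-chromosome genes
    strictly exceeds the cutoff. scikit-learn estimator conventions apply:
    parameters via ``get_params``/``set_params``, fitted attributes with a
    trailing underscore.

    Parameters
    ----------
    trisomy_chromosomes : iterable of chromosome labels (default 3, 5, 7, 9,
        11, 15, 19, 21).
    cutoff : decision threshold on the median trisomy CN (default 2.3).
    auto_cutoff : if True, re-estimate the cutoff from the cohort's bimodal
        median distribution (see :func:`estimate_cutoff`).

    Attributes
    ----------
    medians_ : pandas.Series of per-sample median trisomy copy numbers.
    cutoff_used_ : float, the threshold actually applied.
    labels_ : pandas.Series of "HMM"/"NHMM" per sample.
    call_set_ : PloidyCallSet bundling the above.
    """

    def __init__(
        self,
        trisomy_chromosomes=DEFAULT_TRISOMY_CHROMOSOMES,
        cutoff: float = DEFAULT_CUTOFF,
        auto_cutoff: bool = False,
    ):
        self.trisomy_chromosomes = trisomy_chromosomes
        self.cutoff = cutoff
        self.auto_cutoff = auto_cutoff

    def _params(self) -> PloidyParams:
        return PloidyParams(
            trisomy_chromosomes=frozenset(str(c) for c in self.trisomy_chromosomes),
            cutoff=self.cutoff,
            auto_cutoff=self.auto_cutoff,
        )

    def fit(self, dataset: PairedDataset, y=None) -> "PloidyClassifier":
        params = self._params()
        medians = median_trisomy_cn(dataset, params)
        cutoff = estimate_cutoff(medians) if params.auto_cutoff else params.cutoff
        labels = pd.Series(
            np.where(medians > cutoff, HMM, NHMM), index=medians.index, name="label"
        )
        self.medians_ = medians
        self.cutoff_used_ = float(cutoff)
        self.labels_ = labels
        self.call_set_ = PloidyCallSet(
            calls=pd.DataFrame({"median_trisomy_cn": medians, "label": labels}),
            cutoff_used=float(cutoff),
        )
        logger.info(
            "ploidy: %s at cutoff %.3f",
            self.call_set_.counts(),
            self.cutoff_used_,
        )
        return self

    def fit_predict(self, dataset: PairedDataset, y=None) -> pd.Series:
        return self.fit(dataset).labels_


def classify_ploidy(
    dataset: PairedDataset, params: PloidyParams | None = None
) -> PloidyCallSet:
    """Functional wrapper over :class:`PloidyClassifier`."""
    params = params or PloidyParams()
    clf = PloidyClassifier(
        trisomy_chromosomes=params.trisomy_chromosomes,
        cutoff=params.cutoff,
        auto_cutoff=params.auto_cutoff,
    )
    return clf.fit(dataset).call_set_
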