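"""Synthetic paired expression / copy-number cohorts with known ground truth.

The generator emulates the copy-number architecture of a newly diagnosed
multiple myeloma cohort: roughly half of samples are hyperdiploid (HMM) with
trisomies of chromosomes 3, 5, 7, 9, 11, 15, 19 and 21; non-hyperdiploid
(NHMM) samples frequently lose chromosome 13; 1q gain and 8p/16q losses
occur in both subtypes. Tumor purity (mean 0.6) attenuates the observed copy
number toward the diploid 2, so a true trisomy is observed near
2 + purity = 2.6 rather than 3 — reproducing the bimodal median-CN
distribution with peaks at 2 and 2.6 that array cohorts show.

Per gene g, expression is simulated on the log2 scale as

    x_gs = mu_g + s_g * log2(cn_eff_gs / 2) + noise,

where cn_eff = 2 + purity * (true_cn - 2) is the purity-attenuated dosage,
mu_g ~ Normal(8, 2) is the baseline, and s_g is 1 for dosage-sensitive genes
(a fraction ``frac_sensitive`` of the transcriptome) and 0 for dosage-
resistant ones. Observed copy number adds Gaussian measurement noise to
cn_eff and is floored at 0.1.

All randomness flows through one ``numpy.random.Generator``; the draw order
is fixed (subtype, purity, events, mu_g, s_g, CN noise, expression noise),
so a given seed yields a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .dosage import DesTable
from .io import GeneAnnotation, OmicsMatrix, ValidationError
from .ploidy import DEFAULT_TRISOMY_CHROMOSOMES, HMM, NHMM
from .preprocess import PairedDataset

# Approximate autosome lengths (Mb) and centromere positions (Mb), used to
# allocate genes proportionally and resolve arm tags like "1q" or "8p".
CHROM_LENGTHS_MB = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 136, "11": 135, "12": 134, "13": 115,
    "14": 107, "15": 102, "16": 90, "17": 81, "18": 78, "19": 59,
    "20": 63, "21": 48, "22": 51,
}
CENTROMERE_MB = {
    "1": 125, "2": 93, "3": 91, "4": 50, "5": 48, "6": 61, "7": 60,
    "8": 45, "9": 49, "10": 40, "11": 53, "12": 36, "13": 18,
    "14": 17, "15": 19, "16": 36, "17": 24, "18": 17, "19": 26,
    "20": 28, "21": 13, "22": 15,
}


@dataclass(frozen=True)
class CnaEvent:
    """A recurrent whole-chromosome or arm-level event.

    region : chromosome label ("13") or arm tag ("1q", "8p").
    kind : "loss" (true CN 1) or "gain" (true CN 3).
    p_hmm, p_nhmm : per-sample occurrence probability in each subtype.
    """

    region: str
    kind: str
    p_hmm: float
    p_nhmm: float

    def __post_init__(self):
        if self.kind not in ("loss", "gain"):
            raise ValidationError(f"event kind must be loss/gain, got {self.kind!r}")
        for p in (self.p_hmm, self.p_nhmm):
            if not 0 <= p <= 1:
                raise ValidationError("event probabilities must lie in [0, 1]")


DEFAULT_EVENTS = (
    CnaEvent("13", "loss", 0.1, 0.7),
    CnaEvent("1q", "gain", 0.3, 0.5),
    CnaEvent("8p", "loss", 0.2, 0.2),
    CnaEvent("16q", "loss", 0.2, 0.2),
)


@dataclass
class SimConfig:
    """Study conditions for the simulated cohort.

    Defaults describe a 200-sample, 2000-gene myeloma-like cohort: half
    hyperdiploid, the event table above, purity Normal(0.6, 0.1) truncated to
    [0.1, 1], copy-number noise sd 0.08, 30% dosage-sensitive genes, baseline
    log2 expression Normal(8, 2) and expression noise sd 0.5.
    """

    n_samples: int = 200
    n_genes: int = 2000
    p_hmm: float = 0.5
    trisomy_chromosomes: frozenset = field(
        default_factory=lambda: DEFAULT_TRISOMY_CHROMOSOMES
    )
    events: tuple = DEFAULT_EVENTS
    purity_mean: float = 0.6
    purity_sd: float = 0.1
    cn_noise_sd: float = 0.08
    frac_sensitive: float = 0.3
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 2.0
    expr_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.trisomy_chromosomes = frozenset(str(c) for c in self.trisomy_chromosomes)
        if not 0 <= self.p_hmm <= 1 or not 0 <= self.frac_sensitive <= 1:
            raise ValidationError("probabilities must lie in [0, 1]")
        for sd in (self.purity_sd, self.cn_noise_sd, self.expr_noise_sd, self.expr_baseline_sd):
            if sd < 0:
                raise ValidationError("standard deviations must be >= 0")
        if self.n_samples < 2 or self.n_genes < 2:
            raise ValidationError("need at least 2 samples and 2 genes")
        self.events = tuple(
            e if isinstance(e, CnaEvent) else CnaEvent(**e) for e in self.events
        )


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated cohort.

    samples : DataFrame indexed by sample with subtype and purity.
    genes : DataFrame indexed by gene with chromosome, s_g (sensitivity
        coefficient) and mu_g (baseline log2 expression).
    true_cn : genes x samples integer copy numbers in {1, 2, 3}.
    """

    samples: pd.DataFrame
    genes: pd.DataFrame
    true_cn: pd.DataFrame


def make_annotation(n_genes: int, tx_length_bp: int = 20_000) -> GeneAnnotation:
    """Deterministic annotation: genes allocated to autosomes proportionally
    to chromosome length (largest-remainder rounding) and evenly spaced."""
    chroms = list(CHROM_LENGTHS_MB)
    lengths = np.array([CHROM_LENGTHS_MB[c] for c in chroms], dtype=float)
    quota = n_genes * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: n_genes - counts.sum()]:
        counts[i] += 1
    rows = []
    gene_no = 0
    for chrom, count in zip(chroms, counts):
        length_bp = CHROM_LENGTHS_MB[chrom] * 1_000_000
        for j in range(count):
            start = int((j + 0.5) / max(count, 1) * length_bp) + 1
            rows.append(
                {
                    "gene": f"GENE{gene_no:05d}",
                    "chromosome": chrom,
                    "tx_start": start,
                    "tx_end": start + tx_length_bp - 1,
                }
            )
            gene_no += 1
    table = pd.DataFrame(rows).set_index("gene")
    return GeneAnnotation(table)


def _region_mask(annotation: GeneAnnotation, region: str) -> np.ndarray:
    """Boolean gene mask for a chromosome label or arm tag ('8p'/'1q')."""
    t = annotation.table
    if region and region[-1] in ("p", "q"):
        chrom, arm = region[:-1], region[-1]
        centromere = CENTROMERE_MB[chrom] * 1_000_000
        mid = (t["tx_start"] + t["tx_end"]) / 2
        on_chrom = (t["chromosome"] == chrom).to_numpy()
        if arm == "p":
            return on_chrom & (mid <= centromere).to_numpy()
        return on_chrom & (mid > centromere).to_numpy()
    return (t["chromosome"] == region).to_numpy()


def simulate_cohort(config: SimConfig | None = None) -> tuple[PairedDataset, SyntheticTruth]:
    """Draw a paired cohort and its ground truth. See the module docstring
    for the generative model and the fixed draw order."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    annotation = make_annotation(config.n_genes)
    genes = annotation.gene_symbols
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    n_g, n_s = len(genes), len(samples)
    chrom = annotation.table["chromosome"].to_numpy()

    # draw 1: subtype; draw 2: purity
    is_hmm = rng.random(n_s) < config.p_hmm
    purity = np.clip(
        rng.normal(config.purity_mean, config.purity_sd, n_s), 0.1, 1.0
    )

    true_cn = np.full((n_g, n_s), 2, dtype=int)
    trisomy_mask = np.isin(chrom, list(config.trisomy_chromosomes))
    true_cn[np.ix_(trisomy_mask, is_hmm)] = 3

    # draw 3: events, in config order
    for event in config.events:
        p = np.where(is_hmm, event.p_hmm, event.p_nhmm)
        hit = rng.random(n_s) < p
        mask = _region_mask(annotation, event.region)
        true_cn[np.ix_(mask, hit)] = 1 if event.kind == "loss" else 3

    # draw 4: baseline expression; draw 5: sensitivity labels
    mu_g = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd, n_g)
    s_g = (rng.random(n_g) < config.frac_sensitive).astype(float)

    cn_eff = 2.0 + purity[None, :] * (true_cn - 2)
    # draw 6: CN measurement noise; draw 7: expression noise
    observed_cn = np.maximum(
        cn_eff + rng.normal(0.0, config.cn_noise_sd, (n_g, n_s)), 0.1
    )
    expression = (
        mu_g[:, None]
        + s_g[:, None] * np.log2(cn_eff / 2.0)
        + rng.normal(0.0, config.expr_noise_sd, (n_g, n_s))
    )

    expr_df = pd.DataFrame(expression, index=genes, columns=samples)
    expr_df.index.name = "gene"
    cn_df = pd.DataFrame(observed_cn, index=genes, columns=samples)
    cn_df.index.name = "gene"
    dataset = PairedDataset(
        expression=OmicsMatrix("expression", expr_df),
        copy_number=OmicsMatrix("copy_number", cn_df),
        annotation=annotation,
    )
    truth = SyntheticTruth(
        samples=pd.DataFrame(
            {
                "subtype": np.where(is_hmm, HMM, NHMM),
                "purity": purity,
            },
            index=pd.Index(samples, name="sample"),
        ),
        genes=pd.DataFrame(
            {"chromosome": chrom, "s_g": s_g, "mu_g": mu_g},
            index=pd.Index(genes, name="gene"),
        ),
        true_cn=pd.DataFrame(true_cn, index=genes, columns=samples),
    )
    return dataset, truth


def truth_eval(des: DesTable, truth: SyntheticTruth) -> dict:
    """Score DES recovery of the planted sensitivity labels.

    Returns the AUROC of DES against s_g over genes with defined DES, the
    number of defined genes, and the mean DES by sensitivity label."""
    defined = des.defined()
    if len(defined) == 0:
        raise ValidationError("no genes with defined DES to evaluate")
    labels = truth.genes.loc[defined.index, "s_g"].to_numpy()
    scores = defined["des"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValidationError("defined-DES genes contain a single truth class")
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "n_defined": int(len(defined)),
        "mean_des_sensitive": float(scores[labels == 1].mean()),
        "mean_des_resistant": float(scores[labels == 0].mean()),
    }


def write_cohort(dataset: PairedDataset, truth: SyntheticTruth, out_dir) -> dict:
    """Write the cohort as TSVs (expression, copy_number, annotation,
    truth_samples, truth_genes); returns {name: path}."""
    from pathlib import Path

    from .io import write_gene_annotation, write_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "copy_number": out / "copy_number.tsv",
        "annotation": out / "annotation.tsv",
        "truth_samples": out / "truth_samples.tsv",
        "truth_genes": out / "truth_genes.tsv",
    }
    write_matrix(dataset.expression, paths["expression"])
    write_matrix(dataset.copy_number, paths["copy_number"])
    write_gene_annotation(dataset.annotation, paths["annotation"])
    truth.samples.to_csv(paths["truth_samples"], sep="\t")
    truth.genes.to_csv(paths["truth_genes"], sep="\t")
    return {k: str(v) for k, v in paths.items()}
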