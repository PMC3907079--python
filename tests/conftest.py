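import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from doseffect.io import GeneAnnotation, OmicsMatrix
from doseffect.preprocess import PairedDataset

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(values, genes, samples, role):
    data = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples)
    data.index.name = "gene"
    return OmicsMatrix(role, data)


def make_annotation(genes, chromosomes, starts=None, ends=None):
    n = len(genes)
    starts = starts or [1000 * (i + 1) for i in range(n)]
    ends = ends or [s + 999 for s in starts]
    table = pd.DataFrame(
        {
            "chromosome": [str(c) for c in chromosomes],
            "tx_start": starts,
            "tx_end": ends,
        },
        index=pd.Index(genes, name="gene"),
    )
    return GeneAnnotation(table)


def make_paired(expr_values, cn_values, genes, samples, chromosomes=None):
    chromosomes = chromosomes or ["1"] * len(genes)
    return PairedDataset(
        expression=make_matrix(expr_values, genes, samples, "expression"),
        copy_number=make_matrix(cn_values, genes, samples, "copy_number"),
        annotation=make_annotation(genes, chromosomes),
    )


@pytest.fixture
def paired_builder():
    return make_paired


@pytest.fixture
def matrix_builder():
    return make_matrix


@pytest.fixture
def annotation_builder():
    return make_annotation
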