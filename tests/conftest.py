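import numpy as np
import pandas as pd
import pytest

from offcontext import ExpressionMatrix, TissueAnnotation
from offcontext.containers import LOG2, SOMATIC


def make_annotation(tissue_classes: dict[str, str], samples_per_tissue: int = 1) -> TissueAnnotation:
    """One annotation with ``samples_per_tissue`` samples named <tissue>.s<j>."""
    tissue_of = {
        f"{t}.s{j}": t
        for t in tissue_classes
        for j in range(1, samples_per_tissue + 1)
    }
    return TissueAnnotation(pd.Series(tissue_of), dict(tissue_classes))


def expr_from_tissue_means(tmeans: pd.DataFrame, ann: TissueAnnotation) -> ExpressionMatrix:
    """Expand a genes x tissues mean table into a noiseless sample matrix."""
    cols = {s: tmeans[t] for s, t in ann.tissue_of.items()}
    return ExpressionMatrix(pd.DataFrame(cols), scale=LOG2)


@pytest.fixture
def small_annotation() -> TissueAnnotation:
    return make_annotation(
        {
            "liver": SOMATIC,
            "lung": SOMATIC,
            "brain": SOMATIC,
            "testis": "germline",
            "placenta": "placenta",
            "es_line": "embryonic_stem",
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170)
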