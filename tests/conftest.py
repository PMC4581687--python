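import numpy as np
import pandas as pd
import pytest

from dignet.preprocessing import ExpressionMatrix
from dignet.regnet import RegNetwork


def make_expression(values: np.ndarray, n_disease: int | None = None) -> ExpressionMatrix:
    """Wrap a genes x samples array; second half of samples is 'disease'."""
    n_genes, n_samples = values.shape
    if n_disease is None:
        n_disease = n_samples // 2
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    labels = ["control"] * (n_samples - n_disease) + ["disease"] * n_disease
    frame = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(frame, pd.Series(labels, index=samples))


@pytest.fixture
def tiny_net() -> RegNetwork:
    """One planted instance of each motif class, nothing else.

    joint on (g1, g2) via (m1, t1); crosstalk on (g3, g4) via (m2, t2) with
    t2->g3 and m2->g4; triplet on g5 via (m3, t3) closed by m3->t3.
    """
    return RegNetwork(
        mirnas={"m1", "m2", "m3"},
        tfs={"t1", "t2", "t3"},
        genes={"g1", "g2", "g3", "g4", "g5"},
        mirna_gene={("m1", "g1"), ("m1", "g2"), ("m2", "g4"), ("m3", "g5")},
        tf_gene={("t1", "g1"), ("t1", "g2"), ("t2", "g3"), ("t3", "g5")},
        mirna_tf={("m3", "t3")},
        tf_mirna=set(),
        gene_gene={("g1", "g2"), ("g3", "g4")},
    )
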