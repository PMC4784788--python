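import numpy as np
import pandas as pd
import pytest

from isopipe.models import ExpressionMatrix, TranscriptModel


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 isoforms (2 genes) x 4 samples, balanced 2x2-free design."""
    values = pd.DataFrame(
        {
            "s1": [10.0, 5.0, 0.0],
            "s2": [20.0, 10.0, 0.0],
            "s3": [12.0, 6.0, 1.0],
            "s4": [18.0, 9.0, 2.0],
        },
        index=["t1", "t2", "t3"],
    )
    genes = pd.Series({"t1": "gA", "t2": "gA", "t3": "gB"})
    design = pd.DataFrame(
        {
            "challenge": ["Control", "Control", "BCG", "BCG"],
            "cell": ["microglia"] * 4,
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values, genes, design)


def make_matrix(values: np.ndarray, n_ctrl: int, n_bcg: int,
                genes=None) -> ExpressionMatrix:
    """Array -> ExpressionMatrix with a Control/BCG microglia design."""
    n_units, n_samples = values.shape
    assert n_samples == n_ctrl + n_bcg
    samples = [f"c{i}" for i in range(n_ctrl)] + [f"b{i}" for i in range(n_bcg)]
    units = [f"t{i}" for i in range(n_units)]
    if genes is None:
        genes = units
    df = pd.DataFrame(values.astype(float), index=units, columns=samples)
    design = pd.DataFrame(
        {
            "challenge": ["Control"] * n_ctrl + ["BCG"] * n_bcg,
            "cell": ["microglia"] * n_samples,
        },
        index=samples,
    )
    return ExpressionMatrix(df, pd.Series(genes, index=units), design)


def tx(tid, exons, gene="g1", strand="+"):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, strand=strand, exons=tuple(exons)
    )
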