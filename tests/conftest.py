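import numpy as np
import pandas as pd
import pytest

from anchorgda.core_io import ExpressionMatrix, GeneSignature, SignatureCollection


@pytest.fixture
def tiny_expression_file(tmp_path):
    """3 genes x 4 samples TSV plus a two-column annotation file."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\ts1\ts2\ts3\ts4\n"
        "gja1\t1.0\t2.0\t3.0\t4.0\n"
        "GENEB\t4.0\t3.0\t2.0\t1.0\n"
        "GENEC\t0.5\t0.5\t1.5\t1.5\n"
    )
    ann = tmp_path / "ann.tsv"
    ann.write_text("s1\tNDC\ns2\tNDC\ns3\tALS\ns4\tALS\n")
    return path, ann


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(7)
    genes = ["GJA1", "POSG", "NEGG", "FLAT", "NOISE"]
    samples = [f"n{i}" for i in range(5)] + [f"a{i}" for i in range(6)]
    anchor = rng.normal(0, 1, 11)
    data = np.vstack(
        [
            anchor,
            2.0 * anchor + 1.0,       # perfect positive correlate (affine)
            -anchor,                  # perfect negative correlate
            np.full(11, 3.0),         # constant row
            rng.normal(0, 1, 11),
        ]
    )
    labels = {s: ("NDC" if s.startswith("n") else "ALS") for s in samples}
    return ExpressionMatrix(
        values=pd.DataFrame(data, index=genes, columns=samples), group_labels=labels
    )


@pytest.fixture
def small_collection():
    sigs = [
        GeneSignature("setA", "immune", "src", frozenset({"G1", "G2", "G3"})),
        GeneSignature("setB", "neural", "src", frozenset({"G3", "G4", "G5", "G6"})),
    ]
    return SignatureCollection(signatures=sigs, universe_size=50)
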