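import numpy as np
import pandas as pd
import pytest

from crossde import ExpressionMatrix


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, 2+2 design, hand-chosen intensities."""
    values = pd.DataFrame(
        {
            "A_1": [20.0, 8.0, 5.0],
            "A_2": [20.0, 12.0, 5.0],
            "B_1": [10.0, 5.0, 5.0],
            "B_2": [10.0, 5.0, 5.0],
        },
        index=pd.Index(["Gli1", "Foxf2", "Actb"], name="gene"),
    )
    design = {"A_1": "SHH", "A_2": "SHH", "B_1": "Veh", "B_2": "Veh"}
    return ExpressionMatrix(values=values, design=design)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def write_matrix_files(tmp_path, frame, design, name="m"):
    """Write an expression TSV + design TSV, return both paths."""
    mpath = tmp_path / f"{name}.tsv"
    dpath = tmp_path / f"{name}_design.tsv"
    out = frame.copy()
    out.index.name = "gene"
    out.to_csv(mpath, sep="\t")
    pd.DataFrame({"sample": list(design), "condition": list(design.values())}).to_csv(
        dpath, sep="\t", index=False
    )
    return mpath, dpath
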