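import numpy as np
import pandas as pd
import pytest

import intercell as ic


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard synthetic study: 3 clusters x 20 cells, 2 planted pairs."""
    return ic.make_fixture(seed=7)


@pytest.fixture()
def six_cell_expression():
    """6 cells (3 sender + 3 receiver); gene A only in sender, B in receiver."""
    genes = pd.Index(["A", "B"])
    cells = pd.Index([f"c{i}" for i in range(6)])
    mat = np.array(
        [
            [5.0, 4.0, 6.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 3.0, 5.0, 4.0],
        ]
    )
    labels = pd.Series(["S"] * 3 + ["R"] * 3, index=cells)
    return ic.LabeledExpression(mat, genes, cells, labels)


@pytest.fixture()
def toy_interaction_db():
    AR = ic.ActionRecord
    mk = ic.InteractionRecord.make
    records = [
        mk("A", "B", {"experiments": 150}, 920,
           actions=(AR("binding"), AR("activation", "positive", True, "a"))),
        mk("A", "C", {"database": 80}, 400,
           actions=(AR("binding"),)),
        mk("B", "C", {"textmining": 60}, 250,
           actions=(AR("catalysis", "unspecified", True, "b"),)),
        mk("C", "D", {"experiments": 300, "coexpression": 40}, 710,
           actions=(AR("inhibition", "negative", True, "a"),)),
        mk("E", "E", {"homology": 90}, 150,
           actions=(AR("reaction"),)),
    ]
    return ic.InteractionDatabase(records)


@pytest.fixture()
def toy_gene_table(tmp_path):
    rows = [
        ("IL6", "human", "extracellular region", 5, "cytokine", "GO:0006955"),
        ("IL6R", "human", "plasma membrane", 4, "receptor",
         "GO:0006955;GO:0007165"),
        ("ACTB", "human", "cytoskeleton", 5, "structural protein", ""),
    ]
    path = tmp_path / "genes.tsv"
    pd.DataFrame(
        rows,
        columns=["symbol", "species", "loc_category", "loc_confidence",
                 "function_class", "go_terms"],
    ).to_csv(path, sep="\t", index=False)
    return path
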