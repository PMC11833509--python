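import numpy as np
import pandas as pd
import pytest

from synmatch.tmt import TmtDesign, default_design


@pytest.fixture(scope="session")
def design() -> TmtDesign:
    return default_design()


def make_quant_table(values: np.ndarray, design: TmtDesign, peptides=None) -> pd.DataFrame:
    """Assemble a quant table from an (n_proteins, n_channels) value array."""
    n = len(values)
    tab = pd.DataFrame(
        {
            "protein_id": [f"P{i:04d}" for i in range(n)],
            "gene_symbol": [f"g{i}" for i in range(n)],
            "unique_peptides": peptides if peptides is not None else [2] * n,
        }
    )
    for j, lab in enumerate(design.labels):
        tab[lab] = values[:, j]
    return tab
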