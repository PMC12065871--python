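import numpy as np
import pandas as pd
import pytest

import lipmap as lm


@pytest.fixture
def small_quant_table() -> pd.DataFrame:
    """4 samples (2 conditions x 2 replicates) x 2 peptides, LiP channel."""
    rows = []
    for cond, reps in (("treated", (1, 2)), ("control", (1, 2))):
        for r in reps:
            for pep, inten in (("MDVFMK", 1000.0), ("GLSKAK", 2000.0)):
                rows.append(
                    {
                        "sample_id": f"{cond}_{r}",
                        "condition": cond,
                        "replicate": r,
                        "protein_id": "P1",
                        "peptide_sequence": pep,
                        "assay_type": "LIP",
                        "intensity": inten * (1.1 if cond == "treated" else 1.0),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_experiment():
    """One default synthetic experiment (seed 1) shared across tests."""
    truth = lm.default_truth(seed=1)
    lip, tc, record = lm.simulate_lip_experiment(truth)
    return truth, lip, tc, record


@pytest.fixture(scope="session")
def all_sequences():
    seqs = {"SYUA_SYNTH": lm.ALPHA_SYNUCLEIN}
    seqs.update(dict(lm.synthdata.CARRIER_SEQUENCES))
    return seqs
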