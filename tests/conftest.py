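import numpy as np
import pandas as pd
import pytest

from festflow.repertoire import ClonotypeTable


def make_table(condition_id, rows):
    """Build a ClonotypeTable from (cdr3, reads, well) or
    (cdr3, reads, well, productive) tuples."""
    recs = []
    for row in rows:
        cdr3, reads, well = row[:3]
        productive = row[3] if len(row) > 3 else True
        recs.append({
            "cdr3_aa": cdr3, "v_gene": "TRBV19", "reads": reads,
            "productive": productive, "well_id": well,
        })
    return ClonotypeTable(condition_id=condition_id, records=pd.DataFrame(recs))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_clone_tables():
    """A condition with an expanded clone plus a matched control.

    Clone EXP: 500/5000 reads in the condition vs 10/5000 in the control;
    clone BKG fills the remainder in both.
    """
    cond = make_table("pepX", [
        ("CASSEXPANDAF", 300, "w1"), ("CASSEXPANDAF", 200, "w2"),
        ("CASSBACKGRDF", 2300, "w1"), ("CASSBACKGRDF", 2200, "w2"),
    ])
    ctrl = make_table("no_peptide", [
        ("CASSEXPANDAF", 5, "w1"), ("CASSEXPANDAF", 5, "w2"),
        ("CASSBACKGRDF", 2500, "w1"), ("CASSBACKGRDF", 2490, "w2"),
    ])
    return cond, ctrl
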