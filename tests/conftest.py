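import numpy as np
import pandas as pd
import pytest

from csfscreen.io import IdentificationTable, RECORD_COLUMNS, SampleRecord, StudyDesign


def make_table(rows, peptide_detail=True, dialect="long_tsv"):
    """Build an IdentificationTable from (sample, replicate, accession,
    name, gene, peptide[, q]) tuples."""
    records = []
    for r in rows:
        r = list(r)
        if len(r) == 6:
            r.append(np.nan)
        records.append(dict(zip(RECORD_COLUMNS, r)))
    df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    return IdentificationTable(records=df, dialect=dialect, peptide_detail=peptide_detail)


def make_design(group_sizes, control="control", replicates=("r1", "r2")):
    samples = tuple(
        SampleRecord(sample_id=f"{g}{i + 1:02d}", group=g, replicate_ids=tuple(replicates))
        for g, n in group_sizes.items()
        for i in range(n)
    )
    return StudyDesign(samples=samples, group_labels=tuple(group_sizes), control_group=control)


@pytest.fixture
def two_group_design():
    return make_design({"control": 3, "case": 3})


@pytest.fixture
def cohort_design():
    return make_design({"control": 10, "AD": 10, "PD": 10})
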