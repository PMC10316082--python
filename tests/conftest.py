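import numpy as np
import pandas as pd
import pytest

from pepdesc import PeptideTable, SampleDesign


def make_table(values, samples=None, accessions=None, rt=None, mz=None,
               ids=None) -> PeptideTable:
    """Build a PeptideTable from a 2-D array of abundances (0 = missing)."""
    values = np.asarray(values, dtype=float)
    n_pep, n_samp = values.shape
    samples = samples or [f"s{i + 1}" for i in range(n_samp)]
    ids = ids or [f"pep{i + 1}" for i in range(n_pep)]
    accessions = accessions or ["PROT1"] * n_pep
    idx = pd.Index(ids, name="peptide_id")
    return PeptideTable(
        abundances=pd.DataFrame(values, index=idx, columns=samples),
        protein_accession=pd.Series(list(accessions), index=idx, name="protein"),
        retention_time=None if rt is None else pd.Series(
            np.asarray(rt, float), index=idx, name="retention_time"),
        mz=None if mz is None else pd.Series(
            np.asarray(mz, float), index=idx, name="mz"),
    )


def make_design(m: int, n: int, names=("group1", "group2")) -> SampleDesign:
    ids = [f"s{i + 1}" for i in range(m + n)]
    labels = pd.Series([names[0]] * m + [names[1]] * n,
                       index=pd.Index(ids, name="sample_id"), name="group")
    return SampleDesign(sample_ids=ids, group_labels=labels, group_names=names)


@pytest.fixture
def two_group_design():
    return make_design(2, 2)
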