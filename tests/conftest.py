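import numpy as np
import pytest

from netcbp.data_io import DTIDataset, InteractionMatrix, SimilarityMatrix
from netcbp.synthetic import SyntheticSpec, generate


def make_similarity(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"E{i}" for i in range(values.shape[0])]
    return SimilarityMatrix(list(ids), values)


def make_dataset(D, P, A, drug_ids=None, protein_ids=None):
    A = np.asarray(A)
    drug_ids = drug_ids or [f"D{i}" for i in range(A.shape[0])]
    protein_ids = protein_ids or [f"hsa:{j}" for j in range(A.shape[1])]
    ds = DTIDataset(
        drug_sim=make_similarity(D, drug_ids),
        protein_sim=make_similarity(P, protein_ids),
        interactions=InteractionMatrix(
            list(drug_ids), list(protein_ids), A.astype(np.int8)
        ),
    )
    ds.validate()
    return ds


@pytest.fixture(scope="session")
def default_synthetic():
    """The default planted-cluster dataset (60 drugs, 30 proteins)."""
    dataset, truth = generate(SyntheticSpec())
    return dataset, truth


@pytest.fixture
def transfer_toy():
    """Tiny dataset with one obvious transfer: D0 is highly similar to D1,
    which targets exactly protein hsa:0; other similarities at baseline."""
    base = 0.1
    D = np.full((4, 4), base)
    np.fill_diagonal(D, 1.0)
    D[0, 1] = D[1, 0] = 1.0
    P = np.full((3, 3), base)
    np.fill_diagonal(P, 1.0)
    A = np.zeros((4, 3), dtype=int)
    A[1, 0] = 1  # D1 -> hsa:0
    A[2, 1] = 1
    A[3, 2] = 1
    return make_dataset(D, P, A)
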