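import numpy as np
import pytest

from canonet.datatypes import MultiOmicsDataset, OmicsBlock, Phenotype
from canonet.preprocess import standardize_columns
from canonet.synthetic import SyntheticSpec, generate


def standardized(data: MultiOmicsDataset) -> MultiOmicsDataset:
    """Column-standardize every block (the solver's expected input)."""
    blocks = [
        OmicsBlock(b.label, standardize_columns(b.matrix), b.feature_names, b.subject_ids)
        for b in data.blocks
    ]
    return MultiOmicsDataset(blocks=blocks, phenotype=data.phenotype)


def make_dataset(matrices, y, modality="quantitative", labels=None):
    """Build an aligned dataset from raw arrays (convenience for tests)."""
    n = np.asarray(matrices[0]).shape[0]
    sids = [f"S{i}" for i in range(n)]
    blocks = []
    for t, m in enumerate(matrices):
        m = np.asarray(m, dtype=float)
        lab = labels[t] if labels else f"block{t + 1}"
        blocks.append(OmicsBlock(
            label=lab, matrix=m,
            feature_names=[f"{lab}_f{j}" for j in range(m.shape[1])],
            subject_ids=sids,
        ))
    pheno = Phenotype(values=np.asarray(y), modality=modality, subject_ids=sids)
    return MultiOmicsDataset(blocks=blocks, phenotype=pheno)


@pytest.fixture(scope="session")
def planted_quantitative():
    """Strong planted cross-block signal with a quantitative phenotype."""
    spec = SyntheticSpec(n_subjects=200, block_sizes=(30, 30),
                         planted_sizes=(5, 5), loading=1.0,
                         phenotype_effect=1.0, noise_sd=0.3, seed=7)
    data, truth = generate(spec)
    return standardized(data), truth


@pytest.fixture(scope="session")
def planted_binary():
    """Strong planted signal with a binary phenotype."""
    spec = SyntheticSpec(n_subjects=300, block_sizes=(100, 100),
                         planted_sizes=(5, 5), loading=1.0,
                         phenotype_effect=3.0, noise_sd=0.2,
                         binary=True, seed=5)
    data, truth = generate(spec)
    return standardized(data), truth
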