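import numpy as np
import pytest

from evmir.io_model import CountMatrix, SampleMeta


def make_matrix(counts, features=None, donors=3, library_sizes=None,
                groups=(("cell", "normoxia"), ("cell", "hypoxia"),
                        ("ev", "normoxia"), ("ev", "hypoxia"))):
    """Build a CountMatrix from an array whose columns are ordered group by
    group, ``donors`` samples each."""
    counts = np.asarray(counts)
    n_samples = counts.shape[1]
    assert n_samples == donors * len(groups)
    samples = []
    j = 0
    for comp, cond in groups:
        for d in range(donors):
            lib = (library_sizes[j] if library_sizes is not None
                   else max(1, int(counts[:, j].sum())))
            samples.append(SampleMeta(
                sample_id=f"D{d + 1}_{comp}_{cond}", donor=f"D{d + 1}",
                compartment=comp, condition=cond, library_size=lib))
            j += 1
    if features is None:
        features = [f"mir-{i + 1}" for i in range(counts.shape[0])]
    return CountMatrix(features=features, samples=samples, counts=counts)


def two_group_matrix(counts_a, counts_b, library_sizes=None,
                     group_a=("cell", "normoxia"), group_b=("ev", "normoxia")):
    """Two-group matrix for contrast-level tests: counts_a / counts_b are
    features x donors arrays."""
    counts = np.concatenate([np.asarray(counts_a), np.asarray(counts_b)], axis=1)
    donors = np.asarray(counts_a).shape[1]
    return make_matrix(counts, donors=donors, library_sizes=library_sizes,
                       groups=(group_a, group_b))


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
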