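import numpy as np
import pandas as pd
import pytest

from fanet.association import AssociationMatrix


def matrix_from_array(values, names=None, kinds=None) -> AssociationMatrix:
    """Build an AssociationMatrix directly from a symmetric array (tests only)."""
    values = np.asarray(values, dtype=float)
    p = values.shape[0]
    names = list(names) if names is not None else [chr(ord("A") + i) for i in range(p)]
    idx = pd.Index(names)
    method = pd.DataFrame("pearson", index=idx, columns=idx)
    n_used = pd.DataFrame(93, index=idx, columns=idx)
    return AssociationMatrix(
        tuple(names),
        pd.DataFrame(values, index=idx, columns=idx),
        method,
        n_used,
        kinds or {n: "continuous" for n in names},
    )


def random_association(rng: np.random.Generator, p: int) -> AssociationMatrix:
    """Random symmetric matrix with unit diagonal, entries in [-1, 1]."""
    m = rng.uniform(-1, 1, size=(p, p))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return matrix_from_array(m)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def study_cohort():
    from fanet.synthetic import default_study_specs, generate_cohort

    return generate_cohort(default_study_specs(), n=93, seed=11)
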