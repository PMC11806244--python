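import numpy as np
import pytest

from nicomply.datagen import TrialDataset


def make_dataset(Z, C, X, Y, U=None):
    Z = np.asarray(Z)
    return TrialDataset(id=np.arange(len(Z)), Z=Z, C=np.asarray(C), X=np.asarray(X),
                        Y=np.asarray(Y, dtype=float), U=None if U is None else np.asarray(U))


@pytest.fixture
def six_row_itt():
    """Tiny fixture with both arms and varying X for exact OLS checks."""
    return make_dataset(
        Z=[0, 0, 0, 1, 1, 1],
        C=[1, 1, 1, 1, 1, 1],
        X=[0, 1, 0, 1, 0, 1],
        Y=[1.0, 2.5, 0.5, 3.0, 1.5, 4.0],
    )


@pytest.fixture
def eight_row_pp():
    """Eight rows, two non-compliers (one per arm)."""
    return make_dataset(
        Z=[0, 0, 0, 0, 1, 1, 1, 1],
        C=[1, 1, 1, 0, 1, 1, 1, 0],
        X=[0, 1, 0, 1, 1, 0, 1, 0],
        Y=[1.0, 2.5, 0.5, 9.9, 3.0, 1.5, 4.0, -9.9],
    )


@pytest.fixture
def ipw_hand_fixture():
    """Weighted-mean hand example: arm 0 has an X=0 cell with 2/4 compliers
    (Y = 1 and 3, weight 2) and an all-complying X=1 cell (Y = 2, weight 1);
    arm 1 has 8 compliers all with Y = 2.5.  Weighted arm-0 mean is
    (2*1 + 2*3 + 4*2)/8 = 2.0, so the estimate is 0.5."""
    Z = [0] * 8 + [1] * 8
    X = [0, 0, 0, 0, 1, 1, 1, 1] + [0, 0, 0, 0, 1, 1, 1, 1]
    C = [1, 1, 0, 0, 1, 1, 1, 1] + [1] * 8
    Y = [1.0, 3.0, 0.0, 0.0, 2.0, 2.0, 2.0, 2.0] + [2.5] * 8
    return make_dataset(Z=Z, C=C, X=X, Y=Y)


@pytest.fixture
def sixteen_row_2sls():
    """Deterministic 2SLS fixture: arm 0 complies fully at X=0 and half at
    X=1; arm 1 reversed.  Y values are fixed arbitrary numbers."""
    Z = [0] * 8 + [1] * 8
    X = [0, 0, 0, 0, 1, 1, 1, 1] * 2
    C = [1, 1, 1, 1, 1, 1, 0, 0] + [1, 0, 0, 1, 1, 1, 1, 1]
    Y = [0.8, 1.2, 0.9, 1.1, 1.6, 1.4, 0.7, 0.9,
         1.0, 0.4, 0.6, 1.2, 1.9, 2.1, 1.8, 2.2]
    return make_dataset(Z=Z, C=C, X=X, Y=Y)


@pytest.fixture
def full_compliance_trial():
    rng = np.random.default_rng(7)
    n = 80
    Z = (np.arange(n) % 2).astype(int)
    X = (rng.random(n) < 0.5).astype(int)
    Y = 0.3 * Z + 0.5 * X + rng.normal(0, 1, n)
    return make_dataset(Z=Z, C=np.ones(n, dtype=int), X=X, Y=Y)
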