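import numpy as np
import pytest

from circafosr.basis import build_basis
from circafosr.preprocess import N_EPOCHS, CovariateRow, EpochDay


@pytest.fixture(scope="session")
def basis288():
    """The default 288x18 periodic d10 level-4 basis (shared; it is frozen)."""
    return build_basis()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def make_day(subject_id: str, day_index: int, counts) -> EpochDay:
    counts = np.broadcast_to(np.asarray(counts, dtype=float), (N_EPOCHS,)).copy()
    return EpochDay(subject_id=subject_id, day_index=day_index, counts=counts)


def make_covariates(groups, ages=None, sexes=None):
    n = len(groups)
    ages = ages if ages is not None else [60 + (i % 7) for i in range(n)]
    sexes = sexes if sexes is not None else [i % 2 for i in range(n)]
    return [
        CovariateRow(
            subject_id=f"S{i + 1:04d}", group=int(g), age=float(a), sex=int(s)
        )
        for i, (g, a, s) in enumerate(zip(groups, ages, sexes))
    ]
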