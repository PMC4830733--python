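import numpy as np
import pytest

from stressdoe import (
    ResponseVector,
    ScreeningConfig,
    effects_table,
    fit_full_model,
)
from stressdoe import datasets


@pytest.fixture(scope="session")
def acid_design():
    return datasets.acid_design()


@pytest.fixture(scope="session")
def alkali_design():
    return datasets.alkali_design()


@pytest.fixture(scope="session")
def acid_responses():
    return datasets.acid_responses()


@pytest.fixture(scope="session")
def alkali_responses():
    return datasets.alkali_responses()


@pytest.fixture(scope="session")
def acid_yates():
    """Acid Yates worksheet on integer-rounded responses (worksheet mode)."""
    return effects_table(
        datasets.acid_responses(), ScreeningConfig(yates_rounding="nearest-integer")
    )


@pytest.fixture(scope="session")
def alkali_yates():
    """Alkali Yates worksheet on the published integer response column."""
    y = ResponseVector(
        values=np.array(datasets.ALKALI_YATES_INPUT, dtype=float), label="alkali"
    )
    return effects_table(y, ScreeningConfig())


@pytest.fixture(scope="session")
def acid_model(acid_design, acid_responses):
    return fit_full_model(acid_design, acid_responses)


@pytest.fixture(scope="session")
def alkali_model(alkali_design, alkali_responses):
    return fit_full_model(alkali_design, alkali_responses)


@pytest.fixture(scope="session")
def acid_model_2dp(acid_model):
    """Acid polynomial with 2-dp coefficients (worksheet arithmetic)."""
    return acid_model.rounded(2)


def brute_force_effect_column(runs: np.ndarray, label: str) -> np.ndarray:
    """Independent effect-column construction from a term label."""
    import re

    idx = [int(m) - 1 for m in re.findall(r"X(\d+)", label)]
    col = np.ones(runs.shape[0])
    for i in idx:
        col = col * runs[:, i]
    return col
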