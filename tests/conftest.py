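import numpy as np
import pytest

from triomix.io import Contrast, OmicsMatrix, SampleMetadata
from triomix.simulate import SimConfig


@pytest.fixture
def tiny_matrix():
    """3 features x 6 samples, two groups of 3, log2 scale."""
    values = np.array(
        [
            [5.0, 5.2, 4.8, 7.0, 7.1, 6.9],   # clear +2 shift
            [8.0, 8.1, 7.9, 8.05, 7.95, 8.0],  # null
            [6.0, 6.1, 5.9, 4.0, 3.9, 4.1],   # clear -2 shift
        ]
    )
    return OmicsMatrix(
        layer="mirna",
        feature_ids=["f1", "f2", "f3"],
        sample_ids=[f"s{i}" for i in range(1, 7)],
        values=values,
    )


@pytest.fixture
def two_group_meta():
    return SampleMetadata(
        group_of={f"s{i}": ("model" if i <= 3 else "treated") for i in range(1, 7)}
    )


@pytest.fixture
def contrast():
    return Contrast(group_a="model", group_b="treated")


@pytest.fixture
def small_sim_cfg():
    """Scaled-down simulation retaining the full design structure."""
    return SimConfig(
        n_mirna=120,
        n_protein=90,
        n_metabolite=160,
        mirna_up=6,
        mirna_down=4,
        protein_up=4,
        protein_down=3,
        metabolite_up=3,
        metabolite_down=3,
        seed=7,
    )
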