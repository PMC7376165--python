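import numpy as np
import pandas as pd
import pytest

from npcorona import IntensityTensor
from npcorona.matrixio import COLUMN_LEVELS


def make_tensor(values: dict, scale: str = "linear") -> IntensityTensor:
    """Build a tensor from {protein_id: {(np, cond, sample, rep): value}}."""
    frame = pd.DataFrame.from_dict(values, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=COLUMN_LEVELS)
    frame.index.name = "protein_id"
    return IntensityTensor(frame.astype(float), scale=scale)


def replicate_tensor(per_protein: dict, np_id="NP-001", condition="standard",
                     sample="pool") -> IntensityTensor:
    """Tensor with one (particle, condition, sample) group:
    {protein_id: [replicate values, NaN for missing]}."""
    values = {
        pid: {(np_id, condition, sample, r + 1): v for r, v in enumerate(reps)}
        for pid, reps in per_protein.items()
    }
    return make_tensor(values)


@pytest.fixture(scope="session")
def small_proteome():
    from npcorona import generate_plasma_proteome

    return generate_plasma_proteome(300, 6.0, seed=11)


@pytest.fixture(scope="session")
def small_particles(small_proteome):
    from npcorona import generate_nanoparticles

    return generate_nanoparticles(small_proteome, 4, seed=11)
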