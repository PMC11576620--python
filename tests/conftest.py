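import numpy as np
import pytest

from idproteome import DisorderTrack, ProteinRecord, ProteomeGroup
from idproteome.synthetic import PredictorModel, PoolSpec, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_spec():
    """A three-group corpus small enough for fast end-to-end runs."""
    return SyntheticSpec(
        group_sizes={"younger_lens": 12, "older_lens": 8, "zonules": 10},
        length_range=(40, 80),
        predictor_models=[
            PredictorModel(
                name="predA",
                target_ads={"younger_lens": 0.42, "older_lens": 0.39, "zonules": 0.47},
                ads_sd=0.12,
                noise_sd=0.1,
                corr_length=5,
            ),
            PredictorModel(
                name="predB",
                target_ads={"younger_lens": 0.33, "older_lens": 0.30, "zonules": 0.35},
                ads_sd=0.12,
                noise_sd=0.1,
                corr_length=5,
            ),
        ],
        pools=[
            PoolSpec("A", 38.5),
            PoolSpec("B", 50.5),
        ],
        seed=11,
    )


@pytest.fixture
def toy_group():
    return ProteomeGroup(
        name="toy",
        records=[
            ProteinRecord("P1", "ACDEFGHIKLMNPQRSTVWY" * 3),
            ProteinRecord("P2", "KKEEDDRRAA" * 5),
            ProteinRecord("P3", "ILVFMWYACG" * 4),
        ],
    )


def random_track(rng, n=50, pid="P1", predictor="x"):
    return DisorderTrack(pid, predictor, rng.uniform(0, 1, size=n))
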