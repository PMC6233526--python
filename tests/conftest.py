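import numpy as np
import pytest

from targetprofiler.conformal import SplitConfig, TrainConfig, train_acp
from targetprofiler.dataset import DatasetRecord, TargetDataset
from targetprofiler.synthetic import SyntheticSpec, generate_molecules


def dataset_from_triples(triples, target="T001", assumed_flags=None):
    records = [
        DatasetRecord(
            smiles=smi,
            activity=obs,
            assumed_nonactive=bool(assumed_flags[i]) if assumed_flags else False,
            entry_id=f"E{i:05d}",
        )
        for i, (smi, obs, _true) in enumerate(triples)
    ]
    return TargetDataset(target, records)


@pytest.fixture(scope="session")
def small_training_triples():
    spec = SyntheticSpec(n_active=120, n_nonactive=120, label_noise=0.05, seed=11)
    return generate_molecules(spec, 0)


@pytest.fixture(scope="session")
def small_test_triples():
    spec = SyntheticSpec(n_active=120, n_nonactive=120, label_noise=0.05, seed=11)
    rng = np.random.default_rng([11, 0, 12345])
    return generate_molecules(spec, 0, rng=rng, n_active=60, n_nonactive=60)


@pytest.fixture(scope="session")
def small_dataset(small_training_triples):
    return dataset_from_triples(small_training_triples)


@pytest.fixture(scope="session")
def small_acp(small_dataset):
    """A 5-ICP aggregated conformal predictor on a small noisy motif task."""
    return train_acp(
        small_dataset,
        SplitConfig(calibration_fraction=0.2, n_icp=5, seed=11),
        TrainConfig(cost=1.0),
    )
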