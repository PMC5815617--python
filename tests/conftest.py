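import numpy as np
import pytest

from crossslope.features import FeatureMatrix, build_feature_matrix
from crossslope.gait_data import Dataset, SignalInventory, TerrainClass
from crossslope.preprocess import preprocess_trial
from crossslope.synthetic import generate_dataset, preset_discriminative

#: The signals that carry terrain information in the discriminative preset.
INFORMATIVE = ("ankle_inversion_angvel", "foot_vert_velocity", "foot_ml_angvel")


@pytest.fixture(scope="session")
def preset_dataset() -> Dataset:
    """3 subjects × 3 terrains × 5 trials of the discriminative preset."""
    return generate_dataset(preset_discriminative(seed=1))


@pytest.fixture(scope="session")
def preset_matrix(preset_dataset) -> FeatureMatrix:
    """Mid-swing feature matrix (990 × 124) of the conditioned preset."""
    conditioned = Dataset(
        [preprocess_trial(t) for t in preset_dataset.trials],
        role=preset_dataset.role,
    )
    return build_feature_matrix(conditioned, SignalInventory.full_with_ips())


@pytest.fixture()
def tiny_trial():
    """A minimal hand-built two-signal trial around a heel strike at 0.5 s."""
    from crossslope.gait_data import TrialRecording

    n = 120  # 1 s at 120 Hz
    t = np.arange(n) / 120.0
    return TrialRecording(
        subject_id="T01",
        terrain=TerrainClass.FLUSH,
        series={"a": np.sin(2 * np.pi * t), "b": np.cos(2 * np.pi * t)},
        heel_strike_time=0.5,
        sample_rate=120.0,
        trial_id="T01_flush_00",
        body_mass=80.0,
    )


def permute_trial_labels(matrix: FeatureMatrix, seed: int) -> FeatureMatrix:
    """Permute terrain labels at the trial level (windows move together)."""
    rng = np.random.default_rng(seed)
    trials = list(dict.fromkeys(matrix.df["trial"]))
    labels = [matrix.df.loc[matrix.df["trial"] == t, "label"].iloc[0] for t in trials]
    permuted = dict(zip(trials, rng.permutation(labels)))
    df = matrix.df.copy()
    df["label"] = df["trial"].map(permuted)
    return FeatureMatrix(df, matrix.inventory)
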