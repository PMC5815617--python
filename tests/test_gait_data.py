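"""Domain types and trial-file round trips."""

import numpy as np
import pytest

from crossslope.gait_data import (
    Dataset,
    EventError,
    FormatError,
    SchemaError,
    SignalInventory,
    TerrainClass,
    TERRAIN_ORDER,
    TrialDialect,
    TrialRecording,
    load_dataset,
    read_trial,
    write_manifest,
    write_trial,
)
from crossslope.synthetic import generate_dataset, generate_trial, preset_discriminative


class TestTerrainClass:
    def test_label_slope_bijection(self):
        for t in TerrainClass:
            assert TerrainClass.from_label(t.label) is t
            assert TerrainClass.from_slope(t.slope_deg) is t
        assert len(TerrainClass) == 3
        assert [t.slope_deg for t in TERRAIN_ORDER] == [-15, 0, 15]


class TestInventory:
    @pytest.mark.parametrize(
        "variant,expected",
        [("full_with_ips", 124), ("full_mc_only", 124), ("ips_only", 24)],
    )
    def test_feature_counts(self, variant, expected):
        inv = SignalInventory.from_variant(variant)
        assert inv.feature_count == expected

    def test_full_variants_have_28_plus_6_signals(self):
        for variant in ("full_with_ips", "full_mc_only"):
            inv = SignalInventory.from_variant(variant)
            assert len(inv) == 34

    def test_grf_cop_are_two_stat(self):
        inv = SignalInventory.full_with_ips()
        for name in inv.names:
            n_stats = inv[name].stat_policy.n_stats
            if name.startswith(("grf_", "cop_")):
                assert n_stats == 2
            else:
                assert n_stats == 4

    def test_mc_variant_substitutes_ips_channels(self):
        with_ips = set(SignalInventory.full_with_ips().names)
        mc_only = set(SignalInventory.full_mc_only().names)
        assert {n for n in with_ips if n.startswith("ips_")} == with_ips - mc_only
        assert all(n.startswith("shank_") for n in mc_only - with_ips)

    def test_duplicate_names_rejected(self):
        from crossslope.gait_data import SignalId

        with pytest.raises(SchemaError):
            SignalInventory((SignalId("x"), SignalId("x")))

    def test_subset_unknown_signal(self):
        with pytest.raises(SchemaError, match="nonexistent"):
            SignalInventory.ips_only().subset(["nonexistent"])


class TestTrialIO:
    def test_round_trip_identity(self, tmp_path, tiny_trial):
        path = tmp_path / "trial.tsv"
        write_trial(tiny_trial, path)
        back = read_trial(path)
        assert back.subject_id == tiny_trial.subject_id
        assert back.terrain is tiny_trial.terrain
        assert back.heel_strike_time == tiny_trial.heel_strike_time
        assert back.sample_rate == pytest.approx(tiny_trial.sample_rate)
        assert back.body_mass == tiny_trial.body_mass
        assert set(back.signal_names) == set(tiny_trial.signal_names)
        for name in tiny_trial.signal_names:
            np.testing.assert_array_equal(back.series[name], tiny_trial.series[name])

    def test_deterministic_serialization(self, tmp_path, tiny_trial):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_trial(tiny_trial, p1)
        write_trial(tiny_trial, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_synthetic_round_trip_preserves_length(self, tmp_path):
        trial = generate_trial(
            preset_discriminative(seed=3), 0, TerrainClass.INVERSION, 0
        )
        path = tmp_path / "syn.tsv"
        write_trial(trial, path)
        assert read_trial(path).n_samples == trial.n_samples

    def test_missing_required_signal_named_in_error(self, tmp_path, tiny_trial):
        path = tmp_path / "trial.tsv"
        write_trial(tiny_trial, path)
        dialect = TrialDialect(required_signals=("a", "b", "ips_ml_acc"))
        with pytest.raises(FormatError, match="ips_ml_acc"):
            read_trial(path, dialect)

    def test_heel_strike_missing_is_event_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# terrain: flush\ntime\ta\n" + "\n".join(
            f"{i / 120.0}\t0.0" for i in range(80)
        ) + "\n")
        with pytest.raises(EventError):
            read_trial(path)

    def test_insufficient_pre_heel_strike_margin(self):
        with pytest.raises(EventError, match="before heel strike"):
            TrialRecording(
                subject_id="s",
                terrain=TerrainClass.FLUSH,
                series={"a": np.zeros(60)},
                heel_strike_time=0.1,
                sample_rate=120.0,
            ).validate()


class TestDataset:
    def test_manifest_round_trip_counts(self, tmp_path):
        ds = generate_dataset(
            preset_discriminative(seed=2, trials_per_class=3, n_subjects=1)
        )
        paths = []
        for trial in ds.trials:
            p = tmp_path / f"{trial.trial_id}.tsv"
            write_trial(trial, p)
            paths.append(p)
        manifest = tmp_path / "manifest.txt"
        write_manifest(paths, "training", manifest)
        loaded = load_dataset(manifest)
        assert len(loaded) == 9
        assert loaded.role == "training"
        assert set(loaded.class_counts().values()) == {3}

    def test_empty_manifest_is_error(self, tmp_path):
        manifest = tmp_path / "empty.txt"
        manifest.write_text("# role: training\n")
        with pytest.raises(FormatError):
            load_dataset(manifest)

    def test_mixed_inventories_rejected(self, tmp_path, tiny_trial):
        other = TrialRecording(
            subject_id="T02",
            terrain=TerrainClass.FLUSH,
            series={"a": np.zeros(120)},  # lacks signal "b"
            heel_strike_time=0.5,
            sample_rate=120.0,
            trial_id="T02_flush_00",
        )
        with pytest.raises(SchemaError, match="T02_flush_00"):
            Dataset([tiny_trial, other])
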