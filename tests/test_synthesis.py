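import numpy as np
import pytest

from chemorigin.registry import ClassProfile
from chemorigin.synthesis import (
    ChemTable,
    GeneratorConfig,
    default_generator_config,
    generate_dataset,
)
from conftest import blob_config, make_table


def test_default_region_config_reproduces_the_sampling_plan():
    table = generate_dataset(default_generator_config("region", seed=0))
    assert table.n_samples == 1717
    assert table.n_components == 70
    regions, counts = np.unique(table.region.astype(str), return_counts=True)
    assert len(regions) == 13
    plan = dict(zip(regions, counts))
    assert plan["Yunnan"] == 360 and plan["Shandong"] == 24
    assert set(table.country.astype(str)) == {
        "China", "United States", "Brazil", "Zimbabwe", "Zambia"}


def test_zero_sd_rows_equal_the_configured_means_exactly():
    cfg = blob_config(means=[[1.0, 2.0, 3.0]], sds=0.0, n_per_class=4, seed=7)
    table = generate_dataset(cfg)
    assert np.array_equal(table.values, np.tile([1.0, 2.0, 3.0], (4, 1)))


def test_same_seed_gives_bit_identical_tables():
    t1 = generate_dataset(default_generator_config("country", seed=42))
    t2 = generate_dataset(default_generator_config("country", seed=42))
    assert np.array_equal(t1.values, t2.values)
    assert np.array_equal(t1.region, t2.region)
    t3 = generate_dataset(default_generator_config("country", seed=43))
    assert not np.array_equal(t1.values, t3.values)


def test_sample_means_recover_configured_means_across_seeds():
    # |sample mean - configured mean| < 4 sd / sqrt(n) for >= 99% of
    # (class, component) cells over 20 seeded runs
    within = total = 0
    for seed in range(20):
        cfg = default_generator_config("country", seed=seed)
        cfg.truncate_at_zero = False  # bound applies to the untruncated draw
        table = generate_dataset(cfg)
        for prof in cfg.profiles:
            mask = table.country.astype(str) == prof.class_label
            sample_mean = table.values[mask].mean(axis=0)
            live = prof.sd > 0
            bound = 4 * prof.sd[live] / np.sqrt(prof.n)
            within += int(np.sum(np.abs(sample_mean[live] - prof.mean[live]) < bound))
            total += int(live.sum())
    assert within / total >= 0.99


def test_truncation_inflates_well_separated_means_by_less_than_half_sd():
    cfg = default_generator_config("country", seed=3)
    table = generate_dataset(cfg)
    for prof in cfg.profiles:
        mask = table.country.astype(str) == prof.class_label
        sample_mean = table.values[mask].mean(axis=0)
        safe = prof.mean >= 2 * prof.sd
        shift = sample_mean[safe] - prof.mean[safe]
        assert np.all(shift <= 0.5 * prof.sd[safe] + 1e-12)


def test_truncation_keeps_concentrations_non_negative_and_ph_in_range():
    profiles = [ClassProfile("X", 50, np.array([0.1, 5.0]), np.array([5.0, 40.0]),
                             component_names=("Chlorine", "pH"))]
    cfg = GeneratorConfig(profiles=profiles, region_counts={"X": ("X", 50)},
                          truncate_at_zero=True, seed=1)
    table = generate_dataset(cfg)
    assert np.all(table.column("Chlorine") >= 0)
    ph = table.column("pH")
    assert np.all((ph > 0) & (ph <= 14))


def test_noise_features_are_label_independent():
    # point-biserial |r| < 0.15 against every class indicator at n=1717
    hits = total = 0
    for seed in range(5):
        table = generate_dataset(
            default_generator_config("region", n_noise_features=2, seed=seed))
        assert table.n_components == 72
        for j in (70, 71):
            col = table.values[:, j]
            for region in np.unique(table.region.astype(str)):
                indicator = (table.region.astype(str) == region).astype(float)
                r = np.corrcoef(col, indicator)[0, 1]
                hits += int(abs(r) < 0.15)
                total += 1
    assert hits / total >= 0.95


def test_generator_config_validation():
    prof = ClassProfile("A", 5, np.zeros(3), np.ones(3))
    with pytest.raises(ValueError, match="offset"):
        GeneratorConfig(profiles=[prof], region_counts={"A": ("A", 5)},
                        region_offsets={"A": np.zeros(2)})
    with pytest.raises(ValueError, match="separation_scale"):
        GeneratorConfig(profiles=[prof], region_counts={"A": ("A", 5)},
                        separation_scale=-1.0)
    with pytest.raises(ValueError, match="unknown country"):
        GeneratorConfig(profiles=[prof], region_counts={"B": ("B", 5)})


def test_chem_table_validation():
    with pytest.raises(ValueError, match="missing"):
        make_table(np.full((2, 2), np.nan), ["a", "b"])
    with pytest.raises(ValueError, match="more than one country"):
        ChemTable(np.zeros((2, 1)), ["c1"], np.array(["r", "r"], dtype=object),
                  np.array(["x", "y"], dtype=object))


def test_csv_round_trip_and_errors(tmp_path):
    table = generate_dataset(default_generator_config("country", seed=9))
    path = tmp_path / "table.csv"
    table.write_csv(path)
    back = ChemTable.read_csv(path)
    assert back.component_names == table.component_names
    np.testing.assert_allclose(back.values, table.values, rtol=0, atol=1e-12)
    assert np.array_equal(back.region, table.region)

    df = table.to_frame().drop(columns=["region"])
    with pytest.raises(ValueError, match="region"):
        ChemTable.from_frame(df)
    df2 = table.to_frame()
    df2["Total sugar"] = df2["Total sugar"].astype(object)
    df2.iloc[3, df2.columns.get_loc("Total sugar")] = "oops"
    with pytest.raises(ValueError, match="Total sugar"):
        ChemTable.from_frame(df2)
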