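import numpy as np
import pandas as pd
import pytest

from indigoferm import synthetic
from indigoferm.errors import InputError


class TestGuildTrajectory:
    def test_stable_guild_is_constant(self):
        spec = synthetic.GuildSpec("s", ("A_1",), "stable", 1.0, 5.0, 0.1, 0.1)
        traj = synthetic.guild_trajectory(spec, [1, 5, 50])
        assert traj.tolist() == [0.1, 0.1, 0.1]

    def test_step_limit_of_steep_decliner(self):
        spec = synthetic.GuildSpec("d", ("A_1",), "decliner", 1e6, 5.0, 0.3, 0.0)
        traj = synthetic.guild_trajectory(spec, [2, 10])
        assert traj[0] == pytest.approx(0.3, abs=1e-9)
        assert traj[1] == pytest.approx(0.0, abs=1e-9)

    def test_logistic_midpoint_value(self):
        spec = synthetic.GuildSpec("r", ("A_1",), "early_riser", 1.0, 5.0, 0.01, 0.5)
        traj = synthetic.guild_trajectory(spec, [5])
        assert traj[0] == pytest.approx(0.255)

    def test_input_validation(self):
        spec = synthetic.GuildSpec("r", ("A_1",), "early_riser", 1.0, 5.0, 0.0, 0.5)
        with pytest.raises(InputError):
            synthetic.guild_trajectory(spec, [])
        with pytest.raises(InputError):
            synthetic.guild_trajectory(spec, [5, 3])
        with pytest.raises(InputError):
            synthetic.GuildSpec("bad", ("A_1",), "decliner", 1.0, 5.0, 0.1, 0.5)
        with pytest.raises(InputError):
            synthetic.GuildSpec("bad", ("A_1",), "warp", 1.0, 5.0, 0.1, 0.5)


class TestSimulateDataset:
    def test_single_taxon_gets_all_reads(self):
        cfg = synthetic.SyntheticConfig(
            days=(1, 2), replicates_per_day=2, depth=137,
            guilds=(synthetic.GuildSpec("only", ("Solo_1",), "stable",
                                        1.0, 1.0, 1.0, 1.0),),
            n_background_taxa=0, seed=1)
        ds = synthetic.simulate_dataset(cfg)
        assert (ds.counts.loc["Solo_1"] == 137).all()

    def test_row_sums_equal_depth(self, big_dataset, small_dataset):
        for ds in (big_dataset, small_dataset):
            assert (ds.counts.sum(axis=0) == ds.config.depth).all()

    def test_seeded_determinism_is_bitwise(self):
        a = synthetic.simulate_dataset(synthetic.SyntheticConfig.big_batch(seed=11))
        b = synthetic.simulate_dataset(synthetic.SyntheticConfig.big_batch(seed=11))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.stratified, b.stratified)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        c = synthetic.simulate_dataset(synthetic.SyntheticConfig.big_batch(seed=12))
        assert not a.counts.equals(c.counts)

    def test_orp_scenarios(self, big_dataset, small_dataset):
        big = big_dataset.metadata
        after_first = big[big["day"] > big["day"].min()]
        assert (after_first["orp_mV"] <= -600).all()
        small = small_dataset.metadata
        first = small[small["day"] == small["day"].min()]
        assert (first["orp_mV"] > -400).all()
        day5plus = small[small["day"] >= 5]
        assert (day5plus[day5plus["day"] <= 29]["orp_mV"] <= -598).all()

    def test_planted_signal_has_elevated_copy_number(self, big_dataset):
        truth = big_dataset.truth
        genome = big_dataset.genome_content
        reducers = truth["reducer_taxa"]
        sig_mean = genome.loc[reducers, truth["signal_functions"]].values.mean()
        bkg_mean = genome.loc[reducers, truth["background_functions"]].values.mean()
        assert sig_mean > bkg_mean

    def test_stratified_consistent_with_counts_times_genome(self, big_dataset):
        strat = big_dataset.stratified
        assert (strat["CountContributedByOTU"]
                == strat["GeneCountPerGenome"] * strat["OTUAbundanceInSample"]).all()
        # aggregating the stratified rows recovers the function table
        agg = strat.pivot_table(index="Gene", columns="Sample",
                                values="CountContributedByOTU", aggfunc="sum",
                                fill_value=0)
        ft = big_dataset.function_table
        pd.testing.assert_frame_equal(
            agg.reindex(index=ft.index, columns=ft.columns).astype(float), ft)

    def test_noiseless_sampling_matches_latent_composition(self):
        guild = synthetic.GuildSpec("pair", ("A_1", "B_1"), "stable",
                                    1.0, 1.0, 1.0, 1.0)
        cfg = synthetic.SyntheticConfig(
            days=(1,), replicates_per_day=1000, depth=100,
            guilds=(guild,), n_background_taxa=0,
            noise_dispersion=float("inf"), seed=3)
        ds = synthetic.simulate_dataset(cfg)
        props = (ds.counts / 100).mean(axis=1)
        se = np.sqrt(0.5 * 0.5 / 100 / 1000)  # multinomial SE of the mean
        assert abs(props["A_1"] - 0.5) < 3 * se

    def test_config_validation(self):
        with pytest.raises(InputError):
            synthetic.SyntheticConfig(depth=0)
        with pytest.raises(InputError):
            synthetic.SyntheticConfig(days=(3, 3))
        with pytest.raises(InputError):
            synthetic.SyntheticConfig(n_functions=5, n_signal_functions=6)
        with pytest.raises(InputError):
            synthetic.SyntheticConfig(orp_scenario="sideways")
        big = synthetic.GuildSpec("big", ("A_1",), "stable", 1.0, 1.0, 0.9, 0.9)
        big2 = synthetic.GuildSpec("big2", ("B_1",), "stable", 1.0, 1.0, 0.9, 0.9)
        with pytest.raises(InputError):
            synthetic.SyntheticConfig(guilds=(big, big2))

    def test_metadata_covers_every_sample(self, small_dataset):
        assert set(small_dataset.metadata["sample_id"]) == set(
            small_dataset.counts.columns)
        assert (small_dataset.metadata["dyeing_intensity"] >= 0).all()

    def test_intensity_gated_by_orp(self, small_dataset):
        meta = small_dataset.metadata
        gated_off = meta[meta["orp_mV"] > -550]
        gated_on = meta[(meta["orp_mV"] <= -550) & (meta["day"] >= 7)]
        assert gated_off["dyeing_intensity"].max() < gated_on["dyeing_intensity"].min()
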