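"""State-exposure accounting: conservation, counts and response offsets."""

import io

import numpy as np
import pytest

from mitosub import (
    EXCLUDED,
    build_state_table,
    empirical_tv_ts_ratio,
    extract_events,
    propagate_sequences,
    read_branch_table,
    response_offset,
    response_offsets,
)
from mitosub.branch_time import NodeTimes


def _times(mapping):
    return NodeTimes(dict(mapping), converged=True, log_likelihood=0.0)


@pytest.fixture()
def small_run(tiny_genome):
    """root -> a (T6C syn event), a -> b tip; plus event-free tip c."""
    text = (
        "parent_id\tchild_id\tis_tip\tsubstitutions\n"
        "root\ta\t0\tT6C\n"
        "a\tb\t1\t\n"
        "root\tc\t1\t\n"
    )
    tree = read_branch_table(io.StringIO(text))
    propagate_sequences(tree, tiny_genome.sequence)
    times = _times({"root": 3.0, "a": 1.0, "b": 0.0, "c": 0.0})
    return tree, times


class TestBuildStateTable:
    def test_site_without_events_has_single_row(self, tiny_genome, small_run):
        tree, times = small_run
        table = build_state_table(tree, times, tiny_genome)
        total = table.total_tree_length
        assert total == pytest.approx(6.0)  # 2 + 1 + 3
        rows9 = table.data[table.data.site == 9]
        assert len(rows9) == 1
        assert rows9.exposure.iloc[0] == pytest.approx(total)

    def test_site_with_event_splits_exposure_between_contexts(
        self, tiny_genome, small_run
    ):
        tree, times = small_run
        table = build_state_table(tree, times, tiny_genome)
        rows6 = table.data[table.data.site == 6].sort_values("exposure")
        # context GTT before the event (branch root->a and root->c),
        # context GTC after it (branch a->b)
        assert len(rows6) == 2
        assert rows6.exposure.sum() == pytest.approx(table.total_tree_length)
        assert set(rows6.codon) == {"GTT", "GTC"}
        gtt = rows6[rows6.codon == "GTT"].iloc[0]
        assert gtt.exposure == pytest.approx(5.0)  # root->a (2) + root->c (3)
        assert gtt.n_total == 1 and gtt.n_syn == 1 and gtt.n_ts == 1

    def test_exposure_conserved_per_site(self, sim_dataset):
        table = build_state_table(
            sim_dataset.tree,
            sim_dataset.true_times,
            sim_dataset.genome,
            region_class="protein_coding",
        )
        per_site = table.data.groupby("site").exposure.sum().to_numpy()
        assert np.allclose(per_site, table.total_tree_length, rtol=1e-9)

    def test_total_counts_match_extracted_events(self, sim_dataset):
        events = extract_events(sim_dataset.tree, sim_dataset.genome)
        table = build_state_table(
            sim_dataset.tree,
            sim_dataset.true_times,
            sim_dataset.genome,
            events=events,
        )
        assert table.data.n_total.sum() == len(events)
        assert (table.data.n_ts + table.data.n_tv).equals(table.data.n_total)

    def test_codon_diversity_per_site_stays_small(self, sim_dataset):
        """Per-site codon diversity is a diagnostic: most sites visit few codons."""
        table = build_state_table(
            sim_dataset.tree,
            sim_dataset.true_times,
            sim_dataset.genome,
            region_class="protein_coding",
        )
        per_site = table.data.groupby("site").codon.nunique()
        assert per_site.median() <= 4
        assert per_site.max() <= 4 ** 3  # trivially bounded by codon space

    def test_constant_rate_ratio_converges(self):
        """counts / exposure estimates the true rate (law of large numbers)."""
        from mitosub import SimulationConfig, TrueModel, simulate

        config = SimulationConfig(
            seed=8, n_tips=50, true_model=TrueModel(intercept=-3.0)
        )
        ds = simulate(config)
        table = build_state_table(ds.tree, ds.true_times, ds.genome)
        total_counts = table.data.n_total.sum()
        total_exposure = table.data.exposure.sum()
        rate = total_counts / total_exposure
        se = np.sqrt(total_counts) / total_exposure
        assert abs(rate - np.exp(-3.0)) <= 3 * se


class TestTvTsRatio:
    def test_ratio_from_counts(self, tiny_genome):
        text = (
            "parent_id\tchild_id\tis_tip\tsubstitutions\n"
            + "root\ta\t1\tT6C;G19A;G20T\n"
        )
        tree = read_branch_table(io.StringIO(text))
        propagate_sequences(tree, tiny_genome.sequence)
        events = extract_events(tree, tiny_genome)
        assert empirical_tv_ts_ratio(events) == pytest.approx(0.5)  # 1 tv / 2 ts

    def test_zero_transitions_rejected(self, tiny_genome):
        text = "parent_id\tchild_id\tis_tip\tsubstitutions\nroot\ta\t1\tG20T\n"
        tree = read_branch_table(io.StringIO(text))
        propagate_sequences(tree, tiny_genome.sequence)
        with pytest.raises(ValueError, match="no transitions"):
            empirical_tv_ts_ratio(extract_events(tree, tiny_genome))

    def test_no_transversions_gives_zero(self, tiny_genome):
        text = "parent_id\tchild_id\tis_tip\tsubstitutions\nroot\ta\t1\tT6C\n"
        tree = read_branch_table(io.StringIO(text))
        propagate_sequences(tree, tiny_genome.sequence)
        assert empirical_tv_ts_ratio(extract_events(tree, tiny_genome)) == 0.0


class TestResponseOffset:
    def test_all_mode_is_log_exposure(self):
        row = {"exposure": 2.5}
        assert response_offset(row, "all") == pytest.approx(np.log(2.5))

    def test_syn_mode_weights_possible_changes(self):
        # GTT position 3: 1 synonymous transition, 2 synonymous transversions
        row = {
            "exposure": 2.0,
            "poss_syn_ts": 1,
            "poss_syn_tv": 2,
        }
        r = 0.04551103
        expected = np.log(2.0) + np.log(1 + 2 * r)
        assert response_offset(row, "syn", r) == pytest.approx(expected)

    def test_syn_mode_excluded_when_impossible(self):
        # GTT position 1: no synonymous change possible
        row = {"exposure": 2.0, "poss_syn_ts": 0, "poss_syn_tv": 0}
        assert response_offset(row, "syn", 0.05) is EXCLUDED

    def test_negative_exposure_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            response_offset({"exposure": -1.0}, "all")

    def test_vectorized_matches_scalar(self, sim_dataset):
        table = build_state_table(
            sim_dataset.tree,
            sim_dataset.true_times,
            sim_dataset.genome,
            region_class="protein_coding",
        )
        r = 0.05
        col, offsets, mask = response_offsets(table, "syn", r)
        assert col == "n_syn"
        df = table.data
        for i in list(df.index[:50]) + list(df.index[-50:]):
            scalar = response_offset(df.loc[i], "syn", r)
            if scalar is EXCLUDED:
                assert not mask[df.index.get_loc(i)]
            else:
                assert offsets[df.index.get_loc(i)] == pytest.approx(scalar)
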