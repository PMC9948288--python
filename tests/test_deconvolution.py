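"""k-class aggregation, triage, FDR simulation, and block enrichment."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dropdel import (
    AssayModel,
    ScreenConfig,
    aggregate_hits,
    building_block_enrichment,
    enrichment_uniformity_test,
    productivity_check,
    screen_fdr_simulation,
    triage_by_k,
)
from dropdel.deconvolution import PCR_BEAD_CAP
from dropdel.errors import CorruptTableError
from dropdel.library import LibraryDesign


class TestAggregateHits:
    def test_multiplicity_counting(self, design9):
        table = aggregate_hits([0, 0, 1], design9, active_members={0})
        assert dict(zip(table["member_index"], table["k_hit"])) == {0: 2, 1: 1}
        assert table["active"].tolist() == [True, False]

    def test_all_reads_identical(self, design9):
        table = aggregate_hits([4] * 7, design9)
        assert len(table) == 1 and table.loc[0, "k_hit"] == 7
        assert (table.loc[0, "bb_cycle1"], table.loc[0, "bb_cycle2"]) == (1, 1)

    def test_empty_input(self, design9):
        table = aggregate_hits([], design9)
        assert len(table) == 0

    def test_out_of_design_member_rejected(self, design9):
        with pytest.raises(CorruptTableError):
            aggregate_hits([9], design9)

    def test_pcr_cap_warning_exactly_when_exceeded(self, design9):
        rng = np.random.default_rng(0)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            aggregate_hits(rng.integers(0, 9, PCR_BEAD_CAP), design9)
        with pytest.warns(UserWarning, match="PCR"):
            aggregate_hits(rng.integers(0, 9, PCR_BEAD_CAP + 1), design9)


class TestTriage:
    @staticmethod
    def _fig5d_style_table(design):
        # 4 authentic actives at k = 2 plus one coencapsulated inactive at k = 1
        members = [0, 0, 1, 1, 2, 2, 3, 3, 4]
        return aggregate_hits(members, design, active_members={0, 1, 2, 3})

    def test_fdr_drops_from_20_percent_to_zero(self, design9):
        table = self._fig5d_style_table(design9)
        assert triage_by_k(table, 1).fdr == pytest.approx(0.20)
        assert triage_by_k(table, 2).fdr == 0.0

    def test_all_active_rows_give_zero_fdr(self, design9):
        table = aggregate_hits([0, 1, 1], design9, active_members={0, 1})
        for k_min in (1, 2, 3):
            res = triage_by_k(table, k_min)
            assert res.fdr == 0.0 or math.isnan(res.fdr)

    def test_retained_set_shrinks_with_k_min(self, design9):
        table = self._fig5d_style_table(design9)
        sizes = [triage_by_k(table, k).n_retained for k in range(1, 5)]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 0  # k_min beyond max k_hit empties the set

    def test_k_min_below_one_rejected(self, design9):
        with pytest.raises(ValueError):
            triage_by_k(self._fig5d_style_table(design9), 0)


class TestProductivity:
    @pytest.mark.parametrize(
        "n_droplets,n_hits,productive",
        [(10**6, 32, False), (10**6, 33, True), (0, 0, False)],
    )
    def test_null_expectation_boundary(self, n_droplets, n_hits, productive):
        assert productivity_check(n_droplets, n_hits, z=4.0) is productive


class TestBlockEnrichment:
    def test_single_hit_weights(self, design9):
        table = aggregate_hits([5] * 3, design9)  # member 5 = blocks (1, 2)
        enr = building_block_enrichment(table, design9)
        w = enr.set_index(["cycle", "block"])["weight"]
        assert w[(1, 1)] == 3 and w[(2, 2)] == 3
        for cycle in (1, 2):
            assert enr.loc[enr["cycle"] == cycle, "weight"].sum() == 3

    def test_totals_match_k_hit_sum(self, design9):
        rng = np.random.default_rng(1)
        table = aggregate_hits(rng.integers(0, 9, 200), design9)
        enr = building_block_enrichment(table, design9)
        total = table["k_hit"].sum()
        for cycle in (1, 2):
            assert enr.loc[enr["cycle"] == cycle, "weight"].sum() == total

    def test_uniform_false_hits_pass_uniformity_test(self, design2000):
        rng = np.random.default_rng(2)
        table = aggregate_hits(rng.integers(0, 2000, 5000), design2000)
        enr = building_block_enrichment(table, design2000)
        for cycle in (1, 2):
            _, p = enrichment_uniformity_test(enr, cycle)
            assert p > 0.01

    def test_conserved_block_is_argmax(self, design9):
        # actives 0, 1, 2 share cycle-1 block 0
        table = aggregate_hits([0, 0, 1, 1, 2, 2, 5], design9, active_members={0, 1, 2})
        enr = building_block_enrichment(table, design9)
        cycle1 = enr[enr["cycle"] == 1].set_index("block")["weight"]
        assert cycle1.idxmax() == 0

    def test_corrupt_table_rejected(self, design9):
        table = pd.DataFrame(
            {"member_index": [99], "k_hit": [1], "bb_cycle1": [0], "bb_cycle2": [0]}
        )
        with pytest.raises(CorruptTableError):
            building_block_enrichment(table, design9)


class TestFdrSimulation:
    def test_null_screen_retained_rows_are_all_false(self, design2000):
        # no designated actives: any retained structure is a false discovery
        assay = AssayModel(mu_neg=100.0, sigma_neg=8.0)
        config = ScreenConfig(bead_occupancy=0.5, window=1000)
        curve = screen_fdr_simulation(
            design2000, 2.0, assay, config, n_droplets=20_000,
            replicates=3, seed=5, k_min_values=(1,),
        )
        row = curve.iloc[0]
        if row["n_replicates_with_hits"] > 0:
            assert row["mean_fdr"] == 1.0

    def test_strong_actives_fdr_monotone_every_replicate(
        self, design2000, strong_assay, screen_config
    ):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            curve = screen_fdr_simulation(
                design2000, 3.0, strong_assay, screen_config,
                n_droplets=60_000, replicates=5, seed=6, k_min_values=(1, 2),
            )
        fdr = dict(zip(curve["k_min"], curve["mean_fdr"]))
        assert fdr[2] <= fdr[1]

    def test_false_distinct_members_consistent_with_outlier_rate(self, design2000):
        # without actives, hit droplets are pure sorter noise; the number of
        # false hit *beads* tracks n_droplets * rate * P(droplet has a bead)
        from dropdel import encapsulate, generate_signals, rolling_sorter, sample_aliquot
        from dropdel.screen import finite_window_outlier_rate

        config = ScreenConfig(bead_occupancy=0.5, window=1000)
        assay = AssayModel(mu_neg=100.0, sigma_neg=8.0)
        n, reps, total_beads = 50_000, 6, 0
        for r in range(reps):
            aliquot = sample_aliquot(design2000, 20.0, seed=100 + r)
            stream = encapsulate(aliquot, config, n, seed=200 + r)
            stream = generate_signals(stream, assay, config, seed=300 + r)
            sort = rolling_sorter(stream, config)
            total_beads += sum(stream.bead_counts[i] for i in sort.hit_indices)
        expected = reps * (n - config.window) * finite_window_outlier_rate(4.0, 1000) * 0.5
        assert abs(total_beads - expected) <= 3 * math.sqrt(expected) + 3
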