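"""Transcription-site calling, burst size, population summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from burstlab.ts import (
    burst_size,
    call_transcription_sites,
    cell_summaries,
    population_summaries,
)


def brute_force_matching(introns, exons, max_dist=5.0):
    """Oracle: maximum-cardinality, then minimum-total-distance one-to-one matching."""
    best = (0, 0.0, [])
    n_i, n_e = len(introns), len(exons)
    for k in range(min(n_i, n_e), 0, -1):
        candidates = []
        for isub in itertools.combinations(range(n_i), k):
            for eperm in itertools.permutations(range(n_e), k):
                pairs = list(zip(isub, eperm))
                ds = [
                    np.hypot(
                        introns[i][0] - exons[j][0], introns[i][1] - exons[j][1]
                    )
                    for i, j in pairs
                ]
                if all(d <= max_dist for d in ds):
                    candidates.append((sum(ds), pairs))
        if candidates:
            total, pairs = min(candidates)
            return pairs
    return []


def table_from_points(introns, exons, cell_id=1):
    rows = []
    for x, y in introns:
        rows.append({"channel": "intron", "x": x, "y": y, "intensity": 100.0,
                     "cell_id": cell_id, "compartment": "nuclear"})
    for x, y in exons:
        rows.append({"channel": "exon", "x": x, "y": y, "intensity": 200.0,
                     "cell_id": cell_id, "compartment": "nuclear"})
    return pd.DataFrame(rows)


class TestMatching:
    def test_pair_at_exactly_five_pixels_is_a_site(self):
        spots = table_from_points([(10.0, 10.0)], [(10.0, 15.0)])
        sites = call_transcription_sites(spots)
        assert len(sites) == 1
        assert sites[0].pair_distance == pytest.approx(5.0)

    def test_pair_just_beyond_five_pixels_is_not(self):
        spots = table_from_points([(10.0, 10.0)], [(10.0, 15.01)])
        assert call_transcription_sites(spots) == []

    def test_closest_intron_wins_one_exon(self):
        # two introns at 2 px and 4 px from one exon: the 2-px intron pairs
        spots = table_from_points([(10.0, 12.0), (10.0, 14.0)], [(10.0, 10.0)])
        sites = call_transcription_sites(spots)
        oracle = brute_force_matching([(10.0, 12.0), (10.0, 14.0)], [(10.0, 10.0)])
        assert len(sites) == len(oracle) == 1
        assert (sites[0].x, sites[0].y) == (10.0, 12.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_i, n_e = rng.integers(1, 4, size=2)
        introns = [tuple(rng.uniform(0, 20, 2)) for _ in range(n_i)]
        exons = [tuple(rng.uniform(0, 20, 2)) for _ in range(n_e)]
        sites = call_transcription_sites(table_from_points(introns, exons))
        oracle = brute_force_matching(introns, exons)
        assert len(sites) == len(oracle)

    def test_matching_is_symmetric_in_channel_order(self):
        rng = np.random.default_rng(3)
        introns = [tuple(rng.uniform(0, 15, 2)) for _ in range(3)]
        exons = [tuple(rng.uniform(0, 15, 2)) for _ in range(3)]
        fwd = call_transcription_sites(table_from_points(introns, exons))
        swapped = table_from_points(exons, introns)  # channels exchanged
        rev = call_transcription_sites(swapped)
        fwd_pairs = {(round(s.pair_distance, 9)) for s in fwd}
        rev_pairs = {(round(s.pair_distance, 9)) for s in rev}
        assert fwd_pairs == rev_pairs

    def test_no_cross_cell_pairs(self):
        a = table_from_points([(10.0, 10.0)], [], cell_id=1)
        b = table_from_points([], [(10.0, 11.0)], cell_id=2)
        assert call_transcription_sites(pd.concat([a, b], ignore_index=True)) == []

    def test_empty_input(self):
        assert call_transcription_sites(pd.DataFrame()) == []


def build_cell(ts_intensity, cyto_intensities, cell_id=1):
    rows = [
        {"channel": "intron", "x": 5.0, "y": 5.0, "intensity": 50.0,
         "cell_id": cell_id, "compartment": "nuclear"},
        {"channel": "exon", "x": 5.0, "y": 5.5, "intensity": ts_intensity,
         "cell_id": cell_id, "compartment": "nuclear"},
    ]
    for i, inten in enumerate(cyto_intensities):
        rows.append({"channel": "exon", "x": 20.0 + i, "y": 20.0, "intensity": inten,
                     "cell_id": cell_id, "compartment": "cytoplasmic"})
    return pd.DataFrame(rows)


class TestBurstSize:
    def test_ratio_to_cytoplasmic_median(self):
        spots = build_cell(240.0, [110, 115, 120, 125, 130])
        sites = burst_size(call_transcription_sites(spots), spots)
        assert sites[0].nascent_count == pytest.approx(2.0)

    def test_fewer_than_five_cytoplasmic_spots_is_undefined(self):
        spots = build_cell(240.0, [110, 115, 120, 125])
        sites = burst_size(call_transcription_sites(spots), spots)
        assert sites[0].nascent_count is None

    def test_even_count_median_averages_central_values(self):
        spots = build_cell(240.0, [100, 110, 130, 140, 150, 160])
        sites = burst_size(call_transcription_sites(spots), spots)
        assert sites[0].nascent_count == pytest.approx(240.0 / 135.0)

    def test_median_is_robust_to_a_tenfold_outlier(self):
        clean = build_cell(240.0, [110, 115, 120, 125, 130])
        dirty = build_cell(240.0, [110, 115, 120, 125, 1300])
        s1 = burst_size(call_transcription_sites(clean), clean)
        s2 = burst_size(call_transcription_sites(dirty), dirty)
        assert s1[0].nascent_count == s2[0].nascent_count


class TestPopulationSummaries:
    def make_cells(self, n_ts_list):
        return pd.DataFrame(
            {
                "cell_id": range(1, len(n_ts_list) + 1),
                "n_ts": n_ts_list,
                "n_cyto_exon": 10,
                "transcribing": [n >= 1 for n in n_ts_list],
                "burst_sizes": [[2.0] * n if n else None for n in n_ts_list],
            }
        )

    def test_percent_transcribing(self):
        cells = self.make_cells([0] * 8 + [1, 2])
        assert population_summaries(cells)["percent_transcribing"] == pytest.approx(20.0)

    def test_multi_ts_cell_counts_once_and_lands_in_its_bin(self):
        cells = self.make_cells([0, 3])
        s = population_summaries(cells)
        assert s["percent_transcribing"] == pytest.approx(50.0)
        assert s["ts_count_histogram"]["3"] == pytest.approx(0.5)
        assert sum(s["ts_count_histogram"].values()) == pytest.approx(1.0)

    def test_top_bin_aggregates_five_plus(self):
        cells = self.make_cells([5, 7, 0, 1])
        s = population_summaries(cells)
        assert s["ts_count_histogram"]["5+"] == pytest.approx(0.5)

    def test_invariant_to_cell_relabeling_and_order(self):
        cells = self.make_cells([0, 1, 2, 0])
        shuffled = cells.sample(frac=1, random_state=0).assign(cell_id=[9, 5, 7, 3])
        a = population_summaries(cells)
        b = population_summaries(shuffled)
        assert a["percent_transcribing"] == b["percent_transcribing"]
        assert a["ts_count_histogram"] == b["ts_count_histogram"]

    def test_empty_cell_list_is_an_error(self):
        with pytest.raises(ValueError):
            population_summaries(pd.DataFrame(columns=["n_ts", "transcribing", "burst_sizes"]))


class TestEndToEnd:
    def test_planted_burst_size_two_is_recovered(self, smfish_field):
        from burstlab.spots import SpotDetector

        f = smfish_field
        spots = SpotDetector(psf_sigma=f.spec.psf_sigma).detect_field(
            f.exon, f.intron, f.nucleus_mask, f.cytoplasm_mask
        )
        sites = burst_size(call_transcription_sites(spots), spots)
        cells = cell_summaries(spots, sites)
        s = population_summaries(cells)
        assert 1.8 <= s["median_burst_size"] <= 2.2
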