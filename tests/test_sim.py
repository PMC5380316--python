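"""Tests of the synthetic-data generators: mosaics, WF evolution, panels,
call noise, and IBD cohorts."""

import numpy as np
import pytest
from scipy import stats

import admixtime as at
from admixtime.sim import IBD_STATES, truth_call_table
from admixtime.tracks import haploid_fractions


# ---------------------------------------------------------------------------
# pulse mosaics
# ---------------------------------------------------------------------------

class TestPulseTracks:
    def test_tracks_tile_chromosomes_exactly(self, small_map):
        model = at.PulseModel({"A": 0.3, "B": 0.7}, t=20)
        for tr in at.simulate_pulse_tracks(small_map, model, 10, seed=0):
            tr.validate(small_map)  # raises on gaps/overlaps
            for chrom, L in small_map.lengths_cm.items():
                lengths = np.diff(np.concatenate([[0.0],
                                                  tr.chrom_ends[chrom]]))
                assert abs(lengths.sum() - L) < 1e-9

    def test_single_source_gives_one_segment_per_chromosome(self, small_map):
        model = at.PulseModel({"A": 1.0}, t=30)
        for tr in at.simulate_pulse_tracks(small_map, model, 3, seed=1):
            for chrom in small_map.chromosomes:
                assert len(tr.chrom_ends[chrom]) == 1
                assert tr.label_set[tr.chrom_labels[chrom][0]] == "A"
            assert tr.fraction("A") == 1.0

    def test_mosaic_piece_length_matches_exponential_mean(self,
                                                          long_chromosome_map):
        # raw pieces (before run merging) are exponential(rate G/100);
        # the final piece of each chromosome is truncated, so drop it
        model = at.PulseModel({"A": 0.5, "B": 0.5}, t=30)
        tracks = at.simulate_pulse_tracks(long_chromosome_map, model, 80,
                                          seed=2)
        pieces = np.concatenate([
            np.diff(np.concatenate([[0.0], tr.chrom_ends["1"]]))[:-1]
            for tr in tracks])
        assert pieces.size > 1e4
        se = pieces.std() / np.sqrt(pieces.size)
        assert abs(pieces.mean() - 100 / 30) < 2 * se

    @pytest.mark.parametrize("q", [0.3, 0.5, 0.7])
    @pytest.mark.parametrize("t", [10, 30, 60])
    def test_minor_run_length_law(self, long_chromosome_map, q, t):
        """Maximal B-runs are exponential with rate q*t per Morgan.

        The z band is 3 sigma per cell so the family-wise false-alarm rate
        of the seeded nine-cell grid stays near 1%.
        """
        model = at.PulseModel({"A": q, "B": 1 - q}, t=t)
        tracks = at.simulate_pulse_tracks(long_chromosome_map, model, 30,
                                          seed=100 * t + int(100 * q))
        res = [tr.run_lengths("B", with_censoring=True) for tr in tracks]
        runs = np.concatenate([r[0] for r in res])
        n_complete = int(np.concatenate([r[1] for r in res]).sum())
        est = at.mean_run_length(tracks, "B")  # censoring-aware
        expect = 100.0 / (q * t)
        se = est / np.sqrt(n_complete)  # delta method for total/complete
        assert abs(est - expect) < 3 * se

    def test_rejects_bad_parameters(self, small_map):
        with pytest.raises(ValueError, match="positive"):
            at.PulseModel({"A": 0.5, "B": 0.5}, t=0)
        with pytest.raises(ValueError, match="empty"):
            at.PulseModel({}, t=10)
        with pytest.raises(ValueError, match="sum"):
            at.PulseModel({"A": 0.5, "B": 0.2}, t=10)

    def test_same_seed_bit_identical(self, small_map):
        model = at.PulseModel({"A": 0.4, "B": 0.6}, t=25)
        a = at.simulate_pulse_tracks(small_map, model, 6, seed=7)
        b = at.simulate_pulse_tracks(small_map, model, 6, seed=7)
        for ta, tb in zip(a, b):
            for chrom in small_map.chromosomes:
                np.testing.assert_array_equal(ta.chrom_ends[chrom],
                                              tb.chrom_ends[chrom])
                np.testing.assert_array_equal(ta.chrom_labels[chrom],
                                              tb.chrom_labels[chrom])


class TestPairDiploid:
    def test_two_tracks_form_the_unique_pair(self, small_map):
        model = at.PulseModel({"A": 0.5, "B": 0.5}, t=30)
        tr = at.simulate_pulse_tracks(small_map, model, 2, seed=0)
        pairs = at.pair_diploid(tr, seed=0)
        assert len(pairs) == 1
        assert {p.hap_id for p in pairs[0]} == {"hap0", "hap1"}

    def test_every_track_used_exactly_once(self, small_map):
        model = at.PulseModel({"A": 0.5, "B": 0.5}, t=30)
        tr = at.simulate_pulse_tracks(small_map, model, 12, seed=0)
        pairs = at.pair_diploid(tr, seed=3)
        ids = [p.hap_id for pair in pairs for p in pair]
        assert sorted(ids) == sorted(t.hap_id for t in tr)

    def test_odd_count_rejected(self, small_map):
        model = at.PulseModel({"A": 0.5, "B": 0.5}, t=30)
        tr = at.simulate_pulse_tracks(small_map, model, 3, seed=0)
        with pytest.raises(ValueError, match="odd"):
            at.pair_diploid(tr, seed=0)

    def test_fixed_seed_reproducible(self, small_map):
        model = at.PulseModel({"A": 0.5, "B": 0.5}, t=30)
        tr = at.simulate_pulse_tracks(small_map, model, 8, seed=0)
        p1 = at.pair_diploid(tr, seed=11)
        p2 = at.pair_diploid(tr, seed=11)
        assert [(a.hap_id, b.hap_id) for a, b in p1] == \
               [(a.hap_id, b.hap_id) for a, b in p2]


class TestPainting:
    def _panels(self, gmap, constant: dict[str, int]):
        data = {lab: at.HaplotypeMatrix(
            gmap=gmap,
            data={c: np.full((5, gmap.positions_cm[c].size), v, dtype=np.uint8)
                  for c in gmap.chromosomes},
            hap_ids=[f"{lab}{i}" for i in range(5)])
            for lab, v in constant.items()}
        return data

    def test_identical_panel_haplotypes_dominate(self, small_map):
        panels = self._panels(small_map, {"A": 1, "B": 1})
        model = at.PulseModel({"A": 0.5, "B": 0.5}, t=30)
        tracks = at.simulate_pulse_tracks(small_map, model, 4, seed=0)
        hm = at.paint_haplotypes(tracks, panels, small_map, seed=0)
        for c in small_map.chromosomes:
            assert np.all(hm.data[c] == 1)

    def test_fully_diverged_panels_reproduce_track_labels(self, small_map):
        panels = self._panels(small_map, {"A": 0, "B": 1})
        model = at.PulseModel({"A": 0.5, "B": 0.5}, t=30)
        tracks = at.simulate_pulse_tracks(small_map, model, 6, seed=1)
        hm = at.paint_haplotypes(tracks, panels, small_map, seed=0)
        truth = truth_call_table(tracks, small_map)
        for c in small_map.chromosomes:
            np.testing.assert_array_equal(hm.data[c],
                                          truth.calls[c].astype(np.uint8))

    def test_zero_snp_segment_is_harmless(self):
        gmap = at.GeneticMap(lengths_cm={"1": 10.0},
                             positions_cm={"1": np.array([8.0, 9.0])})
        tr = at.AncestryTrack(
            hap_id="h", label_set=("A", "B"),
            chrom_ends={"1": np.array([0.5, 10.0])},
            chrom_labels={"1": np.array([1, 0], dtype=np.int8)})
        panels = self._panels(gmap, {"A": 0, "B": 1})
        hm = at.paint_haplotypes([tr], panels, gmap, seed=0)
        np.testing.assert_array_equal(hm.data["1"][0], [0, 0])

    def test_missing_panel_rejected(self, small_map):
        model = at.PulseModel({"A": 0.5, "B": 0.5}, t=30)
        tracks = at.simulate_pulse_tracks(small_map, model, 2, seed=0)
        with pytest.raises(ValueError, match="panel"):
            at.paint_haplotypes(tracks, self._panels(small_map, {"A": 0}),
                                small_map, seed=0)


# ---------------------------------------------------------------------------
# Wright--Fisher
# ---------------------------------------------------------------------------

class TestWrightFisher:
    def test_pure_source_stays_pure(self):
        tracks = at.simulate_wf_markov(N=20, q=1.0, L=1.0, t=5, seed=0)
        assert all(tr.fraction("A") == 1.0 for tr in tracks)

    def test_breakpoint_rate_one_per_morgan(self):
        # after one generation, visible ancestry switches occur at rate
        # L * 2q(1-q) per chromosome (a Poisson(L) breakpoint is visible
        # when the two donor parents carry different labels)
        L, q, N = 2.0, 0.5, 1000
        tracks = at.simulate_wf_markov(N=N, q=q, L=L, t=1, seed=3)
        frac_a = np.mean([tr.chrom_labels["1"][0] == 0 for tr in tracks])
        switches = np.array([len(tr.chrom_ends["1"]) - 1 for tr in tracks])
        p = np.mean([tr.fraction("A") for tr in tracks])
        expect = L * 2 * p * (1 - p)
        se = switches.std() / np.sqrt(switches.size)
        assert abs(switches.mean() - expect) < 2 * se + 3 * L / (2 * N)

    def test_variance_matches_closed_form_at_large_n(self):
        # N = 2500 as in the forward-simulation check of the density's
        # variance formula (t reduced for runtime; h = tL = 20)
        q, L, t = 0.5, 2.0, 10
        tracks = at.simulate_wf_markov(N=2500, q=q, L=L, t=t, seed=5)
        x = np.array([tr.fraction("A") for tr in tracks])
        var_expect = at.ancestry_moments(q, t, L)[1]
        se_var = var_expect * np.sqrt(2.0 / (x.size - 1))
        assert abs(x.var(ddof=1) - var_expect) < 2 * se_var

    def test_precondition_validation(self):
        with pytest.raises(ValueError):
            at.simulate_wf_markov(N=0, q=0.5, L=1.0, t=5, seed=0)
        with pytest.raises(ValueError):
            at.simulate_wf_markov(N=10, q=0.5, L=1.0, t=0, seed=0)


class TestTwoWaveSimulator:
    def test_mu_zero_reduces_to_single_pulse(self):
        """With no second wave the B-run lengths match the plain WF pulse
        at t1.  Runs within one finite population share a genealogy, so the
        two-sample test operates on replicate-population mean run lengths
        (independent units), alpha = 0.01."""
        L, t1, reps = 2.0, 25, 8
        means1, means2 = [], []
        for r in range(reps):
            base = at.simulate_wf_markov(N=60, q=0.5, L=L, t=t1,
                                         seed=2100 + r)
            two = at.simulate_two_wave(
                60, at.TwoWaveModel(q=0.5, t1=t1, mu=0.0, t2=10), L=L,
                seed=2200 + r)
            means1.append(at.mean_run_length(base, "B"))
            means2.append(at.mean_run_length(two, "B"))
        assert stats.ttest_ind(means1, means2).pvalue > 0.01

    def test_unrepresentable_wave_warns(self):
        with pytest.warns(UserWarning, match="unrepresentable"):
            at.simulate_two_wave(
                5, at.TwoWaveModel(q=0.5, t1=10, mu=0.01, t2=5), L=0.5,
                seed=0)

    def test_event_ordering_enforced(self):
        with pytest.raises(ValueError, match="t2 < t1"):
            at.TwoWaveModel(q=0.5, t1=10, mu=0.2, t2=15)


# ---------------------------------------------------------------------------
# LAI-call degradation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cohort(small_map):
    model = at.PulseModel({"EU": 0.5, "ME": 0.5}, t=30)
    return at.simulate_pulse_tracks(small_map, model, 40, seed=8)


class TestDegradeCalls:
    def test_perfect_accuracy_is_identity(self, cohort, small_map):
        calls, stats_ = at.degrade_ancestry_calls(cohort, small_map, 1.0,
                                                  seed=0)
        truth = truth_call_table(cohort, small_map)
        assert calls.accuracy_vs(truth) == 1.0
        assert stats_["inflation"] == 1.0

    def test_target_70pct_realized(self, cohort, small_map):
        calls, stats_ = at.degrade_ancestry_calls(cohort, small_map, 0.70,
                                                  seed=1)
        truth = truth_call_table(cohort, small_map)
        acc = calls.accuracy_vs(truth)
        assert 0.68 <= acc <= 0.72
        assert stats_["inflation"] > 1.0  # block errors lengthen runs

    def test_half_accuracy_destroys_information(self, cohort, small_map):
        calls, _ = at.degrade_ancestry_calls(cohort, small_map, 0.5, seed=2)
        truth = truth_call_table(cohort, small_map)
        joint = np.zeros((2, 2))
        for c in calls.calls:
            for a in range(2):
                for b in range(2):
                    joint[a, b] += np.sum((truth.calls[c] == a)
                                          & (calls.calls[c] == b))
        joint /= joint.sum()
        px, py = joint.sum(1), joint.sum(0)
        mi = float(np.nansum(joint * np.log(joint / np.outer(px, py))))
        assert mi < 5e-3

    def test_out_of_range_accuracy_rejected(self, cohort, small_map):
        with pytest.raises(ValueError):
            at.degrade_ancestry_calls(cohort, small_map, 0.3, seed=0)


# ---------------------------------------------------------------------------
# reference panels
# ---------------------------------------------------------------------------

class TestReferencePanels:
    def test_frequencies_bounded(self, small_map):
        _, freqs = at.synth_reference_panels(
            small_map, 20, {"A": 0.01, "B": 0.05}, seed=0)
        for p in freqs.values():
            assert np.all((p >= 0) & (p <= 1))

    def test_drift_targets_pairwise_fst(self):
        gmap = at.GeneticMap.uniform({"1": 100.0}, snps_per_cm=200.0)
        panels, _ = at.synth_reference_panels(
            gmap, 100, {"A": 0.01, "B": 0.01}, seed=1)
        fst = at.hudson_fst(panels["A"].stacked().mean(0),
                            panels["B"].stacked().mean(0), 100, 100)
        assert 0.007 <= fst <= 0.013

    def test_vanishing_drift_gives_vanishing_fst(self):
        gmap = at.GeneticMap.uniform({"1": 100.0}, snps_per_cm=1000.0)
        panels, _ = at.synth_reference_panels(
            gmap, 100, {"A": 1e-5, "B": 1e-5}, seed=2)
        fst = at.hudson_fst(panels["A"].stacked().mean(0),
                            panels["B"].stacked().mean(0), 100, 100)
        assert abs(fst) < 1e-3

    def test_invalid_drift_rejected(self, small_map):
        with pytest.raises(ValueError, match="drift"):
            at.synth_reference_panels(small_map, 5, {"A": 0.0}, seed=0)


# ---------------------------------------------------------------------------
# IBD cohorts
# ---------------------------------------------------------------------------

class TestIBDCohort:
    def test_degenerate_all_hom_eu(self):
        df, _ = at.synth_ibd_cohort(500, f_eu=1.0, p_eu=1.0, lam=1.0, seed=0)
        assert (df["state1"] == 0).all() and (df["state2"] == 0).all()

    def test_true_ibd_never_occupies_opposite_hom_corner(self):
        df, _ = at.synth_ibd_cohort(20000, f_eu=0.4, p_eu=0.5, lam=1.0,
                                    seed=1)
        corner = ((df.state1 == 0) & (df.state2 == 2)) | \
                 ((df.state1 == 2) & (df.state2 == 0))
        assert corner.sum() == 0

    def test_cell_proportions_follow_the_mixture(self):
        lam, f, p = 0.65, 0.42, 0.53
        df, _ = at.synth_ibd_cohort(100_000, f_eu=f, p_eu=p, lam=lam, seed=2)
        A = np.zeros((3, 3))
        np.add.at(A, (df.state1.to_numpy(), df.state2.to_numpy()),
                  df.length_cm.to_numpy())
        A /= A.sum()
        expect = lam * at.ibd_matrix(f, p) + (1 - lam) * at.rand_matrix(p)
        assert np.max(np.abs(A - expect)) < 0.01

    def test_invalid_length_distribution_rejected(self):
        with pytest.raises(ValueError, match="length"):
            at.synth_ibd_cohort(10, f_eu=0.5, p_eu=0.5, lam=0.5, seed=0,
                                length_range_cm=(0.0, 0.0))
        assert IBD_STATES == ("hom-EU", "het", "hom-ME")


# ---------------------------------------------------------------------------
# cross-cutting
# ---------------------------------------------------------------------------

def test_haploid_fraction_sums_to_one_over_labels(pulse_tracks_5050):
    eu = haploid_fractions(pulse_tracks_5050, "EU")
    me = haploid_fractions(pulse_tracks_5050, "ME")
    np.testing.assert_allclose(eu + me, 1.0, atol=1e-12)
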