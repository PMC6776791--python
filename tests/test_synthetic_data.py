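"""Generator contracts: determinism, planted-truth consistency, and the
statistical structure the downstream stages rely on."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy import stats
from skimage.morphology import disk

import crevalid as cv
from crevalid.synthetic_data import PlacementError, nucleus_core_mask


class TestFishImage:
    def test_empty_scene_is_noise_only(self):
        image, truth = cv.simulate_fish_image(
            n_cells=0, background_rate=0.0, image_shape=(128, 128), seed=0
        )
        assert truth.n_cells == 0
        for probe in truth.coexpression_spec.probes:
            chan = image.channels[probe]
            assert len(truth.puncta[probe]) == 0
            # offset * gradient + Gaussian noise only: nothing spot-like
            assert chan.max() < 6.0 * 1.25 + 6 * 4.0

    def test_seeded_determinism(self):
        a_img, a_truth = cv.simulate_fish_image(n_cells=50, seed=7,
                                                image_shape=(512, 512))
        b_img, b_truth = cv.simulate_fish_image(n_cells=50, seed=7,
                                                image_shape=(512, 512))
        for name in a_img.channels:
            np.testing.assert_array_equal(a_img.channels[name],
                                          b_img.channels[name])
        assert a_truth.per_cell_counts.equals(b_truth.per_cell_counts)
        np.testing.assert_array_equal(a_truth.nucleus_centers,
                                      b_truth.nucleus_centers)

    def test_conditional_positivity_within_binomial_ci(self):
        """P(cre+ | target+) of planted states falls in the exact binomial
        99% CI around the specified 0.8 at n=100 cells."""
        spec = cv.CoexpressionSpec.from_rates(p_target=0.5, consistency=0.8,
                                              specificity=0.9)
        _, truth = cv.simulate_fish_image(
            n_cells=100, image_shape=(900, 900), coexpression_spec=spec,
            seed=1,
        )
        pos = truth.positivity
        n_t = int(pos["Drd1a"].sum())
        k = int((pos["Drd1a"] & pos["iCre"]).sum())
        lo, hi = stats.binom.interval(0.99, n_t, 0.8)
        assert lo <= k <= hi

    def test_marginals_converge_at_n2000(self):
        """Planted joint-state frequencies match the spec within 3 SE."""
        spec = cv.CoexpressionSpec.from_rates()
        _, truth = cv.simulate_fish_image(
            n_cells=2000, image_shape=(4096, 4096), coexpression_spec=spec,
            noise_sd=0.0, background_rate=0.0, seed=3,
        )
        pos = truth.positivity.to_numpy().astype(int)
        n = len(pos)
        for state, p in spec.joint.items():
            emp = np.mean((pos == np.array(state)).all(axis=1))
            se = np.sqrt(p * (1 - p) / n)
            assert abs(emp - p) <= 3 * se + 1e-12

    def test_truth_recount_reproduces_per_cell_counts(self, small_scene):
        """Planted puncta inside each planted dilated footprint equal the
        truth table exactly, and background puncta lie outside all."""
        _, truth = small_scene
        shape = (640, 640)
        core = np.zeros(shape, dtype=np.int32)
        for i, ((r0, c0), (a, b), ang) in enumerate(
            zip(truth.nucleus_centers, truth.nucleus_axes,
                truth.nucleus_angles), start=1,
        ):
            rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
            from crevalid.synthetic_data import _elliptical_radius_sq

            core[_elliptical_radius_sq(rr, cc, (r0, c0), (a, b), ang) <= 1] = i
        any_dilated = ndi.binary_dilation(core > 0,
                                          structure=disk(truth.dilation_radius))
        for probe in truth.coexpression_spec.probes:
            table = truth.puncta[probe]
            for cell_id, group in table.groupby("cell"):
                rows = np.rint(group["row"]).astype(int)
                cols = np.rint(group["col"]).astype(int)
                if cell_id == -1:
                    assert not any_dilated[rows, cols].any()
                    continue
                footprint = ndi.binary_dilation(
                    core == cell_id + 1, structure=disk(truth.dilation_radius)
                )
                assert footprint[rows, cols].all()
                assert len(group) == truth.per_cell_counts.loc[cell_id, probe]

    def test_impossible_placement_raises(self):
        with pytest.raises(PlacementError):
            cv.simulate_fish_image(n_cells=200, image_shape=(128, 128), seed=0)

    def test_joint_probabilities_validated(self):
        with pytest.raises(ValueError):
            cv.CoexpressionSpec(joint={(0, 0, 0): 0.5})


@pytest.fixture(scope="module")
def genome():
    return cv.simulate_genome({"chr1": 120_000, "chr2": 80_000}, seed=9)


class TestInsertionReads:
    def test_no_support_means_no_cassette_mates(self, genome):
        truth = cv.InsertionTruth(
            genome=genome, cassette_name="iCre_cassette",
            insertion_contig="chr1", insertion_pos=60_000,
            n_supporting_pairs=0,
        )
        records = cv.simulate_insertion_reads(truth, coverage_pairs=50, seed=1)
        assert not any(r.contig == "iCre_cassette" for r in records)

    def test_exact_support_count_and_proximity(self, genome):
        truth = cv.InsertionTruth(
            genome=genome, cassette_name="iCre_cassette",
            insertion_contig="chr1", insertion_pos=60_000,
            n_supporting_pairs=24, fragment_size=500,
        )
        records = cv.simulate_insertion_reads(truth, coverage_pairs=100, seed=2)
        cassette_ids = {r.read_id for r in records if r.contig == "iCre_cassette"}
        assert len(cassette_ids) == 24
        genome_mates = [r for r in records
                        if r.read_id in cassette_ids and r.contig == "chr1"]
        assert len(genome_mates) == 24
        assert all(abs(r.pos - 60_000) <= 500 for r in genome_mates)

    def test_two_insertions_form_disjoint_groups(self, genome):
        t1 = cv.InsertionTruth(genome=genome, cassette_name="iCre_cassette",
                               insertion_contig="chr1", insertion_pos=30_000,
                               n_supporting_pairs=8)
        t2 = cv.InsertionTruth(genome=genome, cassette_name="iCre_cassette",
                               insertion_contig="chr2", insertion_pos=40_000,
                               n_supporting_pairs=5)
        records = cv.simulate_insertion_reads([t1, t2], coverage_pairs=30,
                                              seed=3)
        cassette_ids = {r.read_id for r in records
                        if r.contig == "iCre_cassette"}
        mates = [r for r in records
                 if r.read_id in cassette_ids and r.contig != "iCre_cassette"]
        by_contig = {c: [m.pos for m in mates if m.contig == c]
                     for c in ("chr1", "chr2")}
        assert len(by_contig["chr1"]) == 8
        assert len(by_contig["chr2"]) == 5
        assert all(abs(p - 30_000) <= 500 for p in by_contig["chr1"])
        assert all(abs(p - 40_000) <= 500 for p in by_contig["chr2"])

    def test_missing_cassette_contig_errors(self):
        with pytest.raises(ValueError, match="cassette"):
            cv.InsertionTruth(
                genome={"chr1": "ACGT" * 100}, cassette_name="iCre_cassette",
                insertion_contig="chr1", insertion_pos=10,
            )

    def test_read_length_must_fit_fragment(self, genome):
        truth = cv.InsertionTruth(
            genome=genome, cassette_name="iCre_cassette",
            insertion_contig="chr1", insertion_pos=60_000, fragment_size=120,
        )
        with pytest.raises(ValueError, match="fragment"):
            cv.simulate_insertion_reads(truth, read_length=150, seed=0)


class TestOptoUnits:
    def test_zero_reliability_behaves_like_untagged(self):
        units, truth = cv.simulate_opto_units(
            n_tagged=1, n_untagged=0, reliability=0.0, n_pulses=60, seed=4
        )
        unit = units[0]
        stims = unit.all_stim_times()
        # no systematic 10-ms evoked excess beyond Poisson expectation
        w = 0.010
        hits = sum(
            np.any((unit.spike_times >= t) & (unit.spike_times < t + w))
            for t in stims
        )
        expected = len(stims) * (1 - np.exp(-truth.baseline_rate_hz * w))
        assert hits <= stats.binom.interval(0.999, len(stims),
                                            1 - np.exp(-5 * w))[1]
        assert hits >= 0 and expected < len(stims)

    def test_full_reliability_every_pulse_answered(self):
        units, _ = cv.simulate_opto_units(
            n_tagged=1, n_untagged=0, reliability=1.0, latency=2.0,
            n_pulses=120, baseline_rate=0.0, seed=5,
        )
        unit = units[0]
        for onsets in unit.stim_blocks.values():
            for t in onsets:
                d = unit.spike_times - t
                d = d[(d >= 0) & (d < 0.01)]
                assert len(d) >= 1
                assert abs(d[0] * 1000 - 2.0) < 2.0  # 2 ms +- jitter

    def test_untagged_count_in_poisson_ci(self):
        units, _ = cv.simulate_opto_units(
            n_tagged=0, n_untagged=1, baseline_rate=5.0, n_pulses=120, seed=6
        )
        unit = units[0]
        lam = 5.0 * unit.session_duration
        lo, hi = stats.poisson.interval(0.99, lam)
        assert lo <= len(unit.spike_times) <= hi

    def test_waveform_shapes_consistent(self):
        units, _ = cv.simulate_opto_units(n_tagged=1, n_untagged=1,
                                          n_pulses=30, seed=7)
        for u in units:
            assert u.spike_waveforms.shape[0] == len(u.spike_times)
            assert u.spike_waveforms.shape[1:] == u.session_waveform.shape

    def test_invalid_reliability_rejected(self):
        with pytest.raises(ValueError):
            cv.simulate_opto_units(reliability=1.5, seed=0)
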