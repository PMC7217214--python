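"""PCR simulator: annealing statistics, conservation, curve phenomenology."""

from dataclasses import replace

import numpy as np
import pytest

from poolpcr.duplex import DuplexKind
from poolpcr.fixtures import s1, x_n
from poolpcr.library import design_code_set
from poolpcr.simulate import (
    PoolState,
    SimConfig,
    Trajectory,
    anneal_step,
    ct_shift_series,
    detect_turning_point,
    extend_step,
    pairing_from_code_set,
    pairing_from_library,
    simulate,
)

PRIMER0 = 50e-9


def fresh_state(strands=1e-9, primers=PRIMER0):
    return PoolState(
        cycle=0,
        primer_a_conc=primers,
        primer_b_conc=primers,
        sense_strand_conc=strands,
        antisense_strand_conc=strands,
        duplex_classes={},
    )


class TestAnnealStep:
    def test_strand_and_primer_totals_unchanged(self):
        state = fresh_state()
        out = anneal_step(state, x_n(20), SimConfig())
        assert out.sense_strand_conc == state.sense_strand_conc
        assert out.primer_b_conc == state.primer_b_conc
        sense_bound = sum(
            c for (kind, _l, _m), c in out.duplex_classes.items()
            if kind in (DuplexKind.PRIMER_TEMPLATE_SENSE, DuplexKind.MATCHED_FULL,
                        DuplexKind.MISMATCHED_FULL)
        )
        assert sense_bound == pytest.approx(state.sense_strand_conc)

    def test_diversity_one_pairs_all_strands_matched(self):
        out = anneal_step(fresh_state(), s1(), SimConfig())
        assert not any(
            kind is DuplexKind.MISMATCHED_FULL
            for (kind, _l, _m) in out.duplex_classes
        )

    def test_ten_member_code_set_matched_probability_is_one_tenth(self):
        codes = design_code_set(10, 20, 16, seed=2)
        model = pairing_from_code_set(codes)
        out = anneal_step(fresh_state(), model, SimConfig(reequilibration_bias=0.0))
        matched = sum(
            c for (kind, _l, _m), c in out.duplex_classes.items()
            if kind is DuplexKind.MATCHED_FULL
        )
        mismatched = sum(
            c for (kind, _l, _m), c in out.duplex_classes.items()
            if kind is DuplexKind.MISMATCHED_FULL
        )
        assert matched / (matched + mismatched) == pytest.approx(0.1)

    def test_late_cycle_mismatch_law_matches_library_distribution(self):
        # with primers gone, pairings are strand-strand with m distributed
        # as the distinct-pair law of the library
        from poolpcr.library import mismatch_distribution

        state = fresh_state(strands=50e-9, primers=0.0)
        out = anneal_step(state, x_n(20), SimConfig())
        dist = mismatch_distribution(x_n(20), distinct_members=True)
        total = sum(
            c for (kind, _l, _m), c in out.duplex_classes.items()
            if kind is DuplexKind.MISMATCHED_FULL
        )
        for (kind, _l, m), conc in out.duplex_classes.items():
            if kind is DuplexKind.MISMATCHED_FULL:
                assert conc / total == pytest.approx(
                    dist.pmf[m] / (1 - 1 / 4**20), rel=1e-9
                )


class TestExtendStep:
    def test_no_hybrids_changes_nothing(self):
        state = fresh_state()
        state.duplex_classes = {(DuplexKind.MATCHED_FULL, "", 0): 1e-9}
        out = extend_step(state, SimConfig())
        assert out.primer_a_conc == state.primer_a_conc
        assert out.sense_strand_conc == state.sense_strand_conc

    def test_extension_consumes_primer_one_for_one(self):
        state = anneal_step(fresh_state(), x_n(20), SimConfig())
        out = extend_step(state, SimConfig())
        assert state.primer_b_conc - out.primer_b_conc == pytest.approx(
            out.antisense_strand_conc - state.antisense_strand_conc
        )


class TestTrajectoryInvariants:
    def test_primer_concentrations_never_increase(self, ladder_specs):
        traj = simulate(ladder_specs["X_12"], SimConfig())
        assert np.all(np.diff(traj.primer_a) <= 1e-18)
        assert np.all(np.diff(traj.primer_b) <= 1e-18)

    def test_conservation_primers_consumed_equal_strands_created(self, s1_spec):
        config = SimConfig()
        traj = simulate(s1_spec, config)
        final = traj.final_state
        created = final.sense_strand_conc - config.initial_template_conc
        consumed = config.primer_conc - final.primer_a_conc
        assert created == pytest.approx(consumed, rel=1e-12)

    def test_single_sequence_pool_f_stays_one(self, s1_spec):
        traj = simulate(s1_spec, SimConfig())
        assert np.allclose(traj.pool_f, 1.0)

    def test_single_sequence_curve_is_monotone_with_unit_plateau(self, s1_spec):
        traj = simulate(s1_spec, SimConfig())
        assert np.all(np.diff(traj.fluorescence) >= -1e-12)
        assert traj.fluorescence[-1] == pytest.approx(1.0, abs=1e-6)

    def test_strand_count_doubles_per_cycle_at_full_efficiency(self, s1_spec):
        config = SimConfig(
            cycles=5, extension_efficiency=1.0, initial_template_conc=1e-13
        )
        traj = simulate(s1_spec, config)
        final = traj.final_state
        assert final.sense_strand_conc == pytest.approx(1e-13 * 2**5, rel=1e-3)

    def test_primer_exhaustion_stops_synthesis(self, s1_spec):
        traj = simulate(s1_spec, SimConfig(cycles=45))
        final = traj.final_state
        assert final.primer_a_conc < 1e-4 * PRIMER0
        # matched output is capped by initial primers + template
        assert final.sense_strand_conc <= PRIMER0 + 100e-12 + 1e-15

    def test_deterministic_mode_is_bit_reproducible(self, ladder_specs):
        a = simulate(ladder_specs["X_16"], SimConfig())
        b = simulate(ladder_specs["X_16"], SimConfig())
        assert np.array_equal(a.fluorescence, b.fluorescence)


class TestCurvePhenomenology:
    def test_high_diversity_curve_rises_then_collapses(self, ladder_specs):
        traj = simulate(ladder_specs["X_20"], SimConfig())
        peak = traj.fluorescence.argmax()
        assert 0 < peak < traj.fluorescence.size - 1
        assert traj.fluorescence[-1] < 0.2 * traj.fluorescence[peak]

    def test_endpoint_ordering_along_diversity_ladder(self, ladder_specs):
        ends = [
            simulate(ladder_specs[f"X_{n}"], SimConfig()).fluorescence[-1]
            for n in range(2, 21, 2)
        ]
        assert all(a >= b for a, b in zip(ends, ends[1:]))

    def test_pool_f_declines_only_after_reshuffling_dominates(self, ladder_specs):
        traj = simulate(ladder_specs["X_20"], SimConfig())
        turning = detect_turning_point(traj)
        assert turning is not None
        consumed = 1 - traj.primer_a / PRIMER0
        growth_start = int(traj.cycle[consumed > 0.01][0])
        exhaustion = int(traj.cycle[consumed > 0.99][0])
        assert growth_start <= turning <= exhaustion
        # F is non-increasing once primers are gone, and ends well below 1
        after = traj.pool_f[exhaustion:]
        assert np.all(np.diff(after) <= 1e-12)
        assert traj.pool_f[-1] < 0.3

    def test_no_turning_point_without_diversity(self, s1_spec):
        traj = simulate(s1_spec, SimConfig())
        assert detect_turning_point(traj) is None

    def test_no_turning_point_on_constant_f(self):
        n = 11
        flat = Trajectory(
            cycle=np.arange(n, dtype=float),
            fluorescence=np.linspace(0, 1, n),
            pool_f=np.full(n, 0.7),
            primer_a=np.zeros(n),
            primer_b=np.zeros(n),
            matched_conc=np.zeros(n),
            mismatched_conc=np.zeros(n),
            aggregate_mass=np.zeros(n),
        )
        assert detect_turning_point(flat) is None


class TestConcentrationSeries:
    def test_higher_concentration_gives_smaller_ct(self, ladder_specs):
        series = ct_shift_series(ladder_specs["X_20"], [1e-12, 1e-10])
        assert series[0][1] > series[1][1]

    def test_identical_concentrations_give_identical_ct(self, s1_spec):
        series = ct_shift_series(s1_spec, [1e-10, 1e-10])
        assert series[0][1] == series[1][1]

    def test_ct_spacing_constant_per_decade(self, ladder_specs):
        series = ct_shift_series(
            ladder_specs["X_20"], [1e-13, 1e-12, 1e-11, 1e-10, 1e-9]
        )
        cts = np.array([ct for _, ct in series])
        spacing = np.diff(cts)
        assert np.abs(spacing - spacing.mean()).max() < 0.15 * abs(spacing.mean())


class TestFiniteCopyMode:
    def test_reproducible_by_seed(self, ladder_specs):
        config = SimConfig(mode="finite_copy", seed=4, cycles=20)
        a = simulate(ladder_specs["X_10"], config)
        b = simulate(ladder_specs["X_10"], config)
        assert np.array_equal(a.fluorescence, b.fluorescence)

    def test_converges_to_deterministic_with_copy_number(self, ladder_specs):
        spec = ladder_specs["X_10"]
        det = simulate(spec, SimConfig(cycles=25))
        deviations = []
        for copies in (200, 200_000):
            traj = simulate(
                spec, SimConfig(cycles=25, mode="finite_copy", seed=8,
                                initial_copies=copies)
            )
            deviations.append(np.abs(traj.fluorescence - det.fluorescence).max())
        assert deviations[1] < deviations[0]
        assert deviations[1] < 0.02

    def test_requires_seed(self):
        with pytest.raises(ValueError):
            SimConfig(mode="finite_copy")


class TestNetworkExtension:
    def test_flag_off_keeps_unit_length_only(self, ladder_specs):
        traj = simulate(ladder_specs["X_20"], SimConfig(cycles=45))
        assert np.all(traj.aggregate_mass == 0)

    def test_single_sequence_never_forms_networks(self, s1_spec):
        traj = simulate(s1_spec, SimConfig(cycles=45, network_extension=True))
        assert traj.aggregate_mass[-1] == 0

    def test_diverse_pool_grows_heavy_tailed_lengths(self, ladder_specs):
        traj = simulate(
            ladder_specs["X_20"], SimConfig(cycles=45, network_extension=True)
        )
        pmf = traj.final_state.length_pmf
        assert pmf is not None
        assert pmf[2] > 0 and pmf[3] > 0 and pmf[4] > 0
        assert traj.aggregate_mass[-1] > 0
        # fluorescence reoccurs late as interwoven networks accumulate dye
        assert traj.fluorescence[-1] > traj.fluorescence[-10]

    def test_sixteen_position_library_also_aggregates(self, ladder_specs):
        traj = simulate(
            ladder_specs["X_16"], SimConfig(cycles=45, network_extension=True)
        )
        assert traj.aggregate_mass[-1] > 0
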