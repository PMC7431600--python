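"""Trace reduction: normalization, stimulated-diameter averaging, the
zero-truncation rule, inclusion criteria, and per-group pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasoconduct import (apply_inclusion_criteria, build_profile, pool_group,
                         relative_constriction, resting_diameter,
                         stimulation_diameter, truncate_profile)
from vasoconduct.synthetic import VesselRecording
from vasoconduct.traces import (CRITERION_LOCAL, CRITERION_POSITIONS,
                                CRITERION_RECOVERY)

from conftest import make_params
from vasoconduct import generate_vessel


def recording_from_grid(diameters, positions=None, times=None, phases=None,
                        vessel_id="v1", group="G"):
    diameters = np.asarray(diameters, float)
    n_pos, n_t = diameters.shape
    if positions is None:
        positions = 50.0 * np.arange(n_pos)
    if times is None:
        times = 10.0 * np.arange(1, n_t + 1)
    if phases is None:
        phases = tuple(["baseline"] * 3 + ["stimulation"] * 3
                       + ["recovery"] * (n_t - 6))
    return VesselRecording(vessel_id=vessel_id, group_label=group,
                           positions=positions, times=times,
                           phases=phases, diameters=diameters)


class TestDiameters:
    def test_resting_diameter_is_baseline_mean(self):
        row = [19.0, 20.0, 21.0, 15.0, 15.0, 15.0, 18.0, 19.0, 20.0]
        rec = recording_from_grid([row])
        assert resting_diameter(rec, 0.0) == pytest.approx(20.0)

    def test_resting_diameter_missing_position_errors(self, noiseless_vessel):
        with pytest.raises(KeyError):
            resting_diameter(noiseless_vessel, 25.0)

    def test_stimulation_diameter_averages_the_three_samples(self):
        row = [20.0, 20.0, 20.0, 16.0, 15.0, 14.0, 19.0, 20.0, 20.0]
        rec = recording_from_grid([row])
        assert stimulation_diameter(rec, 0.0) == pytest.approx(15.0)

    def test_stimulation_diameter_missing_sample_errors(self):
        # only two stimulation-phase samples recorded
        row = [20.0, 20.0, 20.0, 16.0, 15.0]
        rec = recording_from_grid([row], phases=("baseline",) * 3
                                  + ("stimulation",) * 2)
        with pytest.raises(ValueError, match="missing stimulation sample"):
            stimulation_diameter(rec, 0.0)


class TestRelativeConstriction:
    @pytest.mark.parametrize("rest,stim,expected", [
        (20.0, 16.0, 0.20),
        (28.7, 28.7, 0.0),
        (20.0, 22.0, -0.10),
    ])
    def test_examples(self, rest, stim, expected):
        assert relative_constriction(rest, stim) == pytest.approx(expected)

    def test_nonpositive_rest_rejected(self):
        with pytest.raises(ValueError):
            relative_constriction(0.0, 10.0)

    @given(d=st.floats(1.0, 100.0), c=st.floats(-0.5, 0.99))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip_recovers_the_fraction(self, d, c):
        assert relative_constriction(d, d * (1 - c)) == pytest.approx(c, abs=1e-12)


class TestTruncation:
    @pytest.mark.parametrize("values,expected,index", [
        ([0.20, 0.10, -0.02, 0.05], [0.20, 0.10, 0.0, 0.0], 2),
        ([0.20, 0.10, 0.05], [0.20, 0.10, 0.05], None),
        ([-0.01, 0.10, 0.05], [0.0, 0.0, 0.0], 0),
    ])
    def test_rule(self, values, expected, index):
        out, k = truncate_profile(values)
        assert np.array_equal(out, expected)
        assert k == index

    @given(st.lists(st.floats(-0.3, 0.5, allow_nan=False), min_size=1,
                    max_size=12))
    @settings(derandomize=True, max_examples=100)
    def test_idempotent_and_prefix_preserving(self, values):
        once, k = truncate_profile(values)
        twice, k2 = truncate_profile(once)
        assert np.array_equal(once, twice)
        if k is not None:
            assert np.array_equal(once[:k], np.asarray(values)[:k])
            assert np.all(once[k:] == 0.0)


class TestBuildProfile:
    def test_noiseless_round_trip(self, protocol):
        params = make_params(true_local_constriction=0.26,
                             true_length_constant=263.0)
        rec = generate_vessel(params, protocol, seed=2)
        prof = build_profile(rec)
        expected = 0.26 * np.exp(-prof.distances / 263.0)
        assert np.allclose(prof.constriction, expected, atol=1e-12)
        assert prof.truncated_from is None

    def test_null_effect_profile_is_zero(self, protocol):
        rec = generate_vessel(make_params(true_local_constriction=0.0),
                              protocol, seed=2)
        prof = build_profile(rec)
        assert np.all(prof.constriction == 0.0)
        assert prof.truncated_from == 0

    def test_profile_length_matches_positions(self, noiseless_vessel):
        prof = build_profile(noiseless_vessel)
        assert prof.distances.shape == noiseless_vessel.positions.shape


class TestInclusion:
    def _decide(self, protocol, **overrides):
        rec = generate_vessel(make_params(**overrides), protocol, seed=4)
        prof = build_profile(rec)
        return apply_inclusion_criteria(prof, rec)

    def test_weak_local_response_excluded(self, protocol):
        d = self._decide(protocol, true_local_constriction=0.04)
        assert not d.included
        assert set(d.failed_criteria) == {CRITERION_LOCAL}
        assert d.failed_criteria[CRITERION_LOCAL] == pytest.approx(0.04, abs=1e-9)

    def test_poor_recovery_excluded(self, protocol):
        # recovery_tau far longer than the recovery window keeps the vessel
        # constricted at ~40% of baseline after stimulation ends
        d = self._decide(protocol, true_local_constriction=0.60,
                         recovery_tau=1e6)
        assert not d.included
        assert set(d.failed_criteria) == {CRITERION_RECOVERY}

    def test_too_few_positions_excluded(self, protocol):
        d = self._decide(protocol, traceable_length_min=50.0,
                         traceable_length_max=50.0)
        assert not d.included
        assert set(d.failed_criteria) == {CRITERION_POSITIONS}
        assert d.failed_criteria[CRITERION_POSITIONS] == 2.0

    def test_healthy_vessel_included(self, protocol):
        d = self._decide(protocol, true_local_constriction=0.20)
        assert d.included and not d.failed_criteria


class TestPooling:
    def test_per_distance_summary(self, protocol):
        profs = [build_profile(generate_vessel(
            make_params(true_local_constriction=c, traceable_length_min=200.0,
                        traceable_length_max=200.0), protocol, seed=i))
            for i, c in enumerate([0.2, 0.3])]
        pooled = pool_group(profs, "test")
        row0 = pooled.per_distance[pooled.per_distance.distance_um == 0.0]
        assert row0["mean"].iloc[0] == pytest.approx(0.25)
        assert row0["sem"].iloc[0] == pytest.approx(0.05)
        assert row0["n"].iloc[0] == 2

    def test_single_vessel_distance_has_no_sem(self, protocol):
        profs = [build_profile(generate_vessel(
            make_params(traceable_length_min=l, traceable_length_max=l),
            protocol, seed=i)) for i, l in enumerate([100.0, 200.0])]
        pooled = pool_group(profs, "test")
        far = pooled.per_distance[pooled.per_distance.distance_um == 200.0]
        assert far["n"].iloc[0] == 1
        assert np.isnan(far["sem"].iloc[0])

    def test_counts_non_increasing_with_distance(self, protocol):
        params = make_params(n_vessels=8, traceable_length_min=100.0,
                             traceable_length_max=400.0)
        from vasoconduct import generate_cohort
        profs = [build_profile(r)
                 for r in generate_cohort([params], protocol, seed=77)]
        pooled = pool_group(profs, "test")
        counts = pooled.per_distance.sort_values("distance_um")["n"].to_numpy()
        assert np.all(np.diff(counts) <= 0)

    def test_pooled_mean_matches_direct_enumeration(self, protocol):
        params = make_params(n_vessels=5, vasomotion_sd=0.5,
                             measurement_noise_sd=0.3)
        from vasoconduct import generate_cohort
        profs = [build_profile(r)
                 for r in generate_cohort([params], protocol, seed=13)]
        pooled = pool_group(profs, "test")
        for _, row in pooled.per_distance.iterrows():
            direct = [p.constriction[list(p.distances).index(row.distance_um)]
                      for p in profs if row.distance_um in p.distances]
            assert row["mean"] == pytest.approx(np.mean(direct))
            assert row["n"] == len(direct)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pool_group([], "empty")

    def test_label_mismatch_rejected(self, protocol, noiseless_vessel):
        prof = build_profile(noiseless_vessel)
        with pytest.raises(ValueError, match="belongs to"):
            pool_group([prof], "other-group")
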