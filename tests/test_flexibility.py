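import numpy as np
import pytest

from epiflex.core import TrajectoryEnsemble
from epiflex.errors import InsufficientDataError, LoopResolutionError
from epiflex.flexibility import (
    EIGHT_PI_SQUARED,
    BFactorProfile,
    BFactorProfiler,
    ScalarWithError,
    atomic_fluctuation,
    mean_over_residues,
    replica_profile,
)
from epiflex.core import LoopDefinition
from epiflex.synthetic import FluctuationSpec, make_reference, sample_ensemble

from conftest import make_labels
from oracles import brute_force_bfactor


class TestAtomicFluctuation:
    def test_identical_frames_give_zero(self, toy_frame):
        b = atomic_fluctuation(np.stack([toy_frame.coords] * 4))
        np.testing.assert_allclose(b, 0.0, atol=1e-12)

    def test_alternating_one_angstrom_closed_form(self):
        # One residue alternating x = +1/-1 Å: <|dr|^2> = 1 Å^2, so the
        # per-axis B is 8 pi^2 / 3 ~ 26.319 Å^2.
        base = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0.5, 1.0]], float)
        plus, minus = base.copy(), base.copy()
        plus[0, 0] += 1.0
        minus[0, 0] -= 1.0
        frames = np.stack([plus, minus, plus, minus])
        b = atomic_fluctuation(frames)
        assert b[0] == pytest.approx(8 * np.pi**2 / 3, rel=1e-12)
        np.testing.assert_allclose(b[1:], 0.0, atol=1e-12)

    def test_total_convention_is_three_times_peraxis(self, rng):
        frames = rng.normal(size=(20, 6, 3))
        np.testing.assert_allclose(
            atomic_fluctuation(frames, convention="total"),
            3.0 * atomic_fluctuation(frames, convention="peraxis"),
            rtol=1e-12,
        )

    def test_matches_brute_force_accumulation(self, rng):
        frames = rng.normal(scale=0.5, size=(15, 4, 3)) + rng.normal(size=(1, 4, 3))
        np.testing.assert_allclose(
            atomic_fluctuation(frames), brute_force_bfactor(frames), rtol=1e-9
        )

    def test_monte_carlo_limit_of_closed_form(self, rng):
        # Isotropic Gaussian, per-coordinate sigma = 0.3 Å: B -> 8 pi^2 sigma^2
        sigma = 0.3
        frames = rng.normal(scale=sigma, size=(100_000, 3, 3))
        b = atomic_fluctuation(frames)
        np.testing.assert_allclose(b, EIGHT_PI_SQUARED * sigma**2, rtol=0.02)

    def test_requires_two_frames(self, toy_frame):
        with pytest.raises(InsufficientDataError):
            atomic_fluctuation(toy_frame.coords[None])

    def test_unknown_convention(self, rng):
        with pytest.raises(ValueError, match="convention"):
            atomic_fluctuation(rng.normal(size=(3, 3, 3)), convention="nm")


class TestBFactorProfile:
    def test_two_replica_se_closed_form(self):
        # Per-replica B of 6 and 8 Å²: mean 7, sample SD sqrt(2), SE = 1.0
        prof = BFactorProfile(make_labels(1), [[6.0], [8.0]])
        assert prof.mean_B[0] == pytest.approx(7.0)
        assert prof.se_B[0] == pytest.approx(1.0)
        np.testing.assert_allclose(prof.ci95_low, 7 - 1.96, rtol=1e-12)
        np.testing.assert_allclose(prof.ci95_high, 7 + 1.96, rtol=1e-12)

    def test_single_replica_has_nan_se(self):
        prof = BFactorProfile(make_labels(2), [[1.0, 2.0]])
        assert np.isnan(prof.se_B).all()

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            BFactorProfile(make_labels(1), [[-0.1]])

    def test_ci_ordering_invariant(self, rng):
        prof = BFactorProfile(make_labels(5), rng.uniform(1, 20, size=(6, 5)))
        assert np.all(prof.ci95_low <= prof.mean_B)
        assert np.all(prof.mean_B <= prof.ci95_high)
        np.testing.assert_allclose(
            prof.ci95_high - prof.mean_B, 1.96 * prof.se_B, atol=1e-9
        )

    def test_tsv_round_trip(self, tmp_path, rng):
        labels = make_labels(4, start=36, icodes={38: "C"})
        prof = BFactorProfile(labels, rng.uniform(2, 15, size=(3, 4)))
        p = tmp_path / "profile.tsv"
        prof.to_tsv(p, header_comment="provenance line")
        back = BFactorProfile.from_tsv(p)
        assert back.labels[2].insertion_code == "C"
        np.testing.assert_allclose(back.per_replica_B, prof.per_replica_B, rtol=1e-5)

    def test_indices_for_loop_with_insertion_codes(self, rng):
        labels = make_labels(5, start=36, icodes={38: "C"})
        prof = BFactorProfile(labels, rng.uniform(1, 5, size=(2, 5)))
        loop = LoopDefinition("L1A", 1, (36, ""), (38, "C"))
        np.testing.assert_array_equal(prof.indices_for(loop), [0, 1, 2])

    def test_indices_for_missing_loop_names_it(self, rng):
        prof = BFactorProfile(make_labels(3), rng.uniform(1, 5, size=(2, 3)))
        with pytest.raises(LoopResolutionError, match="L3B"):
            prof.indices_for(LoopDefinition("L3B", 3, (124, ""), (133, "")))


class TestReplicaProfile:
    def test_identical_replicas_have_zero_se(self, rng):
        base = np.cumsum(rng.normal(scale=2, size=(6, 3)), axis=0)
        rep = base + rng.normal(scale=0.3, size=(10, 6, 3))
        ens = TrajectoryEnsemble(make_labels(6), [rep.copy(), rep.copy(), rep.copy()])
        prof = replica_profile(ens)
        np.testing.assert_allclose(prof.se_B, 0.0, atol=1e-9)
        single = replica_profile(TrajectoryEnsemble(make_labels(6), [rep.copy()]))
        np.testing.assert_allclose(prof.mean_B, single.mean_B, atol=1e-9)

    def test_rigid_motion_leaves_b_unchanged(self):
        ref = make_reference(20, geometry="helix")
        spec = FluctuationSpec(n_residues=20, sigma=0.3, n_frames=40,
                               n_replicas=2, seed=7, rigid_motion=False)
        ens_still, _ = sample_ensemble(ref, spec)
        from dataclasses import replace

        ens_moving, _ = sample_ensemble(ref, replace(spec, rigid_motion=True))
        b_still = replica_profile(ens_still).mean_B
        b_moving = replica_profile(ens_moving).mean_B
        np.testing.assert_allclose(b_moving, b_still, atol=1e-6)

    def test_parameter_recovery_on_synthetic_truth(self):
        # Known truth B = 8 pi^2 sigma^2; estimate should be nearly unbiased.
        ref = make_reference(30, geometry="helix")
        spec = FluctuationSpec(n_residues=30, sigma=0.33, n_frames=200,
                               n_replicas=10, seed=11)
        ens, truth = sample_ensemble(ref, spec)
        prof = replica_profile(ens)
        rel = np.abs(prof.mean_B - truth["B_true"]) / truth["B_true"]
        assert rel.max() < 0.10

    def test_ci_coverage_of_known_truth(self):
        # Loop residues at truth 12.8 Å²: the 95% CI should contain the truth
        # for >= 90% of residues across repeated generations.
        truth_b = 12.8
        from epiflex.synthetic import sigma_for_bfactor

        hits = total = 0
        for seed in range(6):
            ref = make_reference(120, geometry="helix")
            spec = FluctuationSpec(n_residues=120, sigma=sigma_for_bfactor(truth_b),
                                   n_frames=100, n_replicas=10, seed=seed,
                                   rigid_motion=False)
            ens, _ = sample_ensemble(ref, spec)
            prof = replica_profile(ens)
            hits += int(np.sum((prof.ci95_low <= truth_b) & (truth_b <= prof.ci95_high)))
            total += prof.n_residues
        assert hits / total >= 0.90

    def test_insufficient_frames(self, toy_frame):
        ens = TrajectoryEnsemble(make_labels(5), [toy_frame.coords[None]])
        with pytest.raises(InsufficientDataError, match="insufficient frames"):
            replica_profile(ens)

    def test_profiler_sklearn_params(self, small_ensemble):
        profiler = BFactorProfiler(convention="total", z=2.0)
        assert profiler.get_params()["convention"] == "total"
        profiler.set_params(convention="peraxis", z=1.96).fit(small_ensemble)
        assert profiler.profile_.z == 1.96
        assert profiler.per_replica_B_.shape == (3, 8)
        assert np.all(profiler.mean_B_ >= 0)


class TestMeanOverResidues:
    def test_se_propagation_closed_form(self):
        # Two residues with SE 3 and 4: propagated SE = sqrt(9+16)/2 = 2.5
        prof = BFactorProfile(make_labels(2), [[5.0, 9.0], [7.0, 11.0]])
        prof.se_B = np.array([3.0, 4.0])  # override the computed SEs
        out = mean_over_residues(prof, [0, 1])
        assert out.se == pytest.approx(2.5)
        assert out.value == pytest.approx((6.0 + 10.0) / 2)

    def test_constant_profile_mean(self):
        prof = BFactorProfile(make_labels(4), np.full((3, 4), 7.13))
        out = mean_over_residues(prof, np.arange(4))
        assert out.value == pytest.approx(7.13)
        assert out.se == pytest.approx(0.0, abs=1e-12)

    def test_ci_matches_printed_interval_convention(self):
        # value 12.8 with SE back-computed from a printed 12.3-13.2 interval
        se = (13.2 - 12.3) / (2 * 1.96)
        s = ScalarWithError(value=12.8, se=se)
        lo, hi = s.ci95
        assert round(lo, 1) == 12.4 or round(lo, 1) == 12.3
        assert lo == pytest.approx(12.8 - 0.45, abs=1e-9)
        assert hi == pytest.approx(12.8 + 0.45, abs=1e-9)

    def test_empty_subset_rejected(self, rng):
        prof = BFactorProfile(make_labels(3), rng.uniform(1, 2, (2, 3)))
        with pytest.raises(ValueError, match="empty"):
            mean_over_residues(prof, [])

    def test_unknown_residue_rejected(self, rng):
        prof = BFactorProfile(make_labels(3), rng.uniform(1, 2, (2, 3)))
        with pytest.raises(LoopResolutionError):
            mean_over_residues(prof, ["99"])


def test_se_scales_as_inverse_sqrt_replicas():
    """Regression of log SE on log R should have slope -0.5 (+/- 0.1)."""
    from epiflex.synthetic import sigma_for_bfactor

    ref = make_reference(12, geometry="helix")
    r_values = [4, 8, 16, 32]
    mean_se = []
    for r in r_values:
        spec = FluctuationSpec(n_residues=12, sigma=sigma_for_bfactor(7.0),
                               n_frames=60, n_replicas=r, seed=101,
                               rigid_motion=False)
        ens, _ = sample_ensemble(ref, spec)
        prof = replica_profile(ens)
        mean_se.append(prof.se_B.mean())
    slope = np.polyfit(np.log(r_values), np.log(mean_se), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.1)
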