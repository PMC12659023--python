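import numpy as np
import pytest

from poreflux import (
    CurrentTrace,
    FlowEstimate,
    ParticleTable,
    SpeciesSpec,
    SyntheticSpec,
    Trajectory,
    block_error,
    generate,
    replica_aggregate,
    selectivity_indicator,
    species_currents,
    water_flux,
    windowed_current,
)
from poreflux.flux import AmbiguousDisplacementError
from poreflux.units import E_PER_PS_TO_NA


def brute_force_current_na(coords_z, charges, lz, tau):
    """Independent oracle: loop-and-sum charge-weighted displacements.

    Assumes unwrapped z coordinates saved once per tau.
    """
    out = []
    for k in range(len(coords_z) - 1):
        total = 0.0
        for i, q in enumerate(charges):
            total += q * (coords_z[k + 1][i] - coords_z[k][i])
        out.append(total / (tau * lz) * E_PER_PS_TO_NA)
    return out


def make_traj(z_frames, lz=100.0, dt=20.0, wrapped=False):
    z = np.asarray(z_frames, dtype=float)
    n_frames, n = z.shape
    coords = np.zeros((n_frames, n, 3))
    coords[:, :, 2] = z
    coords[:, :, 0] = 10.0
    coords[:, :, 1] = 10.0
    return Trajectory(
        coords=coords,
        box=np.tile([lz, lz, lz], (n_frames, 1)),
        times=np.arange(n_frames) * dt,
        wrapped=wrapped,
    )


def table(species, charges):
    return ParticleTable(
        ids=np.arange(len(species)),
        species=np.array(species, dtype=object),
        charge=np.array(charges, dtype=float),
    )


class TestWindowedCurrent:
    def test_static_particles_zero(self):
        traj = make_traj([[50.0, 60.0]] * 4)
        trace = windowed_current(traj, table(["cation", "anion"], [1, -1]), 20.0)
        assert np.all(trace.values == 0)

    def test_hand_evaluated_window(self):
        # +1 e moves +1 Å, −1 e moves −1 Å in one 20 ps window, Lz = 100 Å
        traj = make_traj([[50.0, 60.0], [51.0, 59.0]])
        trace = windowed_current(traj, table(["cation", "anion"], [1, -1]), 20.0)
        expected = 0.001 * E_PER_PS_TO_NA  # 0.1602176634 nA
        assert trace.values[0] == pytest.approx(expected, rel=1e-12)
        assert trace.values[0] == pytest.approx(0.1602176634, rel=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        z = rng.normal(50.0, 5.0, size=(6, 7))
        charges = rng.choice([-1.0, 1.0], size=7)
        species = ["cation" if q > 0 else "anion" for q in charges]
        traj = make_traj(z)
        trace = windowed_current(traj, table(species, charges), 20.0)
        oracle = brute_force_current_na(z, charges, 100.0, 20.0)
        assert np.allclose(trace.values, oracle, rtol=1e-12)

    def test_minimum_image_boundary_crossing(self):
        # z: 99 → 1 in a 100 Å box is +2 Å, not −98 Å
        wrapped = make_traj([[99.0], [1.0]], wrapped=True)
        unwrapped = make_traj([[99.0], [101.0]], wrapped=False)
        p = table(["cation"], [1.0])
        tw = windowed_current(wrapped, p, 20.0)
        tu = windowed_current(unwrapped, p, 20.0)
        assert tw.values[0] == tu.values[0]
        assert tw.values[0] == pytest.approx(2.0 / 2000.0 * E_PER_PS_TO_NA)

    def test_tau_must_be_commensurate(self):
        traj = make_traj([[50.0], [51.0], [52.0]])
        with pytest.raises(ValueError, match="multiple"):
            windowed_current(traj, table(["cation"], [1.0]), 30.0)

    def test_tau_stride_sums_subwindow_displacements(self):
        z = [[0.0], [30.0], [60.0]]  # 30 Å per frame would min-image wrongly at tau=40
        unwrapped = make_traj(z, wrapped=False)
        wrapped = make_traj(np.mod(z, 100.0), wrapped=True)
        p = table(["cation"], [1.0])
        tu = windowed_current(unwrapped, p, 40.0)
        tw = windowed_current(wrapped, p, 40.0)
        assert tu.values[0] == tw.values[0]
        assert tu.values[0] == pytest.approx(60.0 / (40.0 * 100.0) * E_PER_PS_TO_NA)

    def test_half_box_displacement_is_ambiguous(self):
        traj = make_traj([[10.0], [60.0]], wrapped=True)
        with pytest.raises(AmbiguousDisplacementError):
            windowed_current(traj, table(["cation"], [1.0]), 20.0)

    def test_empty_species_warns_and_zeros(self):
        traj = make_traj([[50.0], [51.0]])
        with pytest.warns(UserWarning, match="no particles"):
            trace = windowed_current(traj, table(["cation"], [1.0]), 20.0, "anion")
        assert np.all(trace.values == 0)


class TestSpeciesCurrents:
    def test_water_only_gives_zero_ion_traces(self):
        traj = make_traj([[50.0, 60.0], [51.0, 61.0]])
        p = table(["water_oxygen", "water_oxygen"], [0.0, 0.0])
        traces = species_currents(traj, p, 20.0)
        assert np.all(traces["cation"].values == 0)
        assert np.all(traces["anion"].values == 0)

    def test_conservation_identity(self, drift_run):
        traces = species_currents(drift_run.trajectory, drift_run.particles, 20.0)
        total = traces["cation"].values + traces["anion"].values
        assert np.allclose(traces["all"].values, total, rtol=1e-12, atol=1e-12)

    def test_constant_drift_closed_form(self):
        # 50 ions each at v = ±0.01 Å/ps, q = ±1, Lz = 100 → 0.801 nA/species
        spec = SyntheticSpec(
            box=(50.0, 50.0, 100.0),
            species=(
                SpeciesSpec("K", "cation", 50, 1.0, v=0.01, diffusion=0.04),
                SpeciesSpec("Cl", "anion", 50, -1.0, v=-0.01, diffusion=0.04),
            ),
            duration=10_000.0,
            seed=21,
        )
        run = generate(spec)
        expected = 50 * 0.01 / 100.0 * E_PER_PS_TO_NA  # 0.8011 nA
        assert run.truth.expected_current_nA["K"] == pytest.approx(expected)
        traces = species_currents(run.trajectory, run.particles, 20.0)
        for sp in ("cation", "anion"):
            est = block_error(traces[sp], 1000.0)
            assert abs(est.mean - expected) < 3 * est.error


class TestWaterFlux:
    def test_static_water_zero(self):
        traj = make_traj([[50.0, 60.0]] * 3)
        p = table(["water_oxygen", "water_oxygen"], [0.0, 0.0])
        assert np.all(water_flux(traj, p, 20.0).values == 0)

    def test_hand_evaluated_flux(self):
        # 100 waters each +1 Å per 20 ps window, Lz = 100 → 50 molecules/ns
        z0 = np.full(100, 40.0)
        traj = make_traj([z0, z0 + 1.0])
        p = table(["water_oxygen"] * 100, [0.0] * 100)
        trace = water_flux(traj, p, 20.0)
        assert trace.units == "molecules/ns"
        assert trace.values[0] == pytest.approx(50.0, rel=1e-12)

    def test_drift_diffusion_flux_within_3se(self):
        # N·v/Lz = 1000·0.002/100 = 2e-2 /ps = 20 molecules/ns
        spec = SyntheticSpec(
            box=(80.0, 80.0, 100.0),
            species=(
                SpeciesSpec("w", "water_oxygen", 1000, 0.0, v=0.002, diffusion=0.02),
            ),
            duration=8000.0,
            seed=3,
        )
        run = generate(spec)
        assert run.truth.expected_water_flux == pytest.approx(20.0)
        est = block_error(water_flux(run.trajectory, run.particles, 20.0), 800.0)
        assert abs(est.mean - 20.0) < 3 * est.error

    def test_no_water_raises(self):
        traj = make_traj([[50.0], [51.0]])
        with pytest.raises(ValueError, match="water_oxygen"):
            water_flux(traj, table(["cation"], [1.0]), 20.0)


class TestBlockError:
    def test_constant_trace_zero_error(self):
        trace = CurrentTrace(
            times=np.arange(10) * 20.0, values=np.full(10, 3.3), species="all", tau=20.0
        )
        est = block_error(trace, 100.0)
        assert est.error == 0.0
        assert est.mean == pytest.approx(3.3)

    def test_discard_drops_initial_windows(self):
        values = np.concatenate([np.full(5, 100.0), np.full(20, 1.0)])
        trace = CurrentTrace(
            times=np.arange(25) * 20.0, values=values, species="all", tau=20.0
        )
        est = block_error(trace, 100.0, discard=100.0)
        assert est.mean == pytest.approx(1.0)
        assert est.discard == 100.0

    def test_too_few_blocks_raises(self):
        trace = CurrentTrace(
            times=np.arange(5) * 20.0, values=np.ones(5), species="all", tau=20.0
        )
        with pytest.raises(ValueError, match="blocks"):
            block_error(trace, 100.0)

    def test_incomplete_trailing_block_dropped(self):
        # 25 windows, 10-window blocks → 2 complete blocks
        trace = CurrentTrace(
            times=np.arange(25) * 20.0,
            values=np.arange(25.0),
            species="all",
            tau=20.0,
        )
        est = block_error(trace, 200.0)
        assert est.n == 2
        bm = [np.mean(np.arange(0, 10.0)), np.mean(np.arange(10, 20.0))]
        assert est.error == pytest.approx(np.std(bm, ddof=1) / np.sqrt(2))

    def test_iid_gaussian_matches_analytic_sem(self):
        # mean of the block-error estimate over seeds ≈ σ/√(M·B)
        sigma, m, b = 2.0, 10, 20
        rng = np.random.default_rng(17)
        errs = []
        for _ in range(200):
            values = rng.normal(0.0, sigma, m * b)
            trace = CurrentTrace(
                times=np.arange(m * b) * 20.0, values=values, species="all", tau=20.0
            )
            errs.append(block_error(trace, m * 20.0).error)
        analytic = sigma / np.sqrt(m * b)
        assert np.mean(errs) == pytest.approx(analytic, rel=0.05)

    def test_ar1_block_error_exceeds_naive_sem(self):
        rng = np.random.default_rng(23)
        phi, n = 0.9, 800
        wins = 0
        for _ in range(100):
            eps = rng.normal(size=n)
            x = np.empty(n)
            x[0] = eps[0]
            for i in range(1, n):
                x[i] = phi * x[i - 1] + eps[i]
            trace = CurrentTrace(
                times=np.arange(n) * 20.0, values=x, species="all", tau=20.0
            )
            blocked = block_error(trace, 40 * 20.0).error
            naive = np.std(x, ddof=1) / np.sqrt(n)
            wins += blocked > naive
        assert wins >= 95


class TestReplicaAggregate:
    def test_identical_replicas_zero_error(self):
        ests = [FlowEstimate(mean=1.5, error=0.2, n=4) for _ in range(5)]
        agg = replica_aggregate(ests)
        assert agg.mean == pytest.approx(1.5)
        assert agg.error == 0.0
        assert agg.n == 5

    def test_three_replica_arithmetic(self):
        ests = [FlowEstimate(mean=m, error=0.1, n=4) for m in (1.0, 2.0, 3.0)]
        agg = replica_aggregate(ests)
        assert agg.mean == pytest.approx(2.0)
        assert agg.error == pytest.approx(1.0 / np.sqrt(3.0))

    def test_single_replica_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="single replica"):
            agg = replica_aggregate([FlowEstimate(mean=1.0, error=0.3, n=4)])
        assert agg.error == 0.3
        assert agg.n == 1

    def test_synthetic_replicas_recover_truth(self, drift_spec):
        from dataclasses import replace

        ests = []
        truth = None
        for seed in range(10):
            run = generate(replace(drift_spec, seed=seed, duration=4000.0))
            truth = run.truth.expected_total_current_nA
            trace = windowed_current(run.trajectory, run.particles, 20.0)
            ests.append(block_error(trace, 400.0))
        agg = replica_aggregate(ests)
        assert abs(agg.mean - truth) < 3 * agg.error


class TestSelectivity:
    def test_equal_currents_zero_difference(self):
        a = FlowEstimate(mean=1.0, error=0.1, n=3)
        s = selectivity_indicator(a, FlowEstimate(mean=1.0, error=0.1, n=3))
        assert s.difference == 0.0

    def test_quadrature_propagation(self):
        s = selectivity_indicator(
            FlowEstimate(mean=2.0, error=0.1, n=3),
            FlowEstimate(mean=1.0, error=0.1, n=3),
        )
        assert s.difference == pytest.approx(1.0)
        assert s.difference_error == pytest.approx(np.sqrt(0.02), rel=1e-9)
        assert s.ratio_reliable

    def test_negligible_anion_flags_ratio(self):
        s = selectivity_indicator(
            FlowEstimate(mean=2.0, error=0.1, n=3),
            FlowEstimate(mean=0.01, error=0.05, n=3),
        )
        assert not s.ratio_reliable


class TestInvariants:
    def test_telescoping_identity(self, drift_run):
        traj = drift_run.trajectory_unwrapped
        trace = windowed_current(traj, drift_run.particles, 20.0)
        ions = drift_run.particles.mask(("cation", "anion"))
        q = drift_run.particles.charge[ions]
        dz_total = traj.coords[-1, ions, 2] - traj.coords[0, ions, 2]
        lz = traj.box[0, 2]
        expected = (q @ dz_total) / (traj.duration * lz) * E_PER_PS_TO_NA
        assert trace.values.mean() == pytest.approx(expected, rel=1e-10)

    def test_wrap_equivalence_bitwise(self, drift_run):
        tw = windowed_current(drift_run.trajectory, drift_run.particles, 20.0)
        tu = windowed_current(drift_run.trajectory_unwrapped, drift_run.particles, 20.0)
        assert np.array_equal(tw.values, tu.values)

    def test_field_antisymmetry(self, drift_spec):
        from dataclasses import replace

        flipped = replace(
            drift_spec,
            species=tuple(
                replace(sp, v=-sp.v) for sp in drift_spec.species
            ),
        )
        run_p = generate(drift_spec)
        run_m = generate(flipped)
        assert run_m.truth.expected_total_current_nA == pytest.approx(
            -run_p.truth.expected_total_current_nA
        )
        tp = windowed_current(run_p.trajectory, run_p.particles, 20.0)
        tm = windowed_current(run_m.trajectory, run_m.particles, 20.0)
        # same noise stream, opposite drift: means differ by twice the truth
        assert tp.values.mean() - tm.values.mean() == pytest.approx(
            2 * run_p.truth.expected_total_current_nA, rel=0.35
        )
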