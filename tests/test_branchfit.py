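"""Scatter building, robust reference line, and the branch-distance statistic."""

import math

import numpy as np
import pandas as pd
import pytest

from hybridsnv import kras
from hybridsnv.branchfit import (
    InsufficientDataError,
    ScatterData,
    branch_distances,
    build_scatter,
    fit_reference_line,
)
from hybridsnv.probeset import HybridSNVError
from hybridsnv.simulate import SampleSpec, SimulationConfig, noise_free, simulate_array
from hybridsnv.thermo import PenaltyTable


def diagonal_scatter(n=400, noise_sd=0.0, elevated_fraction=0.0, shift=1.5, seed=0):
    """Synthetic scatter with points on the identity line in log-log space."""
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(1.0, 11.0, n))
    y = x + (rng.normal(0.0, noise_sd, n) if noise_sd else 0.0)
    if elevated_fraction:
        idx = rng.choice(n, int(round(n * elevated_fraction)), replace=False)
        y = y.copy()
        y[idx] += shift
    frame = pd.DataFrame(
        {
            "i_ref": np.exp(x),
            "i_test": np.exp(y),
            "retained": True,
            "log_ref": x,
            "log_test": y,
        },
        index=pd.Index([f"p{i}" for i in range(n)], name="probe_id"),
    )
    return ScatterData(data=frame, background_threshold=0.0, n_dropped=0)


class TestBuildScatter:
    def test_identical_tables_all_on_diagonal(self, probeset, config):
        sample = SampleSpec.pure(kras.KRAS_TARGET, 5.0)
        table = simulate_array(probeset, sample, config, seed=3)
        scatter = build_scatter(table, table)
        kept = scatter.retained
        assert (kept["i_ref"] == kept["i_test"]).all()
        assert scatter.n_dropped == int(table.data["below_background"].sum())

    def test_below_threshold_in_one_channel_drops_probe(self, probeset, config):
        sample = SampleSpec.pure(kras.KRAS_TARGET, 5.0)
        table = simulate_array(probeset, sample, noise_free(config), seed=1)
        bright = table.data["intensity"].rank(ascending=False) <= 10
        doctored = table.data.copy()
        doctored.loc[bright[bright].index[:1], "intensity"] = 0.5
        doctored["below_background"] = doctored["intensity"] < 1.0
        tampered = type(table)(data=doctored, meta=dict(table.meta))
        scatter = build_scatter(table, tampered, background_threshold=1.0)
        assert scatter.n_dropped >= 1
        dropped_id = doctored.loc[doctored["intensity"] == 0.5, "probe_id"].iloc[0]
        assert not scatter.data.loc[dropped_id, "retained"]

    def test_known_number_of_dim_probes_dropped(self, probeset, config):
        """The count of removed probes equals the direct below-threshold count."""
        sample = SampleSpec.pure(kras.KRAS_TARGET, 5.0)
        ref = simulate_array(probeset, sample, config, seed=21)
        test = simulate_array(probeset, sample, config, seed=22)
        thr = config.threshold
        scatter = build_scatter(ref, test, background_threshold=thr)
        direct = (
            (ref.data.set_index("probe_id")["intensity"] < thr)
            | (test.data.set_index("probe_id")["intensity"] < thr)
        ).sum()
        assert scatter.n_dropped == int(direct)
        assert len(scatter.retained) == len(probeset) - scatter.n_dropped

    def test_disjoint_probe_sets_error(self, probeset, config):
        sample = SampleSpec.pure(kras.KRAS_TARGET, 5.0)
        table = simulate_array(probeset, sample, config, seed=4)
        renamed = table.data.copy()
        renamed["probe_id"] = renamed["probe_id"] + "_other"
        other = type(table)(data=renamed, meta={})
        with pytest.raises(HybridSNVError):
            build_scatter(table, other)


class TestReferenceLine:
    def test_identity_recovered_on_clean_diagonal(self):
        scatter = diagonal_scatter(n=300)
        line = fit_reference_line(scatter)
        lo, hi = scatter.data["log_ref"].min(), scatter.data["log_ref"].max()
        grid = np.linspace(lo, hi, 200)
        assert np.max(np.abs(line(grid) - grid)) < 1e-6

    def test_minority_elevated_branch_does_not_drag_fit(self):
        """90% on y=x, 10% shifted +1.5: the line stays within 0.05 of identity."""
        scatter = diagonal_scatter(n=500, noise_sd=0.15, elevated_fraction=0.10, seed=7)
        line = fit_reference_line(scatter)
        grid = np.linspace(scatter.data["log_ref"].min(), scatter.data["log_ref"].max(), 400)
        assert np.max(np.abs(line(grid) - grid)) < 0.05

    def test_wt_vs_wt_line_bounded_by_noise_scale(self, probeset, config):
        sample = SampleSpec.pure(kras.KRAS_TARGET, 10.0)
        ref = simulate_array(probeset, sample, config, seed=31)
        test = simulate_array(probeset, sample, config, seed=32)
        scatter = build_scatter(ref, test)
        line = fit_reference_line(scatter)
        pts = scatter.retained
        # median-of-8 lognormal noise has log-sd ~0.066 per channel
        dev = np.abs(line(pts["log_ref"].to_numpy()) - pts["log_ref"].to_numpy())
        assert np.max(dev) < 0.1

    def test_monotone_non_decreasing(self):
        scatter = diagonal_scatter(n=300, noise_sd=0.3, seed=11)
        line = fit_reference_line(scatter)
        assert np.all(np.diff(line.y) >= -1e-12)

    def test_constant_extrapolation_outside_range(self):
        scatter = diagonal_scatter(n=100)
        line = fit_reference_line(scatter)
        assert line(-5.0) == pytest.approx(line(line.x[0]))
        assert line(50.0) == pytest.approx(line(line.x[-1]))

    def test_too_few_points_error(self):
        scatter = diagonal_scatter(n=9)
        with pytest.raises(InsufficientDataError):
            fit_reference_line(scatter)


@pytest.fixture(scope="module")
def mutation():
    return kras.kras_hypothesis("10C→G")


class TestBranchDistances:
    def test_identical_channels_give_zero_distances(self, probeset, config, mutation):
        sample = SampleSpec.pure(kras.KRAS_TARGET, 5.0)
        table = simulate_array(probeset, sample, config, seed=13)
        scatter = build_scatter(table, table)
        line = fit_reference_line(scatter)
        result = branch_distances(scatter, line, probeset, mutation)
        assert result.rho == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(result.distances["distance"], 0.0, atol=1e-9)

    def test_noise_free_rho_matches_closed_form(self, probeset, mutation):
        """Geometric rho equals ln(1 + (c_mut/c_wt) e^(-ddG/RT)) in the linear regime.

        A penalty table with uniformly strong mismatches keeps the mutant's
        residual affinity for reference probes negligible, which is the
        closed form's first-order assumption.
        """
        table = PenaltyTable.uniform(4.0)
        cfg = noise_free(SimulationConfig(penalties=table))
        rt = cfg.thermo.rt
        mut = kras.KRAS_TARGET.with_mutations([(mutation.position, mutation.alt_base)])
        for f in (0.10, 0.016, 0.001):
            ref = simulate_array(probeset, SampleSpec.pure(kras.KRAS_TARGET, 5.0), cfg, seed=1)
            test = simulate_array(
                probeset, SampleSpec.mixture(kras.KRAS_TARGET, mut, 5.0, f), cfg, seed=2
            )
            scatter = build_scatter(ref, test, background_threshold=0.0)
            line = fit_reference_line(scatter)
            result = branch_distances(scatter, line, probeset, mutation)
            x = f / (1.0 - f)
            assert result.rho == pytest.approx(math.log(1 + x * math.exp(4.0 / rt)), abs=1e-3)

    def test_common_gain_cancels(self, probeset, config, mutation):
        """Scaling both channels by 10 leaves every distance unchanged."""
        mut = kras.KRAS_TARGET.with_mutations([(mutation.position, mutation.alt_base)])
        ref = simulate_array(probeset, SampleSpec.pure(kras.KRAS_TARGET, 5.0), config, seed=51)
        test = simulate_array(
            probeset, SampleSpec.mixture(kras.KRAS_TARGET, mut, 5.0, 0.05), config, seed=52
        )
        thr = config.threshold
        s1 = build_scatter(ref, test, background_threshold=thr)
        s2 = build_scatter(ref.scaled(10.0), test.scaled(10.0), background_threshold=10 * thr)
        r1 = branch_distances(s1, fit_reference_line(s1), probeset, mutation)
        r2 = branch_distances(s2, fit_reference_line(s2), probeset, mutation)
        assert r1.rho == pytest.approx(r2.rho, abs=1e-9)
        assert np.allclose(
            r1.distances["distance"], r2.distances["distance"], atol=1e-9
        )

    def test_rho_increases_along_dilution_series(self, probeset, mutation):
        from hybridsnv.simulate import make_dilution_series

        cfg = noise_free(SimulationConfig())
        reference, series = make_dilution_series(
            probeset, mutation, 0.10, 2.5, 5, cfg, c_total=5.0, seed=61
        )
        rhos = []
        for _, table in series:
            scatter = build_scatter(reference, table, background_threshold=0.0)
            line = fit_reference_line(scatter)
            rhos.append(branch_distances(scatter, line, probeset, mutation).rho)
        assert rhos == sorted(rhos, reverse=True)  # fractions decrease along the series

    def test_branch_ordering_on_mixture(self, probeset, config, mutation):
        """mutation branch >= side branches >= reference branch in median distance."""
        mut = kras.KRAS_TARGET.with_mutations([(mutation.position, mutation.alt_base)])
        ref = simulate_array(probeset, SampleSpec.pure(kras.KRAS_TARGET, 10.0), config, seed=71)
        test = simulate_array(
            probeset, SampleSpec.mixture(kras.KRAS_TARGET, mut, 10.0, 0.05), config, seed=72
        )
        scatter = build_scatter(ref, test)
        line = fit_reference_line(scatter)
        result = branch_distances(scatter, line, probeset, mutation)
        med = result.distances.groupby("branch")["distance"].median()
        assert med["mutation"] > med["side"] > med["reference"]
        assert med["mutation"] == pytest.approx(result.rho)

    def test_empty_mutation_set_flagged(self, probeset, config, mutation):
        sample = SampleSpec.pure(kras.KRAS_TARGET, 5.0)
        ref = simulate_array(probeset, sample, config, seed=81)
        test = simulate_array(probeset, sample, config, seed=82)
        scatter = build_scatter(ref, test)
        # remove all mutation-set probes from the scatter
        from hybridsnv.probeset import probes_for_hypothesis

        mut_ids = {p.probe_id for p in probes_for_hypothesis(probeset, mutation)[0]}
        scatter.data.loc[scatter.data.index.isin(mut_ids), "retained"] = False
        line = fit_reference_line(scatter)
        result = branch_distances(scatter, line, probeset, mutation)
        assert not result.valid
        assert math.isnan(result.rho)
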