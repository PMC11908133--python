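import math

import numpy as np
import pytest
from scipy.stats import binom as sp_binom

from clonedyn.errors import ParameterError
from clonedyn.growth import GrowthModelParams, isolated_vaf
from clonedyn.inference import (
    FitnessPosterior,
    binom_logpmf,
    enumerate_structures,
    fit_structure,
    fitness_grid,
    select_structure,
    structure_loglik,
)
from clonedyn.io import ParticipantData
from clonedyn.simulate import CloneSpec, VariantSpec, simulate_participant

from conftest import make_trajectory
from oracle import brute_log_evidence, brute_partitions

BELL = {1: 1, 2: 2, 3: 5, 4: 15, 5: 52, 6: 203}


def _participant(trajectories, pid="P1"):
    return ParticipantData(participant_id=pid, cohort="synthetic", trajectories=trajectories)


def _simulated_participant(scenario, ages, seed, depth=2000.0):
    from clonedyn.io import build_trajectories, MutationObservation

    rng = np.random.default_rng(seed)
    rows, truth = simulate_participant(scenario, ages, rng, depth_mean=depth)
    obs = [
        MutationObservation(
            r["participant_id"], r["cohort"], r["gene"], r["variant"], r["age"],
            r["alt_reads"], r["depth"], r["vaf"], r["unique_alt_reads"], r["gnomad_p"],
        )
        for r in rows
    ]
    return build_trajectories(obs)[0], truth


class TestEnumeration:
    @pytest.mark.parametrize("k", sorted(BELL))
    def test_bell_numbers_and_brute_force_match(self, k):
        labels = [f"m{i}" for i in range(k)]
        partitions, exhaustive = enumerate_structures(labels)
        assert exhaustive and len(partitions) == BELL[k]
        canon = lambda p: frozenset(frozenset(b) for b in p)
        assert {canon(p) for p in partitions} == {canon(p) for p in brute_partitions(labels)}

    def test_canonical_order_endpoints(self):
        partitions, _ = enumerate_structures(["a", "b", "c"])
        assert partitions[0] == (("a", "b", "c"),)  # single clone first
        assert partitions[-1] == (("a",), ("b",), ("c",))  # all independent last

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ParameterError):
            enumerate_structures(["a", "a"])

    def test_reduced_set_beyond_exhaustive_limit(self):
        labels = [f"m{i}" for i in range(5)]
        partitions, exhaustive = enumerate_structures(labels, max_exhaustive=3)
        assert not exhaustive
        assert (tuple((lab,) for lab in labels)) in partitions
        assert (tuple([tuple(labels)])) in partitions
        assert len(partitions) == 2 + 5 * 4 // 2


class TestStructureLoglik:
    def test_truth_beats_perturbed_on_noiseless_data(self, params):
        s, atma = 0.2, 30.0
        ages = [60.0, 70.0, 80.0]
        depth = 100_000
        alts = [int(round(depth * isolated_vaf(s, atma, t, params))) for t in ages]
        traj = make_trajectory("P1", "TET2", "v", ages, alts, [depth] * 3)
        ll_true = structure_loglik([traj], [("TET2:v",)], [s], {"TET2:v": atma}, params)
        ll_pert = structure_loglik([traj], [("TET2:v",)], [s + 0.1], {"TET2:v": atma}, params)
        assert ll_true > ll_pert

    def test_single_observation_matches_scipy_at_mode(self, params):
        s, atma, t, depth = 0.15, 40.0, 70.0, 2000
        v = isolated_vaf(s, atma, t, params)
        k = int(round(depth * v))
        traj = make_trajectory("P1", "TET2", "v", [t], [k], [depth])
        ll = structure_loglik([traj], [("TET2:v",)], [s], {"TET2:v": atma}, params)
        # model VAF at the exact parameters
        assert ll == pytest.approx(float(sp_binom.logpmf(k, depth, max(v, params.error_floor))), abs=1e-8)

    def test_empty_trajectories_zero(self, params):
        assert structure_loglik([], [], [], {}, params) == 0.0

    def test_incomplete_partition_rejected(self, params):
        traj = make_trajectory("P1", "TET2", "v", [70.0], [10], [1000])
        with pytest.raises(ParameterError):
            structure_loglik([traj], [], [], {}, params)


class TestFitStructure:
    def test_degenerate_single_point_grid(self, params):
        traj = make_trajectory("P1", "TET2", "v", [70.0, 76.0], [20, 60], [2000, 2000])
        # single-point grids are not valid FitnessPosterior grids; use 2 points
        posteriors, _, _ = fit_structure([traj], [("TET2:v",)], params, np.array([0.19, 0.21]))
        assert posteriors[0].mass.sum() == pytest.approx(1.0, abs=1e-12)

    def test_flat_trajectory_maps_to_grid_minimum(self, params):
        # constant at the sequencing-error floor (VAF 1e-4): no growth signal
        traj = make_trajectory("P1", "TET2", "v", [70.0, 76.0, 82.0], [1, 1, 1],
                               [10000, 10000, 10000])
        posteriors, _, _ = fit_structure([traj], [("TET2:v",)], params, fitness_grid())
        # no growth signal: MAP in the lowest few percent of the [0, 1] grid
        assert posteriors[0].map_s <= 0.05

    def test_map_recovery_single_clone(self, params):
        part, truth = _simulated_participant(
            [CloneSpec(0.2, (VariantSpec("TET2", "v0", 20.0),))], [50.0, 60.0, 70.0, 80.0], seed=42
        )
        posteriors, _, _ = fit_structure(
            part.trajectories, [("TET2:v0",)], params, fitness_grid()
        )
        assert abs(posteriors[0].map_s - 0.2) <= 0.03

    def test_evidence_matches_brute_force_oracle(self, params):
        """Vectorized evidence equals an independent nested-loop computation."""
        part, _ = _simulated_participant(
            [
                CloneSpec(0.25, (VariantSpec("TET2", "v0", 20.0), VariantSpec("SF3B1", "v1", 32.0))),
                CloneSpec(0.1, (VariantSpec("DNMT3A", "v2", 0.0),)),
            ],
            [55.0, 65.0, 75.0],
            seed=3,
        )
        grid = np.linspace(0.0, 1.0, 20)
        labels = sorted(t.label for t in part.trajectories)
        partitions, _ = enumerate_structures(labels)
        for partition in partitions:
            _, log_ev, _ = fit_structure(part.trajectories, partition, params, grid)
            oracle_ev = brute_log_evidence(part.trajectories, partition, grid, params)
            assert log_ev == pytest.approx(oracle_ev, abs=1e-8)


class TestSelectStructure:
    def test_single_variant_singleton(self, params):
        traj = make_trajectory("P1", "TET2", "v", [70.0, 76.0], [30, 80], [2000, 2000])
        est = select_structure(_participant([traj]), params)
        assert est.structure.blocks == (("TET2:v",),)

    def test_evidence_normalizes_over_candidates(self, params):
        part, _ = _simulated_participant(
            [CloneSpec(0.2, (VariantSpec("TET2", "a", 20.0),)),
             CloneSpec(0.3, (VariantSpec("JAK2", "b", 35.0),))],
            [55.0, 65.0, 75.0],
            seed=8,
        )
        est = select_structure(part, params, grid=fitness_grid(0.5, 0.01))
        evs = np.array([c.log_evidence for c in est.candidates])
        probs = np.exp(evs - evs.max())
        probs /= probs.sum()
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(est.candidates) == 2  # B(2)

    def test_posterior_contraction_with_depth_and_waves(self, params):
        """More waves at higher depth tighten the fitness posterior."""
        iqr = {}
        for label, (ages, depth) in {
            "sparse": ([55.0, 65.0, 75.0, 85.0], 1000.0),
            "dense": ([55.0, 59.0, 63.0, 67.0, 71.0, 75.0, 79.0, 83.0], 2000.0),
        }.items():
            widths = []
            for seed in range(12):
                part, _ = _simulated_participant(
                    [CloneSpec(0.2, (VariantSpec("TET2", "v", 25.0),))], ages, seed=seed,
                    depth=depth,
                )
                est = select_structure(part, params)
                widths.append(est.clones[0].posterior.iqr)
            iqr[label] = np.mean(widths)
        assert iqr["dense"] < iqr["sparse"]

    def test_greedy_search_on_many_variants(self, params):
        scen = [
            CloneSpec(s, (VariantSpec(g, f"v{i}", a),))
            for i, (g, s, a) in enumerate(
                [("TET2", 0.25, 25.0), ("JAK2", 0.15, 10.0), ("SF3B1", 0.3, 40.0),
                 ("ASXL1", 0.1, 5.0)]
            )
        ]
        part, _ = _simulated_participant(scen, [55.0, 65.0, 75.0], seed=21)
        est = select_structure(part, params, grid=fitness_grid(0.5, 0.01), max_exhaustive=3)
        assert not est.structure.exhaustive
        assert sum(len(b) for b in est.structure.blocks) == 4


class TestFitnessPosterior:
    def test_mass_must_normalize(self):
        with pytest.raises(ParameterError):
            FitnessPosterior(grid=np.array([0.0, 0.1]), mass=np.array([0.6, 0.6]))

    def test_quantiles_and_map(self):
        post = FitnessPosterior(grid=np.linspace(0, 1, 101),
                                mass=np.full(101, 1 / 101))
        assert 0.4 < post.quantile(0.5) < 0.6
        assert post.iqr > 0


def test_binom_logpmf_matches_scipy():
    ks = np.array([0, 3, 17, 2000])
    ns = np.array([10, 10, 1800, 2000])
    ps = np.array([1e-4, 0.02, 0.01, 0.4])
    ours = binom_logpmf(ks, ns, ps)
    theirs = sp_binom.logpmf(ks, ns, ps)
    assert np.allclose(ours, theirs, atol=1e-10)
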