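import math

import numpy as np
import pytest
from scipy import stats

from dimerint import cm
from dimerint.cm import (
    CmSchedule,
    EnergyModel,
    FlatEnergy,
    HarmonicVariableEnergy,
    IntraNonbondedModel,
    VariableSet,
    biased_annealing,
    build_helix,
    exploratory_phase,
    metropolis_accept,
    select_fitting_conformer,
)
from dimerint.geometry import fit_axis


class RuggedEnergy(EnergyModel):
    """Multi-well 1-D toy used for acceptance-ratio checks."""

    needs_coords = False

    def __init__(self, var):
        self.var = var

    def energy(self, helix):
        x = helix.get_variable(self.var)
        return 1.5 * math.sin(x / 3.0) ** 2 + 0.002 * x * x


class TestBuildHelix:
    def test_alpha_helix_rise(self):
        """A 20-Ala helix at φ=−63°, ψ=−41.6° has the canonical ~1.5 Å
        Cα rise per residue along its axis."""
        h = build_helix("A" * 20)
        axis, _ = fit_axis(h.ca_coords)
        rise = float(np.mean(np.diff(h.ca_coords @ axis)))
        assert rise == pytest.approx(1.5, abs=0.1)

    def test_deterministic(self):
        a, b = build_helix("ACDEFGHIKL"), build_helix("ACDEFGHIKL")
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_unknown_residue_letter(self):
        with pytest.raises(ValueError, match="X"):
            build_helix("AAAAX")

    def test_too_short(self):
        with pytest.raises(ValueError, match="5"):
            build_helix("AAAA")

    def test_coords_regenerate_from_internal(self):
        h = build_helix("A" * 8)
        ref = h.coords.copy()
        h.set_variable(("phi", 3), -50.0)
        h.set_variable(("phi", 3), ref[0, 0, 0] * 0 - 63.0)  # restore
        h.rebuild_coords()
        np.testing.assert_allclose(h.coords, ref, atol=1e-9)


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-5.0, t, rng) for t in (1.0, 310.0, 3000.0))

    def test_half_acceptance_at_kT_ln2(self):
        """ΔE = kB·T·ln2 accepts with probability exactly 1/2."""
        rng = np.random.default_rng(42)
        T = 310.0
        de = cm.KB_KCAL * T * math.log(2)
        acc = sum(metropolis_accept(de, T, rng) for _ in range(100_000)) / 100_000
        assert acc == pytest.approx(0.5, abs=0.01)

    def test_large_uphill_never_accepted_at_310K(self):
        rng = np.random.default_rng(1)
        assert not any(metropolis_accept(100.0, 310.0, rng) for _ in range(100_000))

    def test_infinite_temperature_accepts_bounded_moves(self):
        rng = np.random.default_rng(2)
        assert all(metropolis_accept(50.0, 1e9, rng) for _ in range(1000))

    def test_nonfinite_delta_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            metropolis_accept(float("nan"), 310.0, rng)
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, rng)


class TestSchedule:
    def test_geometric_ladder_hits_endpoints(self):
        s = CmSchedule()
        temps = s.exploratory_temperatures()
        assert len(temps) == 18
        assert temps[0] == pytest.approx(3000.0)
        assert temps[-1] == pytest.approx(310.0)
        assert np.all(np.diff(temps) < 0)
        bt = s.biased_temperatures()
        assert len(bt) == 7
        assert bt[0] == pytest.approx(749.4) and bt[-1] == pytest.approx(310.0)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            CmSchedule(t_initial=100.0)


def single_var_setup(halfwidth=10.0, steps=10_000, stages=2):
    helix = build_helix("A" * 6)
    variables = VariableSet(torsion_windows={("phi", 2): halfwidth})
    sched = CmSchedule(steps_per_variable=steps, scale=1.0,
                       cooling_steps_exploratory=stages)
    return helix, variables, sched


class TestExploratoryPhase:
    def test_flat_energy_covers_window(self):
        """With E ≡ 0 the 310 K memory covers ≥ 95% of the window bins."""
        helix, variables, sched = single_var_setup(halfwidth=50.0)
        mem = exploratory_phase(helix, variables, sched, FlatEnergy(), seed=1)
        assert mem.coverage(("phi", 2)) >= 0.95

    def test_flat_energy_marginal_is_uniform(self):
        """χ² goodness of fit of the final-stage histogram against the
        uniform marginal: p > 0.01 at 10⁴ samples."""
        helix, variables, sched = single_var_setup(halfwidth=50.0)
        mem = exploratory_phase(helix, variables, sched, FlatEnergy(), seed=3)
        counts = mem.counts(("phi", 2), stage=-1).astype(float)
        res = stats.chisquare(counts)
        assert res.pvalue > 0.01

    def test_seeded_runs_identical(self):
        helix, variables, sched = single_var_setup(steps=2000)
        m1 = exploratory_phase(helix, variables, sched, FlatEnergy(), seed=9)
        m2 = exploratory_phase(helix, variables, sched, FlatEnergy(), seed=9)
        np.testing.assert_array_equal(m1.counts(("phi", 2), -1), m2.counts(("phi", 2), -1))

    def test_harmonic_well_concentrates_memory(self):
        """A harmonic well at +20° inside a ±50° window concentrates the
        310 K memory near the minimum (Boltzmann marginal of a 1-D well)."""
        helix, variables, sched = single_var_setup(halfwidth=50.0)
        center0 = helix.get_variable(("phi", 2))
        target = center0 + 20.0
        model = HarmonicVariableEnergy(("phi", 2), center=target, k=0.01)
        mem = exploratory_phase(helix, variables, sched, model, seed=5)
        assert abs(mem.mean_accepted(("phi", 2)) - target) < 5.0

    def test_empty_variable_set_rejected(self):
        helix = build_helix("A" * 6)
        sched = CmSchedule(scale=0.001)
        with pytest.raises(ValueError, match="empty"):
            exploratory_phase(helix, VariableSet(), sched, FlatEnergy(), seed=0)

    def test_acceptance_nonincreasing_with_cooling(self):
        """On a rugged toy energy, the mean acceptance ratio at 3000 K is
        not lower than at 310 K (averaged over 10 seeds)."""
        hot, cold = [], []
        for seed in range(10):
            helix, variables, sched = single_var_setup(halfwidth=50.0, steps=400,
                                                       stages=6)
            mem = exploratory_phase(helix, variables, sched,
                                    RuggedEnergy(("phi", 2)), seed=seed)
            hot.append(mem.acceptance_by_stage[0])
            cold.append(mem.acceptance_by_stage[-1])
        assert np.mean(hot) >= np.mean(cold)


class TestBiasedAnnealing:
    def test_default_schedule_emits_105_structures(self):
        """The published schedule outputs 105 structures at 310 K."""
        helix = build_helix("A" * 10)
        variables = VariableSet.for_helix(helix)
        sched = CmSchedule(scale=0.001)
        mem = exploratory_phase(helix, variables, sched, FlatEnergy(), seed=0)
        ens = biased_annealing(helix, mem, sched, FlatEnergy(), seed=1)
        assert len(ens) == 105

    def test_all_proposals_inside_populated_space(self):
        helix, variables, sched = single_var_setup(steps=2000)
        mem = exploratory_phase(helix, variables, sched, FlatEnergy(), seed=2)
        ens = biased_annealing(helix, mem, sched, FlatEnergy(), seed=3)
        assert ens.n_proposals > 0
        assert ens.out_of_memory_proposals == 0

    def test_single_bin_memory_degenerates_outputs(self):
        """A memory restricted to one bin per variable pins every output
        to that bin (identical up to the bin width)."""
        helix, variables, sched = single_var_setup(steps=500)
        mem = exploratory_phase(helix, variables, sched, FlatEnergy(), seed=4)
        var = ("phi", 2)
        keep = mem.populated_bins(var)[0]
        mem._counts[var][-1, :] = 0
        mem._counts[var][-1, keep] = 1
        ens = biased_annealing(helix, mem, sched, FlatEnergy(), seed=5)
        values = np.array([c.get_variable(var) for c in ens])
        edges = mem.edges(var)
        assert values.max() - values.min() <= edges[1] - edges[0] + 1e-9

    def test_empty_memory_names_variable(self):
        helix, variables, sched = single_var_setup(steps=100)
        mem = exploratory_phase(helix, variables, sched, FlatEnergy(), seed=6)
        mem._counts[("phi", 2)][-1, :] = 0
        with pytest.raises(ValueError, match="phi"):
            biased_annealing(helix, mem, sched, FlatEnergy(), seed=7)


class TestIntraNonbondedModel:
    def test_deterministic_and_finite(self):
        h = build_helix("A" * 12)
        model = IntraNonbondedModel(12)
        e1, e2 = model.energy(h), model.energy(h)
        assert e1 == e2 and math.isfinite(e1)

    def test_excluded_pairs_do_not_contribute(self):
        """1-2/1-3 exclusion: the scale matrix zeroes bonded neighbours."""
        scale = IntraNonbondedModel._pair_scale_matrix(3, 0.5)
        # N-CA bonded (1-2), N-C 1-3 via CA, N-O 1-3 via CA-C? N..O: N-CA-C-O = 3 bonds -> 1-4
        assert scale[0, 1] == 0.0
        assert scale[0, 2] == 0.0
        assert scale[0, 3] == 0.5
        # symmetric, zero diagonal
        np.testing.assert_array_equal(scale, scale.T)
        assert np.all(np.diag(scale) == 0)


class TestSelectFittingConformer:
    def test_empty_bundle_returns_first(self):
        cands = [build_helix("A" * 8), build_helix("G" * 8)]
        assert select_fitting_conformer(cands, None, clash_cutoff=2.0) is cands[0]

    def test_all_clashing_reports_none(self):
        cands = [build_helix("A" * 8)]
        bundle = cands[0].backbone_coords() + 0.1
        assert select_fitting_conformer(cands, bundle, clash_cutoff=100.0) is None

    def test_planted_nonclashing_candidate_found(self):
        base = build_helix("A" * 8)
        clashing = base.copy()
        far = base.copy()
        far.coords = base.coords + np.array([50.0, 0.0, 0.0])
        far.coords_from_internal = False
        bundle = base.backbone_coords() + np.array([1.0, 0.0, 0.0])
        got = select_fitting_conformer([clashing, far], bundle, clash_cutoff=3.0)
        assert got is far
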