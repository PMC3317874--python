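import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dimerint import energetics, synthetic
from dimerint.energetics import (
    EnergyDecomposition,
    EnergyOptions,
    EnergyTableRow,
    EnergyTerm,
    decompose_interface,
    pair_energy,
    residue_vs_protomer_energy,
    residues_within_radius,
    summarize_table,
)
from dimerint.structures import AtomRecord, Residue

from conftest import make_atom


def brute_force_energy(res, pool, opts):
    """Independent all-pairs reference with the radius rule, pure loops."""
    coul = vdw = 0.0
    for other in pool:
        dmin = min(
            float(np.linalg.norm(ai.coords - aj.coords))
            for ai in res.atoms for aj in other.atoms
        )
        if dmin > opts.residue_radius:
            continue
        for ai in res.atoms:
            for aj in other.atoms:
                r = float(np.linalg.norm(ai.coords - aj.coords))
                eps = r if opts.dielectric_mode == "distance_dependent" else opts.dielectric_constant
                coul += opts.coulomb_constant * ai.charge_q * aj.charge_q / (eps * r)
                vdw += (math.sqrt(ai.lj_A * aj.lj_A) / r**12
                        - math.sqrt(ai.lj_C * aj.lj_C) / r**6)
    return coul, vdw


class TestPairEnergy:
    def test_null_parameters_give_zero(self):
        t = pair_energy(make_atom([0, 0, 0]), make_atom([2.5, 0, 0]))
        assert t.coulombic == 0.0 and t.vdw == 0.0 and t.total() == 0.0

    def test_lj_minimum_matches_closed_form(self):
        """At r = (2A/C)^(1/6) the 12-6 well depth is −C²/(4A)."""
        A, C = 1.0e6, 1.0e3
        r = (2 * A / C) ** (1 / 6)
        t = pair_energy(make_atom([0, 0, 0], A=A, C=C), make_atom([r, 0, 0], A=A, C=C))
        assert t.vdw == pytest.approx(-(C * C) / (4 * A), abs=1e-9)
        assert r == pytest.approx(2000.0 ** (1 / 6), abs=1e-9)

    def test_coulomb_hand_value(self, const_eps_opts):
        """Two unit charges at k/100 Å give exactly 100 kcal/mol at ε=1."""
        t = pair_energy(make_atom([0, 0, 0], q=1.0),
                        make_atom([3.320636, 0, 0], q=1.0), const_eps_opts)
        assert t.coulombic == pytest.approx(100.0, abs=1e-9)

    def test_distance_dependent_dielectric_is_one_over_r_squared(self):
        t = pair_energy(make_atom([0, 0, 0], q=1.0), make_atom([2.0, 0, 0], q=1.0))
        assert t.coulombic == pytest.approx(energetics.COULOMB_K / 4.0)

    def test_coincident_atoms_singular(self):
        with pytest.raises(ZeroDivisionError):
            pair_energy(make_atom([1, 1, 1], q=1.0), make_atom([1, 1, 1], q=1.0))

    @given(
        xyz=st.tuples(*[st.floats(-8, 8) for _ in range(3)]),
        qi=st.floats(-1, 1), qj=st.floats(-1, 1),
        ai=st.floats(0, 1e6), aj=st.floats(0, 1e6),
        ci=st.floats(0, 1e3), cj=st.floats(0, 1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, xyz, qi, qj, ai, aj, ci, cj):
        """pair_energy(i, j) == pair_energy(j, i) exactly."""
        p = np.asarray(xyz)
        if np.linalg.norm(p) < 0.5:
            p = p + 1.0
        x = make_atom([0, 0, 0], q=qi, A=ai, C=ci)
        y = make_atom(p, q=qj, A=aj, C=cj)
        t1, t2 = pair_energy(x, y), pair_energy(y, x)
        assert t1.coulombic == t2.coulombic and t1.vdw == t2.vdw

    def test_vdw_monotone_beyond_minimum_and_vanishing(self):
        A, C = 1.0e6, 1.0e3
        rmin = (2 * A / C) ** (1 / 6)
        rs = np.linspace(rmin, 45, 60)
        es = [pair_energy(make_atom([0, 0, 0], A=A, C=C),
                          make_atom([r, 0, 0], A=A, C=C)).vdw for r in rs]
        assert all(e2 >= e1 for e1, e2 in zip(es, es[1:]))
        assert es[0] == min(es) and abs(es[-1]) < 1e-6


class TestRadiusSelection:
    def test_boundary_inclusive(self):
        a = Residue(1, "ALA", [make_atom([0, 0, 0])])
        b = Residue(2, "ALA", [make_atom([7.0, 0, 0])])
        c = Residue(3, "ALA", [make_atom([7.01, 0, 0])])
        sel = residues_within_radius(a, [b, c], 7.0)
        assert sel == [b]

    def test_empty_pool_ok(self):
        a = Residue(1, "ALA", [make_atom([0, 0, 0])])
        assert residues_within_radius(a, [], 7.0) == []

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(11)
        pool = [
            Residue(i + 1, "ALA", [make_atom(rng.uniform(-15, 15, 3)) for _ in range(3)])
            for i in range(50)
        ]
        anchor = Residue(99, "ALA", [make_atom(rng.uniform(-5, 5, 3))])
        got = {r.seq_number for r in residues_within_radius(anchor, pool, 7.0)}
        want = set()
        for r in pool:
            dmin = min(np.linalg.norm(ai.coords - aj.coords)
                       for ai in anchor.atoms for aj in r.atoms)
            if dmin <= 7.0:
                want.add(r.seq_number)
        assert got == want


class TestDecomposition:
    def test_zero_parameters_give_zero_rows_and_nan_fraction(self):
        spec = synthetic.DimerFixtureSpec(charge_scheme="zero", lj_scheme="zero",
                                          n_cholesterol=2)
        cx = synthetic.make_dimer_fixture(spec)
        pos = [r.bw_position for r in cx.protomer_a.protein_residues]
        with pytest.warns(UserWarning, match="fraction undefined"):
            d = decompose_interface(cx, pos)
        assert all(row.term.total() == 0.0 for row in d.protomer_rows)
        assert math.isnan(d.chol_fraction_percent)

    def test_single_atom_protomers_equal_hand_computed_pair_energies(self, const_eps_opts):
        """Two one-atom protomers plus one cholesterol site per protomer:
        grand total is the hand-summed three pair energies."""
        ra = Residue(1, "ALA", [make_atom([0, 0, 0], q=0.5, A=1e5, C=5e2)],
                     bw_position="4.44")
        rb = Residue(1, "ALA", [make_atom([4.0, 0, 0], q=-0.5, A=1e5, C=5e2)],
                     bw_position="4.44")
        chol_a = Residue(1001, "CLR", [make_atom([2.0, 1.0, 0], A=1e5, C=5e2)],
                         is_ligand=True, ligand_tag="CHOL_A")
        chol_b = Residue(1002, "CLR", [make_atom([2.0, -1.0, 0], A=1e5, C=5e2)],
                         is_ligand=True, ligand_tag="CHOL_B")
        from dimerint.structures import DimerComplex, Protomer
        cx = DimerComplex(Protomer("A", [ra]), Protomer("B", [rb]),
                          ligands=[chol_a, chol_b])
        d = decompose_interface(cx, ["4.44"], const_eps_opts)
        hand = (
            pair_energy(ra.atoms[0], rb.atoms[0], const_eps_opts).total()
            + pair_energy(chol_a.atoms[0], rb.atoms[0], const_eps_opts).total()
            + pair_energy(chol_b.atoms[0], ra.atoms[0], const_eps_opts).total()
        )
        assert d.grand_total.total() == pytest.approx(hand, abs=1e-12)

    def test_degenerate_residue_vs_protomer_equals_pair_energy(self, const_eps_opts):
        from dimerint.structures import Protomer
        ra = Residue(1, "ALA", [make_atom([0, 0, 0], q=1.0)])
        rb = Residue(1, "ALA", [make_atom([3.0, 0, 0], q=1.0)])
        t = residue_vs_protomer_energy(ra, Protomer("B", [rb]), const_eps_opts)
        ref = pair_energy(ra.atoms[0], rb.atoms[0], const_eps_opts)
        assert t.coulombic == ref.coulombic and t.vdw == ref.vdw

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_on_random_toys(self, seed):
        """decompose_interface agrees with the naive all-pairs reference to
        1e-9 kcal/mol on random toy dimers."""
        spec = synthetic.DimerFixtureSpec(
            n_residues_per_protomer=8, separation=5.0 + 0.3 * seed,
            charge_scheme="random", jitter=0.35, seed=seed, n_cholesterol=2,
        )
        cx = synthetic.make_dimer_fixture(spec)
        opts = EnergyOptions()
        pos = [r.bw_position for r in cx.protomer_a.protein_residues]
        d = decompose_interface(cx, pos, opts)
        total = 0.0
        for res in cx.protomer_a.protein_residues:
            c, v = brute_force_energy(res, cx.protomer_b.protein_residues, opts)
            total += c + v
        for tag, pool in (("CHOL_A", cx.protomer_b), ("CHOL_B", cx.protomer_a)):
            c, v = brute_force_energy(cx.ligand(tag), pool.protein_residues, opts)
            total += c + v
        assert d.grand_total.total() == pytest.approx(total, abs=1e-9)

    def test_missing_interface_position_named(self, random_toy_dimer):
        with pytest.raises(KeyError, match="9.99"):
            decompose_interface(random_toy_dimer, ["9.99"])

    def test_unparameterized_atoms_rejected(self):
        from dimerint.structures import DimerComplex, Protomer
        ra = Residue(1, "ALA", [AtomRecord("X", "C", [0.0, 0.0, 0.0])], bw_position="4.44")
        rb = Residue(1, "ALA", [make_atom([3.0, 0, 0])])
        cx = DimerComplex(Protomer("A", [ra]), Protomer("B", [rb]))
        with pytest.raises(KeyError, match="unparameterized"):
            decompose_interface(cx, ["4.44"])


class TestSummarize:
    def test_reference_table_cholesterol_subtotals(self):
        """The transcribed reference table reproduces the published
        cholesterol subtotal: VDW (−2.52)+(−2.49) = −5.01 kcal/mol and
        total −4.83."""
        d = summarize_table(synthetic.load_reference_interface_energies())
        assert d.chol_subtotal.vdw == pytest.approx(-5.01, abs=1e-12)
        assert d.chol_subtotal.coulombic == pytest.approx(0.17, abs=1e-12)
        assert d.chol_subtotal.total() == pytest.approx(-4.83, abs=1e-12)

    def test_single_row_summary(self):
        d = EnergyDecomposition(
            protomer_rows=[EnergyTableRow("A4.55", EnergyTerm(1.0, 1.0))]
        )
        summarize_table(d)
        assert d.protomer_subtotal.total() == 2.0
        assert d.grand_total.total() == 2.0
        assert d.chol_fraction_percent == 0.0

    def test_zero_grand_total_flags_fraction(self):
        d = EnergyDecomposition(protomer_rows=[EnergyTableRow("A4.55", EnergyTerm(0.0, 0.0))])
        with pytest.warns(UserWarning, match="fraction undefined"):
            summarize_table(d)
        assert math.isnan(d.chol_fraction_percent)

    def test_computed_terms_have_exact_total_invariant(self, random_toy_dimer):
        pos = [r.bw_position for r in random_toy_dimer.protomer_a.protein_residues]
        d = decompose_interface(random_toy_dimer, pos)
        for row in d.protomer_rows:
            assert row.term.total() == row.term.coulombic + row.term.vdw
        s = EnergyTerm.zero()
        for row in d.protomer_rows:
            s = s + row.term
        assert d.protomer_subtotal.total() == pytest.approx(s.total(), abs=1e-12)
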