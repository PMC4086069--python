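import numpy as np
import pytest

from icnma import elastic_network as enm
from icnma import fixtures as fx
from icnma import internal_coords as ic
from icnma._geom import dihedral, rotation_about_axis

from oracles import fd_jacobian_eckart


class TestDefineDofs:
    def test_phi_psi_counting_rule(self, helix10):
        dofs = [d for d in ic.define_dofs(helix10) if d.is_torsion]
        # phi of residue 1 and psi of residue 10 are undefined: 2n - 2
        assert len(dofs) == 18
        kinds = {d.kind for d in dofs}
        assert kinds == {"phi", "psi"}

    def test_proline_phi_frozen(self):
        s = fx.make_peptide([fx.HELIX_PHI_PSI] * 10)
        ridx = s.residue_index()
        s.res_names = np.where(ridx == 4, "PRO", s.res_names).astype(object)
        dofs = [d for d in ic.define_dofs(s) if d.is_torsion]
        assert len(dofs) == 17
        assert not any(d.kind == "phi" and d.label.endswith(":5") for d in dofs)

    def test_random_fixation_reproducible(self, helix10):
        a = ic.define_dofs(helix10, fix_spec="random:0.5:7")
        b = ic.define_dofs(helix10, fix_spec="random:0.5:7")
        assert len(ic.free_dofs(a)) == 9
        assert [d.fixed for d in a] == [d.fixed for d in b]

    def test_range_fixation(self, helix10):
        dofs = ic.define_dofs(helix10, fix_spec="A:1-5")
        frozen = [d for d in dofs if d.fixed]
        assert all(int(d.label.split(":")[2]) <= 5 for d in frozen)
        assert len(frozen) == 9  # psi 1-5 + phi 2-5

    def test_second_chain_adds_six_rigid_dofs(self):
        a = fx.make_peptide([fx.HELIX_PHI_PSI] * 6, chain_id="A")
        b = fx.make_peptide([fx.HELIX_PHI_PSI] * 6, chain_id="B")
        b = b.with_coords(b.coords + np.array([20.0, 0.0, 0.0]))
        combined = _concat(a, b)
        dofs = ic.define_dofs(combined)
        rigid = [d for d in dofs if not d.is_torsion]
        assert len(rigid) == 6
        torsions = [d for d in dofs if d.is_torsion]
        assert len(torsions) == 2 * 10  # 2 x (2*6-2)

    def test_nucleic_backbone_set(self):
        u = fx.make_poly_u(6)
        dofs = [d for d in ic.define_dofs(u) if d.is_torsion]
        # interior nucleotides contribute alpha..zeta minus frozen delta
        labels = {d.label for d in dofs}
        assert len(labels) >= 5
        assert all(d.kind == "nucleic_backbone" for d in dofs)

    def test_calpha_virtual_torsions(self, helix10):
        from icnma.structure_io import coarse_grain

        cg = coarse_grain(helix10, "calpha")
        dofs = [d for d in ic.define_dofs(cg) if d.is_torsion]
        assert len(dofs) == 10 - 3
        assert all(d.kind == "calpha_virtual" for d in dofs)

    def test_dof_economy(self, helix10):
        # at least one third fewer DOFs than Cartesian coordinates
        n = len(ic.free_dofs(ic.define_dofs(helix10)))
        assert n < (2.0 / 3.0) * 3 * helix10.n_atoms


class TestJacobian:
    def test_matches_finite_difference(self):
        s = fx.make_peptide([fx.EXTENDED_PHI_PSI] * 3)  # small chain
        dofs = ic.define_dofs(s)
        J = ic.jacobian(s, dofs)
        J_fd = fd_jacobian_eckart(s, dofs, h=1e-6)
        assert np.max(np.abs(J - J_fd)) < 1e-6

    def test_eckart_conditions(self, helix10_nma):
        s, _, dofs, system, _ = helix10_nma
        J = system.jacobian.reshape(s.n_atoms, 3, -1)
        m = s.masses
        lin = np.einsum("i,iak->ak", m, J)
        assert np.max(np.abs(lin)) < 1e-9 * m.sum()
        com = s.center_of_mass()
        d = s.coords - com
        ang = np.einsum("i,iak->ak", m, np.cross(d[:, :, None], J, axis=1))
        assert np.max(np.abs(ang)) < 1e-8 * m.sum()

    def test_assemble_psd_and_pd(self, helix10_nma):
        _, _, _, system, _ = helix10_nma
        wh = np.linalg.eigvalsh(system.hessian)
        assert wh[0] >= -1e-8 * np.trace(system.hessian) / system.n
        wt = np.linalg.eigvalsh(system.kinetic)
        assert wt[0] > 0

    def test_single_free_dof_restriction(self, helix10):
        # freezing all but one DOF reduces assemble to the matching 1x1 block
        net = enm.build_network(helix10)
        dofs_all = ic.define_dofs(helix10)
        full = ic.assemble(helix10, net, dofs_all)
        k = 7
        dofs_one = ic.define_dofs(helix10)
        for i, d in enumerate(dofs_one):
            d.fixed = i != k
        sub = ic.assemble(helix10, net, dofs_one)
        assert sub.hessian.shape == (1, 1)
        assert sub.hessian[0, 0] == pytest.approx(full.hessian[k, k], rel=1e-10)
        assert sub.kinetic[0, 0] == pytest.approx(full.kinetic[k, k], rel=1e-10)

    def test_hessian_matches_energy_curvature(self, helix10_nma):
        # 1-DOF finite-difference energy oracle: V(q e_k) ~ H_kk q^2
        s, net, dofs, system, _ = helix10_nma
        k = 3
        h = 1e-4
        e = np.zeros(system.n)
        e[k] = 1.0
        vp = enm.network_energy(net, ic.rebuild_cartesian(s, dofs, h * e).coords)
        vm = enm.network_energy(net, ic.rebuild_cartesian(s, dofs, -h * e).coords)
        curv = (vp + vm) / h**2  # = 2 V(h)/h^2 = H_kk since V = q^T H q / 2
        assert curv == pytest.approx(system.hessian[k, k], rel=1e-4)


class TestRebuild:
    def test_zero_displacement_is_identity(self, helix10):
        dofs = ic.define_dofs(helix10)
        out = ic.rebuild_cartesian(helix10, dofs, np.zeros(len(ic.free_dofs(dofs))))
        assert np.array_equal(out.coords, helix10.coords)

    def test_pi_rotation_reaches_anti_position(self):
        s = fx.make_peptide([fx.HELIX_PHI_PSI] * 2)
        dofs = ic.define_dofs(s)
        free = ic.free_dofs(dofs)
        k = next(i for i, d in enumerate(free) if d.kind == "psi")
        dq = np.zeros(len(free))
        dq[k] = np.pi
        out = ic.rebuild_cartesian(s, dofs, dq)
        d0 = free[k].value
        d1 = dihedral(*(out.coords[i] for i in free[k].quad))
        assert np.cos(d1 - (d0 + np.pi)) == pytest.approx(1.0, abs=1e-10)

    def test_bond_geometry_exactly_preserved(self, helix10, rng):
        dofs = ic.define_dofs(helix10)
        nfree = len(ic.free_dofs(dofs))
        bond_list = enm.bonds(helix10)
        i, j = np.array(bond_list).T
        ref = np.linalg.norm(helix10.coords[i] - helix10.coords[j], axis=1)
        worst = 0.0
        for _ in range(50):
            dq = rng.normal(scale=0.5, size=nfree)
            out = ic.rebuild_cartesian(helix10, dofs, dq)
            d = np.linalg.norm(out.coords[i] - out.coords[j], axis=1)
            worst = max(worst, np.abs(d - ref).max())
        assert worst < 1e-9

    def test_linearization_consistency(self, helix10, rng):
        dofs = ic.define_dofs(helix10)
        J = ic.jacobian(helix10, dofs)
        nfree = J.shape[1]
        base = rng.normal(size=nfree)
        base /= np.linalg.norm(base)
        errs = []
        for eps in (1e-4, 2e-4):
            dq = eps * base
            out = ic.rebuild_cartesian(helix10, dofs, dq)
            lin = helix10.coords.ravel() + J @ dq
            errs.append(np.linalg.norm(out.coords.ravel() - lin))
        # second-order: error quadruples when the step doubles
        assert errs[1] / errs[0] == pytest.approx(4.0, rel=0.2)
        assert errs[0] < 1e-5

    def test_energy_consistency(self, helix10_nma, rng):
        s, net, dofs, system, _ = helix10_nma
        dq = rng.normal(size=system.n)
        dq *= 1e-3 / np.linalg.norm(dq)
        v = enm.network_energy(net, ic.rebuild_cartesian(s, dofs, dq).coords)
        quad = 0.5 * float(dq @ system.hessian @ dq)
        assert v == pytest.approx(quad, rel=1e-3)


def _concat(a, b):
    from icnma.structure_io import Structure

    return Structure(
        coords=np.vstack([a.coords, b.coords]),
        names=np.concatenate([a.names, b.names]),
        elements=np.concatenate([a.elements, b.elements]),
        res_names=np.concatenate([a.res_names, b.res_names]),
        chain_ids=np.concatenate([a.chain_ids, b.chain_ids]),
        res_numbers=np.concatenate([a.res_numbers, b.res_numbers]),
        icodes=np.concatenate([a.icodes, b.icodes]),
        occupancies=np.concatenate([a.occupancies, b.occupancies]),
        bfactors=np.concatenate([a.bfactors, b.bfactors]),
        masses=np.concatenate([a.masses, b.masses]),
        molecule_class=np.concatenate([a.molecule_class, b.molecule_class]),
        cg_level=a.cg_level,
    )
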