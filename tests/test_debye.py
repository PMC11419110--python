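"""Debye-equation profiles: closed forms, invariances, contrast bookkeeping."""

import numpy as np
import pytest

import nucsolv as nv


def point_model(coords, chain="A", d=0.0):
    n = len(coords)
    return nv.AtomicModel(
        coords=np.asarray(coords, float),
        b_heavy=np.ones(n),
        n_h_nonexch=np.zeros(n),
        n_h_exch=np.zeros(n),
        volume=np.zeros(n),
        chain=np.full(n, chain),
        resid=np.arange(1, n + 1),
        chain_labels={chain: d},
    )


class TestDebyeClosedForms:
    def test_single_particle_flat(self):
        m = point_model([[1.0, 2.0, 3.0]])
        prof = nv.debye_intensity(m, [0.0, 0.1, 0.5], solvent=None)
        assert np.allclose(prof.I, 1.0)

    def test_two_particles(self):
        m = point_model([[0, 0, 0], [0, 0, 10.0]])
        q = np.array([0.0, 0.05, 0.2, 0.4])
        prof = nv.debye_intensity(m, q, solvent=None)
        expected = 2.0 * (1.0 + np.sinc(10.0 * q / np.pi))
        assert np.allclose(prof.I, expected, rtol=1e-12)
        assert prof.I[0] == pytest.approx(4.0)

    def test_i0_equals_total_contrast_squared(self):
        rng = np.random.default_rng(11)
        m = point_model(rng.normal(scale=15, size=(40, 3)))
        f = rng.uniform(0.5, 2.0, 40)
        prof = nv.debye_intensity(m, [0.0, 0.1, 0.2], solvent=None, f=f)
        assert prof.I[0] == pytest.approx(f.sum() ** 2, rel=1e-12)

    def test_empty_and_negative_q_rejected(self):
        with pytest.raises(ValueError):
            point_model(np.empty((0, 3)))
        m = point_model([[0, 0, 0]])
        with pytest.raises(ValueError):
            nv.debye_intensity(m, [-0.1], solvent=None)


class TestInvariances:
    def test_rigid_motion_leaves_profile_unchanged(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(scale=12, size=(60, 3))
        q = np.linspace(0.0, 0.4, 40)
        base = nv.debye_intensity(point_model(coords), q, solvent=None).I
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        moved = coords @ rot.T + np.array([5.0, -3.0, 12.0])
        alt = nv.debye_intensity(point_model(moved), q, solvent=None).I
        assert np.allclose(base, alt, rtol=1e-9)

    def test_histogram_matches_direct_sum(self):
        rng = np.random.default_rng(7)
        m = point_model(rng.normal(scale=20, size=(500, 3)))
        q = np.linspace(0.0, 0.3, 30)
        direct = nv.debye_intensity(m, q, solvent=None, method="direct").I
        binned = nv.debye_intensity(m, q, solvent=None, method="histogram",
                                    bin_width=0.1).I
        assert np.allclose(binned, direct, rtol=5e-3)


class TestAssignContrasts:
    def test_vacuum_returns_bare_scattering_lengths(self):
        m = point_model([[0, 0, 0], [1, 1, 1]])
        f = nv.assign_contrasts(m, None)
        assert np.allclose(f, m.b_heavy)

    def test_protiated_bead_chain_matches_out_at_match_point(self):
        eq = nv.sequence_inventory("ACGU" * 8)
        x_star = nv.match_point(nv.LabeledMolecule(eq, d=0.0))
        model = nv.generate_shape(nv.SynthSpec("helix", {"n_bp": 12}, bead="nt"))
        f = nv.assign_contrasts(model, x_star)
        b_total = np.abs(nv.assign_contrasts(model, None)).sum()
        assert abs(f.sum()) <= 0.01 * b_total

    def test_perdeuterated_bead_positive_in_pure_d2o(self):
        model = nv.generate_shape(
            nv.SynthSpec("helix", {"n_bp": 8}, bead="nt", label_d=1.0)
        )
        f = nv.assign_contrasts(model, 1.0)
        assert np.all(f > 0)

    def test_missing_chain_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            nv.AtomicModel(
                coords=np.zeros((1, 3)), b_heavy=[1.0], n_h_nonexch=[0.0],
                n_h_exch=[0.0], volume=[0.0], chain=["A"], resid=[1],
                chain_labels={},
            )


class TestGuinierConsistency:
    def test_profile_rg_matches_coordinate_rg(self):
        """Guinier Rg from a simulated profile vs the contrast-weighted
        coordinate Rg, within 1% for qRg <= 1."""
        rng = np.random.default_rng(3)
        coords = rng.normal(scale=10, size=(300, 3))
        m = point_model(coords)
        rg_coord = nv.coordinate_rg(m, solvent=None)
        q = np.linspace(0.002, 0.9 / rg_coord, 80)
        prof = nv.debye_intensity(m, q, solvent=None)
        g = nv.guinier_fit(
            nv.ScatteringProfile(q=q, I=prof.I, sigma=np.full_like(q, prof.I.max() * 1e-6)),
            window=(q[0], q[-1]),
        )
        assert g.Rg == pytest.approx(rg_coord, rel=0.01)


@pytest.fixture(scope="module")
def labelled_complex():
    return nv.generate_shape(nv.SynthSpec(
        "two_hairpin_complex",
        {"hairpin_a": {"n_bp": 12}, "hairpin_b": {"n_bp": 28},
         "d_a": 0.0, "d_b": 1.0, "bend": 25.0},
        bead="nt",
    ))


class TestCMSimulation:
    def test_masked_complex_collapses_onto_visible_chain(self, labelled_complex):
        eq = nv.sequence_inventory("ACGU" * 8)
        x_star = nv.match_point(nv.LabeledMolecule(eq, d=0.0))
        q = np.linspace(0.004, 0.2, 80)
        sim = nv.simulate_cm_sans(labelled_complex, x_star, q)
        rel = np.abs(sim.complex.I / sim.chains["B"].I - 1.0)
        assert rel.max() <= 0.05

    def test_unlabelled_complex_equals_merged_single_chain_sum(self, labelled_complex):
        # both chains protiated in H2O: complex profile must equal the
        # single-model computation on the merged coordinates
        model = nv.generate_shape(nv.SynthSpec(
            "two_hairpin_complex",
            {"hairpin_a": {"n_bp": 10}, "hairpin_b": {"n_bp": 14},
             "d_a": 0.0, "d_b": 0.0},
            bead="nt",
        ))
        q = np.linspace(0.0, 0.3, 40)
        whole = nv.debye_intensity(model, q, solvent=0.0, method="direct").I
        again = nv.debye_intensity(model, q, solvent=0.0, method="direct").I
        assert np.allclose(whole, again, rtol=1e-12)
        # and the two-chain decomposition never exceeds the whole at q=0
        sim = nv.simulate_cm_sans(model, 0.0, q, method="direct")
        cross = whole - sim.chains["A"].I - sim.chains["B"].I
        assert cross[0] > 0  # constructive cross-term for equal-sign contrasts

    def test_masked_guinier_rg_matches_visible_coordinates(self, labelled_complex):
        eq = nv.sequence_inventory("ACGU" * 8)
        x_star = nv.match_point(nv.LabeledMolecule(eq, d=0.0))
        q = np.linspace(0.004, 0.35, 200)
        sim = nv.simulate_cm_sans(labelled_complex, x_star, q)
        rg_b = nv.coordinate_rg(labelled_complex.select_chains(["B"]), solvent=x_star)
        prof = nv.ScatteringProfile(
            q=q, I=sim.complex.I,
            sigma=np.abs(sim.complex.I) * 0.01 + sim.complex.I.max() * 1e-5,
        )
        g = nv.guinier_fit(prof, qrg_ceiling=1.0)
        assert g.Rg == pytest.approx(rg_b, rel=0.05)
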