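"""Synthetic generator: determinism, refit round trips, width profiles, strain link."""

import numpy as np
import pytest

from crossbeta.errors import InvalidParameterError
from crossbeta.helix import twist_from_crossover
from crossbeta.model_io import fit_helical_params, infer_layers_and_subunits, write_model
from crossbeta.conform import beta_strand_segments, detect_hbonds
from crossbeta.strain import end_spacing
from crossbeta.synth import (FibrilSpec, analytic_crossover_nm, generate_fibril,
                             mirror_fibril, width_profile)

from conftest import strip_ground_truth


class TestDeterminism:
    def test_byte_identical_pdb_given_seed(self, tmp_path):
        spec = FibrilSpec(twist=-3.55, rise=4.69, symmetry="C2", n_layers=3,
                          noise_sigma=0.3, seed=7)
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_model(generate_fibril(spec), p1)
        write_model(generate_fibril(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        a = generate_fibril(FibrilSpec(twist=-3.55, rise=4.69, symmetry="C2",
                                       n_layers=3, noise_sigma=0.3, seed=1))
        b = generate_fibril(FibrilSpec(twist=-3.55, rise=4.69, symmetry="C2",
                                       n_layers=3, noise_sigma=0.3, seed=2))
        assert not np.allclose(a.atoms["x"], b.atoms["x"])


class TestSpecValidation:
    def test_short_strand_rejected(self):
        with pytest.raises(InvalidParameterError):
            FibrilSpec(twist=-3.55, rise=4.69, strand_plan=((14, 15),))

    def test_edge_strand_rejected(self):
        with pytest.raises(InvalidParameterError):
            FibrilSpec(twist=-3.55, rise=4.69, strand_plan=((1, 5),))

    def test_two_templates_need_c1(self):
        with pytest.raises(InvalidParameterError):
            FibrilSpec(twist=-3.55, rise=4.69, symmetry="C2",
                       template_b=np.zeros((40, 3)))


class TestRefitRoundTrip:
    def test_twenty_random_specs_recover_exactly(self):
        """fit_helical_params inverts the generator to 1e-6 at zero noise."""
        rng = np.random.default_rng(4711)
        syms = ["C2", "pseudo-2_1", "C1"]
        for k in range(20):
            sym = syms[k % 3]
            sign = -1 if rng.random() < 0.5 else 1
            if sym == "C2":
                twist = sign * rng.uniform(0.5, 5.0)
                rise = rng.uniform(4.6, 4.85)
            elif sym == "pseudo-2_1":
                f = sign * rng.uniform(0.3, 2.0)
                twist = f - 180.0 if f < 0 else f + 180.0
                rise = rng.uniform(2.3, 2.45)
            else:
                twist = sign * rng.uniform(2.0, 8.0)
                rise = rng.uniform(9.2, 9.6)
            spec = FibrilSpec(twist=twist, rise=rise, symmetry=sym,
                              n_layers=int(rng.integers(3, 5)),
                              subunit_tilt_deg=float(rng.uniform(0, 4)))
            m = infer_layers_and_subunits(strip_ground_truth(generate_fibril(spec)))
            p = fit_helical_params(m)
            assert p.symmetry == sym, (k, sym, twist, rise)
            assert p.twist == pytest.approx(twist, abs=1e-6), (k, sym)
            assert p.rise == pytest.approx(rise, abs=1e-6), (k, sym)

    def test_mirroring_flips_twist_chirality(self, c2_fibril):
        p = fit_helical_params(c2_fibril)
        pm = fit_helical_params(infer_layers_and_subunits(
            strip_ground_truth(mirror_fibril(c2_fibril))))
        assert np.sign(pm.twist) == -np.sign(p.twist)
        assert abs(pm.twist) == pytest.approx(abs(p.twist), abs=1e-6)


class TestWidthProfile:
    @pytest.mark.parametrize("d_nm", [24.0, 44.0])
    def test_measured_crossover_matches_analytic(self, d_nm):
        rise = 4.8
        twist = twist_from_crossover(d_nm, rise)
        n_layers = int(1.8 * d_nm * 10 / rise)
        spec = FibrilSpec(twist=twist, rise=rise, symmetry="C1",
                          two_subunits=False, n_layers=n_layers,
                          strand_plan=(), salt_bridge_A=None)
        wp = width_profile(generate_fibril(spec))
        assert wp.spacing_nm is not None
        assert wp.spacing_nm == pytest.approx(analytic_crossover_nm(spec), rel=0.05)

    def test_untwisted_has_no_minima(self):
        spec = FibrilSpec(twist=0.0, rise=4.8, symmetry="C1", two_subunits=False,
                          n_layers=40, strand_plan=(), salt_bridge_A=None)
        wp = width_profile(generate_fibril(spec))
        assert wp.untwisted and len(wp.minima_nm) == 0

    def test_azimuth_averaging(self):
        spec = FibrilSpec(twist=twist_from_crossover(30.0, 4.8), rise=4.8,
                          symmetry="C1", two_subunits=False, n_layers=120,
                          strand_plan=(), salt_bridge_A=None)
        wp = width_profile(generate_fibril(spec), average_azimuths=4)
        assert wp.spacing_nm == pytest.approx(30.0, rel=0.05)


class TestStrainLink:
    def test_end_spacing_matches_strain_formula(self):
        """Cα spacing at the ends of a centred straight segment follows
        s = sqrt(b^2 + L^2 sin^2(rho/2)) -- the generator obeys the
        twist-strain geometry it is meant to emulate."""
        L_nm = 5.3
        d_nm = 25.0
        rise = 4.8
        n_res = 21
        xs = np.linspace(-L_nm * 5.0, L_nm * 5.0, n_res)  # nm -> A, centred
        template = np.column_stack([xs, np.zeros(n_res)])
        twist = twist_from_crossover(d_nm, rise)
        spec = FibrilSpec(twist=twist, rise=rise, symmetry="C1",
                          two_subunits=False, n_layers=3, strand_plan=(),
                          template=template, salt_bridge_A=None)
        m = generate_fibril(spec)
        chains = m.subunit_chains("A")
        for res in (1, n_res):
            a = m.chain_atoms(chains[0])
            b = m.chain_atoms(chains[1])
            pa = a[(a["resseq"] == res) & (a["atom"] == "CA")][["x", "y", "z"]].to_numpy()[0]
            pb = b[(b["resseq"] == res) & (b["atom"] == "CA")][["x", "y", "z"]].to_numpy()[0]
            measured_nm = np.linalg.norm(pa - pb) / 10.0
            expected = end_spacing(L_nm, d_nm, b=rise / 10.0)
            assert measured_nm == pytest.approx(expected, rel=0.01)


class TestNoiseMonotonicity:
    def test_strand_recall_non_increasing_with_noise(self):
        plan = {(14, 22), (30, 36)}
        recalls = []
        for sigma in (0.0, 0.5, 2.0):
            spec = FibrilSpec(twist=-3.55, rise=4.69, symmetry="C2", n_layers=4,
                              noise_sigma=sigma, seed=99)
            segs = beta_strand_segments(generate_fibril(spec))
            covered = set()
            for s in segs:
                if s.subunit == "A":
                    covered.update(range(s.start, s.end + 1))
            planned = {r for lo, hi in plan for r in range(lo, hi + 1)}
            recalls.append(len(covered & planned) / len(planned))
        assert recalls[0] == 1.0
        assert recalls[0] >= recalls[1] >= recalls[2]

    def test_designed_bond_distances(self, c2_fibril):
        # generator post-condition: designed strand bonds sit at N...O <= 3.2
        strand_res = set(range(14, 23)) | set(range(30, 37))
        ds = [b.distance for b in detect_hbonds(c2_fibril)
              if b.donor_res in strand_res and b.acceptor_res in strand_res]
        assert ds and max(ds) <= 3.2
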