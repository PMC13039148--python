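import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from piluskit import (
    GeneratorConfig,
    HelicalParams,
    StericCriterion,
    accommodation_profile,
    aperture_profile,
    apply_helical_symmetry,
    make_channel,
    make_sphere_library,
    make_synthetic_subunit,
    sample_conformer_library,
    site_acceptance,
    steric_accept,
    wide_config,
    wide_site_map,
)
from piluskit.model import AssemblyModel, Atom, AttachmentSite, SubunitModel
from piluskit.synth import channel_radius_at


def ring_oxygen_atom(coord):
    return Atom(1, "O5", "O", "NGA", 1, "A", np.asarray(coord, float), is_glycan=True)


def brute_force_accept(conformer_atoms, env_coords, criterion):
    """All-pairs oracle for the accelerated acceptance decision."""
    probe = [
        a
        for a in conformer_atoms
        if (a.is_ring_oxygen if criterion.glycan_atoms == "ring_oxygens" else a.is_glycan)
    ]
    if not probe or env_coords.size == 0:
        return True, math.inf
    pts = np.stack([a.coord for a in probe])
    dmin = float(cdist(pts, env_coords).min())
    return dmin >= criterion.threshold_A, dmin


class TestStericAccept:
    def test_empty_environment_accepts(self):
        ok, dmin = steric_accept(
            [ring_oxygen_atom([0, 0, 0])], np.zeros((0, 3)), StericCriterion(3.25)
        )
        assert ok and math.isinf(dmin)

    def test_coincident_atom_rejected(self):
        ok, dmin = steric_accept(
            [ring_oxygen_atom([1, 2, 3])],
            np.array([[1.0, 2.0, 3.0]]),
            StericCriterion(3.25),
        )
        assert not ok and dmin == 0.0

    def test_distance_exactly_at_threshold_accepted(self):
        ok, dmin = steric_accept(
            [ring_oxygen_atom([3.25, 0, 0])],
            np.array([[0.0, 0.0, 0.0]]),
            StericCriterion(3.25),
        )
        assert ok and dmin == pytest.approx(3.25)

    def test_empty_glycan_selection_accepts_with_inf_distance(self):
        protein_atom = Atom(1, "CA", "C", "ALA", 1, "A", np.zeros(3))
        ok, dmin = steric_accept(
            [protein_atom], np.array([[0.0, 0.0, 0.0]]), StericCriterion(3.25)
        )
        assert ok and math.isinf(dmin)

    @pytest.mark.parametrize("instance", range(10))
    def test_accelerated_matches_brute_force(self, instance):
        rng = np.random.default_rng(1000 + instance)
        env = rng.uniform(-15, 15, size=(500, 3))
        criterion = StericCriterion(threshold_A=float(rng.uniform(1.0, 6.0)))
        for _ in range(50):
            conformer = [
                Atom(
                    i + 1, "O5", "O", "NGA", i + 1, "A",
                    rng.uniform(-15, 15, size=3), is_glycan=True,
                )
                for i in range(4)
            ]
            fast = steric_accept(conformer, env, criterion)
            slow = brute_force_accept(conformer, env, criterion)
            assert fast[0] == slow[0]
            assert fast[1] == pytest.approx(slow[1], abs=1e-12)


class TestSiteAcceptance:
    def test_tiny_threshold_accepts_everything(self, identity_frame_assembly):
        lib = make_sphere_library(200, 10.0, seed=9)
        channel = make_channel(
            GeneratorConfig(seed=0, channel_radius_A=30.0, channel_length_A=30.0)
        )
        acc, tot, frac = site_acceptance(
            identity_frame_assembly,
            AttachmentSite(0, 1),
            lib,
            StericCriterion(threshold_A=1e-9),
            environment=channel,
        )
        assert (acc, tot, frac) == (200, 200, 1.0)

    def test_sphere_in_cylinder_matches_closed_form(self, identity_frame_assembly):
        """Single-atom conformers uniform on a sphere of radius r inside a
        dense cylindrical wall at radius R accept with probability
        1 − sqrt(1 − ((R − t)/r)²)."""
        r, R, t, M = 10.0, 12.0, 3.25, 10000
        lib = make_sphere_library(M, r, seed=5)
        channel = make_channel(
            GeneratorConfig(
                seed=0, channel_radius_A=R, channel_length_A=30.0,
                ring_spacing_A=0.4, ring_arc_A=0.4,
            )
        )
        acc, tot, frac = site_acceptance(
            identity_frame_assembly, AttachmentSite(0, 1), lib,
            StericCriterion(threshold_A=t), environment=channel,
        )
        expected = 1.0 - math.sqrt(1.0 - ((R - t) / r) ** 2)
        se = math.sqrt(expected * (1.0 - expected) / M)
        assert tot == M
        assert abs(frac - expected) <= 3.0 * se

    def test_subsampling_is_seeded_and_reproducible(self, identity_frame_assembly):
        lib = make_sphere_library(500, 10.0, seed=2)
        channel = make_channel(
            GeneratorConfig(seed=0, channel_radius_A=12.0, channel_length_A=30.0)
        )
        kwargs = dict(
            site=AttachmentSite(0, 1), library=lib,
            criterion=StericCriterion(3.25), environment=channel,
            subsample=100, seed=77,
        )
        first = site_acceptance(identity_frame_assembly, **kwargs)
        second = site_acceptance(identity_frame_assembly, **kwargs)
        assert first == second
        assert first[1] == 100

    def test_acceptance_monotone_in_threshold(self, identity_frame_assembly):
        lib = make_sphere_library(2000, 10.0, seed=3)
        channel = make_channel(
            GeneratorConfig(seed=0, channel_radius_A=12.0, channel_length_A=30.0)
        )
        fracs = []
        for t in (3.25, 3.75):
            _, _, frac = site_acceptance(
                identity_frame_assembly, AttachmentSite(0, 1), lib,
                StericCriterion(threshold_A=t), environment=channel,
            )
            fracs.append(frac)
        assert fracs[1] <= fracs[0]

    def test_acceptance_monotone_in_cylinder_radius(self, identity_frame_assembly):
        lib = make_sphere_library(2000, 10.0, seed=3)
        fracs = []
        for R in (11.0, 12.0, 14.0, 20.0):
            channel = make_channel(
                GeneratorConfig(seed=0, channel_radius_A=R, channel_length_A=30.0)
            )
            _, _, frac = site_acceptance(
                identity_frame_assembly, AttachmentSite(0, 1), lib,
                StericCriterion(3.25), environment=channel,
            )
            fracs.append(frac)
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_adding_environment_atoms_never_increases_acceptance(
        self, identity_frame_assembly
    ):
        lib = make_sphere_library(1000, 10.0, seed=4)
        base = make_channel(
            GeneratorConfig(seed=0, channel_radius_A=13.0, channel_length_A=30.0)
        )
        # augmented environment: same wall plus a second, tighter wall
        tight = make_channel(
            GeneratorConfig(seed=0, channel_radius_A=11.5, channel_length_A=30.0)
        )
        both = AssemblyModel(
            subunits=base.subunits + tight.subunits, kind="channel"
        )
        _, _, frac_base = site_acceptance(
            identity_frame_assembly, AttachmentSite(0, 1), lib,
            StericCriterion(3.25), environment=base,
        )
        _, _, frac_both = site_acceptance(
            identity_frame_assembly, AttachmentSite(0, 1), lib,
            StericCriterion(3.25), environment=both,
        )
        assert frac_both <= frac_base


@pytest.fixture(scope="module")
def small_decorated_filament():
    subunit = make_synthetic_subunit(wide_config(seed=21))
    return apply_helical_symmetry(subunit, HelicalParams(92.4, 9.2), 8)


@pytest.fixture(scope="module")
def small_library():
    return sample_conformer_library(
        GeneratorConfig(seed=22, conformer_count=120, monomers_per_conformer=4)
    )


class TestAccommodationProfile:
    def test_no_channel_equals_giant_channel(
        self, small_decorated_filament, small_library
    ):
        criterion = StericCriterion(3.25)
        site_map = wide_site_map()
        kwargs = dict(subsample=40, seed=5, bin_width_A=10.0)
        prof_none = accommodation_profile(
            small_decorated_filament, site_map, small_library, criterion, **kwargs
        )
        giant = make_channel(
            GeneratorConfig(seed=0, channel_radius_A=500.0, channel_length_A=80.0)
        )
        prof_giant = accommodation_profile(
            small_decorated_filament, site_map, small_library, criterion,
            environment=giant, **kwargs,
        )
        np.testing.assert_array_equal(prof_none.n_accepted, prof_giant.n_accepted)
        np.testing.assert_array_equal(prof_none.n_total, prof_giant.n_total)

    def test_constriction_bin_has_minimum_acceptance(
        self, small_decorated_filament, small_library
    ):
        z_mid = 0.5 * float(small_decorated_filament.coords()[:, 2].max())
        channel = make_channel(
            GeneratorConfig(
                seed=0, channel_radius_A=40.0, constriction_depth_A=22.0,
                constriction_z_A=0.0, constriction_sigma_A=6.0,
                channel_length_A=140.0,
            )
        ).translated([0.0, 0.0, z_mid])
        criterion = StericCriterion(3.25)
        prof = accommodation_profile(
            small_decorated_filament, wide_site_map(), small_library, criterion,
            environment=channel, subsample=60, seed=6, bin_width_A=10.0,
        )
        frac = prof.acceptance_fraction
        populated = ~np.isnan(frac)
        assert populated.any()
        min_bin = np.nanargmin(frac)
        constriction_bin = np.searchsorted(prof.bin_edges_A, z_mid, side="right") - 1
        assert frac[min_bin] == pytest.approx(frac[constriction_bin])
        # the profile is verified against per-conformer brute force at the
        # minimum-bin sites via the oracle-equivalence tests of steric_accept

    def test_all_blocking_channel_rejects_everything(
        self, small_decorated_filament, small_library
    ):
        # filament fully wrapped by a wall tight enough to clash with any graft
        z_max = float(small_decorated_filament.coords()[:, 2].max())
        wall_atoms = []
        serial = 1
        for z in np.arange(-30.0, z_max + 30.0, 1.0):
            for ang in np.arange(0, 2 * math.pi, 0.08):
                for radius in np.arange(1.0, 46.0, 3.0):
                    wall_atoms.append(
                        Atom(
                            serial, "CA", "C", "ALA", 1, "A",
                            np.array([radius * math.cos(ang), radius * math.sin(ang), z]),
                        )
                    )
                    serial += 1
        blocker = AssemblyModel(
            subunits=[SubunitModel(atoms=wall_atoms)], kind="channel"
        )
        prof = accommodation_profile(
            small_decorated_filament, wide_site_map(), small_library,
            StericCriterion(3.25), environment=blocker,
            subsample=10, seed=7, bin_width_A=10.0,
        )
        frac = prof.acceptance_fraction
        assert np.all(frac[~np.isnan(frac)] == 0.0)

    def test_profile_tsv_roundtrip_bytes(self, tmp_path, small_decorated_filament, small_library):
        prof = accommodation_profile(
            small_decorated_filament, wide_site_map(), small_library,
            StericCriterion(3.25), subsample=20, seed=8, bin_width_A=10.0,
        )
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        prof.to_tsv(p1)
        prof.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()
        header = p1.read_text().splitlines()
        assert header[0].startswith("# threshold_A=3.25")
        assert header[1].split("\t") == [
            "z_bin_center_A", "n_total", "n_accepted",
            "acceptance_fraction", "rejection_rate",
        ]


class TestApertureProfile:
    def test_perfect_cylinder_constant_profile(self):
        channel = make_channel(
            GeneratorConfig(seed=0, channel_radius_A=25.0, channel_length_A=60.0)
        )
        _, radii = aperture_profile(channel, bin_width_A=5.0)
        populated = radii[~np.isnan(radii)]
        np.testing.assert_allclose(populated, 25.0, atol=1e-9)

    def test_gaussian_constriction_minimum_location_and_depth(self):
        config = GeneratorConfig(
            seed=0, channel_radius_A=30.0, constriction_depth_A=12.0,
            constriction_z_A=10.0, constriction_sigma_A=8.0,
            channel_length_A=100.0,
        )
        channel = make_channel(config)
        centers, radii = aperture_profile(channel, bin_width_A=4.0)
        min_idx = np.nanargmin(radii)
        assert abs(centers[min_idx] - 10.0) <= 2.0  # within the z0 bin
        assert radii[min_idx] == pytest.approx(30.0 - 12.0, abs=0.2)
        # generator ground truth at the atom level
        coords = channel.coords()
        r_expected = channel_radius_at(config, coords[:, 2])
        np.testing.assert_allclose(
            np.hypot(coords[:, 0], coords[:, 1]), r_expected, atol=1e-9
        )

    def test_single_ring_populates_one_bin(self):
        channel = make_channel(
            GeneratorConfig(seed=0, channel_radius_A=10.0, channel_length_A=0.5,
                            ring_spacing_A=1.0)
        )
        _, radii = aperture_profile(channel, bin_width_A=5.0)
        assert np.sum(~np.isnan(radii)) == 1

    def test_empty_channel_rejected(self):
        empty = AssemblyModel(subunits=[SubunitModel(atoms=[])], kind="channel")
        with pytest.raises(ValueError, match="empty channel"):
            aperture_profile(empty)
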