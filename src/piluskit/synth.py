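"""Seeded generators for every input the pipeline needs.

These emulate the geometric structure the analysis assumes: a ~30 Å pilin
subunit with an α-helical N-terminal segment and a globular coil, carrying
surface-exposed attachment serines at the literature residue numbers
(S59/S66/S71 wide-like, S73 narrow-like); self-avoiding-chain glycan
conformer ensembles; and a cylindrical channel with a single Gaussian
constriction whose ground-truth aperture is known by construction.

Every generator is a pure function of its config (seed included); identical
configs give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .glycan import (
    FIRST_MONOMER_OFFSET,
    MONOMER_SPACING,
    OG_LOCAL,
    monomer_template_atoms,
)
from scipy.spatial.transform import Rotation
from .model import (
    AssemblyModel,
    Atom,
    ConformerLibrary,
    GlycanTopology,
    SubunitModel,
    monosaccharide_N,
)

#: α-helix backbone geometry used for the N-terminal segment.
_HELIX_RISE = 1.5       # Å per residue
_HELIX_RADIUS = 2.3     # Å
_HELIX_TURN = 100.0     # degrees per residue
_CA_STEP = 3.8          # Å between consecutive Cα
_MIN_CA_SEP = 3.2       # Å clash floor for the coil walk


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic generators (all lengths in Å).

    ``subunit_residues`` defaults to the wide-like pilin length (125; the
    narrow-like pilin has 111).  ``site_residues`` lists the attachment
    serine numbers.  ``radial_offset_A`` places the subunit centroid off the
    filament axis so helical stacking produces a hollow-free filament wall.
    """

    seed: int = 0
    subunit_residues: int = 125
    subunit_width_A: float = 30.0
    site_residues: tuple[int, ...] = (59, 66, 71)
    radial_offset_A: float = 9.0
    # channel geometry
    channel_radius_A: float = 30.0
    channel_length_A: float = 100.0
    constriction_depth_A: float = 0.0
    constriction_z_A: float = 0.0
    constriction_sigma_A: float = 8.0
    ring_spacing_A: float = 1.5
    ring_arc_A: float = 1.5
    # conformer sampling
    conformer_count: int = 1000
    monomers_per_conformer: int = 4
    step_length_A: float = 5.0
    min_self_distance_A: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "subunit_width_A", "radial_offset_A", "channel_radius_A",
            "channel_length_A", "constriction_sigma_A", "ring_spacing_A",
            "ring_arc_A", "step_length_A", "min_self_distance_A",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for res in self.site_residues:
            if not 1 <= res <= self.subunit_residues:
                raise ValueError(
                    f"site residue {res} outside 1..{self.subunit_residues}"
                )


def wide_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Wide-pilus-like defaults: 125 residues, sites S59/S66/S71."""
    return replace(
        GeneratorConfig(seed=seed, subunit_residues=125, site_residues=(59, 66, 71)),
        **overrides,
    )


def narrow_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Narrow-pilus-like defaults: 111 residues, single site S73."""
    return replace(
        GeneratorConfig(seed=seed, subunit_residues=111, site_residues=(73,)),
        **overrides,
    )


def _sample_ca_trace(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Cα trace: ideal α-helix for the N-terminal third, then a confined
    self-avoiding coil, the whole bounded by ~subunit_width_A."""
    n = config.subunit_residues
    # helix kept short enough that its axial extent stays inside the width cap
    n_helix = max(3, min(17, n // 6))
    radius_cap = 0.38 * config.subunit_width_A
    cas = np.zeros((n, 3))
    for i in range(n_helix):
        ang = math.radians(i * _HELIX_TURN)
        cas[i] = (
            _HELIX_RADIUS * math.cos(ang),
            _HELIX_RADIUS * math.sin(ang),
            i * _HELIX_RISE,
        )
    center = np.array([0.0, 0.0, (n_helix - 1) * _HELIX_RISE * 0.5])
    for i in range(n_helix, n):
        prev = cas[i - 1]
        for _ in range(200):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            cand = prev + _CA_STEP * v
            if np.linalg.norm(cand - center) > radius_cap:
                continue
            d = np.linalg.norm(cas[max(0, i - 40):i - 1] - cand, axis=1)
            if d.size and d.min() < _MIN_CA_SEP:
                continue
            cas[i] = cand
            break
        else:
            # fall back to a radially inward step; always inside the cap
            inward = center - prev
            cas[i] = prev + _CA_STEP * inward / max(np.linalg.norm(inward), 1e-9)
    return cas


def _site_backbone_directions(outward: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Backbone N/C directions at a site serine such that the attachment
    frame maps the canonical Oγ offset onto the outward surface normal.

    With e1 = unit(Cα→N), e2 the Gram-Schmidt of (Cα→C), the graft
    direction is ``û·(e1,e2,e3)`` for ``û = OG_LOCAL/|OG_LOCAL|``; choosing
    the frame as a rotation carrying û onto ``outward`` makes the serine
    surface-exposed in the sense that matters: grafted chains leave the
    subunit body.
    """
    u_hat = OG_LOCAL / np.linalg.norm(OG_LOCAL)
    o = outward / np.linalg.norm(outward)
    v = np.cross(u_hat, o)
    s = np.linalg.norm(v)
    c = float(u_hat @ o)
    if s < 1e-12:
        R0 = np.eye(3) if c > 0 else Rotation.from_rotvec([math.pi, 0, 0]).as_matrix()
    else:
        R0 = Rotation.from_rotvec(v / s * math.atan2(s, c)).as_matrix()
    # frame rows are the columns of the rotation carrying û onto outward
    return R0[:, 0], R0[:, 1]


def make_synthetic_subunit(config: GeneratorConfig) -> SubunitModel:
    """Generate a backbone-only pilin-like subunit.

    Each residue owns N, CA and C pseudo-atoms; attachment serines
    additionally own a surface-pointing OG, with their backbone oriented so
    the attachment frame grafts glycans along the outward surface normal.
    The subunit is placed with its centroid near ``(radial_offset_A, 0, 0)``
    so it can be stacked into a filament around the +z axis directly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    cas = _sample_ca_trace(config, rng)
    # place at the filament radial position before orienting site frames
    cas = cas + (np.array([config.radial_offset_A, 0.0, 0.0]) - cas.mean(axis=0))
    centroid = cas.mean(axis=0)
    sites = set(config.site_residues)
    # attachment serines sit on the outer filament envelope: move their Cα
    # just past the subunit's maximum radius, within the subunit's outward
    # sector (glycosylation sites cluster on the pilin's surface face,
    # clear of neighbouring subunits in the assembled pilus)
    radii = np.hypot(cas[:, 0], cas[:, 1])
    r_surf = float(radii.max()) + 0.5
    max_sector = math.radians(25.0)
    for res_seq in sites:
        i = res_seq - 1
        phi = math.atan2(cas[i, 1], cas[i, 0]) if radii[i] >= 0.5 else 0.0
        phi = max(-max_sector, min(max_sector, phi))
        cas[i, :2] = r_surf * np.array([math.cos(phi), math.sin(phi)])
    atoms: list[Atom] = []
    serial = 1
    n = config.subunit_residues
    for i in range(n):
        res_seq = i + 1
        res_name = "SER" if res_seq in sites else "ALA"
        ca = cas[i]
        if res_seq in sites:
            # surface sites on a filament face radially away from the axis
            outward = np.array([ca[0], ca[1], 0.0])
            if np.linalg.norm(outward) < 1.0:
                outward = ca - centroid
            e1, e2 = _site_backbone_directions(outward)
            n_pos = ca + 1.45 * e1
            c_pos = ca + 1.52 * e2
        else:
            prev_dir = cas[i - 1] - ca if i > 0 else cas[min(1, n - 1)] - ca
            next_dir = cas[i + 1] - ca if i < n - 1 else cas[n - 2] - ca
            prev_dir = prev_dir / max(np.linalg.norm(prev_dir), 1e-9)
            next_dir = next_dir / max(np.linalg.norm(next_dir), 1e-9)
            n_pos = ca + 1.45 * prev_dir
            # keep N and C non-collinear even on straight trace segments
            if abs(prev_dir @ next_dir) > 0.99:
                u, _ = _orthobasis(next_dir)
                next_dir = (next_dir + 0.3 * u)
                next_dir = next_dir / np.linalg.norm(next_dir)
            c_pos = ca + 1.52 * next_dir
        for name, elem, pos in (("N", "N", n_pos), ("CA", "C", ca), ("C", "C", c_pos)):
            atoms.append(
                Atom(
                    serial=serial, name=name, element=elem, res_name=res_name,
                    res_seq=res_seq, chain_id="A", coord=pos,
                )
            )
            serial += 1
        if res_seq in sites:
            outward = ca - centroid
            outward = outward / max(np.linalg.norm(outward), 1e-9)
            atoms.append(
                Atom(
                    serial=serial, name="OG", element="O", res_name="SER",
                    res_seq=res_seq, chain_id="A", coord=ca + 2.4 * outward,
                )
            )
            serial += 1
    subunit = SubunitModel(atoms=atoms, site_residues=sorted(sites))
    subunit.validate_sites()
    return subunit


def sample_chain_centers(
    config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """One self-avoiding chain of monomer centres in the local frame.

    The algorithm (replicated verbatim by the test oracle): centre 0 sits at
    ``OG_LOCAL + FIRST_MONOMER_OFFSET·û`` with ``û = OG_LOCAL/|OG_LOCAL|``;
    each subsequent centre is the previous plus ``step_length_A`` times a
    unit vector drawn from the normalised 3-d standard normal, redrawn (up
    to 200 times) until all non-adjacent centre pairs are at least
    ``min_self_distance_A`` apart.
    """
    u0 = OG_LOCAL / np.linalg.norm(OG_LOCAL)
    centers = [OG_LOCAL + FIRST_MONOMER_OFFSET * u0]
    for k in range(1, config.monomers_per_conformer):
        for _ in range(200):
            v = rng.standard_normal(3)
            v = v / np.linalg.norm(v)
            cand = centers[-1] + config.step_length_A * v
            earlier = np.array(centers[:-1]) if k >= 2 else None
            if earlier is not None:
                d = np.linalg.norm(earlier - cand, axis=1)
                if d.min() < config.min_self_distance_A:
                    continue
            centers.append(cand)
            break
        else:
            raise RuntimeError(
                "self-avoiding chain sampling failed after 200 retries; "
                "loosen min_self_distance_A or step_length_A"
            )
    return np.array(centers)


def sample_conformer_library(
    config: GeneratorConfig, topology: GlycanTopology | None = None
) -> ConformerLibrary:
    """Sample M self-avoiding glycan conformers in the local attachment frame.

    Monomer centres follow :func:`sample_chain_centers`; each centre carries
    the monomer hexagon template oriented normal to the incoming step
    direction.  The topology defaults to repeated GalNAc monomers of the
    configured chain length.
    """
    if config.conformer_count < 1:
        raise ValueError("conformer_count must be >= 1")
    if topology is None:
        topology = GlycanTopology(
            tuple("N" for _ in range(config.monomers_per_conformer)),
            tuple("a(1-3)" for _ in range(config.monomers_per_conformer - 1)),
        )
    if len(topology) != config.monomers_per_conformer:
        raise ValueError("topology length must equal monomers_per_conformer")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    u0 = OG_LOCAL / np.linalg.norm(OG_LOCAL)
    frames: list[list[Atom]] = []
    for _ in range(config.conformer_count):
        centers = sample_chain_centers(config, rng)
        atoms: list[Atom] = []
        serial = 1
        for k, code in enumerate(topology.monomers):
            direction = centers[k] - centers[k - 1] if k > 0 else u0
            monomer = monomer_template_atoms(
                code, centers[k], direction, res_seq=k + 1, serial_start=serial
            )
            atoms.extend(monomer)
            serial += len(monomer)
        frames.append(atoms)
    return ConformerLibrary(frames=frames, topology=topology, seed=config.seed)


def make_sphere_library(
    n_conformers: int, radius_A: float, seed: int = 0
) -> ConformerLibrary:
    """Calibration library: single-ring-oxygen conformers uniform on a sphere.

    The sphere is centred on the local frame origin (not the Oγ offset), so a
    site whose frame is the identity at the origin grafts the points onto a
    sphere centred on the assembly axis — the geometry with a closed-form
    acceptance fraction inside a cylindrical wall.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    v = rng.standard_normal((n_conformers, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = radius_A * v
    frames = [
        [
            Atom(
                serial=1, name="O5", element="O", res_name="NGA", res_seq=1,
                chain_id="A", coord=p, is_glycan=True,
            )
        ]
        for p in pts
    ]
    return ConformerLibrary(frames=frames, topology=monosaccharide_N(), seed=seed)


def _orthobasis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(d @ ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(d, u)


def channel_radius_at(config: GeneratorConfig, z: np.ndarray) -> np.ndarray:
    """Ground-truth local radius R(z) of the generated channel."""
    z = np.asarray(z, dtype=float)
    return config.channel_radius_A - config.constriction_depth_A * np.exp(
        -((z - config.constriction_z_A) ** 2) / (2.0 * config.constriction_sigma_A**2)
    )


def make_channel(config: GeneratorConfig) -> AssemblyModel:
    """Generate a pseudo-atom cylindrical channel on the +z axis.

    Rings of Cα-flagged pseudo-atoms are stacked every ``ring_spacing_A``
    over ``z ∈ [−L/2, +L/2]`` with in-ring arc spacing ``ring_arc_A``; the
    local radius follows a single Gaussian constriction,
    ``R(z) = R − δ·exp(−(z−z₀)²/(2σ²))``.  A closed channel
    (``δ ≥ R``) is refused.
    """
    if config.constriction_depth_A >= config.channel_radius_A:
        raise ValueError(
            "constriction depth >= channel radius closes the channel; "
            "request a smaller depth"
        )
    half = 0.5 * config.channel_length_A
    n_rings = int(math.floor(config.channel_length_A / config.ring_spacing_A)) + 1
    zs = np.linspace(-half, half, n_rings)
    atoms: list[Atom] = []
    serial = 1
    res_seq = 1
    for z in zs:
        r = float(channel_radius_at(config, np.array([z]))[0])
        n_pts = max(3, int(math.ceil(2.0 * math.pi * r / config.ring_arc_A)))
        for j in range(n_pts):
            ang = 2.0 * math.pi * j / n_pts
            atoms.append(
                Atom(
                    serial=serial, name="CA", element="C", res_name="ALA",
                    res_seq=res_seq, chain_id="A",
                    coord=np.array([r * math.cos(ang), r * math.sin(ang), z]),
                )
            )
            serial += 1
        res_seq += 1
    return AssemblyModel(
        subunits=[SubunitModel(atoms=atoms)], kind="channel"
    )
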