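"""Steric accommodation of grafted glycan conformers and channel profiling.

A grafted conformer is accepted if every selected glycan atom keeps at least
a threshold distance from every selected environment atom.  The default
criterion pairs glycan ring oxygens against protein α-carbons at thresholds
of 3.25 Å or 3.75 Å — smaller and larger cut-offs acting as proxies for
lower and higher filament stiffness.  Distances exactly at the threshold
count as accepted.

The per-site statistic is the fraction of an ensemble of conformers accepted
at that site; profiled along the filament axis it localises where a channel
constriction forces glycan rejection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import (
    AccommodationProfile,
    AssemblyModel,
    Atom,
    AttachmentSite,
    ConformerLibrary,
    atom_coords,
    select_atoms,
)
from .glycan import SiteMap, attachment_frame, graft_conformer

#: The two threshold distances used as stiffness proxies (Å).
DEFAULT_THRESHOLDS = (3.25, 3.75)


@dataclass(frozen=True)
class StericCriterion:
    """Accept/reject rule for one grafted conformer.

    ``glycan_atoms`` selects which conformer atoms are tested
    (``ring_oxygens`` default, or ``glycan`` for all sugar atoms) and
    ``protein_atoms`` which environment atoms oppose them
    (``alpha_carbons`` default, or ``protein`` for all).  The attachment
    residue's own atoms are excluded from the environment of its site.
    """

    threshold_A: float = 3.25
    glycan_atoms: str = "ring_oxygens"
    protein_atoms: str = "alpha_carbons"

    def __post_init__(self) -> None:
        if not self.threshold_A > 0:
            raise ValueError(f"threshold must be positive, got {self.threshold_A}")
        if self.glycan_atoms not in {"ring_oxygens", "glycan"}:
            raise ValueError(f"unknown glycan atom selection {self.glycan_atoms!r}")
        if self.protein_atoms not in {"alpha_carbons", "protein"}:
            raise ValueError(f"unknown protein atom selection {self.protein_atoms!r}")


def steric_accept(
    conformer_atoms: list[Atom],
    environment: "np.ndarray | cKDTree",
    criterion: StericCriterion,
) -> tuple[bool, float]:
    """Accept/reject one grafted conformer against an environment.

    ``environment`` is an (N, 3) array of already-selected environment
    coordinates (or a prebuilt KD-tree over them).  Returns
    ``(accepted, min_distance_A)``; an empty glycan selection or empty
    environment accepts with infinite minimum distance.  The spatial-indexed
    path is exact: results match all-pairs brute force.
    """
    if criterion.glycan_atoms == "ring_oxygens":
        probe = [a for a in conformer_atoms if a.is_ring_oxygen]
    else:
        probe = [a for a in conformer_atoms if a.is_glycan]
    if not probe:
        return True, math.inf
    pts = atom_coords(probe)
    if isinstance(environment, cKDTree):
        tree = environment
        if tree.n == 0:
            return True, math.inf
    else:
        env = np.asarray(environment, dtype=float)
        if env.size == 0:
            return True, math.inf
        tree = cKDTree(env)
    dmin = float(np.min(tree.query(pts, k=1)[0]))
    return dmin >= criterion.threshold_A, dmin


def environment_coords(
    assembly: AssemblyModel,
    criterion: StericCriterion,
    exclude_site: AttachmentSite | None = None,
) -> np.ndarray:
    """Environment coordinates for a criterion, optionally excluding the
    attachment residue's own atoms (always within bonded distance of the
    first monomer, so leaving them in rejects everything trivially)."""
    coords = []
    for i, subunit in enumerate(assembly.subunits):
        for a in select_atoms(subunit, criterion.protein_atoms):
            if (
                exclude_site is not None
                and i == exclude_site.subunit_index
                and a.res_seq == exclude_site.res_seq
            ):
                continue
            coords.append(a.coord)
    if not coords:
        return np.zeros((0, 3))
    return np.stack(coords)


def _subsample_indices(
    n_conformers: int, subsample: int | None, seed: int | None, site: AttachmentSite
) -> np.ndarray:
    if subsample is None or subsample >= n_conformers:
        return np.arange(n_conformers)
    if subsample < 0:
        raise ValueError("subsample must be non-negative")
    # per-site deterministic stream: same seed → same subsample
    ss = np.random.SeedSequence(
        entropy=0 if seed is None else seed,
        spawn_key=(site.subunit_index, site.res_seq),
    )
    rng = np.random.default_rng(ss)
    return np.sort(rng.choice(n_conformers, size=subsample, replace=False))


def site_acceptance(
    assembly: AssemblyModel,
    site: AttachmentSite,
    library: ConformerLibrary,
    criterion: StericCriterion,
    environment: AssemblyModel | None = None,
    subsample: int | None = None,
    seed: int | None = None,
) -> tuple[int, int, float]:
    """Acceptance statistics of a conformer library grafted at one site.

    Conformers are grafted rigidly at the site's attachment frame and tested
    against the α-carbons (or all protein atoms) of the assembly plus the
    optional extra ``environment`` (e.g. a docked channel).  Subsampling is
    seeded and without replacement.  Returns ``(accepted, total, fraction)``.
    """
    subunit = assembly.subunits[site.subunit_index]
    frame = attachment_frame(subunit, site.res_seq)
    env = environment_coords(assembly, criterion, exclude_site=site)
    if environment is not None:
        extra = environment_coords(environment, criterion)
        env = np.concatenate([env, extra]) if extra.size else env
    tree = cKDTree(env) if env.size else None
    indices = _subsample_indices(library.n_conformers, subsample, seed, site)
    accepted = 0
    for i in indices:
        placed = graft_conformer(library.frames[i], frame)
        ok, _ = steric_accept(
            placed, tree if tree is not None else np.zeros((0, 3)), criterion
        )
        accepted += ok
    total = len(indices)
    return accepted, total, accepted / total if total else math.nan


def accommodation_profile(
    assembly: AssemblyModel,
    site_map: SiteMap,
    libraries: "ConformerLibrary | dict[int, ConformerLibrary]",
    criterion: StericCriterion,
    environment: AssemblyModel | None = None,
    bin_width_A: float = 5.0,
    subsample: int | None = 1000,
    seed: int | None = None,
) -> AccommodationProfile:
    """Axially binned acceptance of grafted conformers along a filament.

    Every site of every subunit is grafted with its library (a single
    library, or one per site residue number) and assigned to the axial bin
    containing its attachment Oγ z-coordinate; per-bin acceptance pools the
    accepted/total counts of the sites in the bin.  Empty bins are flagged,
    never interpolated.
    """
    if bin_width_A <= 0:
        raise ValueError("bin width must be positive")
    sites = [
        AttachmentSite(subunit_index=i, res_seq=res_seq, topology=topo)
        for i in range(assembly.n_subunits)
        for res_seq, topo in site_map.entries
    ]
    if not sites:
        raise ValueError("site map has no entries")
    per_site: dict[AttachmentSite, tuple[int, int]] = {}
    zs: list[float] = []
    for site in sites:
        subunit = assembly.subunits[site.subunit_index]
        res_atoms = subunit.residue_atoms(site.res_seq)
        if "OG" not in res_atoms:
            raise ValueError(
                f"site residue {site.res_seq} in subunit {site.subunit_index} "
                "has no OG atom"
            )
        zs.append(float(res_atoms["OG"].coord[2]))
        lib = libraries[site.res_seq] if isinstance(libraries, dict) else libraries
        acc, tot, _ = site_acceptance(
            assembly, site, lib, criterion,
            environment=environment, subsample=subsample, seed=seed,
        )
        per_site[site] = (acc, tot)
    z = np.asarray(zs)
    lo = math.floor(z.min() / bin_width_A) * bin_width_A
    hi = math.ceil(z.max() / bin_width_A) * bin_width_A
    if hi <= lo:
        hi = lo + bin_width_A
    edges = np.arange(lo, hi + 0.5 * bin_width_A, bin_width_A)
    n_bins = len(edges) - 1
    n_total = np.zeros(n_bins, dtype=int)
    n_accepted = np.zeros(n_bins, dtype=int)
    bin_idx = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, n_bins - 1)
    for site, b in zip(sites, bin_idx):
        acc, tot = per_site[site]
        n_total[b] += tot
        n_accepted[b] += acc
    return AccommodationProfile(
        bin_edges_A=edges,
        n_total=n_total,
        n_accepted=n_accepted,
        per_site=per_site,
        threshold_A=criterion.threshold_A,
        seed=seed,
    )


def aperture_profile(
    channel: AssemblyModel, bin_width_A: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin minimum radial distance of channel atoms from the +z axis.

    Returns ``(bin_centers_A, radii_A)``; empty bins carry NaN.  The global
    minimum of the profile is the channel aperture.
    """
    if bin_width_A <= 0:
        raise ValueError("bin width must be positive")
    coords = channel.coords()
    if coords.shape[0] == 0:
        raise ValueError("empty channel model")
    z = coords[:, 2]
    r = np.hypot(coords[:, 0], coords[:, 1])
    lo = math.floor(z.min() / bin_width_A) * bin_width_A
    hi = math.ceil(z.max() / bin_width_A) * bin_width_A
    if hi <= lo:
        hi = lo + bin_width_A
    edges = np.arange(lo, hi + 0.5 * bin_width_A, bin_width_A)
    n_bins = len(edges) - 1
    radii = np.full(n_bins, np.nan)
    idx = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, n_bins - 1)
    for b in range(n_bins):
        mask = idx == b
        if np.any(mask):
            radii[b] = float(r[mask].min())
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, radii
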