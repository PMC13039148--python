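"""Core domain types for pilus filament and glycan modelling.

The package-wide coordinate convention is that filament and channel axes run
along +z through the origin; builders emit models in that frame and callers
of the analysis routines are expected to pre-align external models with
:func:`piluskit.helix.align_to_axis`.

Residue numbering is 1-based and preserves author numbering, so glycan
attachment serines are addressed by their ``res_seq`` (e.g. S59, S66, S71 on
the wide pilin, S73 on the narrow pilin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

#: Atom name that marks the single ring oxygen of each sugar monomer.
RING_OXYGEN_NAME = "O5"

#: Residue names used for glycan monomers, keyed by single-letter code:
#: N = GalNAc, H = hexose (Man), W = pseudaminic-acid derivative 5Am7Ac,
#: X = unidentified 346 Da monosaccharide.
GLYCAN_RES_NAMES: dict[str, str] = {
    "N": "NGA",
    "H": "MAN",
    "W": "PSE",
    "X": "UNX",
}
GLYCAN_CODES_BY_RES_NAME: dict[str, str] = {v: k for k, v in GLYCAN_RES_NAMES.items()}


@dataclass(frozen=True)
class Atom:
    """A single atom record.

    ``coord`` is a length-3 float array in Å.  ``is_glycan`` marks sugar
    atoms; the derived flags follow from it and from the atom name:
    an alpha carbon is any non-glycan atom named ``CA``, and a ring oxygen is
    a glycan atom named ``O5`` (one per monomer, by builder convention).
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coord: np.ndarray
    is_glycan: bool = False

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,):
            raise ValueError(f"coord must be a 3-vector, got shape {coord.shape}")
        if not np.all(np.isfinite(coord)):
            raise ValueError(f"non-finite coordinate for atom {self.serial} {self.name}")
        object.__setattr__(self, "coord", coord)
        if self.serial < 1:
            raise ValueError(f"atom serial must be positive, got {self.serial}")

    @property
    def is_alpha_carbon(self) -> bool:
        return self.name == "CA" and not self.is_glycan

    @property
    def is_ring_oxygen(self) -> bool:
        return self.is_glycan and self.name == RING_OXYGEN_NAME

    def moved_to(self, coord: np.ndarray) -> "Atom":
        return replace(self, coord=np.asarray(coord, dtype=float))


def _distinct_residues(atoms: Iterable[Atom]) -> list[tuple[str, int]]:
    seen: dict[tuple[str, int], None] = {}
    for a in atoms:
        seen.setdefault((a.chain_id, a.res_seq), None)
    return list(seen)


@dataclass
class SubunitModel:
    """Ordered atoms of one pilin subunit (possibly glycan-decorated).

    ``site_residues`` lists the 1-based residue numbers of the glycan
    attachment serines; each must exist, be a SER, and own backbone atoms
    N, CA, C plus the side-chain oxygen OG.
    """

    atoms: list[Atom]
    site_residues: list[int] = field(default_factory=list)

    @property
    def residue_count(self) -> int:
        return len(_distinct_residues(self.atoms))

    @property
    def protein_residue_count(self) -> int:
        return len(_distinct_residues(a for a in self.atoms if not a.is_glycan))

    @property
    def glycan_monomer_count(self) -> int:
        return len(_distinct_residues(a for a in self.atoms if a.is_glycan))

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.coord for a in self.atoms])

    def residue_atoms(self, res_seq: int) -> dict[str, Atom]:
        """Atoms of a protein residue keyed by atom name."""
        return {
            a.name: a
            for a in self.atoms
            if a.res_seq == res_seq and not a.is_glycan
        }

    def validate_sites(self) -> None:
        for res in self.site_residues:
            res_atoms = self.residue_atoms(res)
            if not res_atoms:
                raise ValueError(f"site residue {res} not present in subunit")
            names = set(res_atoms)
            missing = {"N", "CA", "C", "OG"} - names
            if missing:
                raise ValueError(
                    f"site residue {res} lacks atoms {sorted(missing)}"
                )
            if res_atoms["CA"].res_name != "SER":
                raise ValueError(
                    f"site residue {res} is {res_atoms['CA'].res_name}, expected SER"
                )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SubunitModel":
        """Rigidly transformed copy: ``x -> R x + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        coords = self.coords() @ R.T + t
        atoms = [a.moved_to(c) for a, c in zip(self.atoms, coords)]
        return SubunitModel(atoms=atoms, site_residues=list(self.site_residues))

    def with_chain(self, chain_id: str) -> "SubunitModel":
        atoms = [replace(a, chain_id=chain_id) for a in self.atoms]
        return SubunitModel(atoms=atoms, site_residues=list(self.site_residues))


@dataclass
class AssemblyModel:
    """An ordered collection of subunits: a filament, a Cn ring or a channel.

    The assembly axis is +z through the origin by convention.  Filament and
    ring assemblies are built from identical subunit copies, so their
    per-subunit atom counts agree; channels are free-form.
    """

    subunits: list[SubunitModel]
    kind: str = "filament"

    def __post_init__(self) -> None:
        if self.kind not in {"filament", "ring", "channel"}:
            raise ValueError(f"unknown assembly kind {self.kind!r}")
        if self.kind in {"filament", "ring"} and self.subunits:
            counts = {len(s.atoms) for s in self.subunits}
            if len(counts) != 1:
                raise ValueError(
                    f"{self.kind} subunit atom counts differ: {sorted(counts)}"
                )

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)

    def atoms(self) -> Iterator[Atom]:
        for s in self.subunits:
            yield from s.atoms

    def atom_list(self) -> list[Atom]:
        return list(self.atoms())

    def coords(self) -> np.ndarray:
        parts = [s.coords() for s in self.subunits if s.atoms]
        if not parts:
            return np.zeros((0, 3))
        return np.concatenate(parts)

    @property
    def protein_residue_count(self) -> int:
        return sum(s.protein_residue_count for s in self.subunits)

    @property
    def glycan_monomer_count(self) -> int:
        return sum(s.glycan_monomer_count for s in self.subunits)

    def translated(self, shift: np.ndarray) -> "AssemblyModel":
        t = np.asarray(shift, dtype=float)
        return AssemblyModel(
            subunits=[s.transformed(np.eye(3), t) for s in self.subunits],
            kind=self.kind,
        )


@dataclass(frozen=True)
class HelicalParams:
    """Helical symmetry: rotation (deg) and axial translation (Å) per subunit.

    Positive twist is a right-handed rotation about +z.
    """

    twist_deg: float
    rise_A: float

    def __post_init__(self) -> None:
        if not abs(self.twist_deg) <= 180.0:
            raise ValueError(f"|twist| must be <= 180°, got {self.twist_deg}")
        if not self.rise_A > 0:
            raise ValueError(f"rise must be positive, got {self.rise_A}")


# Literature values for the two T. thermophilus pilus forms.
WIDE_HELICAL_PARAMS = HelicalParams(twist_deg=92.4, rise_A=9.2)
NARROW_HELICAL_PARAMS = HelicalParams(twist_deg=84.0, rise_A=11.3)


@dataclass(frozen=True)
class ScrewTransform:
    """A rigid motion decomposed as rotation about an axis plus translation
    along it (the generator of helical symmetry)."""

    rotation_angle_deg: float
    axis_direction: np.ndarray
    axis_point: np.ndarray
    translation_along_axis_A: float
    residual_rmsd_A: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.axis_direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("axis_direction must be a unit vector")
        object.__setattr__(self, "axis_direction", d)
        object.__setattr__(
            self, "axis_point", np.asarray(self.axis_point, dtype=float)
        )


@dataclass(frozen=True)
class GlycanTopology:
    """An ordered, linear saccharide: monomer codes (reducing end last,
    nearest the serine) and per-junction linkage labels."""

    monomers: tuple[str, ...]
    linkages: tuple[str, ...] = ()
    attachment: str = "alpha-Ser"

    def __post_init__(self) -> None:
        monomers = tuple(self.monomers)
        object.__setattr__(self, "monomers", monomers)
        object.__setattr__(self, "linkages", tuple(self.linkages))
        if not 1 <= len(monomers) <= 4:
            raise ValueError(f"chain length must be 1..4, got {len(monomers)}")
        unknown = [m for m in monomers if m not in GLYCAN_RES_NAMES]
        if unknown:
            raise ValueError(f"unknown monomer codes {unknown}; expected W/H/N/X")
        if len(monomers) >= 2 and len(self.linkages) != len(monomers) - 1:
            raise ValueError(
                f"{len(monomers)} monomers need {len(monomers) - 1} linkages, "
                f"got {len(self.linkages)}"
            )

    def __len__(self) -> int:
        return len(self.monomers)


def tetrasaccharide_WHNN() -> GlycanTopology:
    """5Am7Ac-α(1-4)Man-α(1-3)GalNAc-α(1-3)GalNAc-α-Ser (full-length chain)."""
    return GlycanTopology(("W", "H", "N", "N"), ("a(1-4)", "a(1-3)", "a(1-3)"))


def trisaccharide_HNN() -> GlycanTopology:
    """α(1-4)Man-α-GalNAc-α(1-3)GalNAc-α-Ser."""
    return GlycanTopology(("H", "N", "N"), ("a(1-4)", "a(1-3)"))


def monosaccharide_N() -> GlycanTopology:
    """A single GalNAc."""
    return GlycanTopology(("N",))


@dataclass(frozen=True)
class AttachmentSite:
    """A glycan attachment point: a serine in a particular subunit."""

    subunit_index: int
    res_seq: int
    topology: GlycanTopology | None = None


@dataclass
class ConformerLibrary:
    """M glycan conformations in the local frame of the attachment residue.

    Every conformer has the same atom count and naming, with at least one
    ring oxygen per monomer, ready for rigid grafting onto a site frame.
    """

    frames: list[list[Atom]]
    topology: GlycanTopology
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("conformer library must hold at least one conformer")
        names0 = [a.name for a in self.frames[0]]
        for i, frame in enumerate(self.frames):
            names = [a.name for a in frame]
            if names != names0:
                raise ValueError(f"conformer {i} atom naming differs from conformer 0")
            n_ring = sum(a.is_ring_oxygen for a in frame)
            if n_ring < len(self.topology):
                raise ValueError(
                    f"conformer {i} has {n_ring} ring oxygens for "
                    f"{len(self.topology)} monomers"
                )

    @property
    def n_conformers(self) -> int:
        return len(self.frames)

    def conformer_coords(self, i: int) -> np.ndarray:
        return np.stack([a.coord for a in self.frames[i]])


@dataclass
class AccommodationProfile:
    """Axially binned steric acceptance of grafted conformers.

    ``bin_edges_A`` has one more entry than the count arrays.  Bins with no
    sampled conformers are flagged (fraction NaN), never interpolated.
    """

    bin_edges_A: np.ndarray
    n_total: np.ndarray
    n_accepted: np.ndarray
    per_site: dict[AttachmentSite, tuple[int, int]]
    threshold_A: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.bin_edges_A = np.asarray(self.bin_edges_A, dtype=float)
        self.n_total = np.asarray(self.n_total, dtype=int)
        self.n_accepted = np.asarray(self.n_accepted, dtype=int)
        if np.any(self.n_accepted > self.n_total):
            raise ValueError("accepted count exceeds total in some bin")
        for site, (acc, tot) in self.per_site.items():
            if acc > tot:
                raise ValueError(f"accepted > total at site {site}")

    @property
    def bin_centers_A(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_A[:-1] + self.bin_edges_A[1:])

    @property
    def acceptance_fraction(self) -> np.ndarray:
        """Per-bin accepted/total; NaN flags empty bins."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_total > 0, self.n_accepted / np.maximum(self.n_total, 1), np.nan
            )

    @property
    def rejection_rate(self) -> np.ndarray:
        return 1.0 - self.acceptance_fraction

    def to_tsv(self, path) -> None:
        from .pdbio import write_profile_tsv  # local import to avoid cycle

        write_profile_tsv(self, path)


def select_atoms(model, role: str) -> list[Atom]:
    """Select atoms of a model by role.

    Roles: ``alpha_carbons`` (protein Cα), ``ring_oxygens`` (glycan O5),
    ``glycan`` (all sugar atoms), ``protein`` (all non-sugar atoms).
    Order is the stable atom order of the model; protein and glycan
    partition the atom list.
    """
    if isinstance(model, AssemblyModel):
        atoms: Sequence[Atom] = model.atom_list()
    elif isinstance(model, SubunitModel):
        atoms = model.atoms
    else:
        atoms = list(model)
    if role == "alpha_carbons":
        return [a for a in atoms if a.is_alpha_carbon]
    if role == "ring_oxygens":
        return [a for a in atoms if a.is_ring_oxygen]
    if role == "glycan":
        return [a for a in atoms if a.is_glycan]
    if role == "protein":
        return [a for a in atoms if not a.is_glycan]
    raise ValueError(
        f"unknown selection role {role!r}; expected alpha_carbons, "
        "ring_oxygens, glycan or protein"
    )


def atom_coords(atoms: Sequence[Atom]) -> np.ndarray:
    if not atoms:
        return np.zeros((0, 3))
    return np.stack([a.coord for a in atoms])
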