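"""Idealized glycan chains, attachment frames and rigid conformer grafting.

The pilin O-glycans are short linear saccharides (1–4 monomers) attached to
surface serines.  For steric analysis only the monomer ring-oxygen positions
matter, so each monomer is represented by a simplified fixed template: a
planar hexagon of five carbons plus one ring oxygen ("O5"), with a link
pseudo-atom toward the previous monomer (or the serine Oγ for the first).

Chains are built in the local attachment frame of their serine — an
orthonormal right-handed basis derived from the residue's backbone N, Cα
and C atoms — and grafted rigidly into assembly coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .model import (
    GLYCAN_RES_NAMES,
    AssemblyModel,
    Atom,
    AttachmentSite,
    ConformerLibrary,
    GlycanTopology,
    SubunitModel,
    monosaccharide_N,
    tetrasaccharide_WHNN,
    trisaccharide_HNN,
)

#: Canonical serine Oγ position in the local attachment frame (Å from Cα).
#: The direction emulates the Cβ–Oγ side chain: away from both backbone
#: bonds (−e1, −e2) and out of the N–Cα–C plane (+e3); |OG_LOCAL| ≈ 2.4 Å.
OG_LOCAL = 2.4 * np.array([-1.0, -1.0, 1.25]) / np.linalg.norm([-1.0, -1.0, 1.25])

#: Glycosidic link length between consecutive monomers (Å).
LINK_LENGTH = 1.43

#: Radius of the planar hexagon monomer template (Å).
RING_RADIUS = 1.4

#: Centre-to-centre spacing of consecutive monomers along the chain (Å).
MONOMER_SPACING = 5.0

#: Offset of the first monomer centre from the serine Oγ (link + ring radius).
FIRST_MONOMER_OFFSET = LINK_LENGTH + RING_RADIUS

#: Atom names of one monomer template: 5 ring carbons, ring oxygen, link atom.
MONOMER_ATOM_NAMES = ("C1", "C2", "C3", "C4", "C5", "O5", "O1")


@dataclass(frozen=True)
class SiteMap:
    """Glycosylation map: attachment serine numbers with their chain topologies."""

    name: str
    entries: tuple[tuple[int, GlycanTopology], ...]

    @property
    def monomers_per_subunit(self) -> int:
        return sum(len(topo) for _, topo in self.entries)


def wide_site_map() -> SiteMap:
    """The wide (PilA4) pilus map: S59 trisaccharide H-N-N, S66 single GalNAc,
    S71 tetrasaccharide W-H-N-N — 8 monomers per subunit."""
    return SiteMap(
        name="wide",
        entries=(
            (59, trisaccharide_HNN()),
            (66, monosaccharide_N()),
            (71, tetrasaccharide_WHNN()),
        ),
    )


def narrow_site_map() -> SiteMap:
    """The narrow (PilA5) pilus map: S73 tetrasaccharide W-H-N-N — 4 monomers."""
    return SiteMap(name="narrow", entries=((73, tetrasaccharide_WHNN()),))


def site_map_by_name(name: str) -> SiteMap:
    maps = {"wide": wide_site_map, "narrow": narrow_site_map}
    if name not in maps:
        raise ValueError(f"unknown site map {name!r}; expected wide or narrow")
    return maps[name]()


@dataclass(frozen=True)
class AttachmentFrame:
    """Local frame of an attachment serine: origin at Cα, right-handed
    orthonormal basis (e1, e2, e3) from the backbone atoms."""

    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray

    def __post_init__(self) -> None:
        basis = self.basis
        if np.max(np.abs(basis @ basis.T - np.eye(3))) > 1e-9:
            raise ValueError("attachment frame basis is not orthonormal")
        if np.linalg.det(basis) < 0:
            raise ValueError("attachment frame basis is left-handed")

    @property
    def basis(self) -> np.ndarray:
        """Rows e1, e2, e3."""
        return np.stack([self.e1, self.e2, self.e3])

    def to_global(self, local: np.ndarray) -> np.ndarray:
        """Map local coordinates into assembly coordinates."""
        return np.asarray(local, dtype=float) @ self.basis + self.origin


def attachment_frame(subunit: SubunitModel, res_seq: int) -> AttachmentFrame:
    """Build the local frame of an attachment residue.

    origin = Cα; e1 = unit(Cα→N); e2 = Gram-Schmidt of (Cα→C) against e1;
    e3 = e1 × e2.  Raises naming the missing atom if the backbone is
    incomplete.
    """
    res_atoms = subunit.residue_atoms(res_seq)
    for name in ("N", "CA", "C"):
        if name not in res_atoms:
            raise ValueError(f"residue {res_seq} is missing backbone atom {name}")
    ca = res_atoms["CA"].coord
    v1 = res_atoms["N"].coord - ca
    v2 = res_atoms["C"].coord - ca
    n1 = np.linalg.norm(v1)
    if n1 < 1e-9:
        raise ValueError(f"residue {res_seq}: N coincides with CA")
    e1 = v1 / n1
    v2p = v2 - (v2 @ e1) * e1
    n2 = np.linalg.norm(v2p)
    if n2 < 1e-9:
        raise ValueError(f"residue {res_seq}: backbone N, CA, C are collinear")
    e2 = v2p / n2
    e3 = np.cross(e1, e2)
    return AttachmentFrame(origin=ca.copy(), e1=e1, e2=e2, e3=e3)


def _perpendicular_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair spanning the plane normal to ``direction``."""
    d = direction / np.linalg.norm(direction)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u = u / np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def monomer_template_atoms(
    code: str,
    center: np.ndarray,
    direction: np.ndarray,
    res_seq: int,
    chain_id: str = "A",
    serial_start: int = 1,
) -> list[Atom]:
    """Instantiate one monomer template at ``center``.

    The hexagonal ring lies in the plane normal to ``direction`` (the
    incoming chain direction); the ring oxygen O5 occupies one vertex and the
    link pseudo-atom O1 sits toward the previous chain unit.
    """
    res_name = GLYCAN_RES_NAMES[code]
    u, v = _perpendicular_basis(direction)
    d = direction / np.linalg.norm(direction)
    atoms: list[Atom] = []
    serial = serial_start
    for i, name in enumerate(MONOMER_ATOM_NAMES[:6]):
        ang = 2.0 * math.pi * i / 6.0
        pos = center + RING_RADIUS * (math.cos(ang) * u + math.sin(ang) * v)
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=name[0],
                res_name=res_name,
                res_seq=res_seq,
                chain_id=chain_id,
                coord=pos,
                is_glycan=True,
            )
        )
        serial += 1
    link_pos = center - (RING_RADIUS + 0.6) * d
    atoms.append(
        Atom(
            serial=serial,
            name="O1",
            element="O",
            res_name=res_name,
            res_seq=res_seq,
            chain_id=chain_id,
            coord=link_pos,
            is_glycan=True,
        )
    )
    return atoms


def build_glycan_chain(topology: GlycanTopology | None) -> list[Atom]:
    """Build an idealized straight glycan chain in the local attachment frame.

    Monomer ``k`` is centred at ``OG_LOCAL + (FIRST_MONOMER_OFFSET +
    k·MONOMER_SPACING)·û`` where ``û`` points radially away from the frame
    origin through the serine Oγ.  Residue numbers are local (1-based along
    the chain) and are reassigned on decoration.
    """
    if topology is None:
        return []
    u = OG_LOCAL / np.linalg.norm(OG_LOCAL)
    atoms: list[Atom] = []
    serial = 1
    for k, code in enumerate(topology.monomers):
        center = OG_LOCAL + (FIRST_MONOMER_OFFSET + k * MONOMER_SPACING) * u
        monomer = monomer_template_atoms(
            code, center, u, res_seq=k + 1, serial_start=serial
        )
        atoms.extend(monomer)
        serial += len(monomer)
    return atoms


def graft_conformer(
    conformer_atoms: list[Atom], frame: AttachmentFrame
) -> list[Atom]:
    """Rigidly place local-frame conformer atoms into assembly coordinates:
    ``x_global = origin + x·e1 + y·e2 + z·e3``.  Distances are preserved."""
    if not conformer_atoms:
        return []
    local = np.stack([a.coord for a in conformer_atoms])
    global_coords = frame.to_global(local)
    return [a.moved_to(c) for a, c in zip(conformer_atoms, global_coords)]


def decorate_assembly(
    filament: AssemblyModel,
    site_map: SiteMap,
    libraries: dict[int, ConformerLibrary] | None = None,
) -> AssemblyModel:
    """Attach glycan chains at every map site of every subunit.

    By default (static-chain mode) each site receives one idealized straight
    chain; when per-site conformer ``libraries`` are given, conformer 0 of
    the site's library is grafted as a deterministic representative.  Glycan
    residue numbers continue after the protein residues of their subunit;
    total monomer count is Σ_sites monomers × n_subunits.
    """
    decorated: list[SubunitModel] = []
    for subunit in filament.subunits:
        chain_id = subunit.atoms[0].chain_id if subunit.atoms else "A"
        max_res = max((a.res_seq for a in subunit.atoms), default=0)
        serial = max((a.serial for a in subunit.atoms), default=0) + 1
        new_atoms = list(subunit.atoms)
        next_res = max_res + 1
        for res_seq, topology in site_map.entries:
            res_atoms = subunit.residue_atoms(res_seq)
            if (
                not res_atoms
                or "OG" not in res_atoms
                or res_atoms["CA"].res_name != "SER"
            ):
                raise ValueError(
                    f"site residue {res_seq} missing or not a glycosylatable "
                    f"serine in subunit chain {chain_id}"
                )
            frame = attachment_frame(subunit, res_seq)
            if libraries is not None and res_seq in libraries:
                local_atoms = libraries[res_seq].frames[0]
            else:
                local_atoms = build_glycan_chain(topology)
            placed = graft_conformer(local_atoms, frame)
            renumbered: list[Atom] = []
            res_offset: dict[int, int] = {}
            for a in placed:
                if a.res_seq not in res_offset:
                    res_offset[a.res_seq] = next_res
                    next_res += 1
                renumbered.append(
                    replace(
                        a,
                        serial=serial,
                        chain_id=chain_id,
                        res_seq=res_offset[a.res_seq],
                    )
                )
                serial += 1
            new_atoms.extend(renumbered)
        decorated.append(
            SubunitModel(atoms=new_atoms, site_residues=list(subunit.site_residues))
        )
    return AssemblyModel(subunits=decorated, kind=filament.kind)


def assembly_sites(
    assembly: AssemblyModel, site_map: SiteMap
) -> list[AttachmentSite]:
    """Enumerate every (subunit, serine) attachment site of a decorated or
    undecorated filament under a site map."""
    return [
        AttachmentSite(subunit_index=i, res_seq=res_seq, topology=topo)
        for i in range(assembly.n_subunits)
        for res_seq, topo in site_map.entries
    ]
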