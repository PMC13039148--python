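"""Readers and writers for the coordinate and table formats the pipeline touches.

The PDB dialect is a strict fixed-column subset of PDB v3.3: ATOM, HETATM,
MODEL, ENDMDL, TER and END records only.  Occupancy and B-factor are written
as constants (1.00 / 0.00), the element column is populated, and output is
byte-deterministic for a given model.  Glycan atoms are written as HETATM
records and recognised on read by their monomer residue names.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Sequence, TextIO

import numpy as np

from .model import (
    GLYCAN_CODES_BY_RES_NAME,
    AccommodationProfile,
    AssemblyModel,
    Atom,
    ConformerLibrary,
    GlycanTopology,
    SubunitModel,
)


class PDBParseError(ValueError):
    """Malformed fixed-width record; message names the offending line."""


_COORD_MIN, _COORD_MAX = -999.999, 9999.999


def _format_atom_name(name: str) -> str:
    # one-letter element names are indented one column per the v3.3 layout
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def _atom_line(atom: Atom, serial: int) -> str:
    record = "HETATM" if atom.is_glycan else "ATOM  "
    x, y, z = atom.coord
    for v in (x, y, z):
        if not (_COORD_MIN <= v <= _COORD_MAX):
            raise ValueError(
                f"coordinate {v:.3f} outside fixed-width PDB range "
                f"[{_COORD_MIN}, {_COORD_MAX}]; refusing to write"
            )
    return (
        f"{record}{serial % 100000:>5d} {_format_atom_name(atom.name)} "
        f"{atom.res_name:>3s} {atom.chain_id}{atom.res_seq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {atom.element:>2s}"
    )


def _write_subunit(fh: TextIO, subunit: SubunitModel, serial: int) -> int:
    for atom in subunit.atoms:
        fh.write(_atom_line(atom, serial) + "\n")
        serial += 1
    if subunit.atoms:
        last = subunit.atoms[-1]
        fh.write(
            f"TER   {serial % 100000:>5d}      {last.res_name:>3s} "
            f"{last.chain_id}{last.res_seq:>4d}\n"
        )
        serial += 1
    return serial


def write_pdb(model, path) -> None:
    """Write a model to ``path`` in the strict PDB subset.

    Accepts a :class:`SubunitModel`, an :class:`AssemblyModel` (one TER-closed
    chain block per subunit) or a :class:`ConformerLibrary` (serialized as
    MODEL/ENDMDL blocks).  Output is identical bytes for identical models.
    """
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        if isinstance(model, ConformerLibrary):
            for i, frame in enumerate(model.frames, start=1):
                fh.write(f"MODEL {i:>8d}\n")
                serial = 1
                for atom in frame:
                    fh.write(_atom_line(atom, serial) + "\n")
                    serial += 1
                fh.write("ENDMDL\n")
        elif isinstance(model, AssemblyModel):
            serial = 1
            for subunit in model.subunits:
                serial = _write_subunit(fh, subunit, serial)
        elif isinstance(model, SubunitModel):
            _write_subunit(fh, model, 1)
        else:
            raise TypeError(f"cannot write object of type {type(model).__name__}")
        fh.write("END\n")


def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21]
        res_seq = int(line[22:26])
        coord = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed record at line {lineno}: {line.rstrip()!r}") from exc
    if not element:
        element = name[:1]
    is_glycan = res_name in GLYCAN_CODES_BY_RES_NAME
    return Atom(
        serial=max(serial, 1),
        name=name,
        element=element,
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain_id,
        coord=coord,
        is_glycan=is_glycan,
    )


def _read_frames(path: Path) -> list[list[tuple[Atom, bool]]]:
    """Parse into per-MODEL lists of (atom, ter_follows) pairs."""
    frames: list[list[tuple[Atom, bool]]] = []
    current: list[tuple[Atom, bool]] = []
    in_model = False
    seen_serials: set[int] = set()
    max_serial = 0
    duplicate_warned = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                if atom.serial in seen_serials:
                    if not duplicate_warned:
                        warnings.warn(
                            f"duplicate atom serial {atom.serial} at line {lineno}; "
                            "renumbering",
                            stacklevel=3,
                        )
                        duplicate_warned = True
                    atom = Atom(
                        serial=max_serial + 1,
                        name=atom.name,
                        element=atom.element,
                        res_name=atom.res_name,
                        res_seq=atom.res_seq,
                        chain_id=atom.chain_id,
                        coord=atom.coord,
                        is_glycan=atom.is_glycan,
                    )
                seen_serials.add(atom.serial)
                max_serial = max(max_serial, atom.serial)
                current.append((atom, False))
            elif rec.startswith("TER"):
                if current:
                    atom, _ = current[-1]
                    current[-1] = (atom, True)
            elif rec.startswith("MODEL"):
                in_model = True
                current = []
                seen_serials = set()
                max_serial = 0
            elif rec.startswith("ENDMDL"):
                frames.append(current)
                current = []
            elif rec.startswith("END"):
                break
    if not in_model:
        frames = [current]
    elif current:
        frames.append(current)
    return [f for f in frames if f] or [[]]


def _partition_subunits(tagged: Sequence[tuple[Atom, bool]]) -> list[SubunitModel]:
    """Split an atom stream into subunits at TER records and chain changes."""
    subunits: list[SubunitModel] = []
    bucket: list[Atom] = []
    prev_chain: str | None = None
    for atom, ter_follows in tagged:
        if bucket and atom.chain_id != prev_chain:
            subunits.append(_finish_subunit(bucket))
            bucket = []
        bucket.append(atom)
        prev_chain = atom.chain_id
        if ter_follows:
            subunits.append(_finish_subunit(bucket))
            bucket = []
            prev_chain = None
    if bucket:
        subunits.append(_finish_subunit(bucket))
    return subunits


def _finish_subunit(atoms: list[Atom]) -> SubunitModel:
    # every SER owning an OG is a candidate glycan attachment site
    sites = sorted(
        {
            a.res_seq
            for a in atoms
            if not a.is_glycan and a.res_name == "SER" and a.name == "OG"
        }
    )
    return SubunitModel(atoms=list(atoms), site_residues=sites)


def read_pdb(path, kind: str = "filament"):
    """Read a single-model PDB-subset file.

    Returns a :class:`SubunitModel` when the file holds a single chain block,
    otherwise an :class:`AssemblyModel` of the given ``kind``.  Multi-MODEL
    files (conformer libraries) are read with :func:`read_model_frames`.
    """
    path = Path(path)
    frames = _read_frames(path)
    if len(frames) > 1:
        raise PDBParseError(
            f"{path} holds {len(frames)} MODEL blocks; use read_model_frames"
        )
    subunits = _partition_subunits(frames[0])
    if len(subunits) == 1:
        return subunits[0]
    return AssemblyModel(subunits=subunits, kind=kind)


def read_model_frames(path) -> list[list[Atom]]:
    """Read a multi-MODEL file into per-model atom lists (conformer frames)."""
    path = Path(path)
    return [[atom for atom, _ in frame] for frame in _read_frames(path)]


def read_conformer_library(path, topology: GlycanTopology) -> ConformerLibrary:
    """Read a MODEL/ENDMDL conformer file into a :class:`ConformerLibrary`."""
    frames = read_model_frames(path)
    return ConformerLibrary(frames=frames, topology=topology)


def write_profile_tsv(profile: AccommodationProfile, path) -> None:
    """Serialize an accommodation profile; empty bins carry ``na`` fractions."""
    path = Path(path)
    frac = profile.acceptance_fraction
    rej = profile.rejection_rate
    with path.open("w", newline="\n") as fh:
        seed = "none" if profile.seed is None else str(profile.seed)
        fh.write(f"# threshold_A={profile.threshold_A:.2f} seed={seed}\n")
        fh.write("z_bin_center_A\tn_total\tn_accepted\tacceptance_fraction\trejection_rate\n")
        for z, tot, acc, f, r in zip(
            profile.bin_centers_A, profile.n_total, profile.n_accepted, frac, rej
        ):
            fs = "na" if math.isnan(f) else f"{f:.6f}"
            rs = "na" if math.isnan(r) else f"{r:.6f}"
            fh.write(f"{z:.3f}\t{tot}\t{acc}\t{fs}\t{rs}\n")


def write_aperture_tsv(bin_centers_A, radii_A, path) -> None:
    """Serialize an aperture profile; empty bins carry ``na`` radii."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("z_bin_center_A\taperture_radius_A\n")
        for z, r in zip(bin_centers_A, radii_A):
            rs = "na" if math.isnan(r) else f"{r:.3f}"
            fh.write(f"{z:.3f}\t{rs}\n")
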