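"""Decorate wide and narrow filaments with their O-glycan maps.

The wide pilus carries three serine sites per subunit (S59 trisaccharide,
S66 monosaccharide, S71 tetrasaccharide: 8 monomers); the narrow pilus a
single tetrasaccharide at S73 (4 monomers).  Decorating full-length model
filaments reproduces the composition bookkeeping of the refined structures.
"""

from piluskit import (
    NARROW_HELICAL_PARAMS,
    WIDE_HELICAL_PARAMS,
    apply_helical_symmetry,
    decorate_assembly,
    make_synthetic_subunit,
    narrow_config,
    narrow_site_map,
    select_atoms,
    wide_config,
    wide_site_map,
)

for label, config, params, n, site_map in (
    ("wide", wide_config(seed=1), WIDE_HELICAL_PARAMS, 45, wide_site_map()),
    ("narrow", narrow_config(seed=2), NARROW_HELICAL_PARAMS, 31, narrow_site_map()),
):
    subunit = make_synthetic_subunit(config)
    filament = apply_helical_symmetry(subunit, params, n)
    decorated = decorate_assembly(filament, site_map)
    print(
        f"{label}: {decorated.protein_residue_count} protein residues, "
        f"{decorated.glycan_monomer_count} glycan monomers, "
        f"{len(select_atoms(decorated, 'ring_oxygens'))} ring oxygens"
    )
# Protein residues are residues-per-subunit x subunits; glycan monomers are
# map-monomers-per-subunit x subunits, one ring oxygen per monomer.
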