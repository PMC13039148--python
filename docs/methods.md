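# Methods

## Coordinate conventions

All assemblies use a single axis convention: the filament or channel axis is
+z through the origin.  Builders emit models in this frame; external models
are brought into it with `align_to_axis`, which maps a user-supplied axis
(two points) rigidly onto +z.  Residue numbering is 1-based and preserves
author numbering, so the glycan attachment serines are addressed directly as
S59/S66/S71 (wide pilin) and S73 (narrow pilin).  Positive twist is a
right-handed rotation about +z; a deposited model refined under the opposite
handedness convention simply shows a negated twist.

## Screw-symmetry fitting

`fit_screw_transform` superposes subunit *a* onto subunit *b* with a Kabsch
fit (SVD with determinant correction; if the unconstrained optimum is a
reflection the best proper rotation is returned with a warning) and
decomposes the rigid map into a rotation angle about a fitted axis, the axis
direction and point, and the translation along the axis.  Numerical choices:

- The rotation axis is taken from the rotation vector and normalised to the
  +z hemisphere, so the reported angle carries the handedness sign.  Angles
  are reported in (−180°, 180°]; at exactly 180° the decomposition is
  intrinsically ambiguous, and the fitted range is restricted to below that
  in the property suites.
- Near-identity rotations (|angle| < ~6e-9 deg) are treated as pure
  translations: the axis defaults to the translation direction and the
  reported translation is the full displacement norm.
- The axis point is the minimum-norm least-squares solution of
  `(I − R)p = t_perp`, i.e. the point on the screw axis closest to the
  origin.
- `fit_helical_parameters` averages per-pair angles with a circular mean
  (avoiding wrap-around bias) and per-pair translations arithmetically.
  Pairs deviating from the means by more than 0.5° or 0.5 Å (defaults)
  raise an error naming the offending pairs.  A filament of identity-related
  subunits is flagged degenerate rather than given helical parameters.

Recovery on noiseless filaments is exact to ~1e-12; the test suites assert
1e-6.

## Glycan model

Chains are linear, 1–4 monomers, with monomer codes N (GalNAc), H
(hexose/Man), W (pseudaminic-acid derivative 5Am7Ac) and X (an unidentified
346 Da monosaccharide).  The wide map is S59: H-N-N, S66: N, S71: W-H-N-N
(8 monomers per subunit); the narrow map is S73: W-H-N-N (4 monomers).  W is
kept as its own code rather than substituted by a chemically similar sialic
acid: the analysis is purely geometric and needs no force-field parameters.
Linkage labels (α(1-3)/α(1-4)) are carried as metadata only; the geometry is
linkage-agnostic.

Each monomer is a fixed template: a planar hexagon of radius 1.4 Å (five
carbons plus one ring oxygen named "O5") and a link pseudo-atom, 7 atoms in
all.  The steric statistic depends only on ring-oxygen positions, so this
simplified template is adequate; it is *not* a chemically accurate sugar.
Glycosidic link length is 1.43 Å and consecutive monomer centres are 5.0 Å
apart.  Exactly one ring oxygen per monomer is the package-wide convention;
readers flag "O5" within glycan residues (`NGA`, `MAN`, `PSE`, `UNX`).  When
loading third-party glycosylated models with different monomer chemistry, a
per-monomer ring-oxygen name table would be needed; only the "O5" default is
implemented.

The attachment frame is built from the serine backbone: origin Cα,
e1 = unit(Cα→N), e2 = Gram–Schmidt of (Cα→C) against e1, e3 = e1×e2.  The
canonical Oγ anchor in this frame is 2.4 Å along (−e1 −e2 +1.25·e3)
normalised — the side-chain direction, pointing away from both backbone
bonds and out of the N–Cα–C plane.  Chains and conformers anchor their first
monomer at `Oγ_local + (1.43 + 1.4)·û` where û is the anchor direction.
Grafting is rigid placement only; clashing conformers are rejected, never
relaxed, which keeps the acceptance statistic well-defined.

## Steric criterion

A conformer is accepted iff the minimum distance between its selected glycan
atoms (ring oxygens by default; all glycan atoms optionally) and the
selected environment atoms (α-carbons by default; all protein atoms
optionally) is ≥ the threshold.  Defaults 3.25 Å and 3.75 Å; distances
exactly at the threshold count as accepted (the boundary convention is
documented rather than specified by the underlying physics).  The attachment
residue's own atoms are excluded from the environment of its site — the
first monomer is always within bonded distance of them, so leaving them in
rejects everything trivially.  The accelerated implementation (one KD-tree
nearest-neighbour query per conformer) returns results identical to all-pairs
brute force, which the tests assert instance-by-instance.

Profiles assign each site to the axial bin containing its Oγ z-coordinate
(default bin width 5 Å, configurable; profile-level analyses in the tests
and examples use 10 Å) and pool accepted/total counts per bin; per-site
counts are also retained, since it is equally natural to report per-site
curves.  Empty bins are flagged `na`, never interpolated.  Ensemble
subsampling is seeded and without replacement, with an independent
deterministic substream per site, so a rerun with the same seed reproduces
the TSV byte-for-byte.  Default subsample is min(M, 1000).

## Synthetic data

The generators emulate the geometric structure the analysis assumes, not
real pilin chemistry:

- **Subunit** (`make_synthetic_subunit`): backbone-only residues (N, CA, C;
  OG on site serines).  An ideal α-helical N-terminal segment (≤17 residues)
  plus a self-avoiding coil confined to 0.38× the subunit width around the
  helix centre keep the Ritter bounding-sphere diameter within ±20% of the
  30 Å target (verified over 80 seeds per preset).  The subunit is placed
  with its centroid ~9 Å off the +z axis, ready for helical stacking.
  Attachment serines are treated as surface sites of the *assembled
  filament*: their Cα is moved onto the subunit's outer radial envelope
  (max radius + 0.5 Å), within a ±25° angular sector of the subunit's
  outward face, and their backbone N/C pseudo-atoms are oriented so the
  attachment frame maps the Oγ anchor direction onto the outward radial
  normal.  Without this, backbone-random site frames graft chains into the
  filament wall and the acceptance statistic degenerates to zero — real
  glycosylation sites sit on the filament exterior.  The Cα trace is
  consequently not bond-continuous at site residues; no analysis in the
  package depends on trace continuity.
- **Conformers** (`sample_conformer_library`): M self-avoiding chains of
  monomer centres, step 5.0 Å, uniformly random step directions, non-adjacent
  centres ≥ 3.0 Å apart, rejection-sampled with bounded retries.  Hexagon
  templates are laid on the centres normal to the incoming step.  This is a
  documented, reproducible stand-in for a molecular-dynamics conformer
  ensemble: it reproduces ensemble *breadth*, not torsional statistics, so
  profile numbers characterise the geometry of filament + channel, not real
  glycan thermodynamics.
- **Channel** (`make_channel`): rings of Cα-flagged pseudo-atoms on +z,
  ring spacing 1.5 Å and in-ring arc 1.5 Å by default, radius
  `R(z) = R − δ·exp(−(z−z₀)²/(2σ²))` — a minimal single-constriction family
  whose ground-truth aperture (R − δ at z₀) is known by construction.
  A closed channel (δ ≥ R) is refused.
- **Calibration library** (`make_sphere_library`): single-ring-oxygen
  conformers uniform on a sphere about the frame origin.  For a site whose
  frame is the identity on the axis, inside a dense cylindrical wall of
  radius R at threshold t, the acceptance fraction has the closed form
  1 − √(1 − ((R−t)/r)²); the test suite checks agreement within 3 standard
  errors at M = 10,000 (wall discretised at 0.4 Å, fine enough that the
  discretisation bias is well below the Monte-Carlo error).

All generators are pure functions of their config (seed included).

## Problem sizes

Full-length filaments (45 × 125 and 31 × 111 residues) are used for
stoichiometry and I/O; parameter-recovery fits use 10-subunit filaments
(9 consecutive pairs); accommodation profiles in tests and examples use
8-subunit filaments with ensembles of 80–200 conformers subsampled to
40–100 per site, which already give per-bin fractions with ~0.05 resolution;
the closed-form calibration uses the full M = 10,000.

## Known limitations

- The monomer template is geometric, not chemical; absolute acceptance
  values depend on the template and ensemble breadth and should be compared
  only within the package's own family of models.  Trends (threshold
  monotonicity, environment additivity, constriction localisation) are the
  reliable outputs.
- Reproducing the published ~50% accommodation figure for the narrow pilus
  inside its secretin requires the deposited filament/channel coordinates
  and conformer arrays; the package reads such inputs (PDB subset,
  multi-MODEL conformer files) but does not ship or fetch them.
- PDB I/O is deliberately a strict subset: no mmCIF, altlocs, insertion
  codes or occupancies.  Serials wrap at 99,999 in the fixed-width field;
  readers renumber duplicates with a warning.
- Screw fitting assumes atom correspondence by order between subunits.
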