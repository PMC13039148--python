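"""Build a helical filament from one subunit and recover its parameters.

A synthetic pilin-like subunit (125 residues, ~30 Å wide) is stacked into a
45-subunit filament with the wide-pilus screw operator (92.4° twist, 9.2 Å
rise per subunit).  Fitting screw transforms between consecutive subunits
then recovers the parameters, validating the round trip.
"""

from piluskit import (
    WIDE_HELICAL_PARAMS,
    apply_helical_symmetry,
    fit_helical_parameters,
    make_synthetic_subunit,
    wide_config,
)

subunit = make_synthetic_subunit(wide_config(seed=1))
print(f"subunit: {subunit.residue_count} residues, attachment sites {subunit.site_residues}")

filament = apply_helical_symmetry(subunit, WIDE_HELICAL_PARAMS, 45)
print(f"filament: {filament.n_subunits} subunits, {filament.protein_residue_count} residues")

fit = fit_helical_parameters(filament)
print(f"recovered twist {fit.twist_deg:.4f} deg, rise {fit.rise_A:.4f} A "
      f"(residual RMSD {fit.max_residual_rmsd_A:.2e} A)")
# The recovered values equal the construction parameters to numerical
# precision: the screw decomposition inverts the helical operator exactly.
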