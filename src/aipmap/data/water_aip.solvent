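# Water AIP ensemble for the solvation model.
#
# The published water parameterization (total AIP density theta and the
# donor/acceptor site values) lives in external supplementary data; the
# values below were calibrated once by least squares against a published
# table of 22 per-contact free energies for a protein-ligand complex
# (see docs/methods.md, "Water parameterization").  Swap this file to use
# a different solvent or the original published ensemble.
name water (calibrated 2-site ensemble)
theta 0.577709
temperature 298.0
# site  epsilon  mole_fraction
site 2.316264 0.5
site -5.986637 0.5
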