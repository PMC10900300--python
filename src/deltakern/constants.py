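"""Physical constants and unit conversions.

Internal units are Angstrom and kcal/mol throughout; conversions happen
only at I/O boundaries (e.g. the Bohr-based Gaussian cube header).
"""

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_MOL_K = 1.987204259e-3

#: Bohr radii per Angstrom (cube files store lengths in Bohr).
BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
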