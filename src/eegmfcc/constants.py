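"""Physical constants and unit conversions used throughout the package.

Structure-layer coordinates are angstrom; energies are hartree internally and
excitation energies are reported in eV. All conversions funnel through the
constants below so there is a single source of truth.
"""

#: hartree -> eV (CODATA).
HARTREE_EV = 27.211386245988

#: angstrom -> bohr.
BOHR_PER_ANGSTROM = 1.8897259886

#: hc in eV*nm, for excitation-energy <-> wavelength conversion.
EV_NM = 1239.84193
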