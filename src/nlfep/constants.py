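"""Physical constants and unit conventions.

The package works in a single fixed unit system:

====================  =============
quantity              unit
====================  =============
length                angstrom (A)
energy                kcal/mol
temperature           kelvin
mass                  amu
time                  ps
====================  =============

Velocities are therefore A/ps and forces kcal/mol/A.
"""

#: Boltzmann constant, kcal/(mol K).
KB_KCAL_MOL_K = 0.0019872041

#: Conversion factor: 1 kcal/mol expressed in amu A^2 / ps^2.
#: (1 amu A^2/ps^2 = 10.0 J/mol exactly to 5 significant digits.)
KCAL_MOL_TO_AKMA = 418.4
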