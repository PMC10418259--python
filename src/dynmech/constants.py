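"""Physical constants in the unit system used throughout the package.

Lengths are in nm (traces) or Angstrom (structures), forces in pN,
stiffness in pN/nm, drag in pN s/nm, energies in pN nm, time in s.
"""

#: Boltzmann constant, pN nm / K (1.380649e-23 J/K, 1 J = 1e21 pN nm).
BOLTZMANN_PN_NM = 1.380649e-2
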