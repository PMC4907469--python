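"""Unit system of the simulator.

Quantities are carried in a GROMACS-like molecular unit system:

=============  =======================
length         nm
energy         kJ/mol
mass           u (atomic mass units, g/mol)
time           ps
force          kJ mol^-1 nm^-1
2-D stress     kJ mol^-1 nm^-2 (force per length)
temperature    K
=============  =======================

These units are internally consistent: with masses in u, forces in
kJ mol^-1 nm^-1 give accelerations in nm ps^-2 directly, so no conversion
factors appear in the equations of motion.
"""

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 8.314462618e-3

#: femtoseconds per picosecond (configs state the time step in fs).
FS_PER_PS = 1000.0
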