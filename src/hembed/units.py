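"""Unit constants.

Everything inside the library is in Hartree atomic units (bohr, hartree,
electron charge e, electron mass, a.u. time).  Conversions happen only at
I/O boundaries (XYZ/PDB/cube-angstrom dialect use angstrom, GRO uses nm).
"""

# CODATA 2018
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM
NM_TO_BOHR = 10.0 * ANGSTROM_TO_BOHR
BOHR_TO_NM = 1.0 / NM_TO_BOHR

AMU_TO_AU = 1822.888486209  # unified atomic mass unit -> electron masses

HARTREE_TO_KCAL_MOL = 627.509474063
KCAL_MOL_TO_HARTREE = 1.0 / HARTREE_TO_KCAL_MOL

AU_TIME_TO_FS = 2.4188843265857e-2
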