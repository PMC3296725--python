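"""Physical constants and shared defaults.

Units throughout the package: lengths in angstroms, energies in kcal/mol,
rates in min^-1, temperatures in kelvin, concentrations in molarity.
"""

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Reference temperature of the model-compound exchange-rate table, K.
T_REFERENCE = 293.0

#: Disulfide S-S distance cutoff (inclusive), angstrom.
DISULFIDE_CUTOFF = 2.3

#: Backbone H-bond N...O distance cutoff (inclusive), angstrom.
HBOND_DISTANCE_CUTOFF = 3.28

#: H-bond angle window at both donor and acceptor (inclusive), degrees.
HBOND_ANGLE_MIN = 90.0
HBOND_ANGLE_MAX = 180.0

#: Contact-order matrix backbone-N distance cutoff (inclusive), angstrom.
CONTACT_CUTOFF = 7.0

#: Free-energy tolerance for "consistent" comparisons, kcal/mol.
ENERGY_TOLERANCE = 0.4

#: pD = pH-meter reading + 0.4 in D2O (deuterium isotope correction).
PD_CORRECTION = 0.4

# Idealised backbone geometry used by the coordinate builders.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 117.2
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.5
OMEGA_TRANS = 180.0

#: Torsion windows (phi_center, psi_center, half_width) per secondary-structure
#: class, degrees.
TORSION_WINDOWS = {
    "alpha_helix": (-57.0, -47.0, 30.0),
    "three_ten_helix": (-60.0, -30.0, 30.0),
    "parallel_beta": (-119.0, -113.0, 30.0),
    "antiparallel_beta": (-139.0, 135.0, 30.0),
}

#: Three-letter to one-letter amino-acid codes (standard residues only).
AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
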