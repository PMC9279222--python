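"""Physical constants and per-element tables shared across the package.

Units follow small-angle scattering convention: lengths in Å, volumes in
Å³, scattering lengths in electrons (e), electron densities in e/Å³,
molar masses in g/mol.
"""

from __future__ import annotations

# van der Waals radii (Å) used as atom occupancy radii on the excluded-volume
# grid; Bondi values for the elements found in proteins.
VDW_RADIUS: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.7

# Displaced solvent volumes per atom (Å³), Fraser-style dummy-atom values,
# used for the protein excess scattering length b = Z - rho_solvent * V.
DISPLACED_VOLUME: dict[str, float] = {
    "H": 5.15,
    "C": 16.44,
    "N": 2.49,
    "O": 9.13,
    "S": 19.86,
    "P": 5.73,
    "SE": 28.73,
}
DEFAULT_DISPLACED_VOLUME = 16.44

# n-decyl-beta-D-maltopyranoside (DM, C22H42O11, 482.6 g/mol):
# decyl tail C10H21 and maltoside head C12H21O11.
DM_TAIL_VOLUME = 294.0      # Å³ per decyl chain
DM_HEAD_DRY_VOLUME = 350.0  # Å³ per maltoside headgroup, dry
DM_TAIL_ELECTRONS = 81.0    # e per C10H21
DM_HEAD_ELECTRONS = 181.0   # e per C12H21O11
DM_MOLAR_MASS = 482.6       # g/mol

# Aqueous buffer electron density (e/Å³) for the SEC buffers used with DM.
BUFFER_ELECTRON_DENSITY = 0.340

# SEC-MALS refractive-index increments (ml/g).
DNDC_PROTEIN = 0.1850
DNDC_DM = 0.1473

# Minimum distance between a detergent Monte-Carlo point and any protein
# atom center (Å).
PROTEIN_CLEARANCE = 3.0

# Ideal consecutive Calpha-Calpha distance (Å) for connectivity restraints.
CA_CA_IDEAL = 3.8
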