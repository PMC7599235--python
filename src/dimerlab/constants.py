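"""Physical constants, unit conversions and chemistry tables.

All energies are kcal/mol, distances Å, forces pN. SASA is computed in Å²
internally and reported in nm² at the report layer. Conversions are derived
from CODATA values via :mod:`scipy.constants` rather than hard-coded.
"""

from __future__ import annotations

from scipy import constants as _sc

# --- unit conversions -------------------------------------------------------

#: J per kcal (thermochemical calorie)
_J_PER_KCAL = _sc.calorie * 1000.0

#: kcal/mol carried by 1 pN acting over 1 Å (per molecule, scaled by N_A)
KCAL_PER_PN_ANGSTROM: float = 1e-12 * 1e-10 * _sc.Avogadro / _J_PER_KCAL

#: Boltzmann constant in kcal/mol/K
KB_KCAL_PER_MOL_K: float = _sc.Boltzmann * _sc.Avogadro / _J_PER_KCAL


def kbt(temperature_k: float) -> float:
    """Thermal energy k_B*T in kcal/mol at the given temperature (K)."""
    return KB_KCAL_PER_MOL_K * temperature_k


# --- residue chemistry ------------------------------------------------------

#: Chemical class of each standard residue, the convention of the
#: contact-based binding-affinity model (charged/polar/apolar).
RESIDUE_CLASS: dict[str, str] = {
    **{aa: "charged" for aa in "DEKRH"},
    **{aa: "apolar" for aa in "ACGFIMLPVW"},
    **{aa: "polar" for aa in "NQSTY"},
}

STANDARD_AA = frozenset(RESIDUE_CLASS)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Atomic masses (u) for the elements occurring in proteins.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971,
}

#: Element-level van der Waals radii (Å), ProtOr-flavoured defaults.
#: Carbon uses the tetrahedral ProtOr value; backbone carbonyl carbons are
#: overridden by name below.
VDW_RADII: dict[str, float] = {
    "C": 1.88, "N": 1.64, "O": 1.42, "S": 1.77, "P": 1.87,
    "H": 1.00, "SE": 1.90,
}

#: Name-specific radius overrides applied after the element lookup.
VDW_RADII_BY_NAME: dict[str, float] = {
    "C": 1.61,   # backbone carbonyl carbon (trigonal)
}

#: Theoretical maximum accessible surface area per residue (Å²),
#: Tien et al. 2013, used for relative SASA.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# --- contact-based binding-affinity model -----------------------------------

#: Coefficients of the contact-based affinity model (kcal/mol per contact or
#: per NIS percentage point). Interface contacts are classified by the
#: residue-class pair of the two partners at the 5.5 Å heavy-atom rule;
#: NIS terms are percentages of non-interacting surface residues by class.
#: Source: the published contacts+NIS regression (version "IC-NIS 2015").
AFFINITY_COEFFS: dict[str, float] = {
    "cc": -0.09459,       # charged-charged
    "ca": -0.10007,       # charged-apolar
    "pp": 0.19577,        # polar-polar
    "pa": -0.22671,       # polar-apolar
    "cp": 0.0,            # charged-polar (not in the published model)
    "aa": 0.0,            # apolar-apolar (not in the published model)
    "nis_apolar": 0.18681,
    "nis_charged": 0.13810,
    "intercept": -15.9433,
}

#: Relative-SASA threshold above which a residue counts as surface for NIS.
NIS_REL_SASA_THRESHOLD: float = 0.05

# --- geometric interaction rules (Å unless noted) ---------------------------

CONTACT_CUTOFF: float = 5.5          # heavy-atom residue-pair contact rule
HBOND_CUTOFF: float = 3.5            # donor-acceptor heavy-atom distance
HBOND_ANGLE_MIN_DEG: float = 120.0   # donor-H...acceptor angle, if H present
IONIC_CUTOFF: float = 4.0            # opposite-charge N/O side-chain pair
HYDROPHOBIC_CUTOFF: float = 5.0      # C-C between apolar side-chain groups
CATION_PI_CUTOFF: float = 6.0        # charged N to aromatic ring centroid
CATION_PI_ANGLE_MAX_DEG: float = 60.0

# --- simulation protocol defaults (the published study conditions) ----------

TEMPERATURE_K: float = 300.0
BOX_SIDE: float = 120.0
PULL_FORCE_PN: float = 368.0
DISSOCIATION_THRESHOLD: float = 41.0
N_RUNS: int = 24
N_CYCLES: int = 500_000
BURN_IN: int = 200_000
N_SNAPSHOTS: int = 3_000
N_BOOTSTRAP: int = 10_000
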