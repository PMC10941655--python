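"""Shared chemical reference data and small-geometry helpers.

Element van der Waals radii, amino-acid code tables, per-residue maximum
solvent accessibilities, and the ideal-geometry atom placement used for
CB reconstruction and side-chain growth.
"""

from __future__ import annotations

import numpy as np

# Bondi-style van der Waals radii (Å), fixed so SASA and clash scores are
# reproducible across platforms. Keys are upper-case element symbols.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
    "FE": 1.52,
    "MN": 1.55,
}

AA3_TO_1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA1_TO_3: dict[str, str] = {v: k for k, v in AA3_TO_1.items()}

# Common chemically modified residues and their standard parents, used only
# when sequences are extracted in "mapped" mode.
NONSTANDARD_PARENT: dict[str, str] = {
    "MSE": "M",  # selenomethionine
    "SEC": "C",  # selenocysteine (one-letter U is not in our alphabet)
    "SEP": "S",
    "TPO": "T",
    "PTR": "Y",
    "HYP": "P",
    "MLY": "K",
    "CSO": "C",
    "PCA": "Q",
}

STANDARD_AA1 = set(AA1_TO_3)

# Theoretical maximum solvent accessibility (Å²) of residue X in an extended
# Gly-X-Gly tripeptide (Tien et al. 2013, theoretical column). Used to
# normalise relative SASA.
MAX_SASA_GXG: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


def element_radius(element: str) -> float:
    """Return the vdW radius for an element symbol, or raise KeyError."""
    return VDW_RADII[element.upper()]


def guess_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name when no element field exists.

    Handles the common protein atoms; two-letter metals are not guessed.
    """
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Place atom D from three reference atoms by internal coordinates.

    D is positioned so that |C-D| = ``bond``, the B-C-D angle equals
    ``angle_deg`` and the A-B-C-D dihedral equals ``dihedral_deg``
    (natural extension reference frame construction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)

    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])

    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        raise ValueError("reference atoms are collinear; frame undefined")
    n /= n_norm
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def soft_sphere_overlap(
    coords_a: np.ndarray, radii_a: np.ndarray,
    coords_b: np.ndarray, radii_b: np.ndarray,
) -> float:
    """Squared soft-sphere overlap between two heavy-atom sets (Å² units).

    Sum over pairs of ``max(0, r_i + r_j - d)**2``; zero iff no pair is
    closer than the sum of its vdW radii. Monotone in interpenetration,
    which is all a geometric clash criterion needs.
    """
    from scipy.spatial import cKDTree

    coords_a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    coords_b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if len(coords_a) == 0 or len(coords_b) == 0:
        return 0.0
    radii_a = np.asarray(radii_a, dtype=float)
    radii_b = np.asarray(radii_b, dtype=float)
    max_reach = radii_a.max() + radii_b.max()
    tree_b = cKDTree(coords_b)
    total = 0.0
    for i, neighbours in enumerate(cKDTree(coords_a).query_ball_tree(tree_b, max_reach)):
        for j in neighbours:
            d = np.linalg.norm(coords_a[i] - coords_b[j])
            pen = radii_a[i] + radii_b[j] - d
            if pen > 0:
                total += pen * pen
    return float(total)


def build_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal CB from backbone N, CA, C.

    Tetrahedral L-amino-acid geometry: CA-CB 1.53 Å, N-CA-CB 110.4°,
    C-N-CA-CB dihedral -122.5°.
    """
    return place_atom(c, n, ca, 1.53, 110.4, -122.5)
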