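"""Element inference and atomic masses.

PDB files produced by modelling pipelines frequently lack the element
columns (77-78), so the element must be recovered from the atom name.
The fallback consults a two-letter element table first, but only for
residues that are not standard amino acids or waters: in a protein
residue, "CA" is an alpha-carbon, never calcium.
"""

from __future__ import annotations

# Standard atomic masses (Da), sufficient for protein/ligand/lipid/water work.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971, "BR": 79.904,
    "I": 126.904, "LI": 6.94, "AL": 26.982, "SI": 28.085, "B": 10.81,
}

# Two-letter symbols that can plausibly open an atom name.  Deliberately
# excludes CA/NA/... collisions for protein atoms; see infer_element.
_TWO_LETTER = {
    "CL", "BR", "FE", "ZN", "MG", "MN", "CU", "NI", "SE", "NA", "CA",
    "LI", "AL", "SI", "CD", "HG", "CO", "CR", "MO",
}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation-variant names
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
}

WATER_RESIDUES = {"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC", "H2O"}


def infer_element(atom_name: str, residue_name: str) -> str:
    """Infer an element symbol from an atom name.

    For standard amino-acid and water residues the element is the first
    alphabetic character of the name (handles names like "1HB", "CA",
    "OXT").  For anything else the first two characters are checked
    against a two-letter element table before falling back to the first
    alphabetic character, so that ions ("CL", "NA") and lipid phosphorus
    beads resolve correctly.
    """
    name = atom_name.strip().upper()
    resname = residue_name.strip().upper()
    if not name:
        raise ValueError("empty atom name; cannot infer element")
    alpha = [c for c in name if c.isalpha()]
    if not alpha:
        raise ValueError(f"atom name {atom_name!r} has no alphabetic character")
    if resname not in STANDARD_AMINO_ACIDS and resname not in WATER_RESIDUES:
        head = "".join(alpha[:2])
        if head in _TWO_LETTER:
            return head.capitalize()
    return alpha[0]


def mass_of(element: str) -> float:
    """Atomic mass in Da; raises for unknown elements."""
    key = element.strip().upper()
    try:
        return ATOMIC_MASSES[key]
    except KeyError:
        raise KeyError(f"no mass tabulated for element {element!r}") from None
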