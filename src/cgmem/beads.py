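"""Bead chemistry: classification of CG beads into chemical classes.

The default table covers MARTINI-style DPPC (NC3 choline, PO4 phosphate,
GL1/GL2 glycerol, C1A..C4A and C1B..C4B acyl-tail beads, where the digit is
the bead's position along its chain), MARTINI water (W), monovalent ions
(NA+/CL-) and the twenty standard amino acids (any bead name, typically BB
plus SC1..SC4 side-chain beads).  Other lipid species can be added through a
YAML table (see :func:`load_classification_table`).
"""

from __future__ import annotations

from enum import IntEnum
from pathlib import Path

import yaml

from .errors import ClassificationError


class BeadClass(IntEnum):
    PROTEIN = 0
    CHOLINE = 1
    PHOSPHATE = 2
    GLYCEROL = 3
    TAIL_1 = 4
    TAIL_2 = 5
    TAIL_3 = 6
    TAIL_4 = 7
    WATER = 8
    ION = 9


#: head-group classes: choline + phosphate + glycerol
HEAD_CLASSES = frozenset({BeadClass.CHOLINE, BeadClass.PHOSPHATE, BeadClass.GLYCEROL})
#: acyl-tail classes, indexed by position along the chain
TAIL_CLASSES = frozenset(
    {BeadClass.TAIL_1, BeadClass.TAIL_2, BeadClass.TAIL_3, BeadClass.TAIL_4}
)
#: solvent classes (water and ions are kept distinct internally and merged
#: only for display/fraction purposes)
SOLVENT_CLASSES = frozenset({BeadClass.WATER, BeadClass.ION})
#: classes that belong to a lipid molecule
LIPID_CLASSES = HEAD_CLASSES | TAIL_CLASSES

AMINO_ACIDS_3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AMINO_ACIDS_1 = {v: k for k, v in AMINO_ACIDS_3.items()}

_DPPC_BEADS = {
    "NC3": BeadClass.CHOLINE,
    "PO4": BeadClass.PHOSPHATE,
    "GL1": BeadClass.GLYCEROL,
    "GL2": BeadClass.GLYCEROL,
}
for _chain in "AB":
    for _k in range(1, 5):
        _DPPC_BEADS[f"C{_k}{_chain}"] = BeadClass(int(BeadClass.TAIL_1) + _k - 1)

DEFAULT_TABLE: dict[tuple[str, str], BeadClass] = {}
for _bead, _cls in _DPPC_BEADS.items():
    DEFAULT_TABLE[("DPPC", _bead)] = _cls
for _res, _bead in [("W", "W"), ("SOL", "W"), ("WAT", "W")]:
    DEFAULT_TABLE[(_res, _bead)] = BeadClass.WATER
for _ion in ("NA+", "CL-", "NA", "CL", "ION"):
    for _bead in ("NA+", "CL-", "NA", "CL"):
        DEFAULT_TABLE[(_ion, _bead)] = BeadClass.ION


def classify_bead(
    residue_name: str,
    bead_name: str,
    table: dict[tuple[str, str], BeadClass] | None = None,
) -> BeadClass:
    """Map one (residue name, bead name) pair to its :class:`BeadClass`.

    Standard amino-acid residues classify as PROTEIN regardless of bead name.
    Raises :class:`ClassificationError` for unmapped pairs.
    """
    if residue_name in AMINO_ACIDS_3:
        return BeadClass.PROTEIN
    tab = DEFAULT_TABLE if table is None else table
    try:
        return tab[(residue_name, bead_name)]
    except KeyError:
        raise ClassificationError([(residue_name, bead_name)]) from None


def load_classification_table(path: str | Path) -> dict[tuple[str, str], BeadClass]:
    """Extend the default table from a YAML file.

    Layout::

        POPC:
          NC3: CHOLINE
          PO4: PHOSPHATE
          ...

    Returns a new table (the default is never mutated).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    table = dict(DEFAULT_TABLE)
    for resname, beads in raw.items():
        for bead, label in beads.items():
            table[(str(resname), str(bead))] = BeadClass[str(label)]
    return table
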