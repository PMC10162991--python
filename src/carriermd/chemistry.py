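"""Residue chemistry tables: H-bond donors/acceptors, aromatic rings, masses.

Sidechain chemistry for the standard amino acids is loaded from the
packaged ``data/hbond_chemistry.yaml``; backbone N-H / C=O and a generic
rule for ligands (any N/O with an attached hydrogen donates, any N/O
accepts) are applied programmatically.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

AROMATIC_RESIDUES = ("PHE", "TYR", "TRP", "HIS")

# Purine / pyrimidine ring atoms (PDB nucleotide naming); two rings for
# purines, one for pyrimidines.  Used for "the aromatic rings of the
# nucleotide" in pi-interaction detection.
PURINE_RINGS = (("N9", "C8", "N7", "C5", "C4"),
                ("C4", "C5", "C6", "N1", "C2", "N3"))
PYRIMIDINE_RING = (("N1", "C2", "N3", "C4", "C5", "C6"),)

# Nucleotide moiety atom-name sets (GDP/GTP/UDP-like ligands).
PHOSPHATE_ATOMS = frozenset(
    ["PA", "PB", "PG", "P",
     "O1A", "O2A", "O3A", "O1B", "O2B", "O3B", "O1G", "O2G", "O3G"])
BASE_ATOMS = frozenset(
    ["N1", "C2", "N2", "N3", "C4", "C5", "C6", "O6", "N7", "C8", "N9",
     "O2", "O4", "H1", "H8", "H21", "H22", "H3", "H5", "H6", "H2"])

ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                 "P": 30.974, "S": 32.06}
DEFAULT_MASS = 12.011


@lru_cache(maxsize=1)
def load_chemistry() -> dict:
    """Load sidechain donor/acceptor/ring tables from the packaged YAML."""
    ref = resources.files("carriermd.data") / "hbond_chemistry.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh)


def masses_for(elements: np.ndarray) -> np.ndarray:
    return np.array([ATOMIC_MASSES.get(e, DEFAULT_MASS) for e in elements])


def is_ribose_atom(name: str) -> bool:
    return name.endswith("'")


def moiety_of(atom_name: str) -> str:
    """Classify a nucleotide atom as phosphate, ribose or base."""
    if atom_name in PHOSPHATE_ATOMS:
        return "phosphate"
    if is_ribose_atom(atom_name):
        return "ribose"
    if atom_name in BASE_ATOMS:
        return "base"
    return "other"
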