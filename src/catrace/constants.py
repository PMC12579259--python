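"""Shared channel and label conventions.

Every module that touches per-voxel encodings, label masks, or predicted
probability volumes imports its channel semantics from here so that the
orderings can never drift apart.

Axis convention
---------------
Volumes are indexed ``data[i, j, k]`` with ``i`` along world ``z``, ``j``
along world ``y`` and ``k`` along world ``x``.  World coordinates are in
Angstrom.

Channel semantics of the 24-channel structure encoding
------------------------------------------------------
channel 0: Calpha occupancy, 1: N, 2: C, 3: O,
channels 4..23: the 20 canonical amino-acid types, alphabetical by
three-letter code (``AA_ORDER``).  The same 20-type order is used for the
amino-acid probability volumes and for candidate amino-acid profiles.

Label masks
-----------
backbone / calpha masks: 0 background, 1 neighbour of any atom,
2 other atom, 3 target atom (any backbone atom / the Calpha).
amino mask: 0 none, 1..20 amino-acid type index (``AA_ORDER`` position + 1)
at Calpha voxels and their 26-neighbourhood.
"""

from __future__ import annotations

# Alphabetical by three-letter code.
AA_ORDER: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS",
    "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO",
    "SER", "THR", "TRP", "TYR", "VAL",
)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: three-letter code -> 0-based index into the 20-type order
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}

#: backbone atom names, in the channel order of the structure encoding
BACKBONE_ATOMS: tuple[str, ...] = ("CA", "N", "C", "O")

N_AA = 20
N_ENCODE_CHANNELS = 24  # 4 backbone-atom channels + 20 amino-acid channels

# grid partitioning geometry
CORE_SIZE = 48   # non-overlapping core block edge, voxels
PAD_SIZE = 8     # context padding per face, voxels
PATCH_SIZE = CORE_SIZE + 2 * PAD_SIZE  # 64


def aa_index_of_letter(letter: str) -> int:
    """0-based amino-acid type index of a one-letter residue code."""
    try:
        return AA_INDEX[ONE_TO_THREE[letter.upper()]]
    except KeyError:
        raise ValueError(f"unknown residue letter {letter!r}") from None
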