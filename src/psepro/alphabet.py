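"""Canonical amino-acid alphabet shared by every module.

All 20-dimensional math in this package is defined over the standard amino
acids in a single fixed column order: alphabetical one-letter codes. Parsers
that encounter other orders (e.g. PSI-BLAST's ARND... layout) reorder into
this one at the boundary.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 standard residues in canonical (alphabetical) column order."""

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

AMBIGUITY: str = "X"
"""Single symbol every non-standard character is folded into."""

ALPHABET: str = AMINO_ACIDS + AMBIGUITY

GAP_CHARS: frozenset[str] = frozenset("-.")


def is_standard(residue: str) -> bool:
    return residue in AA_INDEX
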