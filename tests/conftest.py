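from __future__ import annotations

import numpy as np
import pytest

from psepro import (
    SyntheticSpec,
    blosum62_model,
    default_property_table,
    generate_dataset,
)
from psepro.alphabet import AMINO_ACIDS

#: PSI-BLAST prints its columns in this order; fixtures use it so parsing
#: exercises the reordering into the canonical alphabet.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"


@pytest.fixture(scope="session")
def props():
    return default_property_table()


@pytest.fixture(scope="session")
def subst_model():
    return blosum62_model()


@pytest.fixture(scope="session")
def default_fixture():
    """The default R/K-enriched two-class dataset (n=60, seed 0)."""
    X, y, manifest = generate_dataset(SyntheticSpec(seed=0))
    return X, y, manifest


def make_pssm_text(percent_rows: np.ndarray, query: str) -> str:
    """Render percentage rows (canonical column order) as a PSI-BLAST PSSM."""
    perm = [AMINO_ACIDS.index(a) for a in PSIBLAST_ORDER]
    letters = "  ".join(PSIBLAST_ORDER)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        f"            {letters}   {letters}",
    ]
    for j, row in enumerate(np.asarray(percent_rows, dtype=float)):
        lods = " ".join("  0" for _ in range(20))
        perc = " ".join(f"{row[i]:3g}" for i in perm)
        lines.append(f"{j + 1:5d} {query[j]}  {lods}  {perc}  0.36 0.80")
    lines.append("")
    return "\n".join(lines) + "\n"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
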