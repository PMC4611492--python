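"""Physicochemical property tables and their normalization.

The sequence-order correlation factors compare residues through a panel of
physicochemical properties. The default panel is the canonical seven-property
set used throughout the PseAAC literature:

1. hydrophobicity (Tanford-style consensus scale),
2. hydrophilicity (Hopp-Woods),
3. side-chain mass (Da),
4. pK1 (alpha-carboxyl dissociation constant),
5. pK2 (alpha-amino dissociation constant),
6. isoelectric point (pI),
7. mean accessible surface area (100 A^2, Gly-X-Gly context).

The shipped raw values are a stand-in for any particular publication's
supplementary table: users with a preferred panel should load their own file
with :func:`load_property_table` (TSV, one property per row: name followed by
20 values in canonical alphabetical residue order). Every property row is
z-scored over the 20 residues before use, so affine differences between
published scales do not affect the features.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS

# Raw values, canonical order A C D E F G H I K L M N P Q R S T V W Y.
_DEFAULT_RAW: dict[str, list[float]] = {
    "hydrophobicity": [
        0.62, 0.29, -0.90, -0.74, 1.19, 0.48, -0.40, 1.38, -1.50, 1.06,
        0.64, -0.78, 0.12, -0.85, -2.53, -0.18, -0.05, 1.08, 0.81, 0.26,
    ],
    "hydrophilicity": [
        -0.5, -1.0, 3.0, 3.0, -2.5, 0.0, -0.5, -1.8, 3.0, -1.8,
        -1.3, 0.2, 0.0, 0.2, 3.0, 0.3, -0.4, -1.5, -3.4, -2.3,
    ],
    "side_chain_mass": [
        15.0, 47.0, 59.0, 73.0, 91.0, 1.0, 82.0, 57.0, 73.0, 57.0,
        75.0, 58.0, 42.0, 72.0, 101.0, 31.0, 45.0, 43.0, 130.0, 107.0,
    ],
    "pK1": [
        2.35, 1.71, 1.88, 2.19, 2.58, 2.34, 1.78, 2.32, 2.20, 2.36,
        2.28, 2.18, 1.99, 2.17, 2.18, 2.21, 2.15, 2.29, 2.38, 2.20,
    ],
    "pK2": [
        9.87, 10.78, 9.60, 9.67, 9.24, 9.60, 8.97, 9.76, 8.90, 9.60,
        9.21, 9.09, 10.60, 9.13, 9.09, 9.15, 9.12, 9.74, 9.39, 9.11,
    ],
    "pI": [
        6.11, 5.02, 2.98, 3.08, 5.91, 6.06, 7.64, 6.04, 9.47, 6.04,
        5.74, 5.41, 6.30, 5.65, 10.76, 5.68, 5.60, 6.02, 5.88, 5.63,
    ],
    "accessible_surface_area": [
        1.181, 1.461, 1.587, 1.862, 2.228, 0.881, 2.025, 1.810, 2.258, 1.931,
        2.034, 1.655, 1.468, 1.932, 2.560, 1.298, 1.525, 1.645, 2.663, 2.368,
    ],
}


@dataclass
class PropertyTable:
    """Raw and z-scored physicochemical property values for the 20 residues."""

    names: list[str]
    raw: np.ndarray
    normalized: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if self.raw.shape != (len(self.names), 20):
            raise ValueError("raw must be (n_properties, 20)")
        if self.normalized.shape != self.raw.shape:
            raise ValueError("normalized must match raw shape")
        mu = self.normalized.mean(axis=1)
        sd = self.normalized.std(axis=1)
        if np.max(np.abs(mu)) > 1e-9 or np.max(np.abs(sd - 1.0)) > 1e-9:
            raise ValueError("normalized rows must have mean 0 and population sd 1")

    @property
    def n_properties(self) -> int:
        return len(self.names)

    def value(self, name: str, residue: str) -> float:
        """Normalized value of one property for one residue."""
        return float(
            self.normalized[self.names.index(name), AA_INDEX[residue]]
        )


def normalize_properties(
    raw: np.ndarray, names: list[str] | None = None
) -> PropertyTable:
    """Z-score each property row over the 20 standard residues.

    The population standard deviation (divide by n = 20) is used, following
    the PseAAC convention.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 20:
        raise ValueError("raw property table must have shape (n_properties, 20)")
    if names is None:
        names = [f"property_{i + 1}" for i in range(raw.shape[0])]
    if len(names) != raw.shape[0]:
        raise ValueError("names length must match number of property rows")
    sd = raw.std(axis=1)
    scale = 1.0 + np.abs(raw).max(axis=1)
    if np.any(sd <= 1e-12 * scale):
        bad = names[int(np.argmin(sd / scale))]
        raise ValueError(f"property {bad!r} is constant across residues")
    normalized = (raw - raw.mean(axis=1, keepdims=True)) / sd[:, None]
    return PropertyTable(names=list(names), raw=raw, normalized=normalized)


@lru_cache(maxsize=1)
def default_property_table() -> PropertyTable:
    """The packaged seven-property panel, normalized."""
    names = list(_DEFAULT_RAW)
    raw = np.array([_DEFAULT_RAW[n] for n in names])
    return normalize_properties(raw, names)


def load_property_table(path: str | Path) -> PropertyTable:
    """Load a property table from TSV: name + 20 canonical-order values per row.

    Lines starting with ``#`` are comments; an optional header line whose
    fields after the first are the 20 amino-acid letters is accepted and must
    be in canonical order.
    """
    path = Path(path)
    names: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[1:] == list(AMINO_ACIDS):
            continue  # header row
        if len(fields) != 21:
            raise ValueError(
                f"{path}: line {lineno}: expected name + 20 values, "
                f"got {len(fields)} fields"
            )
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}")
        names.append(fields[0])
    if not rows:
        raise ValueError(f"{path}: no property rows found")
    return normalize_properties(np.array(rows), names)


def write_property_table(table: PropertyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\t" + "\t".join(AMINO_ACIDS) + "\n")
        for name, row in zip(table.names, table.raw):
            fh.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
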