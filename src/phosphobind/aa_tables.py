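"""Amino-acid categories and physicochemical properties.

Two reference tables drive the whole method:

* a partition of the 20 canonical amino acids into five side-chain
  categories (positive charged, negative charged, polar uncharged,
  hydrophobic, special), used by the relevance-sampling rule and the
  similarity score;
* a 20 x 9 physicochemical property matrix (hydrophobicity H1,
  hydrophilicity H2, hydrogen bond H3, side-chain volume V, polarity P1,
  polarizability P2, solvent-accessible surface area SASA, net charge
  index NCI, average residue mass MASS), column-standardized to zero mean
  and unit SD before any feature is computed.

Both tables ship as TSV package data and are validated against built-in
checksums at load time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

#: The 20 canonical amino acids, alphabetical one-letter order (frozen row order).
CANONICAL_AA: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Property columns in frozen print order; all feature indices reference it.
PROPERTY_COLUMNS: tuple[str, ...] = (
    "H1", "H2", "H3", "V", "P1", "P2", "SASA", "NCI", "MASS",
)

#: The five side-chain categories.
CATEGORY_LABELS: tuple[str, ...] = (
    "positive-charged",
    "negative-charged",
    "polar-uncharged",
    "hydrophobic",
    "special",
)

_DATA_CHECKSUMS = {
    "aa_categories.tsv": "dc9b2a3391dabbe3b72de6795106fee24ab6034f14246b56c9747eb01fc19dab",
    "aa_properties.tsv": "5d98804874e1b0fb05d8ca8ac2b0bd82e86f4412c77a1f045f5674242f69e7a2",
}


def validate_aa(code: str) -> str:
    """Return ``code`` if it is a canonical one-letter amino acid, else raise.

    Raises
    ------
    ValueError
        Naming the offending character.
    """
    if not isinstance(code, str) or code not in CANONICAL_AA:
        raise ValueError(f"not a canonical amino acid one-letter code: {code!r}")
    return code


def _read_package_tsv(name: str) -> pd.DataFrame:
    ref = resources.files("phosphobind.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = _DATA_CHECKSUMS[name]
    if digest != expected:
        raise RuntimeError(
            f"package data file {name} failed checksum validation "
            f"(got {digest}, expected {expected})"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t", index_col="aa")


@dataclass(frozen=True)
class CategoryTable:
    """Partition of the 20 amino acids into the five side-chain categories."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.assignment) != set(CANONICAL_AA):
            raise ValueError("category table must cover exactly the 20 canonical amino acids")
        bad = set(self.assignment.values()) - set(CATEGORY_LABELS)
        if bad:
            raise ValueError(f"unknown category labels: {sorted(bad)}")

    def __getitem__(self, aa: str) -> str:
        return category_of(aa, self)

    def members(self, category: str) -> tuple[str, ...]:
        """Amino acids in ``category``, alphabetical."""
        return tuple(a for a in CANONICAL_AA if self.assignment[a] == category)


@dataclass(frozen=True)
class PropertyTable:
    """Raw 20 x 9 physicochemical matrix, rows = amino acids, columns = properties."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if tuple(self.values.index) != CANONICAL_AA:
            raise ValueError("property table rows must be the 20 canonical amino acids in order")
        if tuple(self.values.columns) != PROPERTY_COLUMNS:
            raise ValueError(f"property table columns must be {PROPERTY_COLUMNS}")
        if self.values.isna().any().any():
            raise ValueError("property table has missing entries")


@dataclass(frozen=True)
class NormalizedPropertyTable:
    """Column-standardized property matrix with the means/SDs used.

    ``denormalize`` recovers the raw table: raw = values * sds + means.
    """

    values: pd.DataFrame
    column_means: pd.Series
    column_sds: pd.Series
    ddof: int = 0  # population SD over the 20 amino acids

    def denormalize(self) -> pd.DataFrame:
        return self.values * self.column_sds + self.column_means

    def row(self, aa: str) -> np.ndarray:
        """Normalized 9-vector for one amino acid (frozen property order)."""
        validate_aa(aa)
        return self.values.loc[aa].to_numpy()


def load_category_table() -> CategoryTable:
    """Load and validate the shipped five-category partition."""
    df = _read_package_tsv("aa_categories.tsv")
    table = CategoryTable(assignment=df["category"].to_dict())
    sizes = {cat: len(table.members(cat)) for cat in CATEGORY_LABELS}
    expected = {
        "positive-charged": 3,
        "negative-charged": 2,
        "polar-uncharged": 4,
        "hydrophobic": 8,
        "special": 3,
    }
    if sizes != expected:
        raise RuntimeError(f"category sizes {sizes} do not match the expected partition")
    return table


def load_property_table() -> PropertyTable:
    """Load and validate the shipped 20 x 9 property matrix."""
    df = _read_package_tsv("aa_properties.tsv")
    return PropertyTable(values=df.astype(float))


def category_of(aa: str, table: CategoryTable) -> str:
    """The unique side-chain category containing ``aa``."""
    validate_aa(aa)
    return table.assignment[aa]


def normalize_properties(raw: PropertyTable, ddof: int = 0) -> NormalizedPropertyTable:
    """Standardize each property column to zero mean and unit SD.

    The SD uses the population divisor (n = 20) by default: the 20 amino
    acids are the entire population of interest.  ``ddof=1`` switches to the
    sample divisor.
    """
    means = raw.values.mean(axis=0)
    sds = raw.values.std(axis=0, ddof=ddof)
    if (sds <= 0).any():
        bad = list(sds.index[sds <= 0])
        raise ValueError(f"cannot standardize constant property column(s): {bad}")
    return NormalizedPropertyTable(
        values=(raw.values - means) / sds,
        column_means=means,
        column_sds=sds,
        ddof=ddof,
    )


def default_normalized_properties(ddof: int = 0) -> NormalizedPropertyTable:
    """Convenience: load the shipped table and standardize it."""
    return normalize_properties(load_property_table(), ddof=ddof)
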