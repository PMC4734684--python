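"""Motif featurization: 27 positional + 27 auto-cross-covariance values.

Each motif maps to 54 features.  Block one is positional: the standardized
value of each of the 9 physicochemical properties at each of the 3 variable
positions (3 x 9 = 27), positions in stored N-to-C order.  Block two couples
positions: for each property j and each unordered position pair (m, n), the
product of the two positions' deviations from the 3-position mean of that
property,

    AC(m, n, j) = (x_mj - mean_i x_ij) * (x_nj - mean_i x_ij),

with pairs in fixed order (1,2), (1,3), (2,3) — another 3 x 9 = 27 values.
Only same-property couplings are used (auto covariance, no cross terms), and
only the three positions of the motif's own terminal enter the mean.

A handy identity follows from deviations summing to zero: for every property
the three pair terms sum to -1/2 * sum of squared deviations, hence are
jointly non-positive and vanish exactly when the triple is constant.
"""

from __future__ import annotations

import numpy as np

from .aa_tables import PROPERTY_COLUMNS, NormalizedPropertyTable
from .peptide_library import PeptideMotif

#: Unordered position pairs of the variable triple, frozen order (1-based).
AC_PAIRS: tuple[tuple[int, int], ...] = ((1, 2), (1, 3), (2, 3))

#: Total feature count: 27 positional + 27 auto-cross-covariance.
N_FEATURES = 54


def positional_features(motif: PeptideMotif, norm: NormalizedPropertyTable) -> np.ndarray:
    """The 27 positional values: position-major, property-minor order."""
    return np.concatenate([norm.row(aa) for aa in motif.residues])


def ac_features(motif: PeptideMotif, norm: NormalizedPropertyTable) -> np.ndarray:
    """The 27 auto-cross-covariance values, pair-major, property-minor order."""
    x = np.stack([norm.row(aa) for aa in motif.residues])  # 3 x 9
    dev = x - x.mean(axis=0, keepdims=True)
    return np.concatenate([dev[m - 1] * dev[n - 1] for m, n in AC_PAIRS])


def featurize(motif: PeptideMotif, norm: NormalizedPropertyTable) -> np.ndarray:
    """Full 54-value feature vector: positional block then AC block."""
    return np.concatenate([positional_features(motif, norm), ac_features(motif, norm)])


def featurize_library(
    motifs: list[PeptideMotif], norm: NormalizedPropertyTable
) -> np.ndarray:
    """Feature matrix (n_motifs x 54) for a motif list."""
    if not motifs:
        return np.empty((0, N_FEATURES))
    return np.stack([featurize(m, norm) for m in motifs])


def feature_names(terminal: str) -> list[str]:
    """Stable names for the 54 features of one terminal's motifs.

    Positional block: ``pos_<position>_<property>``; AC block:
    ``ac_<position>x<position>_<property>``.
    """
    labels = ("P-3", "P-2", "P-1") if terminal == "N" else ("P+1", "P+2", "P+3")
    names = [f"pos_{lab}_{prop}" for lab in labels for prop in PROPERTY_COLUMNS]
    names += [
        f"ac_{labels[m - 1]}x{labels[n - 1]}_{prop}"
        for m, n in AC_PAIRS
        for prop in PROPERTY_COLUMNS
    ]
    return names
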