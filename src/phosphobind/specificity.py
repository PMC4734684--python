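"""Isoform-specificity analyses of predicted binders.

Downstream of affinity prediction: extract each isoform's top-k binders,
summarize them as position weight matrices / position frequencies, intersect
top lists across the seven 14-3-3 isoforms to find consensus binders, call
isoform-specific binders (in one isoform's top list and no other's), and
compare called motifs to reference binders with a per-position similarity
score — 3 for an identical residue, 1 for a same-category residue, 0
otherwise — whose significance is assessed by a randomization test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aa_tables import CANONICAL_AA, CategoryTable, category_of, validate_aa
from .peptide_library import AffinityRecord, PeptideMotif

#: Row order of position weight matrices.
POSITION_LABELS: tuple[str, ...] = ("P-3", "P-2", "P-1", "P+1", "P+2", "P+3")


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-position amino-acid weights over the six variable positions.

    ``weights`` is a 6 x 20 frame (rows = positions P-3..P+3 excluding the
    center, columns = amino acids); rows of positions never covered by the
    input motifs are flagged in ``covered`` and left as NaN, not zero-filled.
    Covered rows sum to 1.
    """

    weights: pd.DataFrame
    covered: tuple[bool, ...]
    mode: str  # "frequency" or "affinity-weighted"

    def __post_init__(self) -> None:
        if tuple(self.weights.index) != POSITION_LABELS:
            raise ValueError(f"PWM rows must be {POSITION_LABELS}")
        if tuple(self.weights.columns) != CANONICAL_AA:
            raise ValueError("PWM columns must be the 20 canonical amino acids")
        for lab, cov in zip(POSITION_LABELS, self.covered):
            row = self.weights.loc[lab]
            if cov and abs(row.sum() - 1.0) > 1e-9:
                raise ValueError(f"covered PWM row {lab} must sum to 1")


@dataclass(frozen=True)
class SimilarityScore:
    """Per-position 3/1/0 similarity of a motif to a reference triple."""

    total: int
    per_position: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(v not in (0, 1, 3) for v in self.per_position):
            raise ValueError("per-position scores must be 0, 1 or 3")
        if self.total != sum(self.per_position):
            raise ValueError("total must equal the sum of per-position scores")


def top_k(records: list[AffinityRecord], k: int) -> list[PeptideMotif]:
    """The k highest-affinity motifs, affinity ties broken lexicographically."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(records):
        raise ValueError(f"k={k} exceeds the {len(records)} available records")
    for rec in records:
        if rec.affinity is None:
            raise ValueError("all records must carry an affinity")
    ranked = sorted(records, key=lambda r: (-r.affinity, r.motif.encode()))
    return [rec.motif for rec in ranked[:k]]


def position_frequencies(
    motifs: list[PeptideMotif],
    weights: list[float] | np.ndarray | None = None,
) -> PositionWeightMatrix:
    """Per-position amino-acid frequencies, optionally affinity-weighted.

    N-terminal motifs populate P-3..P-1 and C-terminal ones P+1..P+3; a
    merged list covers all six positions.  With ``weights`` (e.g. predicted
    affinities) each motif contributes proportionally to its weight.
    """
    if not motifs:
        raise ValueError("need at least one motif")
    if weights is None:
        w = np.ones(len(motifs))
        mode = "frequency"
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(motifs),):
            raise ValueError("weights must match the motif list length")
        if (w < 0).any() or not np.isfinite(w).all():
            raise ValueError("weights must be finite and non-negative")
        mode = "affinity-weighted"

    counts = pd.DataFrame(0.0, index=list(POSITION_LABELS), columns=list(CANONICAL_AA))
    for motif, wt in zip(motifs, w):
        for lab, aa in zip(motif.position_labels(), motif.residues):
            counts.loc[lab, aa] += wt

    covered = []
    out = counts.copy()
    for lab in POSITION_LABELS:
        total = counts.loc[lab].sum()
        if total > 0:
            out.loc[lab] = counts.loc[lab] / total
            covered.append(True)
        else:
            out.loc[lab] = np.nan
            covered.append(False)
    return PositionWeightMatrix(weights=out, covered=tuple(covered), mode=mode)


def consensus_binders(top_lists: dict[str, list[PeptideMotif]]) -> list[PeptideMotif]:
    """Deduplicated motifs present in every isoform's top list."""
    if len(top_lists) < 2:
        raise ValueError("need top lists from at least two isoforms")
    sets = [set(lst) for lst in top_lists.values()]
    common = set.intersection(*sets)
    return sorted(common, key=lambda m: m.encode())


def isoform_specific(
    top_lists: dict[str, list[PeptideMotif]], target: str
) -> list[PeptideMotif]:
    """Motifs in the target isoform's top list and in no other's."""
    if target not in top_lists:
        raise ValueError(f"unknown isoform {target!r}; have {sorted(top_lists)}")
    others: set[PeptideMotif] = set()
    for name, lst in top_lists.items():
        if name != target:
            others.update(lst)
    seen: set[PeptideMotif] = set()
    out = []
    for motif in top_lists[target]:
        if motif not in others and motif not in seen:
            seen.add(motif)
            out.append(motif)
    return out


def similarity_score(
    motif: PeptideMotif,
    reference_triple: tuple[str, str, str],
    categories: CategoryTable,
) -> SimilarityScore:
    """Score a motif against an aligned reference triple with the 3/1/0 rule."""
    if len(reference_triple) != 3:
        raise ValueError("reference triple must have exactly three residues")
    per = []
    for aa, ref in zip(motif.residues, reference_triple):
        validate_aa(ref)
        if aa == ref:
            per.append(3)
        elif category_of(aa, categories) == category_of(ref, categories):
            per.append(1)
        else:
            per.append(0)
    return SimilarityScore(total=sum(per), per_position=tuple(per))


def randomization_pvalue(
    observed: int,
    reference_triple: tuple[str, str, str],
    categories: CategoryTable,
    null_alphabets: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]] | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    terminal: str = "N",
) -> float:
    """Monte-Carlo p-value for an observed similarity score.

    Null motifs draw each position uniformly from its alphabet (all 20 amino
    acids by default); p = fraction of null scores >= observed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if null_alphabets is None:
        null_alphabets = (CANONICAL_AA, CANONICAL_AA, CANONICAL_AA)
    for alpha in null_alphabets:
        if not alpha:
            raise ValueError("null alphabets must be non-empty")
    rng = np.random.default_rng(seed)
    hits = 0
    draws = [rng.choice(len(a), size=n_iter) for a in null_alphabets]
    for it in range(n_iter):
        residues = tuple(null_alphabets[pos][draws[pos][it]] for pos in range(3))
        motif = PeptideMotif(terminal=terminal, residues=residues)
        if similarity_score(motif, reference_triple, categories).total >= observed:
            hits += 1
    return hits / n_iter


def write_pwm(pwm: PositionWeightMatrix, path) -> None:
    """Write a PWM as a 6 x 20 TSV with position row labels."""
    pwm.weights.to_csv(path, sep="\t", index_label="position", float_format="%.6g")
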