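"""Hexapeptide phosphomotifs and the combinatorial sublibraries.

A motif is the six-residue context P-3 P-2 P-1 - pS/T - P+1 P+2 P+3 around a
phosphorylated serine or threonine.  The experimental library varies only one
terminal at a time: an N-terminal motif fixes P-3..P-1 and leaves the C side
wildcard (X), and vice versa.  The restricted building-block alphabets are
10 residues (R,E,F,L,Q,A,G,V,K,P) at the two inner positions and 5
(R,E,F,L,P) at the outermost one, giving 5 x 10 x 10 = 500 motifs per
terminal; the full 20-amino-acid space is 20^3 = 8,000 per terminal.

Text encoding: a 7-character token, wildcards as ``X`` and the center as
lowercase ``s``/``t`` (``x`` when unspecified), e.g. N-terminal RAF ->
``RAFsXXX``, C-terminal FGP -> ``XXXsFGP``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

from .aa_tables import CANONICAL_AA, validate_aa

#: Building blocks used at the two positions adjacent to the phospho-center.
PAPER_ALPHABET_P12: tuple[str, ...] = tuple("REFLQAGVKP")
#: Building blocks used at the outermost variable position.
PAPER_ALPHABET_P3: tuple[str, ...] = tuple("REFLP")

_TERMINALS = ("N", "C")
_CENTERS = ("s", "t", "x")


@dataclass(frozen=True, order=True)
class PeptideMotif:
    """One terminal's three variable residues around the fixed pS/pT center.

    ``residues`` are always stored N-to-C: (P-3, P-2, P-1) for an N-terminal
    motif, (P+1, P+2, P+3) for a C-terminal one.  The center (pS vs pT) is
    metadata only and never enters features.
    """

    terminal: str
    residues: tuple[str, str, str]
    center: str = "x"

    def __post_init__(self) -> None:
        if self.terminal not in _TERMINALS:
            raise ValueError(f"terminal must be 'N' or 'C', got {self.terminal!r}")
        if len(self.residues) != 3:
            raise ValueError("a motif has exactly three variable residues")
        for aa in self.residues:
            validate_aa(aa)
        if self.center not in _CENTERS:
            raise ValueError(f"center must be 's', 't' or 'x', got {self.center!r}")

    def encode(self) -> str:
        """7-character token, e.g. ``RAFsXXX`` or ``XXXsFGP``."""
        triple = "".join(self.residues)
        if self.terminal == "N":
            return f"{triple}{self.center}XXX"
        return f"XXX{self.center}{triple}"

    @classmethod
    def decode(cls, token: str) -> "PeptideMotif":
        """Parse the 7-character token form."""
        if len(token) != 7:
            raise ValueError(f"motif token must have 7 characters, got {token!r}")
        center = token[3]
        if center not in _CENTERS:
            raise ValueError(f"center character must be s/t/x, got {center!r} in {token!r}")
        left, right = token[:3], token[4:]
        if right == "XXX" and left != "XXX":
            return cls(terminal="N", residues=tuple(left), center=center)
        if left == "XXX" and right != "XXX":
            return cls(terminal="C", residues=tuple(right), center=center)
        raise ValueError(
            f"exactly one terminal must carry residues and the other be XXX: {token!r}"
        )

    def position_labels(self) -> tuple[str, str, str]:
        return ("P-3", "P-2", "P-1") if self.terminal == "N" else ("P+1", "P+2", "P+3")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.encode()


@dataclass(frozen=True)
class SublibrarySpec:
    """Per-position alphabets of one terminal's factorial sublibrary."""

    terminal: str
    alphabet_p12: tuple[str, ...] = PAPER_ALPHABET_P12
    alphabet_p3: tuple[str, ...] = PAPER_ALPHABET_P3

    def __post_init__(self) -> None:
        if self.terminal not in _TERMINALS:
            raise ValueError(f"terminal must be 'N' or 'C', got {self.terminal!r}")
        if not self.alphabet_p12 or not self.alphabet_p3:
            raise ValueError("sublibrary alphabets must be non-empty")
        for aa in (*self.alphabet_p12, *self.alphabet_p3):
            validate_aa(aa)
        if len(set(self.alphabet_p12)) != len(self.alphabet_p12) or len(
            set(self.alphabet_p3)
        ) != len(self.alphabet_p3):
            raise ValueError("sublibrary alphabets must not contain duplicates")

    @classmethod
    def paper(cls, terminal: str) -> "SublibrarySpec":
        """The experimental building-block library (500 motifs)."""
        return cls(terminal=terminal)

    @classmethod
    def full(cls, terminal: str) -> "SublibrarySpec":
        """All 20 amino acids at every position (8,000 motifs per terminal)."""
        return cls(terminal=terminal, alphabet_p12=CANONICAL_AA, alphabet_p3=CANONICAL_AA)

    def size(self) -> int:
        return len(self.alphabet_p3) * len(self.alphabet_p12) ** 2


@dataclass(frozen=True)
class AffinityRecord:
    """A motif with its measured or simulated affinity (arbitrary intensity units).

    ``affinity`` may be None for prediction inputs.
    """

    motif: PeptideMotif
    affinity: float | None

    def __post_init__(self) -> None:
        if self.affinity is not None:
            a = float(self.affinity)
            if not (math.isfinite(a) and a >= 0):
                raise ValueError(f"affinity must be finite and >= 0, got {self.affinity!r}")
            object.__setattr__(self, "affinity", a)


def enumerate_sublibrary(spec: SublibrarySpec, center: str = "s") -> list[PeptideMotif]:
    """Full Cartesian product of the sublibrary, in deterministic order.

    Alphabets are sorted; the outermost position (P-3 for N, P+3 for C) varies
    slowest, so the listing is lexicographic in outer-to-inner residue order.
    """
    p3 = sorted(spec.alphabet_p3)
    p12 = sorted(spec.alphabet_p12)
    motifs: list[PeptideMotif] = []
    for outer, mid, inner in itertools.product(p3, p12, p12):
        if spec.terminal == "N":
            residues = (outer, mid, inner)  # (P-3, P-2, P-1)
        else:
            residues = (inner, mid, outer)  # (P+1, P+2, P+3)
        motifs.append(PeptideMotif(terminal=spec.terminal, residues=residues, center=center))
    return motifs


# --- affinity-table I/O -----------------------------------------------------

_TSV_HEADER = ["motif_id", "terminal", "sequence", "affinity"]


def write_affinity_table(records: list[AffinityRecord], path: str | Path) -> None:
    """Write records as TSV (columns motif_id, terminal, sequence, affinity).

    Affinities are written with full ``repr`` precision so a write/read
    round-trip is exact; missing affinities become empty fields.
    """
    path = Path(path)
    lines = ["\t".join(_TSV_HEADER)]
    for i, rec in enumerate(records, start=1):
        aff = "" if rec.affinity is None else repr(rec.affinity)
        lines.append(f"{i}\t{rec.motif.terminal}\t{rec.motif.encode()}\t{aff}")
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text("\n".join(lines) + "\n")
    tmp.replace(path)


def read_affinity_table(path: str | Path) -> list[AffinityRecord]:
    """Read an affinity TSV, reporting the 1-based line number of any bad row."""
    path = Path(path)
    records: list[AffinityRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_HEADER:
            raise ValueError(f"{path}: line 1: expected header {_TSV_HEADER}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 fields, got {len(parts)}")
            _, terminal, sequence, aff_text = parts
            try:
                motif = PeptideMotif.decode(sequence)
                if motif.terminal != terminal:
                    raise ValueError(
                        f"terminal tag {terminal!r} disagrees with sequence {sequence!r}"
                    )
                affinity = None if aff_text == "" else float(aff_text)
                records.append(AffinityRecord(motif=motif, affinity=affinity))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return records
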