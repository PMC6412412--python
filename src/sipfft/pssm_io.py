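"""Reading and constructing position-specific scoring matrices.

A PSSM is the N x 20 log-odds profile PSI-BLAST emits for a query of
length N: entry (alpha, beta) scores finding amino acid beta at sequence
position alpha. This module parses the ASCII dialect produced by
``psiblast -out_ascii_pssm``, writes it back (round-trip safe), and
builds a substitution-matrix fallback profile for sequences that have no
PSI-BLAST profile: with a single query sequence the per-position residue
frequencies collapse to an indicator, so row alpha of the fallback PSSM
is simply the Dayhoff mutation-matrix row of the residue at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

#: Canonical internal amino-acid column order (alphabetical one-letter codes).
CANONICAL_ORDER = "ACDEFGHIKLMNPQRSTVWY"


class PssmParseError(ValueError):
    """Raised when a PSSM file does not follow the PSI-BLAST ASCII layout."""


@dataclass
class SubstitutionMatrix:
    """A 20 x 20 amino-acid substitution score matrix."""

    name: str
    scores: np.ndarray
    residue_order: str = CANONICAL_ORDER

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (20, 20):
            raise ValueError(f"substitution matrix must be 20x20, got {self.scores.shape}")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("substitution matrix contains non-finite entries")
        if sorted(self.residue_order) != sorted(CANONICAL_ORDER):
            raise ValueError("residue_order must be a permutation of the 20 standard amino acids")

    def row(self, residue: str) -> np.ndarray:
        return self.scores[self.residue_order.index(residue)]


@dataclass
class PssmProfile:
    """One protein's N x 20 position-specific scoring matrix.

    Rows follow sequence positions 1..N; columns follow ``residue_order``.
    ``source`` records whether the profile came from a PSI-BLAST file or
    from the substitution-matrix fallback.
    """

    protein_id: str
    matrix: np.ndarray
    sequence: str
    residue_order: str = CANONICAL_ORDER
    source: str = "psiblast_ascii"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError(f"PSSM must have 20 columns, got shape {self.matrix.shape}")
        if self.matrix.shape[0] < 1:
            raise ValueError("PSSM must have at least one row")
        if self.matrix.shape[0] != len(self.sequence):
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} rows but sequence length is {len(self.sequence)}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("PSSM contains non-finite entries")
        if sorted(self.residue_order) != sorted(CANONICAL_ORDER):
            raise ValueError("residue_order must be a permutation of the 20 standard amino acids")
        if self.source not in ("psiblast_ascii", "dayhoff_fallback"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def reordered(self, order: str = CANONICAL_ORDER) -> "PssmProfile":
        """Return a copy with columns permuted into ``order``."""
        idx = [self.residue_order.index(a) for a in order]
        return PssmProfile(
            protein_id=self.protein_id,
            matrix=self.matrix[:, idx],
            sequence=self.sequence,
            residue_order=order,
            source=self.source,
        )


def load_dayhoff_matrix() -> SubstitutionMatrix:
    """The Dayhoff amino-acid mutation matrix, in canonical column order."""
    m = substitution_matrices.load("DAYHOFF")
    order = str(m.alphabet)
    idx = [order.index(a) for a in CANONICAL_ORDER]
    scores = np.asarray(m, dtype=float)[np.ix_(idx, idx)]
    return SubstitutionMatrix(name="DAYHOFF", scores=scores, residue_order=CANONICAL_ORDER)


def _is_header_line(tokens: list[str]) -> bool:
    return (
        len(tokens) in (20, 40)
        and all(len(t) == 1 and t.isalpha() for t in tokens)
        and sorted(set(tokens[:20])) == sorted(CANONICAL_ORDER)
    )


def parse_psiblast_pssm(path: str | Path, protein_id: str | None = None) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM file into a :class:`PssmProfile`.

    The file layout: a header line listing the 20-residue column order
    (often repeated twice, once for the log-odds block and once for the
    percentage block), then one row per position holding the position
    index, the query residue, 20 log-odds integers and 20 weighted
    percentages. The log-odds block is kept; percentages (and, when
    present, the two trailing information-content columns) are ignored.
    Columns are reordered to the canonical alphabetical order on ingest.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_idx = None
    residue_order = None
    for i, line in enumerate(lines):
        tokens = line.split()
        if _is_header_line(tokens):
            header_idx = i
            residue_order = "".join(tokens[:20])
            break
    if header_idx is None:
        raise PssmParseError(f"{path}: no PSSM header line with 20 residue letters found")

    rows: list[list[float]] = []
    residues: list[str] = []
    for line in lines[header_idx + 1 :]:
        tokens = line.split()
        if not tokens:
            continue
        if not tokens[0].lstrip("-").isdigit():
            break  # footer (Lambda/K statistics) ends the matrix block
        if len(tokens) < 2 or len(tokens[1]) != 1 or not tokens[1].isalpha():
            raise PssmParseError(f"{path}: malformed data row: {line!r}")
        pos = int(tokens[0])
        numeric = tokens[2:]
        if len(numeric) not in (40, 42):
            raise PssmParseError(
                f"{path}: position {pos}: expected 40 numeric fields "
                f"(20 log-odds + 20 percentages), got {len(numeric)}"
            )
        try:
            values = [float(v) for v in numeric[:20]]
        except ValueError as exc:
            raise PssmParseError(f"{path}: position {pos}: non-numeric field") from exc
        rows.append(values)
        residues.append(tokens[1].upper())

    if not rows:
        raise PssmParseError(f"{path}: PSSM contains no data rows")

    profile = PssmProfile(
        protein_id=protein_id or path.stem,
        matrix=np.array(rows, dtype=float),
        sequence="".join(residues),
        residue_order=residue_order,
        source="psiblast_ascii",
    )
    return profile.reordered(CANONICAL_ORDER)


def write_psiblast_pssm(profile: PssmProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect accepted by the parser.

    Numeric entries are written with shortest round-trip float formatting
    so write -> parse is exactly the identity on (matrix, sequence,
    residue_order); the 20 percentage columns are written as zeros.
    """
    path = Path(path)
    header = " ".join(profile.residue_order)
    out = [
        "",
        "Last position-specific scoring matrix computed",
        f"    {header}  {header}",
    ]
    for alpha in range(profile.length):
        vals = " ".join(repr(float(v)) for v in profile.matrix[alpha])
        pct = " ".join("0" for _ in range(20))
        out.append(f"{alpha + 1} {profile.sequence[alpha]} {vals} {pct}")
    out.append("")
    path.write_text("\n".join(out))


def dayhoff_pssm(
    sequence: str,
    subst: SubstitutionMatrix | None = None,
    protein_id: str = "",
) -> PssmProfile:
    """Construct a fallback PSSM for a bare sequence.

    With a single sequence the per-position amino-acid frequency is an
    indicator of the observed residue, so position alpha's profile row
    is the substitution-matrix row of that residue. Residue 'X'
    (unknown) yields a zero row; any other non-standard character is an
    error.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if subst is None:
        subst = load_dayhoff_matrix()
    order = subst.residue_order
    matrix = np.zeros((len(sequence), 20), dtype=float)
    for alpha, aa in enumerate(sequence.upper()):
        if aa == "X":
            continue
        if aa not in order:
            raise ValueError(f"unknown residue {aa!r} at position {alpha + 1}")
        matrix[alpha] = subst.scores[order.index(aa)]
    profile = PssmProfile(
        protein_id=protein_id or sequence[:8],
        matrix=matrix,
        sequence=sequence.upper(),
        residue_order=order,
        source="dayhoff_fallback",
    )
    return profile.reordered(CANONICAL_ORDER)
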