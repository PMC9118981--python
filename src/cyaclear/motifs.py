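"""Motif-based mining of cyanuric acid hydrolase (CAH) candidates.

CAHs carry a highly conserved glycine-rich stretch in the C-terminal
metal-binding region, written here in PROSITE-like dash notation, e.g.
``S-G-G-X-E-X-Q-G-P-X-G-G-G-P`` where ``X`` matches any standard residue.
Candidates are classified by combining a motif scan with a check of two
anchor arginines that distinguish CAHs from the closely related
barbiturases: a sequence is a CAH candidate only if the motif sits near the
C-terminus *and* both anchors are conserved after global alignment to a
reference CAH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .align import AnchorSpec, check_anchors

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Diagnostic CAH motif (C-terminal metal-binding region).
CAH_MOTIF = "S-G-G-X-E-X-Q-G-P-X-G-G-G-P"

#: Default fraction of the sequence the motif start must lie beyond to count
#: as "near the C-terminus" (final quarter of the chain).
DEFAULT_C_TERM_THRESHOLD = 0.75


class SequenceError(ValueError):
    """Raised for sequences containing gaps, stops or non-standard residues."""


class PatternError(ValueError):
    """Raised for malformed motif pattern strings."""


@dataclass(frozen=True)
class ProteinRecord:
    """A sanitized protein sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"{self.id}: empty sequence")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise SequenceError(
                f"{self.id}: non-standard residues {sorted(bad)} "
                "(gaps/stops/ambiguity codes are rejected; sanitize first)"
            )

    def __len__(self) -> int:
        return len(self.residues)


def sanitize_residues(raw: str, *, seq_id: str = "?", lenient: bool = False) -> str:
    """Upper-case and validate a residue string.

    Gap characters (``-``, ``.``) and stops (``*``) always raise.  Ambiguity
    codes (B/Z/J/U/O/X...) raise in strict mode; with ``lenient=True`` the
    offending residues are dropped instead.
    """
    s = raw.strip().upper()
    if any(c in s for c in "-.*"):
        raise SequenceError(f"{seq_id}: sequence contains gap or stop characters")
    bad = set(s) - _AA_SET
    if bad:
        if not lenient:
            raise SequenceError(f"{seq_id}: non-standard residues {sorted(bad)}")
        s = "".join(c for c in s if c in _AA_SET)
    if not s:
        raise SequenceError(f"{seq_id}: empty sequence after sanitization")
    return s


@dataclass(frozen=True)
class MotifPattern:
    """Ordered positional pattern; each position is a set of allowed residues.

    Wildcard positions allow all 20 standard residues.
    """

    positions: tuple[frozenset[str], ...]
    wildcard: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise PatternError("pattern must have at least one position")
        for i, allowed in enumerate(self.positions):
            if not allowed <= _AA_SET:
                raise PatternError(f"position {i + 1}: invalid residues {sorted(allowed - _AA_SET)}")

    def __len__(self) -> int:
        return len(self.positions)


def parse_pattern(text: str) -> MotifPattern:
    """Parse a dash-separated motif such as ``"S-G-G-X-E-..."``.

    Tokens are single standard residues or ``X`` (wildcard).  Anything else
    raises :class:`PatternError` naming the offending token.
    """
    tokens = text.strip().split("-")
    positions: list[frozenset[str]] = []
    wildcard: list[bool] = []
    for tok in tokens:
        if tok == "X":
            positions.append(_AA_SET)
            wildcard.append(True)
        elif len(tok) == 1 and tok in _AA_SET:
            positions.append(frozenset(tok))
            wildcard.append(False)
        else:
            raise PatternError(f"invalid pattern token {tok!r} in {text!r}")
    return MotifPattern(tuple(positions), tuple(wildcard))


def format_pattern(pattern: MotifPattern) -> str:
    """Inverse of :func:`parse_pattern` for single-residue/wildcard patterns."""
    out = []
    for allowed, wild in zip(pattern.positions, pattern.wildcard):
        if wild:
            out.append("X")
        elif len(allowed) == 1:
            out.append(next(iter(allowed)))
        else:  # pragma: no cover - not producible via parse_pattern
            out.append("[" + "".join(sorted(allowed)) + "]")
    return "-".join(out)


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 1-based residue index
    matched: str
    relative_position: float  # start / len(sequence), in (0, 1]


def scan(record: ProteinRecord, pattern: MotifPattern) -> list[MotifHit]:
    """Report every window of ``record`` matching ``pattern``.

    Hits are returned in ascending start order (1-based, inclusive);
    overlapping hits are all reported.
    """
    seq = record.residues
    n, m = len(seq), len(pattern)
    hits: list[MotifHit] = []
    for start0 in range(n - m + 1):
        for j, allowed in enumerate(pattern.positions):
            if seq[start0 + j] not in allowed:
                break
        else:
            hits.append(
                MotifHit(
                    seq_id=record.id,
                    start=start0 + 1,
                    matched=seq[start0 : start0 + m],
                    relative_position=(start0 + 1) / n,
                )
            )
    return hits


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-column residue frequencies plus information content in bits."""

    alphabet: str
    frequencies: tuple[dict[str, float], ...]
    information_bits: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.frequencies)


def pfm_from_alignment(aligned: list[str]) -> PositionFrequencyMatrix:
    """Column-wise residue frequencies of an equal-length alignment.

    Gap characters (``-`` or ``.``) are excluded from column counts.  The
    information content of a column is ``log2(20) - H`` where ``H`` is the
    Shannon entropy of the column's residue distribution.
    """
    if len(aligned) < 2:
        raise ValueError("alignment needs at least two sequences")
    width = len(aligned[0])
    seqs = [s.upper() for s in aligned]
    for s in seqs:
        if len(s) != width:
            raise ValueError("aligned sequences must all have the same length")
    freqs: list[dict[str, float]] = []
    info: list[float] = []
    max_bits = math.log2(len(AMINO_ACIDS))
    for col in range(width):
        counts: dict[str, int] = {}
        for s in seqs:
            c = s[col]
            if c in ("-", "."):
                continue
            if c not in _AA_SET:
                raise SequenceError(f"column {col + 1}: non-standard residue {c!r}")
            counts[c] = counts.get(c, 0) + 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"column {col + 1} contains only gaps")
        f = {aa: n / total for aa, n in counts.items()}
        h = -sum(p * math.log2(p) for p in f.values() if p > 0)
        freqs.append(f)
        info.append(max_bits - h)
    return PositionFrequencyMatrix(AMINO_ACIDS, tuple(freqs), tuple(info))


@dataclass
class CandidateReport:
    seq_id: str
    hits: list[MotifHit]
    anchors_ok: dict[int, bool] = field(default_factory=dict)
    verdict: str = "negative"  # CAH-candidate | barbiturase-like | negative


def classify(
    record: ProteinRecord,
    pattern: MotifPattern,
    anchors: AnchorSpec,
    *,
    c_term_threshold: float = DEFAULT_C_TERM_THRESHOLD,
) -> CandidateReport:
    """Classify a sequence as CAH candidate, barbiturase-like, or negative.

    CAH-candidate: at least one motif hit starting in the C-terminal portion
    (relative position >= ``c_term_threshold``) and every anchor residue
    conserved after global alignment to the reference.  Barbiturase-like:
    motif present but at least one anchor fails.  Negative: no qualifying
    motif hit (anchors are not evaluated in that case).
    """
    hits = scan(record, pattern)
    c_term_hits = [h for h in hits if h.relative_position >= c_term_threshold]
    report = CandidateReport(seq_id=record.id, hits=hits)
    if not c_term_hits:
        return report
    report.anchors_ok = check_anchors(record.residues, anchors)
    if all(report.anchors_ok.values()):
        report.verdict = "CAH-candidate"
    else:
        report.verdict = "barbiturase-like"
    return report
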