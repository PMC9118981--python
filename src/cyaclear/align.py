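"""Global protein alignment for anchor-residue conservation checks.

CAHs are distinguished from barbiturases by two conserved arginines (R194
and R324 in the reference numbering).  To decide whether a candidate
conserves them, the candidate is globally aligned to the reference and the
candidate residue landing in each anchor column is compared to the required
residue.

The aligner is a Gotoh affine-gap Needleman-Wunsch with BLOSUM62 scores
(loaded from Biopython's substitution-matrix data), gap open 11 and gap
extend 1 (a gap of length L costs ``11 + (L-1)``).  Traceback ties are
broken deterministically: diagonal, then up (gap in the second sequence),
then left — so identical inputs always give identical alignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

NEG_INF = float(-1e30)

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

#: Default anchor positions (1-based, reference numbering): the two
#: arginines whose loss marks a barbiturase-like sequence.
DEFAULT_ANCHORS = {194: "R", 324: "R"}


@lru_cache(maxsize=1)
def _blosum62() -> tuple[dict[str, int], np.ndarray]:
    mat = substitution_matrices.load("BLOSUM62")
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    idx = {aa: i for i, aa in enumerate(alphabet)}
    sub = np.zeros((20, 20))
    for a in alphabet:
        for b in alphabet:
            sub[idx[a], idx[b]] = mat[a, b]
    return idx, sub


@dataclass(frozen=True)
class Alignment:
    """A global alignment of ``seq_a`` against ``seq_b``.

    ``pairs`` lists (a_pos, b_pos) per alignment column with 1-based residue
    indices, ``None`` marking a gap in that sequence.
    """

    seq_a: str
    seq_b: str
    score: float
    pairs: tuple[tuple[int | None, int | None], ...]

    @property
    def aligned_strings(self) -> tuple[str, str]:
        top = "".join(self.seq_a[i - 1] if i else "-" for i, _ in self.pairs)
        bot = "".join(self.seq_b[j - 1] if j else "-" for _, j in self.pairs)
        return top, bot


def global_align(
    seq_a: str,
    seq_b: str,
    *,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Optimal global alignment of two residue strings (Gotoh, affine gaps)."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    idx, sub = _blosum62()
    try:
        xa = np.array([idx[c] for c in seq_a])
        xb = np.array([idx[c] for c in seq_b])
    except KeyError as exc:  # pragma: no cover - callers sanitize first
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from exc
    n, m = len(seq_a), len(seq_b)

    # State matrices: M diagonal, IX gap in seq_b (up), IY gap in seq_a (left).
    M = np.full((n + 1, m + 1), NEG_INF)
    IX = np.full((n + 1, m + 1), NEG_INF)
    IY = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        IX[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        IY[0, j] = -gap_open - (j - 1) * gap_extend

    for i in range(1, n + 1):
        srow = sub[xa[i - 1], xb]  # substitution scores vs all of seq_b
        m_prev, ix_prev, iy_prev = M[i - 1], IX[i - 1], IY[i - 1]
        best_prev = np.maximum(np.maximum(m_prev, ix_prev), iy_prev)
        M[i, 1:] = srow + best_prev[:-1]
        IX[i, 1:] = np.maximum(
            np.maximum(m_prev[1:] - gap_open, ix_prev[1:] - gap_extend),
            iy_prev[1:] - gap_open,
        )
        # IY has an in-row dependence; plain loop.
        m_row, ix_row, iy_row = M[i], IX[i], IY[i]
        for j in range(1, m + 1):
            iy_row[j] = max(
                m_row[j - 1] - gap_open,
                iy_row[j - 1] - gap_extend,
                ix_row[j - 1] - gap_open,
            )

    # Traceback; tie-break preference: M (diagonal) > IX (up) > IY (left).
    def pick(candidates: list[tuple[float, str]]) -> str:
        best_score = max(c[0] for c in candidates)
        for score, state in candidates:
            if score >= best_score - 1e-9:
                return state
        raise AssertionError  # pragma: no cover

    i, j = n, m
    state = pick([(M[i, j], "M"), (IX[i, j], "IX"), (IY[i, j], "IY")])
    final_score = {"M": M[i, j], "IX": IX[i, j], "IY": IY[i, j]}[state]
    pairs: list[tuple[int | None, int | None]] = []
    while i > 0 or j > 0:
        if state == "M":
            pairs.append((i, j))
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = pick([(M[i, j], "M"), (IX[i, j], "IX"), (IY[i, j], "IY")])
        elif state == "IX":
            pairs.append((i, None))
            state = pick(
                [
                    (M[i - 1, j] - gap_open, "M"),
                    (IX[i - 1, j] - gap_extend, "IX"),
                    (IY[i - 1, j] - gap_open, "IY"),
                ]
            )
            i -= 1
        else:  # IY
            pairs.append((None, j))
            state = pick(
                [
                    (M[i, j - 1] - gap_open, "M"),
                    (IX[i, j - 1] - gap_open, "IX"),
                    (IY[i, j - 1] - gap_extend, "IY"),
                ]
            )
            j -= 1
    pairs.reverse()
    return Alignment(seq_a=seq_a, seq_b=seq_b, score=float(final_score), pairs=tuple(pairs))


@dataclass(frozen=True)
class AnchorSpec:
    """Reference sequence plus required residues at 1-based reference positions."""

    reference_id: str
    reference_sequence: str
    anchors: tuple[tuple[int, str], ...] = tuple(sorted(DEFAULT_ANCHORS.items()))

    def __post_init__(self) -> None:
        for pos, aa in self.anchors:
            if not 1 <= pos <= len(self.reference_sequence):
                raise ValueError(
                    f"anchor position {pos} beyond reference length {len(self.reference_sequence)}"
                )
            if len(aa) != 1 or not aa.isalpha():
                raise ValueError(f"invalid anchor residue {aa!r}")


def check_anchors(candidate: str, spec: AnchorSpec) -> dict[int, bool]:
    """Per-anchor conservation flags for ``candidate`` against the reference.

    The candidate is globally aligned to the reference; anchor ``pos`` is
    conserved iff the candidate residue aligned to reference position ``pos``
    equals the required residue (a gap in the candidate fails the anchor).
    """
    aln = global_align(spec.reference_sequence, candidate)
    ref_to_cand: dict[int, int | None] = {}
    for a_pos, b_pos in aln.pairs:
        if a_pos is not None:
            ref_to_cand[a_pos] = b_pos
    flags: dict[int, bool] = {}
    for pos, required in spec.anchors:
        cand_pos = ref_to_cand.get(pos)
        flags[pos] = cand_pos is not None and candidate[cand_pos - 1] == required
    return flags
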