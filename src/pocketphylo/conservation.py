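"""Per-column conservation scoring and 1–9 grade binning for a master MSA.

The scorer is a weighted-entropy functional analogue of tree-aware rate
estimators: rows get Henikoff–Henikoff position-based weights (so dense
clusters of near-identical sequences do not dominate), each column gets

    score = (1 - H_w / ln 20) * (1 - gap_fraction)

where ``H_w`` is the weighted Shannon entropy of the amino-acid frequencies
in the column. Scores are then rank-binned into nine equal-frequency grades,
grade 9 = most conserved (maroon in the usual colouring), grade 1 = most
variable (turquoise). Equal-frequency binning fixes the whole-alignment
background of grades 7–9 at ~1/3 of scored columns by construction.

Columns whose gap fraction exceeds ``max_gap_fraction`` (default 0.5) are
left unscored (grade None) and excluded from all fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import AMINO_ACIDS, GAP, Msa

LN20 = math.log(20.0)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class ConservationProfile:
    """Per-column conservation of an alignment (1-based columns)."""

    scores: list[float | None]       # None = unscored (too gappy)
    grades: list[int | None]
    gap_fractions: list[float]

    @property
    def n_columns(self) -> int:
        return len(self.scores)

    def scored_columns(self) -> list[int]:
        return [i + 1 for i, s in enumerate(self.scores) if s is not None]

    def grade_of(self, column: int) -> int | None:
        return self.grades[column - 1]


def sequence_weights(msa: Msa) -> np.ndarray:
    """Henikoff–Henikoff position-based row weights, normalised to sum 1.

    At each column a row receives ``1 / (r * s)`` where ``r`` is the number
    of distinct symbols in the column and ``s`` the count of the row's own
    symbol; gaps count as a 21st symbol type.
    """
    n = msa.n_rows
    if n == 1:
        return np.ones(1)
    raw = np.zeros(n)
    cols = np.array([list(r) for r in msa.rows], dtype="U1").T
    for col in cols:
        symbols, counts = np.unique(col, return_counts=True)
        r = len(symbols)
        count_of = dict(zip(symbols.tolist(), counts.tolist()))
        for i, ch in enumerate(col):
            raw[i] += 1.0 / (r * count_of[ch])
    total = raw.sum()
    if total == 0:
        return np.full(n, 1.0 / n)
    return raw / total


def column_score(
    msa: Msa, column: int, weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """(score, gap_fraction) for a 1-based column.

    The gap fraction is weighted; amino-acid frequencies are weighted
    frequencies among the non-gap rows.
    """
    if weights is None:
        weights = np.full(msa.n_rows, 1.0 / msa.n_rows)
    chars = [row[column - 1] for row in msa.rows]
    w = np.asarray(weights, dtype=float)
    gap_w = sum(wi for wi, ch in zip(w, chars) if ch == GAP or ch == "X")
    total_w = w.sum()
    gap_fraction = gap_w / total_w if total_w else 1.0
    freqs = np.zeros(20)
    for wi, ch in zip(w, chars):
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            freqs[idx] += wi
    s = freqs.sum()
    if s <= 0:
        return 0.0, gap_fraction
    freqs /= s
    nz = freqs[freqs > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return (1.0 - entropy / LN20) * (1.0 - gap_fraction), gap_fraction


def assign_grades(scores: list[float | None]) -> list[int | None]:
    """Equal-frequency binning of scored columns into grades 1..9.

    Columns are ranked by score; rank ``r`` (1-based, ascending) maps to
    grade ``floor((r-1)*9/n) + 1``. Tied scores all receive the grade of the
    lowest rank in the tie (ties share the lower grade).
    """
    scored = [(s, i) for i, s in enumerate(scores) if s is not None]
    n = len(scored)
    grades: list[int | None] = [None] * len(scores)
    if n == 0:
        return grades
    scored.sort(key=lambda t: (t[0], t[1]))
    # min rank per distinct score value
    min_rank: dict[float, int] = {}
    for rank, (s, _) in enumerate(scored, start=1):
        min_rank.setdefault(s, rank)
    for rank, (s, idx) in enumerate(scored, start=1):
        r = min_rank[s]
        grades[idx] = (r - 1) * 9 // n + 1
    return grades


def conservation_profile(
    msa: Msa,
    weights: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> ConservationProfile:
    """Score and grade every column of the alignment."""
    if weights is None:
        weights = sequence_weights(msa)
    scores: list[float | None] = []
    gap_fractions: list[float] = []
    for col in range(1, msa.n_columns + 1):
        score, gap_frac = column_score(msa, col, weights)
        gap_fractions.append(gap_frac)
        scores.append(None if gap_frac > max_gap_fraction else score)
    return ConservationProfile(
        scores=scores,
        grades=assign_grades(scores),
        gap_fractions=gap_fractions,
    )


def conserved_fraction(
    grades: list[int | None],
    site_subset: set[int] | None = None,
    threshold: int = 7,
) -> tuple[float, int, int]:
    """(fraction, n_conserved, n_scored) of sites at grade >= threshold.

    ``site_subset`` is a set of 1-based columns; None means all columns.
    Unscored columns are excluded from both numerator and denominator.
    """
    if site_subset is None:
        picked = [g for g in grades if g is not None]
    else:
        picked = [
            grades[c - 1] for c in site_subset
            if 1 <= c <= len(grades) and grades[c - 1] is not None
        ]
    n_scored = len(picked)
    n_cons = sum(1 for g in picked if g >= threshold)
    fraction = n_cons / n_scored if n_scored else math.nan
    return fraction, n_cons, n_scored
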