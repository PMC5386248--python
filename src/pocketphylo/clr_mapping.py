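"""Cavity-lining-residue (CLR) consensus calling and cross-group mapping.

The CLR procedure works at two levels, both majority-vote based:

* per protein: a residue position is a consensus CLR site when it lines the
  catalytic pocket in at least 2 of the protein's 3 structure models;
* per group: a master-MSA column is a group CLR when the consensus sites of
  at least 2 of the group's 3 member proteins project onto it.

Sites are 1-based sequence positions; group-level sites are 1-based master
alignment columns, so CLR sets are comparable across groups. The per-protein
cavity volume is the arithmetic mean over the three models.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import LowIdentityError, PocketPhyloError
from .io_formats import Msa, StructureModel
from .phylogeny import _char_score, _nw_align


@dataclass
class ClrProfile:
    """Per-protein consensus CLR sites plus pocket geometry summaries."""

    protein_id: str
    consensus_sites: set[int]
    per_model_sites: list[set[int]]
    volumes: list[float]
    depths: list[float]

    def __post_init__(self):
        union: set[int] = set().union(*self.per_model_sites) \
            if self.per_model_sites else set()
        if not self.consensus_sites <= union:
            raise PocketPhyloError(
                "consensus sites must be a subset of the per-model union"
            )

    @property
    def mean_volume(self) -> float:
        return sum(self.volumes) / len(self.volumes)

    @property
    def mean_depth(self) -> float:
        return sum(self.depths) / len(self.depths)


@dataclass
class GroupClrProfile:
    """Group-level CLR columns (master MSA coordinates)."""

    group_label: str
    member_proteins: list[str]
    group_columns: set[int]
    regioselectivity: str = ""
    mean_volume: float = math.nan

    @property
    def n_clr(self) -> int:
        return len(self.group_columns)


def _required_count(n: int, min_count: int | None, allow_any_n: bool) -> int:
    if not allow_any_n and n != 3:
        raise PocketPhyloError(
            f"expected exactly 3 inputs, got {n}; pass allow_any_n=True to "
            "use the generalised ceil(2n/3) rule"
        )
    if min_count is not None:
        return min_count
    return math.ceil(2 * n / 3)


def map_structure_positions(
    model: StructureModel, sequence: str, min_identity: float = 0.9,
) -> dict[tuple[str, int], int]:
    """Map model residues (chain, residue_index) to 1-based sequence positions.

    The model's extracted one-letter sequence is globally aligned to
    ``sequence`` (match +1 / mismatch -1 / gap -2); only aligned matches and
    mismatches produce map entries. Fails when identity over aligned
    positions falls below ``min_identity`` — the model evidently does not
    correspond to the sequence (e.g. full-length vs domain numbering can
    still map, but an unrelated chain cannot).
    """
    residues = model.residues()
    model_seq = model.one_letter_sequence()
    ia, ib = _nw_align(model_seq, sequence.upper(), -2.0, -2.0, _char_score)
    matches = aligned = 0
    mapping: dict[tuple[str, int], int] = {}
    for x, y in zip(ia, ib):
        if x is None or y is None:
            continue
        aligned += 1
        if model_seq[x] == sequence[y].upper():
            matches += 1
        chain_id, residue_index, _ = residues[x]
        mapping[(chain_id, residue_index)] = y + 1
    identity = matches / aligned if aligned else 0.0
    if identity < min_identity:
        raise LowIdentityError(
            f"model {model.model_id!r} aligns to the sequence with identity "
            f"{identity:.2f} < {min_identity}"
        )
    return mapping


def consensus_sites(
    site_sets: Sequence[set[int]],
    min_count: int | None = None,
) -> set[int]:
    """Elements present in at least ``min_count`` of the given sets.

    ``min_count`` defaults to the "at least twice in three" rule
    (``ceil(2n/3)`` in general).
    """
    n = len(site_sets)
    required = min_count if min_count is not None else math.ceil(2 * n / 3)
    counts = Counter()
    for s in site_sets:
        counts.update(set(s))
    return {site for site, c in counts.items() if c >= required}


def group_clr(
    profiles: Sequence[ClrProfile],
    msa: Msa,
    group_label: str,
    min_count: int | None = None,
    allow_any_n: bool = False,
    regioselectivity: str = "",
) -> GroupClrProfile:
    """Project member proteins' consensus sites to master-MSA columns and
    keep columns supported by at least ``min_count`` (default 2-of-3) members.

    A site that falls on a gapped alignment position for its protein simply
    contributes nothing.
    """
    n = len(profiles)
    required = _required_count(n, min_count, allow_any_n)
    counts: Counter[int] = Counter()
    for prof in profiles:
        if prof.protein_id not in msa.sequence_ids:
            raise PocketPhyloError(
                f"protein {prof.protein_id!r} missing from the master MSA"
            )
        p2c = msa.pos_to_col[msa.row_index(prof.protein_id)]
        cols = {p2c[pos] for pos in prof.consensus_sites if pos in p2c}
        counts.update(cols)
    columns = {col for col, c in counts.items() if c >= required}
    mean_volume = (
        sum(p.mean_volume for p in profiles) / n if n else math.nan
    )
    return GroupClrProfile(
        group_label=group_label,
        member_proteins=[p.protein_id for p in profiles],
        group_columns=columns,
        regioselectivity=regioselectivity,
        mean_volume=mean_volume,
    )


def common_clr(group_profiles: Sequence[GroupClrProfile]) -> set[int]:
    """Columns present in every supplied group's CLR set."""
    if not group_profiles:
        return set()
    out = set(group_profiles[0].group_columns)
    for g in group_profiles[1:]:
        out &= g.group_columns
    return out


def group_specific_clr(
    group_profiles: Sequence[GroupClrProfile],
) -> dict[str, set[int]]:
    """For each group, the columns appearing in that group and no other."""
    out: dict[str, set[int]] = {}
    for g in group_profiles:
        others: set[int] = set()
        for h in group_profiles:
            if h.group_label != g.group_label:
                others |= h.group_columns
        out[g.group_label] = g.group_columns - others
    return out


def clr_summary(group_profiles: Sequence[GroupClrProfile]) -> pd.DataFrame:
    """Table-style summary: one row per group, stable group ordering."""
    rows = [
        {
            "group": g.group_label,
            "regioselectivity": g.regioselectivity,
            "member_proteins": ",".join(g.member_proteins),
            "n_clr": g.n_clr,
            "mean_volume": g.mean_volume,
        }
        for g in sorted(group_profiles, key=lambda g: g.group_label)
    ]
    return pd.DataFrame(
        rows,
        columns=["group", "regioselectivity", "member_proteins", "n_clr",
                 "mean_volume"],
    )


def occupancy_matrix(
    group_profiles: Sequence[GroupClrProfile],
) -> pd.DataFrame:
    """0/1 matrix of CLR columns (rows) x groups (columns)."""
    groups = sorted(g.group_label for g in group_profiles)
    by_label = {g.group_label: g for g in group_profiles}
    all_cols = sorted(set().union(*(g.group_columns for g in group_profiles))
                      ) if group_profiles else []
    data = {
        lab: [int(c in by_label[lab].group_columns) for c in all_cols]
        for lab in groups
    }
    return pd.DataFrame(data, index=pd.Index(all_cols, name="column"))
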