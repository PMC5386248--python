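"""Association statistics and the end-of-run report bundle.

The headline statistic is the Pearson correlation between a group's CLR
count and its mean cavity volume, with a two-sided p-value from the exact
t transform ``t = r * sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.
Because group counts are tiny, an optional permutation p-value is offered.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel
from scipy import stats

from .clr_mapping import ClrProfile, GroupClrProfile
from .errors import ZeroVarianceError


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    p_permutation: float | None = None


def pearson(
    x: Sequence[float],
    y: Sequence[float],
    permutation: bool = False,
    n_permutations: int = 10000,
    seed: int = 0,
) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs for a p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    p_perm = None
    if permutation:
        perm = stats.pearsonr(
            x, y, method=stats.PermutationMethod(
                n_resamples=n_permutations,
                rng=np.random.default_rng(seed),
            ),
        )
        p_perm = float(perm.pvalue)
    return CorrelationResult(
        r=float(res.statistic), p_value=float(res.pvalue), n=len(x),
        p_permutation=p_perm,
    )


def clr_volume_correlation(
    group_profiles: Sequence[GroupClrProfile],
    profiles_by_id: Mapping[str, ClrProfile] | None = None,
    **kwargs,
) -> CorrelationResult:
    """Correlate per-group CLR counts with per-group mean cavity volumes.

    x = n_clr per group; y = the group's mean over member proteins of the
    protein-level mean volume. Pairs are ordered by group label.
    """
    groups = sorted(group_profiles, key=lambda g: g.group_label)
    x, y = [], []
    for g in groups:
        x.append(g.n_clr)
        if profiles_by_id is not None:
            vols = [profiles_by_id[p].mean_volume for p in g.member_proteins]
            y.append(sum(vols) / len(vols))
        else:
            y.append(g.mean_volume)
    return pearson(x, y, **kwargs)


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

class GroupRow(BaseModel):
    group: str
    regioselectivity: str
    member_proteins: list[str]
    n_clr: int
    mean_volume: float


class FractionBlock(BaseModel):
    fraction: float
    n_conserved: int
    n_scored: int


class CorrelationBlock(BaseModel):
    r: float
    p_value: float
    n: int
    p_permutation: float | None = None


class RunMetadata(BaseModel):
    seed: int
    package_version: str
    config_hash: str
    timestamp: str


class Report(BaseModel):
    """Machine-readable end-of-run report (the schema of the JSON output)."""

    groups: list[GroupRow]
    common_clr_columns: list[int]
    specific_clr_columns: dict[str, list[int]]
    conserved_background: FractionBlock
    conserved_all_clr: FractionBlock
    conserved_common_clr: FractionBlock
    clr_volume_correlation: CorrelationBlock
    metadata: RunMetadata


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_report(
    group_profiles: Sequence[GroupClrProfile],
    common_columns: set[int],
    specific_columns: Mapping[str, set[int]],
    conserved_background: tuple[float, int, int],
    conserved_all_clr: tuple[float, int, int],
    conserved_common_clr: tuple[float, int, int],
    correlation: CorrelationResult,
    seed: int,
    config: Mapping,
    timestamp: str = "",
) -> Report:
    from . import __version__

    def _frac(t):
        return FractionBlock(fraction=t[0], n_conserved=t[1], n_scored=t[2])

    return Report(
        groups=[
            GroupRow(
                group=g.group_label,
                regioselectivity=g.regioselectivity,
                member_proteins=list(g.member_proteins),
                n_clr=g.n_clr,
                mean_volume=g.mean_volume,
            )
            for g in sorted(group_profiles, key=lambda g: g.group_label)
        ],
        common_clr_columns=sorted(common_columns),
        specific_clr_columns={
            k: sorted(v) for k, v in sorted(specific_columns.items())
        },
        conserved_background=_frac(conserved_background),
        conserved_all_clr=_frac(conserved_all_clr),
        conserved_common_clr=_frac(conserved_common_clr),
        clr_volume_correlation=CorrelationBlock(
            r=correlation.r, p_value=correlation.p_value, n=correlation.n,
            p_permutation=correlation.p_permutation,
        ),
        metadata=RunMetadata(
            seed=seed,
            package_version=__version__,
            config_hash=config_hash(config),
            timestamp=timestamp,
        ),
    )


def write_report(report: Report, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(report.model_dump_json(indent=2) + "\n")


def report_json_schema() -> dict:
    """The JSON schema of the report (shipped programmatically)."""
    return Report.model_json_schema()
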