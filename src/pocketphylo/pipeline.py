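"""End-to-end orchestration: config validation, staged execution, caching.

A run directory receives one sub-result per stage (alignment, tree, group
assignment, per-protein pocket profiles, conservation table, report). The
config is a single YAML document; all randomness flows from its ``seed``.
"""

from __future__ import annotations

import datetime
import json
import logging
import time
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from . import clr_mapping, conservation, io_formats, phylogeny, stats_report
from .errors import ConfigError, PocketPhyloError
from .pocket_geometry import (
    GridParams,
    detect_pockets,
    select_catalytic_pocket,
)

logger = logging.getLogger("pocketphylo")


class GridConfig(BaseModel):
    spacing: float = 0.6
    probe_small: float = 1.4
    probe_large: float = 4.0
    vdw_table: dict[str, float] | None = None
    min_volume: float = 25.0

    def to_params(self) -> GridParams:
        kwargs = self.model_dump()
        if kwargs["vdw_table"] is None:
            kwargs.pop("vdw_table")
        return GridParams(**kwargs)


class PhylogenyConfig(BaseModel):
    gap_policy: str = "pairwise_deletion"
    bootstrap_replicates: int = 0

    @field_validator("gap_policy")
    @classmethod
    def _check_policy(cls, v):
        if v not in phylogeny.GAP_POLICIES:
            raise ValueError(f"unknown gap policy {v!r}")
        return v


class ProteinEntry(BaseModel):
    models: list[str] = Field(min_length=3, max_length=3)
    anchors: list[str] = Field(default_factory=list)  # "CHAIN:RESI" strings

    def anchor_set(self) -> set[tuple[str, int]]:
        out = set()
        for item in self.anchors:
            chain, _, resi = item.partition(":")
            out.add((chain, int(resi)))
        return out


class ConservationConfig(BaseModel):
    max_gap_fraction: float = 0.5
    conserved_threshold: int = 7


class RunConfig(BaseModel):
    seed: int
    alignment: str | None = None
    sequences: str | None = None           # unaligned; progressive-aligned
    grid: GridConfig = GridConfig()
    phylogeny: PhylogenyConfig = PhylogenyConfig()
    conservation: ConservationConfig = ConservationConfig()
    group_seeds: dict[str, list[str]] = Field(default_factory=dict)
    groups: dict[str, dict[str, ProteinEntry]]
    min_count: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        try:
            return cls.model_validate(data)
        except Exception as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc

    def validate_paths(self, base: Path) -> None:
        missing = []
        for name in (self.alignment, self.sequences):
            if name is not None and not (base / name).exists():
                missing.append(str(base / name))
        for g, proteins in self.groups.items():
            for pid, entry in proteins.items():
                for m in entry.models:
                    if not (base / m).exists():
                        missing.append(str(base / m))
        if self.alignment is None and self.sequences is None:
            raise ConfigError("config needs 'alignment' or 'sequences'")
        if missing:
            raise ConfigError(f"missing input files: {missing}")


class StageTimer:
    def __init__(self):
        self.timings: dict[str, float] = {}

    def stage(self, name: str):
        timer = self

        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timer.timings[name] = time.perf_counter() - self.t0
                status = "failed" if exc_type else "done"
                logger.info("stage %s: %s (%.2fs)", name, status,
                            timer.timings[name])
                return False
        return _Ctx()


def run_pipeline(
    config: RunConfig,
    base_dir: str | Path,
    out_dir: str | Path,
    force: bool = False,
) -> stats_report.Report:
    """Execute every stage and write the report bundle into ``out_dir``."""
    base = Path(base_dir)
    out = Path(out_dir)
    config.validate_paths(base)
    report_path = out / "report.json"
    if report_path.exists() and not force:
        raise ConfigError(
            f"{report_path} exists; pass force=True (--force) to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)
    timer = StageTimer()
    grid = config.grid.to_params()

    with timer.stage("align"):
        if config.alignment is not None:
            msa = io_formats.read_alignment(base / config.alignment)
        else:
            records = io_formats.read_fasta(base / config.sequences)
            msa = phylogeny.progressive_align(records)
        io_formats.write_alignment(msa, out / "master_alignment.fasta")

    with timer.stage("tree"):
        dm = phylogeny.distance_matrix(msa, config.phylogeny.gap_policy)
        dm.to_tsv(out / "distances.tsv")
        if config.phylogeny.bootstrap_replicates > 0:
            tree = phylogeny.bootstrap_support(
                msa, config.phylogeny.bootstrap_replicates,
                seed=config.seed, gap_policy=config.phylogeny.gap_policy,
            )
        else:
            tree = phylogeny.neighbor_joining(dm)
        io_formats.write_newick(tree, out / "tree.nwk")
        if config.group_seeds:
            assignment = phylogeny.assign_groups(tree, config.group_seeds)
            with open(out / "group_assignment.tsv", "w") as fh:
                fh.write("leaf\tgroup\n")
                for leaf, g in sorted(assignment.items()):
                    fh.write(f"{leaf}\t{g}\n")

    with timer.stage("pockets"):
        profiles: dict[str, clr_mapping.ClrProfile] = {}
        for g, proteins in config.groups.items():
            for pid, entry in proteins.items():
                if pid not in msa.sequence_ids:
                    raise PocketPhyloError(
                        f"stage pockets: protein {pid!r} not in alignment"
                    )
                sequence = msa.ungapped(pid)
                anchor = entry.anchor_set() or None
                per_model_sites, volumes, depths = [], [], []
                for mpath in entry.models:
                    model = io_formats.read_pdb(
                        base / mpath, protein_id=pid)
                    pockets = detect_pockets(model, grid)
                    pocket = select_catalytic_pocket(pockets, anchor)
                    mapping = clr_mapping.map_structure_positions(
                        model, sequence)
                    sites = {
                        mapping[key] for key in pocket.lining_residues
                        if key in mapping
                    }
                    per_model_sites.append(sites)
                    volumes.append(pocket.volume)
                    depths.append(pocket.depth)
                profiles[pid] = clr_mapping.ClrProfile(
                    protein_id=pid,
                    consensus_sites=clr_mapping.consensus_sites(
                        per_model_sites, config.min_count),
                    per_model_sites=per_model_sites,
                    volumes=volumes,
                    depths=depths,
                )

    with timer.stage("clr"):
        group_profiles = []
        for g in sorted(config.groups):
            members = [profiles[pid] for pid in config.groups[g]]
            group_profiles.append(clr_mapping.group_clr(
                members, msa, group_label=g, min_count=config.min_count,
                allow_any_n=len(members) != 3,
            ))
        common = clr_mapping.common_clr(group_profiles)
        specific = clr_mapping.group_specific_clr(group_profiles)
        clr_mapping.clr_summary(group_profiles).to_csv(
            out / "group_summary.tsv", sep="\t", index=False)
        clr_mapping.occupancy_matrix(group_profiles).to_csv(
            out / "clr_occupancy.tsv", sep="\t")

    with timer.stage("conservation"):
        profile = conservation.conservation_profile(
            msa, max_gap_fraction=config.conservation.max_gap_fraction)
        with open(out / "conservation.tsv", "w") as fh:
            fh.write("column\tscore\tgrade\tgap_fraction\n")
            for i in range(profile.n_columns):
                s = profile.scores[i]
                fh.write(
                    f"{i + 1}\t{'' if s is None else f'{s:.6f}'}\t"
                    f"{'' if profile.grades[i] is None else profile.grades[i]}"
                    f"\t{profile.gap_fractions[i]:.4f}\n"
                )

    with timer.stage("stats"):
        thr = config.conservation.conserved_threshold
        all_clr = set().union(*(g.group_columns for g in group_profiles)) \
            if group_profiles else set()
        background = conservation.conserved_fraction(
            profile.grades, None, thr)
        frac_all = conservation.conserved_fraction(profile.grades, all_clr, thr)
        frac_common = conservation.conserved_fraction(
            profile.grades, common, thr)
        corr = stats_report.clr_volume_correlation(group_profiles, profiles)
        report = stats_report.build_report(
            group_profiles=group_profiles,
            common_columns=common,
            specific_columns=specific,
            conserved_background=background,
            conserved_all_clr=frac_all,
            conserved_common_clr=frac_common,
            correlation=corr,
            seed=config.seed,
            config=config.model_dump(),
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )
        stats_report.write_report(report, report_path)
        (out / "timings.json").write_text(json.dumps(timer.timings, indent=2))
    return report
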