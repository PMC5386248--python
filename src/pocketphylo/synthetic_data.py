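"""Ground-truth-labelled synthetic inputs for every pipeline stage.

Structures are shells of pseudo-atoms (one sphere per "atom", element C,
analysed with an inflated 2.5 Å van der Waals radius so that thin shells
are probe-tight at the default grid spacing). A cavity of analytic volume
and depth is carved and the wall atoms are assigned to designated "lining"
residue positions, so pocket detection and CLR calling can be checked
against planted truth. Sequence families are evolved on a known tree under
a 20-state Poisson (Jukes–Cantor-like) model with per-site rates; rate-0
sites are invariant, giving planted conserved columns.

``make_study`` combines both into a full multi-group study shaped like a
published PT-domain analysis: 7 groups x 3 proteins x 3 jittered structure
models, a planted set of 27 CLR columns common to all groups, 11 and 8
columns specific to the two large-cavity groups, per-group CLR counts of
31–45, and a monotone cavity-volume ladder across groups.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .errors import ConfigError
from .io_formats import (
    AMINO_ACIDS,
    ONE_TO_THREE,
    AtomRecord,
    Msa,
    StructureModel,
)
from .pocket_geometry import GridParams

#: inflated van der Waals radius of the pseudo-atoms (Å)
PSEUDO_VDW = 2.5


def synthetic_grid_params(spacing: float = 0.6, probe_small: float = 1.4,
                          probe_large: float = 4.0, **kwargs) -> GridParams:
    """Grid parameters matching the pseudo-atom radius of the generators."""
    return GridParams(
        spacing=spacing,
        probe_small=probe_small,
        probe_large=probe_large,
        vdw_table={"C": PSEUDO_VDW},
        **kwargs,
    )


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


@dataclass(frozen=True)
class CavitySpec:
    """Cavity geometry request: sphere / dimple (hemisphere) / channel."""

    kind: str                      # "sphere" | "dimple" | "channel"
    radius: float = 5.0            # cavity radius (sphere/dimple) or bore free radius
    length: float = 12.0           # channel only

    def __post_init__(self):
        if self.kind not in ("sphere", "dimple", "channel"):
            raise ConfigError(f"unknown cavity kind {self.kind!r}")

    @property
    def analytic_volume(self) -> float:
        if self.kind == "sphere":
            return 4.0 / 3.0 * math.pi * self.radius ** 3
        if self.kind == "dimple":
            return 2.0 / 3.0 * math.pi * self.radius ** 3
        return math.pi * self.radius ** 2 * self.length

    @property
    def analytic_depth(self) -> float:
        if self.kind == "channel":
            return self.length
        return self.radius


@dataclass
class CavityTruth:
    """Planted geometry facts for one synthetic structure."""

    volume: float
    depth: float
    lining_positions: set[int]
    enclosed: bool


def _lattice_disk(radius: float, z: float, spacing: float) -> np.ndarray:
    ax = np.arange(-radius, radius + spacing / 2, spacing)
    xx, yy = np.meshgrid(ax, ax)
    keep = xx ** 2 + yy ** 2 <= radius ** 2
    pts = np.stack([xx[keep], yy[keep], np.full(keep.sum(), z)], axis=1)
    return pts


def _lattice_square(half: float, z: float, spacing: float) -> np.ndarray:
    ax = np.arange(-half, half + spacing / 2, spacing)
    xx, yy = np.meshgrid(ax, ax)
    pts = np.stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)], axis=1)
    return pts


def _cavity_points(
    cavity: CavitySpec, probe_small: float, shell_thickness: float,
    wall_spacing: float, outer_spacing: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(lining atom coordinates, other atom coordinates) for a cavity."""
    offset = PSEUDO_VDW + probe_small  # wall stand-off from the void surface
    if cavity.kind == "sphere":
        a = cavity.radius + offset
        n_wall = int(math.ceil(4 * math.pi * a ** 2 / wall_spacing ** 2))
        wall = a * fibonacci_sphere(n_wall)
        b = a + shell_thickness
        n_out = int(math.ceil(4 * math.pi * b ** 2 / outer_spacing ** 2))
        outer = b * fibonacci_sphere(n_out)
        return wall, outer
    if cavity.kind == "dimple":
        a = cavity.radius + offset
        n_hemi = int(math.ceil(4 * math.pi * a ** 2 / wall_spacing ** 2))
        pts = a * fibonacci_sphere(n_hemi)
        wall = pts[pts[:, 2] <= 0.35 * wall_spacing]  # lower hemisphere + rim
        plates = []
        half = a + 7.0
        for z in (0.0, -2.0, -4.0):
            plate = _lattice_square(half, z, 1.8)
            keep = np.linalg.norm(plate, axis=1) > a + 0.6 * wall_spacing
            plates.append(plate[keep])
        return wall, np.concatenate(plates)
    # channel: a blind cylindrical bore, mouth at z = length
    rho = cavity.radius + offset
    rings = []
    for z in np.arange(-offset, cavity.length + wall_spacing / 2,
                       wall_spacing):
        n_ring = int(math.ceil(2 * math.pi * rho / wall_spacing))
        theta = 2 * math.pi * np.arange(n_ring) / n_ring
        rings.append(np.stack(
            [rho * np.cos(theta), rho * np.sin(theta),
             np.full(n_ring, z)], axis=1,
        ))
    bottom = _lattice_disk(rho, -offset, wall_spacing)
    wall = np.concatenate(rings + [bottom])
    return wall, np.zeros((0, 3))


def _atoms_from_points(
    lining_pts: np.ndarray,
    other_pts: np.ndarray,
    lining_positions: list[int],
    other_positions: list[int],
    residue_names: dict[int, str] | None,
    chain_id: str = "A",
) -> list[AtomRecord]:
    atoms: list[AtomRecord] = []
    per_res_counter: dict[int, int] = {}
    serial = 0

    def _emit(points: np.ndarray, positions: list[int]):
        nonlocal serial
        for k, (x, y, z) in enumerate(points):
            pos = positions[k % len(positions)]
            per_res_counter[pos] = per_res_counter.get(pos, 0) + 1
            serial += 1
            resn = residue_names.get(pos, "ALA") if residue_names else "ALA"
            atoms.append(AtomRecord(
                serial=serial,
                name=f"C{per_res_counter[pos]}",
                element="C",
                residue_index=pos,
                residue_name=resn,
                chain_id=chain_id,
                x=float(x), y=float(y), z=float(z),
            ))
    _emit(lining_pts, lining_positions)
    if len(other_pts) and other_positions:
        _emit(other_pts, other_positions)
    atoms.sort(key=lambda a: (a.chain_id, a.residue_index, a.name))
    atoms = [
        AtomRecord(serial=i + 1, name=a.name, element=a.element,
                   residue_index=a.residue_index,
                   residue_name=a.residue_name, chain_id=a.chain_id,
                   x=a.x, y=a.y, z=a.z)
        for i, a in enumerate(atoms)
    ]
    return atoms


def make_cavity_structure(
    n_residues: int,
    cavity: CavitySpec,
    shell_thickness: float = 2.2,
    seed: int = 0,
    probe_small: float = 1.4,
    wall_spacing: float = 1.5,
    outer_spacing: float = 2.0,
    lining_positions: list[int] | None = None,
    other_positions: list[int] | None = None,
    residue_names: dict[int, str] | None = None,
    protein_id: str = "synthetic",
    model_id: str = "m0",
) -> tuple[StructureModel, CavityTruth]:
    """Build a pseudo-atom shell with a carved cavity of known geometry.

    ``n_residues`` residues line the cavity wall; outer-shell atoms are
    spread over additional residue indices, so the planted lining set is
    exactly ``lining_positions`` (default 1..n_residues). Deterministic for
    a given configuration; ``seed`` is accepted for interface symmetry with
    the other generators (the geometry itself is jitter-free).
    """
    del seed  # geometry is deterministic; jitter_ensemble adds noise
    wall, outer = _cavity_points(
        cavity, probe_small, shell_thickness, wall_spacing, outer_spacing
    )
    if lining_positions is None:
        lining_positions = list(range(1, n_residues + 1))
    if len(lining_positions) != n_residues:
        raise ConfigError("lining_positions length must equal n_residues")
    if other_positions is None:
        n_other_res = max(1, len(outer) // 3)
        start = max(lining_positions) + 1
        other_positions = list(range(start, start + n_other_res))
    atoms = _atoms_from_points(
        wall, outer, lining_positions, other_positions, residue_names
    )
    model = StructureModel(protein_id=protein_id, model_id=model_id,
                           atoms=atoms)
    truth = CavityTruth(
        volume=cavity.analytic_volume,
        depth=cavity.analytic_depth,
        lining_positions=set(lining_positions),
        enclosed=cavity.kind == "sphere",
    )
    return model, truth


def jitter_ensemble(
    model: StructureModel, sigma: float, n: int = 3, seed: int = 0,
) -> list[StructureModel]:
    """n copies of a model with iid Gaussian coordinate noise (std sigma)."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        disp = rng.normal(0.0, sigma, size=(len(model.atoms), 3)) \
            if sigma > 0 else np.zeros((len(model.atoms), 3))
        atoms = [
            AtomRecord(
                serial=a.serial, name=a.name, element=a.element,
                residue_index=a.residue_index, residue_name=a.residue_name,
                chain_id=a.chain_id,
                x=a.x + disp[i, 0], y=a.y + disp[i, 1], z=a.z + disp[i, 2],
            )
            for i, a in enumerate(model.atoms)
        ]
        out.append(StructureModel(
            protein_id=model.protein_id,
            model_id=f"{model.model_id}_j{k + 1}",
            atoms=atoms,
        ))
    return out


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def simulate_family(
    tree: dendropy.Tree,
    length: int,
    rates: np.ndarray | float = 1.0,
    seed: int = 0,
    root_sequence: str | None = None,
    indel_rate: float = 0.0,
    indel_mean_length: float = 3.0,
) -> tuple[list[tuple[str, str]], Msa]:
    """Evolve a protein family on a tree under a 20-state Poisson model.

    Over a branch of length ``b`` a site with rate ``r`` differs from its
    parent with probability ``(19/20) * (1 - exp(-(20/19) * r * b))``;
    rate-0 sites are invariant. With ``indel_rate > 0`` sites are deleted
    along branches (geometric lengths), which introduces gaps in the true
    alignment; there are no insertions, so root coordinates define the
    alignment columns. Returns unaligned leaf records plus the true MSA.
    """
    rng = np.random.default_rng(seed)
    rates = np.broadcast_to(np.asarray(rates, dtype=float), (length,)).copy()
    if np.any(rates < 0):
        raise ConfigError("site rates must be non-negative")
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    if root_sequence is None:
        root = rng.integers(0, 20, size=length)
    else:
        if len(root_sequence) != length:
            raise ConfigError("root_sequence length mismatch")
        idx = {c: i for i, c in enumerate(AMINO_ACIDS)}
        root = np.array([idx[c] for c in root_sequence.upper()])
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root}
    present: dict[int, np.ndarray] = {
        id(tree.seed_node): np.ones(length, dtype=bool)
    }
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        b = node.edge.length or 0.0
        parent_seq = seqs[id(node.parent_node)]
        parent_present = present[id(node.parent_node)]
        lam = (20.0 / 19.0) * rates * b
        p_redraw = 1.0 - np.exp(-lam)
        redraw = rng.random(length) < p_redraw
        child = parent_seq.copy()
        # a "redraw" picks uniformly among all 20, giving
        # P(differ) = (19/20)(1 - exp(-(20/19) r b)) exactly
        child[redraw] = rng.integers(0, 20, size=int(redraw.sum()))
        child_present = parent_present.copy()
        if indel_rate > 0:
            starts = np.where(
                child_present & (rng.random(length) < indel_rate * b)
            )[0]
            for s in starts:
                glen = rng.geometric(1.0 / indel_mean_length)
                child_present[s:s + glen] = False
        seqs[id(node)] = child
        present[id(node)] = child_present
    ids, rows = [], []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else str(id(leaf))
        s = seqs[id(leaf)]
        mask = present[id(leaf)]
        row = "".join(
            chr(aa[s[i]]) if mask[i] else "-" for i in range(length)
        )
        ids.append(label)
        rows.append(row)
    msa = Msa(ids, rows)
    records = [(sid, msa.ungapped(sid)) for sid in ids]
    return records, msa


# ---------------------------------------------------------------------------
# The full multi-group study
# ---------------------------------------------------------------------------

#: per-group planted CLR counts (31–45 range) and cavity radii (monotone
#: volume ladder I < II < VI < III < VII < IV < V)
DEFAULT_GROUPS = ("I", "II", "III", "IV", "V", "VI", "VII")
DEFAULT_N_CLR = {"I": 31, "II": 34, "III": 36, "IV": 44, "V": 45,
                 "VI": 33, "VII": 41}
DEFAULT_RADII = {"I": 4.0, "II": 4.15, "VI": 4.3, "III": 4.5,
                 "VII": 5.0, "IV": 5.5, "V": 5.7}
DEFAULT_SPECIFICS = {"IV": 11, "V": 8}


@dataclass
class StudyConfig:
    """Configuration of the planted multi-group study (the defaults are the
    study conditions; see docs/methods.md)."""

    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    proteins_per_group: int = 3
    models_per_protein: int = 3
    n_clr: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_CLR))
    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    n_common: int = 27
    specifics: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPECIFICS))
    n_shared_columns: int = 18
    sequence_length: int = 240
    n_conserved_common: int = 25
    n_conserved_other_clr: int = 28
    variable_rate: float = 1.5
    stem_branch: float = 0.2
    internal_branch: float = 0.15
    within_branch: float = 0.05
    jitter_sigma: float = 0.3
    spacing: float = 0.6
    wall_spacing: float = 1.5

    def validate(self) -> None:
        if self.proteins_per_group != 3 or self.models_per_protein != 3:
            raise ConfigError(
                "the study design uses exactly 3 proteins per group and 3 "
                "models per protein (the 2-of-3 consensus rules)"
            )
        for g in self.group_labels:
            if g not in self.n_clr or g not in self.radii:
                raise ConfigError(f"group {g!r} missing n_clr or radius")
            low = self.n_common + self.specifics.get(g, 0)
            if self.n_clr[g] < low:
                raise ConfigError(
                    f"group {g!r}: n_clr {self.n_clr[g]} below "
                    f"common+specific {low}"
                )


def _shared_column_plan(config: StudyConfig) -> dict[str, int]:
    """How many 'shared' (2..n-1 groups) columns each group needs."""
    return {
        g: config.n_clr[g] - config.n_common - config.specifics.get(g, 0)
        for g in config.group_labels
    }


def _build_shared_memberships(config: StudyConfig) -> list[set[str]]:
    """Memberships for the 'shared' CLR columns (each in >=2 but < all
    groups), chosen greedily so each group's remaining demand is met.

    With the default plan this realises 18 shared columns whose group
    memberships sum to the per-group demands implied by the Table-style
    CLR counts, for 27 + 19 + 18 = 64 distinct CLR columns in total.
    """
    remaining = _shared_column_plan(config)
    if any(v < 0 for v in remaining.values()):
        raise ConfigError("negative shared-column demand")
    n_groups = len(config.group_labels)
    n_cols = config.n_shared_columns
    total = sum(remaining.values())
    if not (2 * n_cols <= total <= (n_groups - 1) * n_cols):
        raise ConfigError(
            f"{total} shared memberships cannot be spread over "
            f"{n_cols} columns with 2..{n_groups - 1} groups each"
        )
    if max(remaining.values(), default=0) > n_cols:
        raise ConfigError("a group demands more shared columns than exist")
    columns: list[set[str]] = []
    for j in range(n_cols):
        rem_cols = n_cols - j
        rem_total = sum(remaining.values())
        # groups whose demand equals the remaining column count must appear
        forced = [g for g in config.group_labels
                  if remaining[g] == rem_cols and remaining[g] > 0]
        m = max(2, len(forced), math.ceil(rem_total / rem_cols))
        m = min(m, n_groups - 1, sum(1 for v in remaining.values() if v > 0))
        order = sorted(
            (g for g in config.group_labels if remaining[g] > 0),
            key=lambda g: (g not in forced, -remaining[g], g),
        )
        chosen = set(order[:m])
        if len(chosen) < 2:
            raise ConfigError("shared-column demands not realisable")
        for g in chosen:
            remaining[g] -= 1
        columns.append(chosen)
    if any(v != 0 for v in remaining.values()):
        raise ConfigError(
            f"shared-column plan infeasible; leftovers {remaining}"
        )
    return columns


@dataclass
class SyntheticStudy:
    """A fully labelled synthetic study (see module docstring)."""

    config: StudyConfig
    seed: int
    members: dict[str, list[str]]                 # group -> protein ids
    sequences: dict[str, str]                     # protein id -> sequence
    models: dict[str, list[StructureModel]]       # protein id -> 3 models
    msa: Msa                                      # true master alignment
    tree: dendropy.Tree
    lining_positions: dict[str, set[int]]         # protein id -> planted sites
    volumes: dict[str, float]                     # protein id -> analytic Å^3
    depths: dict[str, float]
    group_columns: dict[str, set[int]]
    common_columns: set[int]
    specific_columns: dict[str, set[int]]
    conserved_columns: set[int]
    anchors: dict[str, set[tuple[str, int]]]      # protein id -> dyad-style anchors
    group_seeds: dict[str, list[str]]             # group -> seed leaf ids

    def all_clr_columns(self) -> set[int]:
        return set().union(*self.group_columns.values())

    def truth_dict(self) -> dict:
        return {
            "seed": self.seed,
            "members": {g: list(v) for g, v in sorted(self.members.items())},
            "lining_positions": {
                p: sorted(v) for p, v in sorted(self.lining_positions.items())
            },
            "volumes": dict(sorted(self.volumes.items())),
            "depths": dict(sorted(self.depths.items())),
            "group_columns": {
                g: sorted(v) for g, v in sorted(self.group_columns.items())
            },
            "common_columns": sorted(self.common_columns),
            "specific_columns": {
                g: sorted(v) for g, v in sorted(self.specific_columns.items())
            },
            "conserved_columns": sorted(self.conserved_columns),
        }

    def save_truth(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.truth_dict(), indent=2))

    @staticmethod
    def load_truth(path: str | Path) -> dict:
        return json.loads(Path(path).read_text())

    def grid_params(self) -> GridParams:
        return synthetic_grid_params(spacing=self.config.spacing)


def _study_tree(config: StudyConfig) -> tuple[dendropy.Tree, dict[str, list[str]]]:
    """Caterpillar of group clades, 3 leaves per group, known lengths."""
    parts = []
    members: dict[str, list[str]] = {}
    for g in config.group_labels:
        ids = [f"{g}_p{k}" for k in range(1, config.proteins_per_group + 1)]
        members[g] = ids
        clade = "(" + ",".join(
            f"{pid}:{config.within_branch}" for pid in ids
        ) + f"):{config.stem_branch}"
        parts.append(clade)
    newick = parts[0]
    for clade in parts[1:]:
        newick = f"({newick},{clade}):{config.internal_branch}"
    tree = dendropy.Tree.get(data=newick + ";", schema="newick",
                            preserve_underscores=True)
    return tree, members


def make_study(config: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Build the default planted study: structures, sequences and truths."""
    config = config or StudyConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    L = config.sequence_length
    groups = list(config.group_labels)

    # --- column plan -------------------------------------------------------
    shared_memberships = _build_shared_memberships(config)
    n_specific = sum(config.specifics.values())
    n_cols_needed = config.n_common + n_specific + len(shared_memberships)
    if n_cols_needed > L:
        raise ConfigError("sequence too short for the requested column plan")
    perm = rng.permutation(L) + 1  # 1-based columns
    cursor = 0
    common_columns = set(int(c) for c in perm[cursor:cursor + config.n_common])
    cursor += config.n_common
    specific_columns: dict[str, set[int]] = {g: set() for g in groups}
    for g in sorted(config.specifics):
        k = config.specifics[g]
        specific_columns[g] = set(int(c) for c in perm[cursor:cursor + k])
        cursor += k
    shared_columns: dict[int, set[str]] = {}
    for membership in shared_memberships:
        shared_columns[int(perm[cursor])] = membership
        cursor += 1
    group_columns: dict[str, set[int]] = {}
    for g in groups:
        cols = set(common_columns) | specific_columns[g]
        cols |= {c for c, mem in shared_columns.items() if g in mem}
        group_columns[g] = cols
        assert len(cols) == config.n_clr[g]

    # --- conserved-site plan ----------------------------------------------
    common_sorted = sorted(common_columns)
    conserved = set(common_sorted[:config.n_conserved_common])
    other_clr = sorted(set().union(*group_columns.values()) - common_columns)
    pick = rng.permutation(len(other_clr))[:config.n_conserved_other_clr]
    conserved |= {other_clr[i] for i in pick}

    # --- sequences ---------------------------------------------------------
    tree, members = _study_tree(config)
    rates = np.full(L, config.variable_rate)
    for c in conserved:
        rates[c - 1] = 0.0
    fam_seed = int(rng.integers(0, 2 ** 31 - 1))
    records, msa = simulate_family(tree, L, rates, seed=fam_seed)
    sequences = dict(records)

    # --- structures --------------------------------------------------------
    models: dict[str, list[StructureModel]] = {}
    lining_positions: dict[str, set[int]] = {}
    volumes: dict[str, float] = {}
    depths: dict[str, float] = {}
    anchors: dict[str, set[tuple[str, int]]] = {}
    for g in groups:
        cavity = CavitySpec(kind="sphere", radius=config.radii[g])
        lining = sorted(group_columns[g])  # no indels: positions == columns
        other = sorted(set(range(1, L + 1)) - set(lining))
        for pid in members[g]:
            resnames = {
                i + 1: ONE_TO_THREE[sequences[pid][i]] for i in range(L)
            }
            base, truth = make_cavity_structure(
                n_residues=len(lining),
                cavity=cavity,
                wall_spacing=config.wall_spacing,
                lining_positions=lining,
                other_positions=other,
                residue_names=resnames,
                protein_id=pid,
                model_id=pid,
            )
            jseed = int(rng.integers(0, 2 ** 31 - 1))
            models[pid] = jitter_ensemble(
                base, config.jitter_sigma, n=config.models_per_protein,
                seed=jseed,
            )
            lining_positions[pid] = set(lining)
            volumes[pid] = truth.volume
            depths[pid] = truth.depth
            anchors[pid] = {("A", lining[0]), ("A", lining[1])}

    return SyntheticStudy(
        config=config,
        seed=seed,
        members=members,
        sequences=sequences,
        models=models,
        msa=msa,
        tree=tree,
        lining_positions=lining_positions,
        volumes=volumes,
        depths=depths,
        group_columns=group_columns,
        common_columns=common_columns,
        specific_columns={g: v for g, v in specific_columns.items()},
        conserved_columns=conserved,
        anchors=anchors,
        group_seeds={g: [members[g][0]] for g in groups},
    )


def write_run_directory(study: SyntheticStudy, out_dir: str | Path) -> Path:
    """Write PDBs, FASTA, the true alignment, truths and a pipeline config."""
    import yaml

    from .io_formats import write_alignment, write_fasta, write_pdb

    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    records = [(pid, study.sequences[pid])
               for g in study.members for pid in study.members[g]]
    write_fasta(records, out / "sequences.fasta")
    write_alignment(study.msa, out / "alignment.fasta")
    study.save_truth(out / "truth.json")
    cfg: dict = {
        "seed": study.seed,
        "alignment": "alignment.fasta",
        "grid": {
            "spacing": study.config.spacing,
            "probe_small": 1.4,
            "probe_large": 4.0,
            "vdw_table": {"C": PSEUDO_VDW},
        },
        "phylogeny": {
            "gap_policy": "pairwise_deletion",
            "bootstrap_replicates": 0,
        },
        "group_seeds": {g: list(v) for g, v in study.group_seeds.items()},
        "groups": {},
    }
    for g, pids in study.members.items():
        cfg["groups"][g] = {}
        for pid in pids:
            paths = []
            for m in study.models[pid]:
                rel = f"structures/{m.model_id}.pdb"
                write_pdb(m, out / rel)
                paths.append(rel)
            cfg["groups"][g][pid] = {
                "models": paths,
                "anchors": [f"{c}:{r}" for c, r in sorted(study.anchors[pid])],
            }
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return out / "config.yaml"
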