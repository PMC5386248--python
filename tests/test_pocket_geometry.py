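import math

import numpy as np
import pytest

from pocketphylo.errors import GeometryError, NoPocketError
from pocketphylo.io_formats import AtomRecord, StructureModel
from pocketphylo.pocket_geometry import (
    GridParams,
    blocked_mask,
    detect_pockets,
    exterior_region,
    lining_residues,
    make_grid,
    pocket_depth,
    select_catalytic_pocket,
)
from pocketphylo.synthetic_data import (
    CavitySpec,
    make_cavity_structure,
    synthetic_grid_params,
)


def single_atom_model():
    return StructureModel(
        protein_id="x", model_id="m",
        atoms=[AtomRecord(1, "C1", "C", 1, "ALA", "A", 0.0, 0.0, 0.0)],
    )


def solid_ball_model(radius=6.0, spacing=1.5):
    ax = np.arange(-radius, radius + spacing / 2, spacing)
    pts = np.stack(np.meshgrid(ax, ax, ax), axis=-1).reshape(-1, 3)
    pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    atoms = [
        AtomRecord(i + 1, "C1", "C", i + 1, "ALA", "A", *map(float, p))
        for i, p in enumerate(pts)
    ]
    return StructureModel(protein_id="ball", model_id="m", atoms=atoms)


class TestBlockedMask:
    def test_single_atom_digital_ball_volume(self):
        """Blocked region of one C atom at probe 1.4 is a ball of radius
        vdW + probe = 3.1 Å; the voxel count must match the analytic volume
        within a surface-layer band."""
        model = single_atom_model()
        params = GridParams(spacing=0.4)
        mask = blocked_mask(model, params, probe=1.4)
        h = params.spacing
        vol = mask.sum() * h ** 3
        r = 1.70 + 1.4
        analytic = 4 / 3 * math.pi * r ** 3
        surface_band = 4 * math.pi * r ** 2 * h  # one-voxel surface shell
        assert abs(vol - analytic) < surface_band

    def test_empty_structure_rejected(self):
        model = single_atom_model()
        model.atoms = []
        with pytest.raises(GeometryError):
            blocked_mask(model, GridParams(), probe=1.4)

    def test_monotone_in_probe(self):
        model = single_atom_model()
        params = GridParams(spacing=0.5)
        grid = make_grid(model, params)
        m0 = blocked_mask(model, params, probe=0.0, grid=grid)
        m14 = blocked_mask(model, params, probe=1.4, grid=grid)
        assert np.all(m14[m0])  # blocked(0) subset of blocked(1.4)


class TestExteriorRegion:
    def test_no_atoms_all_exterior(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        assert exterior_region(mask).all()

    def test_hollow_shell_interior_not_exterior(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[2:7, 2:7, 2:7] = True
        mask[3:6, 3:6, 3:6] = False  # sealed interior cavity
        ext = exterior_region(mask)
        assert not ext[4, 4, 4]
        assert ext[0, 0, 0]

    def test_exterior_touches_boundary(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        ext = exterior_region(mask)
        assert ext[0].all() and ext[-1].all()


class TestDetectPockets:
    def test_solid_ball_has_no_pockets(self):
        pockets = detect_pockets(solid_ball_model(), GridParams(spacing=0.6))
        assert pockets == []

    def test_enclosed_sphere_volume_and_classification(self, sphere_fixture):
        _, truth, params, pockets = sphere_fixture
        enclosed = [p for p in pockets if p.enclosed]
        assert len(enclosed) == 1
        assert enclosed[0].volume == pytest.approx(truth.volume, rel=0.10)
        assert enclosed[0].mouth_voxels.shape[0] == 0

    def test_dimple_is_open_with_mouth(self):
        model, truth, _ = _dimple()
        pockets = detect_pockets(
            model, synthetic_grid_params(spacing=0.6, probe_large=8.0))
        assert pockets
        p = pockets[0]
        assert not p.enclosed
        assert p.mouth_voxels.shape[0] > 0
        assert p.volume == pytest.approx(truth.volume, rel=0.15)

    def test_volume_is_voxel_count_times_h3(self, sphere_fixture):
        _, _, params, pockets = sphere_fixture
        for p in pockets:
            assert p.volume == pytest.approx(
                p.n_voxels * params.spacing ** 3)

    def test_mouth_subset_of_voxels_and_enclosed_iff_no_mouth(self):
        model, _, _ = _dimple()
        pockets = detect_pockets(
            model, synthetic_grid_params(spacing=0.6, probe_large=8.0))
        for p in pockets:
            vox = {tuple(v) for v in p.voxels}
            mouth = {tuple(v) for v in p.mouth_voxels}
            assert mouth <= vox
            assert p.enclosed == (len(mouth) == 0)

    def test_envelope_grows_with_probe_large(self):
        model, _, _ = _dimple()
        vols = []
        for pl in (7.0, 8.0, 10.0):
            ps = detect_pockets(
                model, synthetic_grid_params(spacing=0.6, probe_large=pl))
            vols.append(sum(p.volume for p in ps))
        assert vols[0] <= vols[1] <= vols[2]

    def test_volume_converges_as_grid_refines(self, rng):
        """Halving h moves the voxel volume toward the continuous limit.

        The limit is the continuous free-space volume of the shell (its
        cavity surface bulges slightly between wall atoms, so the analytic
        ball volume is a lower bound, not the limit); it is estimated by
        Monte-Carlo integration over an enclosing ball.
        """
        from scipy.spatial import cKDTree

        model, truth = make_cavity_structure(
            20, CavitySpec("sphere", radius=5.0))
        coords = np.array([[a.x, a.y, a.z] for a in model.atoms])
        tree = cKDTree(coords)
        r_mc = truth.depth + 1.0  # cavity radius + bump allowance
        pts = rng.uniform(-r_mc, r_mc, size=(400000, 3))
        pts = pts[np.linalg.norm(pts, axis=1) <= r_mc]
        inside = tree.query(pts)[0] >= 2.5 + 1.4  # beyond vdW + probe
        v_cont = (4 / 3 * math.pi * r_mc ** 3) * inside.mean()
        errs = []
        for h in (0.8, 0.4):
            ps = detect_pockets(model, synthetic_grid_params(spacing=h))
            enc = [p for p in ps if p.enclosed][0]
            errs.append(abs(enc.volume - v_cont))
        assert errs[1] < errs[0]

    def test_rigid_motion_changes_little(self, rng):
        model, truth = make_cavity_structure(
            20, CavitySpec("sphere", radius=4.5))
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.uniform(-3, 3, 3)
        coords = np.array([[a.x, a.y, a.z] for a in model.atoms]) @ q.T + t
        rotated = StructureModel(
            protein_id="rot", model_id="m",
            atoms=[
                AtomRecord(a.serial, a.name, a.element, a.residue_index,
                           a.residue_name, a.chain_id, *map(float, c))
                for a, c in zip(model.atoms, coords)
            ],
        )
        params = synthetic_grid_params(spacing=0.6)
        p1 = [p for p in detect_pockets(model, params) if p.enclosed][0]
        p2 = [p for p in detect_pockets(rotated, params) if p.enclosed][0]
        assert abs(p2.volume - p1.volume) / p1.volume < 0.05
        assert len(p1.lining_residues ^ p2.lining_residues) <= 1


def _dimple():
    model, truth = make_cavity_structure(30, CavitySpec("dimple", radius=5.0))
    return model, truth, None


class TestDepth:
    def test_channel_depth(self):
        model, truth = make_cavity_structure(
            20, CavitySpec("channel", radius=2.0, length=12.0))
        params = synthetic_grid_params(spacing=0.6)
        p = detect_pockets(model, params)[0]
        assert abs(p.depth - truth.depth) <= 2 * params.spacing

    def test_dimple_depth(self):
        model, truth, _ = _dimple()
        params = synthetic_grid_params(spacing=0.6, probe_large=8.0)
        p = detect_pockets(model, params)[0]
        assert abs(p.depth - truth.depth) <= 2 * params.spacing

    def test_single_voxel_pocket_depth_zero(self, sphere_fixture):
        _, _, params, pockets = sphere_fixture
        p = pockets[0]
        from pocketphylo.pocket_geometry import Pocket

        tiny = Pocket(
            pocket_id=0, voxels=p.voxels[:1], grid=p.grid,
            volume=params.spacing ** 3,
            mouth_voxels=p.voxels[:0], enclosed=True,
        )
        assert pocket_depth(tiny, params) == 0.0

    def test_enclosed_sphere_depth_near_radius(self, sphere_fixture):
        _, truth, params, pockets = sphere_fixture
        enc = [p for p in pockets if p.enclosed][0]
        assert abs(enc.depth - truth.depth) <= 2.0  # half geodesic diameter


class TestLiningAndSelection:
    def test_planted_shell_lining_recovered(self, sphere_fixture):
        model, truth, params, pockets = sphere_fixture
        enc = [p for p in pockets if p.enclosed][0]
        got = {resi for _, resi in enc.lining_residues}
        assert got == truth.lining_positions

    def test_no_pocket_empty_lining(self, sphere_fixture):
        model, _, params, pockets = sphere_fixture
        from pocketphylo.pocket_geometry import Pocket

        empty = Pocket(
            pocket_id=0, voxels=pockets[0].voxels[:0], grid=pockets[0].grid,
            volume=0.0, mouth_voxels=pockets[0].voxels[:0], enclosed=True,
        )
        assert lining_residues(empty, model, params) == set()

    def test_selection_rules(self, sphere_fixture):
        _, truth, _, pockets = sphere_fixture
        enc = [p for p in pockets if p.enclosed][0]
        anchor = ("A", sorted(truth.lining_positions)[0])
        assert select_catalytic_pocket(pockets, {anchor}) is enc
        assert select_catalytic_pocket(pockets) is max(
            pockets, key=lambda p: p.volume)
        with pytest.raises(NoPocketError):
            select_catalytic_pocket(pockets, {("A", 99999)})
        with pytest.raises(NoPocketError):
            select_catalytic_pocket([])
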