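"""File readers, channel frames, projection, unwrapping, cache."""

import numpy as np
import pytest

from tstperm import trajectory as tj
from tstperm.errors import (
    ConfigurationError,
    FormatError,
    GeometryError,
)


def _write_water_pdb(path, frames, box=(60.0, 60.0, 60.0)):
    """Multi-model PDB of water oxygens; ``frames`` is (n_frames, n, 3)."""
    import MDAnalysis as mda

    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    u.add_TopologyAttr("names", ["OH2"] * n)
    u.add_TopologyAttr("resnames", ["TIP3"] * n)
    u.add_TopologyAttr("resids", np.arange(1, n + 1))
    u.dimensions = [*box, 90.0, 90.0, 90.0]
    with mda.Writer(str(path), multiframe=True) as w:
        for f in frames:
            u.atoms.positions = f
            w.write(u.atoms)
    return path


@pytest.fixture
def three_frame_pdb(tmp_path):
    frames = np.zeros((3, 2, 3))
    frames[:, 0, 2] = [0.0, 1.0, 2.0]  # water 1 drifts along z
    frames[:, 1, 2] = [5.0, 5.0, 5.0]
    frames[:, 1, 0] = 3.0
    return _write_water_pdb(tmp_path / "w.pdb", frames)


class TestReader:
    def test_three_frame_two_waters(self, three_frame_pdb):
        bundle = tj.read_topology_and_trajectory(three_frame_pdb)
        assert bundle.frames_count == 3
        assert len(bundle.tracks["all"]) == 2
        assert bundle.tracks["all"][0].z == pytest.approx([0.0, 1.0, 2.0])

    def test_stride_halves_frames_and_doubles_dt(self, tmp_path):
        frames = np.zeros((10, 1, 3))
        frames[:, 0, 2] = np.arange(10)
        pdb = _write_water_pdb(tmp_path / "ten.pdb", frames)
        bundle = tj.read_topology_and_trajectory(pdb, frame_stride=2)
        assert bundle.frames_count == 5
        ref = tj.read_topology_and_trajectory(pdb)
        assert bundle.dt_frame == 2 * ref.dt_frame

    def test_periodic_unwrap_continues_past_boundary(self, tmp_path):
        # +29 -> -29 in a 60 Å box is a +2 Å step to +31, not a sign flip
        frames = np.zeros((3, 1, 3))
        frames[:, 0, 2] = [27.0, 29.0, -29.0]
        pdb = _write_water_pdb(tmp_path / "pbc.pdb", frames)
        bundle = tj.read_topology_and_trajectory(pdb, box=(60.0, 60.0, 60.0))
        assert bundle.tracks["all"][0].z == pytest.approx([27.0, 29.0, 31.0])

    def test_empty_selection_rejected(self, three_frame_pdb):
        with pytest.raises(ConfigurationError):
            tj.read_topology_and_trajectory(
                three_frame_pdb, water_selection="resname XXX")

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            tj.read_topology_and_trajectory(tmp_path / "nope.pdb")

    def test_atom_count_mismatch_rejected(self, tmp_path, three_frame_pdb):
        import MDAnalysis as mda

        # DCD with 3 atoms against a 2-atom topology
        other = _write_water_pdb(tmp_path / "three.pdb",
                                 np.zeros((2, 3, 3)))
        u = mda.Universe(str(other))
        dcd = tmp_path / "three.dcd"
        with mda.Writer(str(dcd), n_atoms=3) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
        with pytest.raises(FormatError):
            tj.read_topology_and_trajectory(three_frame_pdb, dcd)

    def test_pdb_plus_dcd_round_trip(self, tmp_path):
        import MDAnalysis as mda

        frames = np.zeros((4, 2, 3))
        frames[:, 0, 2] = [0, 2, 4, 6]
        frames[:, 1, 2] = [5, 5, 5, 5]
        pdb = _write_water_pdb(tmp_path / "top.pdb", frames[:1])
        u = mda.Universe(str(pdb))
        dcd = tmp_path / "trj.dcd"
        with mda.Writer(str(dcd), n_atoms=2) as w:
            for f in frames:
                u.atoms.positions = f
                u.dimensions = [60, 60, 60, 90, 90, 90]
                w.write(u.atoms)
        bundle = tj.read_topology_and_trajectory(pdb, dcd)
        assert bundle.frames_count == 4
        assert bundle.tracks["all"][0].z == pytest.approx([0, 2, 4, 6],
                                                          abs=1e-4)


class TestChannelFrames:
    def test_explicit_identity(self):
        frames = tj.build_channel_frames(
            {"monomers": [{"id": "A", "origin": [0, 0, 0],
                           "axis": [0, 0, 1]}]})
        assert frames[0].monomer_id == "A"
        assert frames[0].axis == pytest.approx([0, 0, 1])

    def test_axis_from_residue_centroids(self, tmp_path):
        # EC group centred at (0,0,10), IC group at (0,0,-10)
        frames_xyz = np.zeros((2, 2, 3))
        frames_xyz[:, 0, 2] = 10.0
        frames_xyz[:, 1, 2] = -10.0
        pdb = _write_water_pdb(tmp_path / "axis.pdb", frames_xyz)
        frames = tj.build_channel_frames(
            {"monomers": [{"id": "A", "ec_residues": "resid 1",
                           "ic_residues": "resid 2"}]},
            topology_path=pdb,
        )
        assert frames[0].axis == pytest.approx([0, 0, 1])
        assert frames[0].origin == pytest.approx([0, 0, 0])

    def test_tetramer_spec_passthrough(self):
        spec = {"monomers": [
            {"id": f"M{i}", "origin": [10 * i, 0, 0], "axis": [0, 0, 1]}
            for i in range(4)
        ], "channel": {"radius_gate": 6.0, "z_bulk_ec": 12.0,
                       "z_bulk_ic": -12.0}}
        frames = tj.build_channel_frames(spec)
        assert len(frames) == 4
        assert len({f.monomer_id for f in frames}) == 4
        assert all(f.z_bulk_ec == 12.0 for f in frames)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(GeometryError):
            tj.ChannelFrame(monomer_id="bad", axis=np.zeros(3))

    def test_invalid_configs_rejected(self, tmp_path):
        with pytest.raises(ConfigurationError):
            tj.build_channel_frames({"monomers": []})
        with pytest.raises(ConfigurationError):
            tj.build_channel_frames({"monomers": [{"id": "A"}]})
        with pytest.raises(ConfigurationError):
            tj.build_channel_frames(
                {"monomers": [{"id": "A", "ec_residues": "resid 1",
                               "ic_residues": "resid 2"}]})


class TestProjection:
    def _bundle(self, positions):
        positions = np.asarray(positions, dtype=float)
        return tj.TrajectoryBundle(
            frames_count=positions.shape[0],
            dt_frame=1.0,
            tracks={},
            raw_positions=positions,
        )

    def test_identity_frame(self):
        bundle = self._bundle([[[0, 0, 5.0]], [[0, 0, 6.0]]])
        frame = tj.ChannelFrame(monomer_id="A")
        z, ok = tj.project_to_channel_frame(bundle, frame)
        assert z[:, 0] == pytest.approx([5.0, 6.0])
        assert ok.all()

    def test_lateral_gate(self):
        bundle = self._bundle([[[30.0, 30.0, 5.0]], [[1.0, 0.0, 5.0]]])
        frame = tj.ChannelFrame(monomer_id="A", radius_gate=8.0)
        z, ok = tj.project_to_channel_frame(bundle, frame)
        assert z[:, 0] == pytest.approx([5.0, 5.0])
        assert not ok[0, 0]
        assert ok[1, 0]

    def test_gate_only_applies_inside_slab(self):
        # far from the axis but beyond the bulk threshold: bulk, ok=True
        bundle = self._bundle([[[30.0, 30.0, 20.0]], [[30.0, 30.0, 20.0]]])
        frame = tj.ChannelFrame(monomer_id="A", radius_gate=8.0)
        _, ok = tj.project_to_channel_frame(bundle, frame)
        assert ok.all()

    def test_rotated_frame(self):
        bundle = self._bundle([[[7.0, 0, 0]], [[7.0, 0, 0]]])
        frame = tj.ChannelFrame(monomer_id="A", axis=[1.0, 0, 0])
        z, _ = tj.project_to_channel_frame(bundle, frame)
        assert z[:, 0] == pytest.approx([7.0, 7.0])

    def test_origin_projects_to_exact_zero(self):
        origin = np.array([3.1, -2.2, 7.7])
        bundle = self._bundle([[origin], [origin]])
        frame = tj.ChannelFrame(monomer_id="A", origin=origin,
                                axis=[0.3, -0.4, 0.5])
        z, _ = tj.project_to_channel_frame(bundle, frame)
        assert np.all(z == 0.0)

    def test_nearest_axis_wins_assignment(self):
        # one water on monomer A's axis, one on B's
        pos = np.zeros((2, 2, 3))
        pos[:, 0, 0] = 0.0
        pos[:, 1, 0] = 20.0
        bundle = self._bundle(pos)
        frames = [
            tj.ChannelFrame(monomer_id="A", origin=[0, 0, 0]),
            tj.ChannelFrame(monomer_id="B", origin=[20, 0, 0]),
        ]
        tracks = tj.assign_tracks(bundle, frames)
        assert tracks["A"][0].lateral_ok.all()
        assert not tracks["A"][1].lateral_ok.any()
        assert tracks["B"][1].lateral_ok.all()


class TestUnwrap:
    def test_hand_checked_case(self):
        pos = np.zeros((3, 1, 3))
        pos[:, 0, 2] = [29.0, -29.0, -27.0]
        out = tj.unwrap_coordinates(pos, np.array([60.0, 60.0, 60.0]))
        assert out[:, 0, 2] == pytest.approx([29.0, 31.0, 33.0])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_wrapped_coordinate_preserved_mod_box(self, seed):
        rng = np.random.default_rng(seed)
        box = np.array([25.0, 30.0, 35.0])
        steps = rng.normal(0, 3, size=(50, 4, 3))
        true_path = np.cumsum(steps, axis=0)
        wrapped = (true_path + box / 2) % box - box / 2
        out = tj.unwrap_coordinates(wrapped, box)
        # unwrapping must not move any point off its periodic image
        assert np.allclose((out - wrapped) % box, 0.0, atol=1e-6) or \
            np.allclose(((out - wrapped) % box) - box, 0.0, atol=1e-6) or \
            np.allclose(np.minimum((out - wrapped) % box,
                                   box - (out - wrapped) % box), 0.0,
                        atol=1e-6)
        # and with steps below half the box it recovers the true path
        assert np.allclose(out - out[0], true_path - true_path[0], atol=1e-9)


def test_cache_round_trip_bit_exact(tmp_path, eq_bundle):
    path = tmp_path / "bundle.npz"
    small = tj.TrajectoryBundle(
        frames_count=eq_bundle.frames_count,
        dt_frame=eq_bundle.dt_frame,
        tracks={"synthetic": eq_bundle.tracks["synthetic"][:3]},
        temperature=eq_bundle.temperature,
        box=eq_bundle.box,
    )
    tj.save_bundle(small, path)
    loaded = tj.load_bundle(path)
    assert loaded.frames_count == small.frames_count
    assert loaded.dt_frame == small.dt_frame
    for a, b in zip(small.tracks["synthetic"], loaded.tracks["synthetic"]):
        assert np.array_equal(a.z, b.z)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.vz, b.vz)


def test_load_missing_cache_rejected(tmp_path):
    with pytest.raises(FormatError):
        tj.load_bundle(tmp_path / "none.npz")
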