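"""Shared fixtures and independent oracle implementations.

The oracles deliberately re-derive quantities by a different route than
the package (brute-force scans, O(n²) loops) so tests compare two
independent computations.
"""

from __future__ import annotations

import numpy as np
import pytest

from tstperm import synthetic
from tstperm.trajectory import ChannelFrame, ParticleTrack


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_traversals(z: np.ndarray, z_bulk_ic: float,
                           z_bulk_ec: float) -> tuple[int, int]:
    """Complete bulk-to-bulk passages by region-sequence scanning.

    Labels each frame IC-bulk (−1), EC-bulk (+1) or in-channel (0), drops
    the zeros, and counts −1→+1 transitions (and the mirror) in the
    remaining sequence.  Entirely independent of the event state machine.
    """
    z = np.asarray(z, dtype=float)
    label = np.zeros(z.size, dtype=int)
    label[z <= z_bulk_ic] = -1
    label[z >= z_bulk_ec] = 1
    seq = label[label != 0]
    if seq.size < 2:
        return 0, 0
    steps = np.diff(seq)
    up = int(np.count_nonzero(steps == 2))
    down = int(np.count_nonzero(steps == -2))
    return up, down


def brute_force_hbond_pairs(o_pos: np.ndarray, h_pos: np.ndarray,
                            d_max: float, angle_max: float) -> int:
    """O(n²) water-water hydrogen-bond count (unique unordered pairs).

    ``o_pos``: (N, 3) oxygens; ``h_pos``: (N, 2, 3) the two hydrogens of
    each water.
    """
    n = o_pos.shape[0]
    bonded = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.linalg.norm(o_pos[i] - o_pos[j]) > d_max:
                continue
            for k in range(2):
                h = h_pos[i, k]
                dh = h - o_pos[i]
                ha = o_pos[j] - h
                cosdev = np.dot(dh, ha) / (
                    np.linalg.norm(dh) * np.linalg.norm(ha))
                dev = np.degrees(np.arccos(np.clip(cosdev, -1, 1)))
                if dev <= angle_max:
                    bonded.add((min(i, j), max(i, j)))
    return len(bonded)


def make_track(z, times=None, lateral_ok=None, particle_id=0) -> ParticleTrack:
    z = np.asarray(z, dtype=float)
    if times is None:
        times = np.arange(z.size, dtype=float)
    return ParticleTrack(particle_id=particle_id, times=times, z=z,
                         lateral_ok=lateral_ok)


@pytest.fixture
def default_frame() -> ChannelFrame:
    """Dividing plane at 0, bulk thresholds at ±15 Å."""
    return ChannelFrame(monomer_id="M0")


# ---------------------------------------------------------------------------
# shared equilibrium simulation (used by several statistical tests)
# ---------------------------------------------------------------------------

EQ_SPEC = synthetic.LangevinSpec(
    n_particles=60,
    n_steps=400_000,
    dt=0.005,
    save_stride=2,
    friction=2.0,
    temperature=298.15,
    box_z=40.0,
    channel_halfwidth=10.0,
    barrier_height=1.0,
    barrier_width=1.5,
    seed=7,
)


@pytest.fixture(scope="session")
def eq_bundle():
    """Moderate equilibrium run with a 1 kcal/mol barrier (2 ns, 60
    particles); shared across statistical tests."""
    return synthetic.simulate(EQ_SPEC)


@pytest.fixture(scope="session")
def eq_frame():
    return synthetic.channel_frame(EQ_SPEC)
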