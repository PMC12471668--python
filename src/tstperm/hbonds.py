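"""Hydrogen-bond statistics of single-file channel waters.

Counts simultaneous hydrogen bonds formed (i) amongst the single-file
waters in the channel and (ii) between those waters and the pore-lining
residues, and builds the probability histogram of the per-frame counts.
A geometric criterion is used: donor-heavy-atom–acceptor distance within
``d_max`` and donor–hydrogen···acceptor deviation from linearity within
``angle_max`` (3.5 Å / 30° by default — the common MD convention; the
criterion is configurable and recorded in output metadata).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DataError, TopologyError
from .trajectory import ParticleTrack


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition.

    ``d_max``: donor-heavy-atom (O/N) to acceptor distance cutoff (Å).
    ``angle_max``: maximum deviation (degrees) of the D–H···A angle from
    linearity (0° = perfectly collinear).
    """

    d_max: float = 3.5
    angle_max: float = 30.0

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ConfigurationError("d_max must be positive")
        if not 0 < self.angle_max < 90:
            raise ConfigurationError("angle_max must be in (0, 90) degrees")


def select_single_file_waters(
    tracks: Sequence[ParticleTrack],
    region: tuple[float, float],
) -> list[np.ndarray]:
    """Per-frame particle ids inside the single-file region.

    ``region`` is a z interval (from
    :func:`tstperm.density.single_file_region` or set explicitly).
    Selection is per frame: a water is included on frames where it passes
    the lateral gate and its z lies inside the interval.
    """
    lo, hi = region
    if not hi > lo:
        raise ConfigurationError("empty single-file region")
    if not tracks:
        return []
    n_frames = len(tracks[0])
    ids = np.array([t.particle_id for t in tracks])
    z = np.stack([t.z for t in tracks], axis=1)  # (frames, particles)
    lat = np.stack(
        [
            t.lateral_ok if t.lateral_ok is not None
            else np.ones(n_frames, dtype=bool)
            for t in tracks
        ],
        axis=1,
    )
    sel = (z > lo) & (z < hi) & lat
    return [ids[sel[f]] for f in range(n_frames)]


def _bond_pairs(
    donor_heavy: np.ndarray,
    hydrogens: np.ndarray,
    h_to_donor: np.ndarray,
    acceptors: np.ndarray,
    criterion: HBondCriterion,
) -> np.ndarray:
    """(n_bonds, 2) array of (hydrogen index, acceptor index) pairs.

    A pair qualifies when the donor-heavy–acceptor distance is within
    ``d_max`` and the D–H···A deviation from linearity within
    ``angle_max``.  Each donor hydrogen pairs at most once with each
    acceptor by construction.
    """
    if hydrogens.size == 0 or acceptors.size == 0:
        return np.empty((0, 2), dtype=int)
    d_pos = donor_heavy[h_to_donor]  # (Nh, 3)
    # distance criterion on heavy atoms
    dist = np.linalg.norm(d_pos[:, None, :] - acceptors[None, :, :], axis=2)
    cand = dist <= criterion.d_max
    # angle criterion: deviation between (H - D) and (A - H)
    dh = hydrogens - d_pos  # (Nh, 3)
    ha = acceptors[None, :, :] - hydrogens[:, None, :]  # (Nh, Na, 3)
    dh_n = np.linalg.norm(dh, axis=1)
    ha_n = np.linalg.norm(ha, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosdev = np.einsum("hi,hai->ha", dh, ha) / (dh_n[:, None] * ha_n)
    cosdev = np.clip(cosdev, -1.0, 1.0)
    ok = cand & (ha_n > 1e-6) & (
        np.degrees(np.arccos(cosdev)) <= criterion.angle_max
    )
    h_idx, a_idx = np.nonzero(ok)
    return np.column_stack([h_idx, a_idx])


def count_hbonds(
    donor_heavy: np.ndarray,
    hydrogens: np.ndarray,
    h_to_donor: np.ndarray,
    acceptors: np.ndarray,
    criterion: HBondCriterion = HBondCriterion(),
    donor_mol: np.ndarray | None = None,
    acceptor_mol: np.ndarray | None = None,
    unordered_pairs: bool = False,
) -> int:
    """Hydrogen-bond count for one frame of coordinates.

    Parameters
    ----------
    donor_heavy, hydrogens, h_to_donor:
        Donor heavy-atom positions (Nd, 3), donor hydrogen positions
        (Nh, 3), and the index of each hydrogen's heavy atom.
    acceptors:
        Acceptor positions (Na, 3).
    donor_mol, acceptor_mol:
        Optional molecule labels; bonds within one molecule are never
        counted when both are given.
    unordered_pairs:
        For symmetric pairings (water–water): collapse bonds to unique
        unordered molecule pairs, so a doubly-bonded pair counts once and
        the result does not depend on enumeration order.
    """
    donor_heavy = np.atleast_2d(np.asarray(donor_heavy, dtype=float))
    hydrogens = np.atleast_2d(np.asarray(hydrogens, dtype=float))
    acceptors = np.atleast_2d(np.asarray(acceptors, dtype=float))
    h_to_donor = np.asarray(h_to_donor, dtype=int)
    if hydrogens.shape[0] != h_to_donor.shape[0]:
        raise DataError("h_to_donor must map every hydrogen")
    pairs = _bond_pairs(donor_heavy, hydrogens, h_to_donor, acceptors,
                        criterion)
    if pairs.size == 0:
        return 0
    if donor_mol is not None and acceptor_mol is not None:
        donor_mol = np.asarray(donor_mol)
        acceptor_mol = np.asarray(acceptor_mol)
        dmol = donor_mol[h_to_donor[pairs[:, 0]]]
        amol = acceptor_mol[pairs[:, 1]]
        keep = dmol != amol
        pairs = pairs[keep]
        if unordered_pairs:
            a = dmol[keep]
            b = amol[keep]
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            return int(np.unique(np.column_stack([lo, hi]), axis=0).shape[0])
    return int(pairs.shape[0])


def water_water_counts(
    universe,
    water_selection: str = "resname TIP3 TIP3P SOL WAT HOH",
    criterion: HBondCriterion = HBondCriterion(),
) -> np.ndarray:
    """Per-frame water–water hydrogen-bond counts for an MDAnalysis
    Universe (each unordered water pair counted once)."""
    waters = universe.select_atoms(water_selection)
    o_sel = waters.select_atoms("name O OW OH2")
    h_sel = waters.select_atoms("name H H1 H2 HW1 HW2")
    if len(o_sel) == 0:
        raise ConfigurationError("no water oxygens in selection")
    if len(h_sel) != 2 * len(o_sel):
        raise TopologyError(
            f"expected 2 hydrogens per water, found {len(h_sel)} hydrogens "
            f"for {len(o_sel)} oxygens (first water residue: "
            f"{o_sel.residues[0].resname} {o_sel.residues[0].resid})"
        )
    o_res = o_sel.resindices
    h_res = h_sel.resindices
    h_to_donor = np.searchsorted(o_res, h_res)
    counts = []
    for _ in universe.trajectory:
        counts.append(
            count_hbonds(
                o_sel.positions,
                h_sel.positions,
                h_to_donor,
                o_sel.positions,
                criterion=criterion,
                donor_mol=o_res,
                acceptor_mol=o_res,
                unordered_pairs=True,
            )
        )
    return np.asarray(counts, dtype=int)


def pore_lining_residues(
    universe,
    water_selection: str,
    protein_selection: str = "protein",
    cutoff: float = 4.5,
    min_fraction: float = 0.01,
) -> list[int]:
    """Residue indices with any heavy atom within ``cutoff`` of a
    selected water in at least ``min_fraction`` of frames.

    Computed once from the trajectory; an explicit residue list in the
    configuration overrides this heuristic.
    """
    prot = universe.select_atoms(
        f"({protein_selection}) and not name H*")
    waters = universe.select_atoms(water_selection)
    if len(prot) == 0 or len(waters) == 0:
        return []
    n_frames = 0
    hits: dict[int, int] = {}
    for _ in universe.trajectory:
        n_frames += 1
        near = prot.select_atoms(
            f"around {cutoff} group waters", waters=waters)
        for ri in set(near.resindices):
            hits[ri] = hits.get(ri, 0) + 1
    return sorted(
        ri for ri, c in hits.items() if c / n_frames >= min_fraction
    )


@dataclass
class HBondHistogram:
    """Probability histogram of simultaneous hydrogen-bond counts."""

    counts_axis: np.ndarray  # integer bond counts
    probability: np.ndarray  # sums to 1
    kind: str  # "water-water" | "water-protein"
    monomer_id: str = "averaged"
    n_frames: int = 0
    mean: float = 0.0
    criterion: HBondCriterion = field(default_factory=HBondCriterion)

    def __post_init__(self) -> None:
        self.counts_axis = np.asarray(self.counts_axis, dtype=int)
        self.probability = np.asarray(self.probability, dtype=float)
        if abs(self.probability.sum() - 1.0) > 1e-9:
            raise DataError("histogram probabilities must sum to 1")
        if np.any(self.probability < 0):
            raise DataError("probabilities must be non-negative")


def hbond_histogram(
    counts: np.ndarray,
    kind: str,
    monomer_id: str = "averaged",
    criterion: HBondCriterion = HBondCriterion(),
) -> HBondHistogram:
    """Normalized histogram (and mean) of per-frame bond counts."""
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise DataError("need at least one frame of counts")
    axis = np.arange(counts.max() + 1)
    freq = np.bincount(counts, minlength=axis.size).astype(float)
    return HBondHistogram(
        counts_axis=axis,
        probability=freq / counts.size,
        kind=kind,
        monomer_id=monomer_id,
        n_frames=int(counts.size),
        mean=float(counts.mean()),
        criterion=criterion,
    )


def merge_histograms(histograms: Sequence[HBondHistogram],
                     monomer_id: str = "averaged") -> HBondHistogram:
    """Frame-weighted average of per-monomer histograms.

    Equals the histogram of the pooled per-frame counts; the mean is the
    frame-weighted mean of the inputs.
    """
    if not histograms:
        raise DataError("no histograms to merge")
    kinds = {h.kind for h in histograms}
    if len(kinds) != 1:
        raise DataError(f"cannot merge different kinds: {kinds}")
    n_max = max(h.counts_axis.max() for h in histograms)
    axis = np.arange(n_max + 1)
    total_frames = sum(h.n_frames for h in histograms)
    prob = np.zeros(axis.size)
    mean = 0.0
    for h in histograms:
        prob[: h.probability.size] += h.probability * (h.n_frames / total_frames)
        mean += h.mean * (h.n_frames / total_frames)
    return HBondHistogram(
        counts_axis=axis,
        probability=prob,
        kind=histograms[0].kind,
        monomer_id=monomer_id,
        n_frames=total_frames,
        mean=mean,
        criterion=histograms[0].criterion,
    )
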