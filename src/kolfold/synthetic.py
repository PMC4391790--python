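"""Synthetic fixtures: alignments with controlled conservation, toy CA
traces and correlated score tracks.

Everything the analysis modules consume can be generated here, in the
same formats, so the pipeline is exercisable without any external data.
All generators take an explicit seed and are bit-reproducible; none
touches global random state.

The geometry constants mirror real protein backbones where it matters
for the descriptors: consecutive CA-CA distances are exactly 3.81 Å in
every trace, the ideal helix uses the canonical 100° twist per residue
with a 1.52 Å rise (radius ≈ 2.28 Å follows from the chord constraint),
and the extended strand is a planar zigzag with a 6.5 Å i→i+2 span.
These fixtures are idealized: no side chains, no sterics, no
evolutionary model behind the alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from kolfold.msa import AMINO_ACIDS, GAP, Msa
from kolfold.structure import CaTrace, make_trace

#: Consecutive CA-CA distance (Å) in all generated traces.
CA_CA_DISTANCE = 3.81

#: Ideal-helix geometry: 100 degrees of twist per residue, 1.52 Å rise;
#: the radius follows from requiring the CA-CA chord to be exactly 3.81 Å.
HELIX_TWIST_DEG = 100.0
HELIX_RISE = 1.52
HELIX_RADIUS = float(
    np.sqrt(CA_CA_DISTANCE**2 - HELIX_RISE**2)
    / (2.0 * np.sin(np.deg2rad(HELIX_TWIST_DEG / 2.0)))
)

#: Extended strand: i -> i+2 span of the planar zigzag.
STRAND_SPAN = 6.5


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column effective residue-type count k (1 = fully conserved,
    20 = uniform over all amino acids), with an optional Dirichlet
    concentration for non-uniform type frequencies within each column's
    chosen set (None = exactly uniform)."""

    k: tuple[int, ...]
    concentration: float | None = None

    def __post_init__(self) -> None:
        if not self.k:
            raise ValueError("empty profile")
        for k in self.k:
            if not 1 <= k <= 20:
                raise ValueError(f"k must be in 1..20, got {k}")
        if self.concentration is not None and self.concentration <= 0:
            raise ValueError("concentration must be positive")

    @classmethod
    def constant(cls, length: int, k: int, concentration: float | None = None):
        return cls(k=(k,) * length, concentration=concentration)


def synth_msa(
    length: int,
    n_seqs: int,
    profile: ConservationProfile,
    gap_rate: float = 0.0,
    seed: int = 0,
) -> Msa:
    """Alignment with i.i.d. columns of controlled conservation.

    Column j draws its residues from ``profile.k[j]`` randomly chosen
    residue types (uniformly within the set, or with Dirichlet-sampled
    frequencies when a concentration is given); gaps then replace
    residues independently at *gap_rate*.
    """
    if len(profile.k) != length:
        raise ValueError(
            f"profile length {len(profile.k)} != alignment length {length}"
        )
    if not 0 <= gap_rate < 1:
        raise ValueError(f"gap_rate must be in [0, 1), got {gap_rate}")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    columns = np.empty((length, n_seqs), dtype="<U1")
    for j, k in enumerate(profile.k):
        types = rng.choice(aa, size=k, replace=False)
        if profile.concentration is None or k == 1:
            probs = np.full(k, 1.0 / k)
        else:
            probs = rng.dirichlet(np.full(k, profile.concentration))
        columns[j] = rng.choice(types, size=n_seqs, p=probs)
    if gap_rate > 0:
        gaps = rng.random((length, n_seqs)) < gap_rate
        columns[gaps] = GAP
    rows = tuple("".join(columns[:, s]) for s in range(n_seqs))
    ids = tuple(f"seq{s + 1}" for s in range(n_seqs))
    return Msa(ids=ids, rows=rows)


def _random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20.0, 20.0, size=3)
    return R, t


def synth_helix_trace(n_res: int, seed_offset: int = 0) -> CaTrace:
    """Ideal alpha-helical CA trace with exact 3.81 Å CA-CA distances.

    ``seed_offset=0`` leaves the helix on the canonical z-axis frame; a
    nonzero offset applies a reproducible random rigid transform.
    """
    if n_res < 3:
        raise ValueError(f"need at least 3 residues, got {n_res}")
    i = np.arange(n_res)
    theta = np.deg2rad(HELIX_TWIST_DEG) * i
    coords = np.column_stack(
        [
            HELIX_RADIUS * np.cos(theta),
            HELIX_RADIUS * np.sin(theta),
            HELIX_RISE * i,
        ]
    )
    if seed_offset:
        R, t = _random_rigid_transform(np.random.default_rng(seed_offset))
        coords = coords @ R.T + t
    return make_trace(coords)


def synth_extended_trace(n_res: int) -> CaTrace:
    """Extended-strand CA trace: planar zigzag, CA-CA 3.81 Å, i->i+2 6.5 Å."""
    if n_res < 3:
        raise ValueError(f"need at least 3 residues, got {n_res}")
    half_span = STRAND_SPAN / 2.0
    amplitude = float(np.sqrt(CA_CA_DISTANCE**2 - half_span**2) / 2.0)
    i = np.arange(n_res)
    coords = np.column_stack(
        [
            half_span * i,
            amplitude * np.where(i % 2 == 0, 1.0, -1.0),
            np.zeros(n_res),
        ]
    )
    return make_trace(coords)


def synth_globule_trace(n_res: int, seed: int = 0, min_clearance: float = 3.5) -> CaTrace:
    """Compact random-walk CA trace with 3.81 Å steps.

    Steps are drawn isotropically with a bias back toward the origin
    (keeping the walk globular) and rejected if they approach any prior
    CA closer than *min_clearance*.
    """
    if n_res < 3:
        raise ValueError(f"need at least 3 residues, got {n_res}")
    rng = np.random.default_rng(seed)
    coords = [np.zeros(3)]
    while len(coords) < n_res:
        current = coords[-1]
        for _ in range(200):
            direction = rng.normal(size=3)
            direction -= 0.05 * current  # drift toward origin
            direction /= np.linalg.norm(direction)
            candidate = current + CA_CA_DISTANCE * direction
            prior = np.array(coords[:-1]) if len(coords) > 1 else None
            if prior is None or np.min(
                np.linalg.norm(prior - candidate, axis=1)
            ) >= min_clearance:
                coords.append(candidate)
                break
        else:
            # dead end: accept the last candidate to guarantee termination
            coords.append(candidate)
    return make_trace(np.array(coords))


def synth_hinge_pair(
    trace: CaTrace,
    hinge_index: int,
    angle_deg: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    axis: np.ndarray | None = None,
) -> tuple[CaTrace, CaTrace]:
    """A/I conformational pair: one domain rotated about a hinge.

    Residues after *hinge_index* (1-based) in the I copy are rotated by
    *angle_deg* about *axis* (default z) through the hinge CA, emulating
    a domain switch; independent isotropic Gaussian noise of *noise_sd*
    Å is then added to both copies.  A residue at perpendicular distance
    r from the axis moves by the chord ``2 r sin(angle/2)``.
    """
    if not 1 < hinge_index < trace.length:
        raise ValueError(
            f"hinge_index must be inside 2..{trace.length - 1}, got {hinge_index}"
        )
    rng = np.random.default_rng(seed)
    axis = np.array([0.0, 0.0, 1.0]) if axis is None else np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    coords_i = trace.coords.copy()
    if angle_deg != 0.0:
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
        pivot = trace.coords[hinge_index - 1]
        moving = slice(hinge_index, None)  # 0-based: residues after the hinge
        coords_i[moving] = (coords_i[moving] - pivot) @ R.T + pivot
    coords_a = trace.coords.copy()
    if noise_sd > 0:
        coords_a = coords_a + rng.normal(0.0, noise_sd, coords_a.shape)
        coords_i = coords_i + rng.normal(0.0, noise_sd, coords_i.shape)
    return (
        CaTrace(residue_ids=trace.residue_ids, coords=coords_a),
        CaTrace(residue_ids=trace.residue_ids, coords=coords_i),
    )


def axis_distance(
    points: np.ndarray, pivot: np.ndarray, axis: np.ndarray
) -> np.ndarray:
    """Perpendicular distance of each point from the line (pivot, axis)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    rel = np.atleast_2d(points) - np.asarray(pivot, float)
    return np.linalg.norm(np.cross(rel, axis), axis=1)


def synth_correlated_tracks(
    n: int, rho: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal track pair with population correlation *rho*:
    ``y = rho * x + sqrt(1 - rho^2) * eps``."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [-1, 1], got {rho}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    y = rho * x + np.sqrt(1.0 - rho**2) * eps
    return x, y
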