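"""Per-residue structural descriptors from CA traces.

* **HST(C)** encoding of secondary structure: Sheet=1, Helix=2,
  3_10-helix=3, Turn=4, Coil=5.
* **HST(D)** ("differentiated"): HST with the first and last residues of
  every maximal sheet run set to 0 and of every helix run to 0.5, so SSE
  termini stand out as "antispikes" below the rest of the track.
* **AREA**: area (Å²) of the triangle spanned by CA(i), CA(i+2) and the
  protein's centre of gravity — a scalar proxy for local backbone
  geometry (compact helices give small areas, extended strands and coil
  give large ones).
* **Contact maps** from CA-CA distances.
* **DISP**: per-residue CA displacement between two cognate
  conformations (e.g. active vs inactive) after optional rigid
  superposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

log = logging.getLogger(__name__)

#: HST(C) numeric code table.
HST_CODES = {"S": 1.0, "H": 2.0, "G": 3.0, "T": 4.0, "C": 5.0}

#: HST(D) terminus values for sheet and helix runs.
HSTD_TERMINUS = {"S": 0.0, "H": 0.5}

#: DSSP letter -> HST letter. B (isolated bridge), I (pi helix), S (bend)
#: and blank/other all map to coil.
DSSP_TO_HST = {"E": "S", "H": "H", "G": "G", "T": "T"}


@dataclass(frozen=True)
class CaTrace:
    """Ordered CA coordinates (Å) of one chain.

    ``residue_ids[k]`` is ``(chain_id, residue_number, insertion_code)``
    for ``coords[k]``.
    """

    residue_ids: tuple[tuple[str, int, str], ...]
    coords: np.ndarray  # (L, 3) float64

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (L, 3), got {coords.shape}")
        if len(self.residue_ids) != coords.shape[0]:
            raise ValueError(
                f"{len(self.residue_ids)} residue ids but {coords.shape[0]} coordinates"
            )
        object.__setattr__(self, "coords", coords)

    @property
    def length(self) -> int:
        return self.coords.shape[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CaTrace":
        """Return a copy with ``x -> R x + t`` applied to every CA."""
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return CaTrace(residue_ids=self.residue_ids, coords=new)


@dataclass(frozen=True)
class ContactMap:
    """Symmetric boolean relation over residue pairs ``(i, j)``, 1-based, i < j."""

    L: int
    contacts: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for i, j in self.contacts:
            if not (1 <= i < j <= self.L):
                raise ValueError(f"invalid pair ({i}, {j}) for L={self.L}")

    @property
    def n_pairs(self) -> int:
        """Size of the pair universe i < j."""
        return self.L * (self.L - 1) // 2


def make_trace(coords: np.ndarray, chain: str = "A", start: int = 1) -> CaTrace:
    """Build a CaTrace from bare coordinates with sequential residue numbers."""
    coords = np.asarray(coords, dtype=float)
    ids = tuple((chain, start + k, "") for k in range(coords.shape[0]))
    return CaTrace(residue_ids=ids, coords=coords)


def read_ca_trace(
    pdb_path: str | Path, chain: str | None = None, model_index: int = 0
) -> CaTrace:
    """Read the CA trace of one chain from a PDB file.

    Uses the first model by default and the highest-occupancy altloc for
    each CA; residues without a CA atom are skipped with a warning.
    """
    structure = gemmi.read_structure(str(pdb_path))
    if len(structure) == 0:
        raise ValueError(f"{pdb_path}: no models")
    model = structure[model_index]
    available = [ch.name for ch in model]
    if chain is None:
        if len(available) != 1:
            raise ValueError(
                f"{pdb_path}: multiple chains {available}, specify one"
            )
        chain = available[0]
    if chain not in available:
        raise ValueError(
            f"{pdb_path}: chain {chain!r} not found; available chains: {available}"
        )
    ids: list[tuple[str, int, str]] = []
    coords: list[list[float]] = []
    for residue in model[chain]:
        best = None
        for atom in residue:
            if atom.name == "CA":
                if best is None or atom.occ > best.occ:
                    best = atom
        if best is None:
            log.warning(
                "%s: residue %s %s has no CA atom, skipped",
                pdb_path, chain, residue.seqid.num,
            )
            continue
        icode = residue.seqid.icode.strip()
        ids.append((chain, residue.seqid.num, icode))
        coords.append([best.pos.x, best.pos.y, best.pos.z])
    if not coords:
        raise ValueError(f"{pdb_path}: chain {chain!r} has no CA atoms")
    return CaTrace(residue_ids=tuple(ids), coords=np.array(coords))


def write_ca_pdb(trace: CaTrace, path: str | Path) -> None:
    """Write a minimal CA-only PDB file for *trace*."""
    with open(path, "w") as fh:
        for serial, ((chain, resnum, icode), xyz) in enumerate(
            zip(trace.residue_ids, trace.coords), start=1
        ):
            fh.write(
                f"ATOM  {serial:5d}  CA  ALA {chain:1s}{resnum:4d}{icode or ' ':1s}"
                f"   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"           C\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Secondary-structure encoding


def dssp_to_hst(letters: str) -> str:
    """Map DSSP letters to the HST alphabet (E->S, H->H, G->G, T->T, else C)."""
    return "".join(DSSP_TO_HST.get(c, "C") for c in letters.upper())


def hst_encode(ss_letters: str) -> np.ndarray:
    """Numeric HST track: S=1, H=2, G=3, T=4, C=5."""
    if not ss_letters:
        raise ValueError("empty secondary-structure string")
    try:
        return np.array([HST_CODES[c] for c in ss_letters.upper()])
    except KeyError as exc:
        raise ValueError(
            f"letter {exc.args[0]!r} is not in the HST alphabet SHGTC; "
            "map DSSP input with dssp_to_hst() first"
        ) from None


def _maximal_runs(letters: str) -> Iterable[tuple[str, int, int]]:
    """Yield (letter, start, end) of maximal runs, 0-based inclusive ends."""
    start = 0
    for k in range(1, len(letters) + 1):
        if k == len(letters) or letters[k] != letters[start]:
            yield letters[start], start, k - 1
            start = k


def hst_differentiate(
    ss_letters: str, terminus_values: dict[str, float] | None = None
) -> np.ndarray:
    """HST(D) track: HST with SSE-terminus residues re-valued.

    The first and last residues of every maximal run of S become 0 and
    of every run of H become 0.5 (a length-1 run receives the terminus
    value once).  *terminus_values* can extend the rule to G/T runs.
    """
    values = hst_encode(ss_letters)
    terminus = HSTD_TERMINUS if terminus_values is None else terminus_values
    letters = ss_letters.upper()
    for letter, start, end in _maximal_runs(letters):
        if letter in terminus:
            values[start] = terminus[letter]
            values[end] = terminus[letter]
    return values


# ---------------------------------------------------------------------------
# CA-trace geometry


def center_of_gravity(trace: CaTrace) -> np.ndarray:
    """Unweighted centroid of the CA coordinates."""
    return trace.coords.mean(axis=0)


def triangle_area_track(trace: CaTrace, cg: np.ndarray | None = None) -> np.ndarray:
    """AREA track: triangle (CA_i, CA_{i+2}, CG) areas in Å².

    Reported at position i for i = 1 .. L-2 (a slight rightward offset
    relative to the residue axis, since the triangle spans i .. i+2).
    Collinear triples give area 0.
    """
    if trace.length < 3:
        raise ValueError(f"need at least 3 residues, got {trace.length}")
    if cg is None:
        cg = center_of_gravity(trace)
    a = trace.coords[:-2]
    b = trace.coords[2:]
    cross = np.cross(b - a, cg - a)
    return 0.5 * np.linalg.norm(cross, axis=1)


def contact_map_from_structure(
    trace: CaTrace, cutoff: float = 8.0, min_separation: int = 1
) -> ContactMap:
    """Contacts: pairs (i, j) with ||CA_i - CA_j|| <= cutoff, j - i >= min_separation.

    With the default ``min_separation=1`` the pair universe is all i < j
    pairs, of size L(L-1)/2.
    """
    if trace.length < 2:
        raise ValueError("need at least 2 residues")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dists = squareform(pdist(trace.coords))
    contacts = set()
    L = trace.length
    for i in range(L):
        for j in range(i + min_separation, L):
            if dists[i, j] <= cutoff:
                contacts.add((i + 1, j + 1))
    return ContactMap(L=L, contacts=frozenset(contacts))


def superpose(
    trace_a: CaTrace, trace_i: CaTrace, fit_positions: Sequence[int] | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of *trace_i* onto *trace_a*.

    Solves the orthogonal-Procrustes problem (Kabsch) for the optimal
    rotation R and translation t minimizing ||A - (R I + t)||; returns
    ``(R, t, rmsd)`` where rmsd is over the fitted positions.
    *fit_positions* (1-based) restricts the fit to a subset — e.g. a
    static domain — while the transform still applies to every residue.
    """
    if trace_a.length != trace_i.length:
        raise ValueError(
            f"length mismatch: {trace_a.length} vs {trace_i.length}"
        )
    if fit_positions is None:
        A = trace_a.coords
        I = trace_i.coords
    else:
        idx = np.asarray(fit_positions, dtype=int) - 1
        A = trace_a.coords[idx]
        I = trace_i.coords[idx]
    if A.shape[0] < 3:
        raise ValueError("need at least 3 fitted positions for a rigid fit")
    centroid_a = A.mean(axis=0)
    centroid_i = I.mean(axis=0)
    rot, rssd = Rotation.align_vectors(A - centroid_a, I - centroid_i)
    R = rot.as_matrix()
    t = centroid_a - R @ centroid_i
    rmsd = rssd / np.sqrt(A.shape[0])
    return R, t, float(rmsd)


def displacement_track(
    trace_a: CaTrace,
    trace_i: CaTrace,
    superpose_first: bool = True,
    fit_positions: Sequence[int] | None = None,
) -> np.ndarray:
    """DISP track: per-residue CA displacement (Å) between cognate structures.

    ``DISP_i = ||CA_i^A - T(CA_i^I)||`` where T is the rigid
    superposition of I onto A (applied by default; *fit_positions*
    restricts the fit, e.g. to a static domain).  With
    ``superpose_first=False`` raw coordinates are compared.
    """
    if trace_a.length != trace_i.length:
        raise ValueError(
            f"length mismatch: A has {trace_a.length} residues, I has {trace_i.length}"
        )
    coords_i = trace_i.coords
    if superpose_first:
        R, t, _ = superpose(trace_a, trace_i, fit_positions=fit_positions)
        coords_i = coords_i @ R.T + t
    return np.linalg.norm(trace_a.coords - coords_i, axis=1)


def difference_track(
    track_a: Sequence[float | None], track_i: Sequence[float | None]
) -> list[float | None]:
    """Elementwise |A - I| for paired per-residue tracks.

    Used for accessibility (OACC = |OACA - OACI|) and B-value
    (BVLC = |BVLA - BVLI|) differences.  Positions where either input
    is ``None`` (missing) stay ``None``.
    """
    if len(track_a) != len(track_i):
        raise ValueError(
            f"length mismatch: {len(track_a)} vs {len(track_i)}"
        )
    return [
        None if a is None or b is None else abs(a - b)
        for a, b in zip(track_a, track_i)
    ]
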