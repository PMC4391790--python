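"""Pairwise correlation of per-residue tracks.

Sequence-derived scores (ENT/VAR/KOL) are compared against
structure-derived tracks (AREA, B-values, accessibilities, DISP,
HST/HSTD) position by position.  Because a sequence score can track the
*tempo* of a structural signal while running in the opposite sense,
reports default to the absolute value of the Pearson coefficient;
signed values and Spearman rank correlation are available.

Tracks are dicts ``{position: value}`` with 1-based positions; any
per-position sequence (list/array) is accepted and converted, ``None``
marking missing values.  Pairing uses pairwise deletion and supports an
integer lag to compensate for tracks reported at an offset position
(e.g. the AREA triangle spans residues i..i+2 but is reported at i).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TrackPair:
    """Aligned values of two tracks at their common defined positions."""

    positions: tuple[int, ...]
    x: np.ndarray
    y: np.ndarray

    @property
    def n(self) -> int:
        return len(self.positions)


def as_track(values: Mapping[int, float] | Sequence[float | None]) -> dict[int, float]:
    """Coerce a per-position sequence or mapping to ``{position: value}``.

    Sequences are assumed to start at position 1; ``None``/NaN entries
    are treated as missing and dropped.
    """
    if isinstance(values, Mapping):
        items = values.items()
    else:
        items = enumerate(values, start=1)
    track = {}
    for pos, v in items:
        if v is None:
            continue
        v = float(v)
        if np.isnan(v):
            continue
        track[int(pos)] = v
    return track


def pair_tracks(
    x: Mapping[int, float] | Sequence[float | None],
    y: Mapping[int, float] | Sequence[float | None],
    lag: int = 0,
) -> TrackPair:
    """Pair ``(x_i, y_{i+lag})`` over positions defined in both tracks."""
    tx = as_track(x)
    ty = as_track(y)
    positions = sorted(p for p in tx if (p + lag) in ty)
    if len(positions) < 3:
        raise ValueError(
            f"only {len(positions)} overlapping positions (need >= 3)"
        )
    return TrackPair(
        positions=tuple(positions),
        x=np.array([tx[p] for p in positions]),
        y=np.array([ty[p + lag] for p in positions]),
    )


def correlation(
    pair: TrackPair, mode: str = "absolute", method: str = "pearson"
) -> float | None:
    """Correlation coefficient of a track pair.

    ``method`` is ``"pearson"`` (product-moment, default) or
    ``"spearman"`` (rank).  ``mode="absolute"`` (default) returns |r|;
    ``"signed"`` returns r.  Returns ``None`` (undefined) when either
    track has zero variance.
    """
    if mode not in ("absolute", "signed"):
        raise ValueError(f"mode must be 'absolute' or 'signed', got {mode!r}")
    if np.ptp(pair.x) == 0 or np.ptp(pair.y) == 0:
        return None
    if method == "pearson":
        r = stats.pearsonr(pair.x, pair.y).statistic
    elif method == "spearman":
        r = stats.spearmanr(pair.x, pair.y).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return abs(float(r)) if mode == "absolute" else float(r)


def correlation_report(
    tracks: Mapping[str, Mapping[int, float] | Sequence[float | None]],
    pairs: Iterable[tuple[str, str, int]],
    mode: str = "absolute",
    method: str = "pearson",
) -> list[dict]:
    """One row per requested (x-name, y-name, lag) triple.

    Each row carries ``x``, ``y``, ``lag``, ``n`` and ``r`` (``None``
    when undefined).  Unknown track names raise KeyError.
    """
    report = []
    for x_name, y_name, lag in pairs:
        for name in (x_name, y_name):
            if name not in tracks:
                raise KeyError(
                    f"unknown track {name!r}; available: {sorted(tracks)}"
                )
        pair = pair_tracks(tracks[x_name], tracks[y_name], lag=lag)
        r = correlation(pair, mode=mode, method=method)
        report.append(
            {"x": x_name, "y": y_name, "lag": lag, "n": pair.n, "r": r}
        )
    return report


def write_correlation_tsv(report: Iterable[dict], path: str | Path) -> None:
    """Write a correlation report as TSV: ``x y lag n r`` ('.' = undefined)."""
    with open(path, "w") as fh:
        fh.write("x\ty\tlag\tn\tr\n")
        for row in report:
            r = "." if row["r"] is None else f"{row['r']:.4f}"
            fh.write(f"{row['x']}\t{row['y']}\t{row['lag']}\t{row['n']}\t{r}\n")
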