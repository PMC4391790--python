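"""Box-filter contact prediction and its evaluation.

Residue positions whose complexity scores fall inside configured bounds
("boxes") are taken as fold-preserving positions; every pair of passing
positions is predicted to be in contact.  Two published box choices:

* VAR/ENT box ("1:2 box"): 0.5 <= VAR <= 1.5 and 50 <= ENT <= 60.
* KOL box: 1.5 <= KOL <= 3.5.

Both are configuration, not constants — the right bounds depend on the
score convention of the upstream alignment pipeline.  Predictions are
scored against an experimental contact map with the standard 2x2
confusion counts and the Matthews correlation coefficient
``MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``.

:func:`load_reference_confusions` ships the published confusion counts
for box-filter predictions on 20 conformational-pair chains (both
methods), usable as exact arithmetic fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from kolfold.complexity import FLAG_OK, ComplexityRecord
from kolfold.structure import ContactMap

#: Published default box bounds per score.
DEFAULT_BOXES = {
    "var": (0.5, 1.5),
    "ent": (50.0, 60.0),
    "kol": (1.5, 3.5),
}


@dataclass(frozen=True)
class ScoreFilter:
    """Inclusive bounds on one complexity score ('var', 'ent' or 'kol')."""

    score: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.score not in ("var", "ent", "kol"):
            raise ValueError(f"unknown score {self.score!r}")
        if self.lower > self.upper:
            raise ValueError(
                f"lower bound {self.lower} exceeds upper bound {self.upper}"
            )

    def accepts(self, value: float | None) -> bool:
        return value is not None and self.lower <= value <= self.upper


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts over the residue-pair universe."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def mcc(self) -> float:
        return mcc(self)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient of a 2x2 confusion matrix.

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``, with the
    four marginal sums formed before multiplication so large counts do
    not overflow.  If any marginal is zero the coefficient is undefined
    and 0.0 is returned (standard convention).
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    s1, s2, s3, s4 = tp + fp, tp + fn, tn + fp, tn + fn
    if 0 in (s1, s2, s3, s4):
        return 0.0
    denom = math.sqrt(s1) * math.sqrt(s2) * math.sqrt(s3) * math.sqrt(s4)
    return (tp * tn - fp * fn) / denom


def passing_positions(
    track: Sequence[ComplexityRecord],
    filters: Iterable[ScoreFilter],
    combine: str = "all",
) -> set[int]:
    """Positions whose scores fall inside the filter boxes.

    ``combine="all"`` (default) requires every filter to accept;
    ``"any"`` requires at least one.  Flagged-undefined positions never
    pass.
    """
    filters = list(filters)
    if not filters:
        raise ValueError("at least one filter is required")
    if combine not in ("all", "any"):
        raise ValueError(f"combine must be 'all' or 'any', got {combine!r}")
    op = all if combine == "all" else any
    passing = set()
    for record in track:
        if record.flag != FLAG_OK:
            continue
        values = {"var": record.var, "ent": record.ent, "kol": record.kol}
        if op(f.accepts(values[f.score]) for f in filters):
            passing.add(record.position)
    return passing


def predict_contacts(positions: set[int], L: int) -> ContactMap:
    """Predicted map: all pairs (i, j), i < j, of passing positions."""
    bad = {p for p in positions if not 1 <= p <= L}
    if bad:
        raise ValueError(f"positions {sorted(bad)} outside 1..{L}")
    ordered = sorted(positions)
    contacts = frozenset(
        (ordered[a], ordered[b])
        for a in range(len(ordered))
        for b in range(a + 1, len(ordered))
    )
    return ContactMap(L=L, contacts=contacts)


def confusion(
    pred: ContactMap,
    actual: ContactMap,
    mask: set[int] | None = None,
) -> ConfusionCounts:
    """Confusion counts of *pred* against *actual* over the pair universe.

    Pairs touching a position in *mask* are excluded from all four
    counts (used when some positions have no defined score).  Without a
    mask the counts sum to L(L-1)/2.
    """
    if pred.L != actual.L:
        raise ValueError(f"length mismatch: {pred.L} vs {actual.L}")
    mask = mask or set()
    tp = fp = fn = tn = 0
    for i in range(1, pred.L + 1):
        if i in mask:
            continue
        for j in range(i + 1, pred.L + 1):
            if j in mask:
                continue
            pair = (i, j)
            p = pair in pred.contacts
            a = pair in actual.contacts
            if p and a:
                tp += 1
            elif p:
                fp += 1
            elif a:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def load_reference_confusions() -> list[dict]:
    """Published confusion counts for 20 chains x 2 box-filter methods.

    Each entry has keys ``protein`` (PDB id + chain), ``method``
    (``VRN`` = VAR/ENT box, ``KLM`` = KOL box), ``counts``
    (:class:`ConfusionCounts`) and ``reported_mcc`` (the published
    4-decimal MCC).  The counts serve as exact inputs for MCC
    arithmetic and pair-universe checks.
    """
    text = (
        resources.files("kolfold").joinpath("data/contact_benchmark.tsv").read_text()
    )
    rows = []
    lines = text.strip().splitlines()
    for line in lines[1:]:
        protein, method, tp, fp, fn, tn, reported = line.split("\t")
        rows.append(
            {
                "protein": protein,
                "method": method,
                "counts": ConfusionCounts(
                    tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn)
                ),
                "reported_mcc": float(reported),
            }
        )
    return rows


def write_confusion_tsv(
    rows: Iterable[tuple[str, str, ConfusionCounts]], path: str | Path
) -> None:
    """Write ``protein method tp fp fn tn mcc`` rows as TSV."""
    with open(path, "w") as fh:
        fh.write("protein\tmethod\ttp\tfp\tfn\ttn\tmcc\n")
        for protein, method, c in rows:
            fh.write(
                f"{protein}\t{method}\t{c.tp}\t{c.fp}\t{c.fn}\t{c.tn}\t{c.mcc:.4f}\n"
            )


def contact_map_text(cmap: ContactMap, width: int | None = None) -> str:
    """Plain-text matrix rendering of a contact map ('#' contact, '.' none)."""
    width = width or cmap.L
    lines = []
    for i in range(1, min(cmap.L, width) + 1):
        row = []
        for j in range(1, min(cmap.L, width) + 1):
            if i == j:
                row.append("\\")
            else:
                pair = (min(i, j), max(i, j))
                row.append("#" if pair in cmap.contacts else ".")
        lines.append("".join(row))
    return "\n".join(lines)
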