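"""End-to-end orchestration: alignment -> complexity tracks -> structure
tracks -> correlations + contact prediction -> TSV reports.

Outputs are a pure function of (config, inputs): every stage is
deterministic, and the run manifest records parameters, package version
and input checksums so any number in the reports can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from kolfold import __version__
from kolfold.complexity import complexity_track, write_complexity_tsv
from kolfold.contacts import (
    DEFAULT_BOXES,
    ScoreFilter,
    confusion,
    passing_positions,
    predict_contacts,
    write_confusion_tsv,
)
from kolfold.correlation import correlation_report, write_correlation_tsv
from kolfold.msa import read_alignment
from kolfold.structure import (
    contact_map_from_structure,
    displacement_track,
    hst_differentiate,
    hst_encode,
    read_ca_trace,
    triangle_area_track,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Inputs and parameters for one pipeline run.

    Filter bounds default to the published boxes (VAR 0.5-1.5,
    ENT 50-60, KOL 1.5-3.5); contact definition defaults to CA-CA
    <= 8.0 Å over all i < j pairs.
    """

    alignment: str | Path
    outdir: str | Path
    dialect: str = "aligned-fasta"
    pdb_a: str | Path | None = None
    pdb_i: str | Path | None = None
    chain_a: str | None = None
    chain_i: str | None = None
    ss: str | None = None  # secondary-structure letter string (HST alphabet)
    min_freq: float = 0.01
    var_bounds: tuple[float, float] = DEFAULT_BOXES["var"]
    ent_bounds: tuple[float, float] = DEFAULT_BOXES["ent"]
    kol_bounds: tuple[float, float] = DEFAULT_BOXES["kol"]
    contact_cutoff: float = 8.0
    min_separation: int = 1
    lag: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name, (lo, hi) in (
            ("var", self.var_bounds), ("ent", self.ent_bounds), ("kol", self.kol_bounds)
        ):
            if lo > hi:
                raise PipelineError(f"config: {name} bounds {lo} > {hi}")
        for name, path in (
            ("alignment", self.alignment), ("pdb_a", self.pdb_a), ("pdb_i", self.pdb_i)
        ):
            if path is not None and not Path(path).exists():
                raise PipelineError(f"config: {name} file {path} does not exist")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every applicable stage; return {output name: path}.

    Structure-dependent stages are skipped with a logged notice when no
    PDB input is given; the complexity TSV is always produced.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    manifest: dict = {
        "version": __version__,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
        },
        "inputs": {},
        "stages": {},
    }
    for name in ("alignment", "pdb_a", "pdb_i"):
        path = getattr(config, name)
        if path is not None:
            manifest["inputs"][name] = {
                "path": str(path), "sha256": _sha256(Path(path))
            }

    # Stage 1: complexity scores
    try:
        msa = read_alignment(config.alignment, dialect=config.dialect)
        records = complexity_track(msa, min_freq=config.min_freq)
    except Exception as exc:
        raise PipelineError(f"complexity stage failed on {config.alignment}: {exc}")
    path = outdir / "complexity.tsv"
    write_complexity_tsv(records, path)
    outputs["complexity"] = path
    manifest["stages"]["complexity"] = {
        "n_seqs": msa.n_seqs, "length": msa.length,
        "positions_scored": sum(1 for r in records if r.flag == "ok"),
    }
    log.info("complexity: %d positions scored", msa.length)

    tracks: dict[str, object] = {
        "var": [r.var for r in records],
        "ent": [r.ent for r in records],
        "kol": [r.kol for r in records],
    }

    # Stage 2: structure tracks
    trace_a = None
    if config.pdb_a is not None:
        try:
            trace_a = read_ca_trace(config.pdb_a, chain=config.chain_a)
            area = triangle_area_track(trace_a)
            tracks["area"] = list(area)
            if config.ss:
                tracks["hst"] = list(hst_encode(config.ss))
                tracks["hstd"] = list(hst_differentiate(config.ss))
            if config.pdb_i is not None:
                trace_i = read_ca_trace(config.pdb_i, chain=config.chain_i)
                tracks["disp"] = list(displacement_track(trace_a, trace_i))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"structure stage failed on {config.pdb_a}: {exc}")
        path = outdir / "structure_tracks.tsv"
        _write_structure_tsv(tracks, path)
        outputs["structure_tracks"] = path
        manifest["stages"]["structure"] = {"length": trace_a.length}
    else:
        log.info("no PDB input: structure-dependent stages skipped")

    # Stage 3: correlations of sequence scores with structure tracks
    if trace_a is not None:
        pairs = []
        for struct_name in ("area", "hst", "hstd", "disp"):
            if struct_name in tracks:
                for score in ("ent", "var", "kol"):
                    pairs.append((struct_name, score, config.lag))
        try:
            report = correlation_report(tracks, pairs)
        except Exception as exc:
            raise PipelineError(f"correlation stage failed: {exc}")
        path = outdir / "correlations.tsv"
        write_correlation_tsv(report, path)
        outputs["correlations"] = path
        manifest["stages"]["correlation"] = {"n_pairs": len(report)}

    # Stage 4: contact prediction + evaluation
    if trace_a is not None:
        try:
            actual = contact_map_from_structure(
                trace_a, cutoff=config.contact_cutoff,
                min_separation=config.min_separation,
            )
            L = trace_a.length
            n_scored = min(len(records), L)
            rows = []
            for method, filters in (
                ("VRN", [ScoreFilter("var", *config.var_bounds),
                         ScoreFilter("ent", *config.ent_bounds)]),
                ("KLM", [ScoreFilter("kol", *config.kol_bounds)]),
            ):
                passing = {
                    p for p in passing_positions(records[:n_scored], filters)
                    if p <= L
                }
                pred = predict_contacts(passing, L)
                rows.append((Path(str(config.pdb_a)).stem, method,
                             confusion(pred, actual)))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"contact stage failed: {exc}")
        path = outdir / "confusion.tsv"
        write_confusion_tsv(rows, path)
        outputs["confusion"] = path
        manifest["stages"]["contacts"] = {
            "pair_universe": actual.n_pairs,
            "actual_contacts": len(actual.contacts),
        }
        log.info("contacts: %d pairs evaluated", actual.n_pairs)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = manifest_path
    return outputs


def _write_structure_tsv(tracks: dict, path: Path) -> None:
    names = [n for n in ("hst", "hstd", "area", "disp") if n in tracks]
    length = max(len(tracks[n]) for n in names)
    with open(path, "w") as fh:
        fh.write("position\t" + "\t".join(names) + "\n")
        for pos in range(1, length + 1):
            row = [str(pos)]
            for n in names:
                values = tracks[n]
                v = values[pos - 1] if pos <= len(values) else None
                row.append("." if v is None else f"{v:.6f}")
            fh.write("\t".join(row) + "\n")
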