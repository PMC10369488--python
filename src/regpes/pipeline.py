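"""End-to-end orchestration: load/simulate -> segment -> select -> REG -> report.

The pipeline mirrors the standard workflow for a partitioned-energy study:
validate the term table (or simulate one), compute the recovery error,
split the total-energy profile into segments, select the minimal geometry
set per segment with the RMSE-calibrated RDP scan, optionally restrict the
terms to an atom subset, and finally run the per-segment REG ranking on
the selected geometries.

All outputs are plain text: delimited tables printed at 6 significant
digits for reading, full-precision JSON alongside for machines, and a run
log recording the package version, the configuration, the seed and every
decision taken (selected points, min-3 overrides, discarded-term counts).
Reruns with the same configuration produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .energy_data import Dataset, read_dataset, read_xyz, recovery_error, write_dataset
from .rdp_select import DEFAULT_STEP, Polyline, select_points
from .reg_core import DEFAULT_R_THRESHOLD, analyze
from .segmentation import split_segments
from .synthetic import GeneratorSpec, generate
from .truncation import filter_terms, sphere_select

__all__ = ["RunConfig", "PipelineError", "RunReport", "run"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""


@dataclass
class RunConfig:
    """Plain-text-serializable configuration of one pipeline run."""

    output_dir: str
    table: str | None = None
    simulate: dict | None = None
    unit: str = "kJ/mol"
    r_threshold: float = DEFAULT_R_THRESHOLD
    rdp_tolerance: float = 0.5
    rdp_step: float = DEFAULT_STEP
    rdp_per_segment: bool = True
    rdp_normalize_x: bool = True
    atoms: list[str] | None = None
    sphere: dict | None = None
    seed: int = 0

    _SCHEMA = {
        "output_dir",
        "table",
        "simulate",
        "unit",
        "r_threshold",
        "rdp_tolerance",
        "rdp_step",
        "rdp_per_segment",
        "rdp_normalize_x",
        "atoms",
        "sphere",
        "seed",
    }

    def __post_init__(self) -> None:
        if (self.table is None) == (self.simulate is None):
            raise ValueError("exactly one of 'table' or 'simulate' must be given")
        if self.atoms is not None and self.sphere is not None:
            raise ValueError("give either an explicit atom list or a sphere spec, not both")
        if self.sphere is not None:
            unknown = set(self.sphere) - {"xyz", "center", "radius"}
            if unknown:
                raise ValueError(f"unknown sphere key(s) {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - cls._SCHEMA
        if unknown:
            raise ValueError(f"unknown configuration key(s) {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"configuration file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class RunReport:
    """Paths and in-memory results of a completed pipeline run."""

    output_dir: Path
    dataset: Dataset
    recovery: dict
    segments: list
    selection: dict
    reg_results: list
    files: list[Path] = field(default_factory=list)


def _to_builtin(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_to_builtin) + "\n")


def _load_input(config: RunConfig) -> Dataset:
    if config.table is not None:
        return read_dataset(config.table, unit=config.unit)
    sim = dict(config.simulate or {})
    model = sim.pop("model")
    grid = sim.pop("grid", None)
    spec = GeneratorSpec(
        model=model,
        grid=tuple(grid) if grid is not None else tuple(np.linspace(0.0, 1.0, 11)),
        params=sim,
        seed=config.seed,
    )
    return generate(spec)


def run(config: RunConfig) -> RunReport:
    """Execute the full workflow described by ``config``.

    Writes segments.json, rdp_scan.csv, rdp_selection.json, a per-segment
    REG table (reg_segment_<k>.csv) plus full-precision reg.json,
    recovery.json and run_log.json into the output directory.  Any stage
    error removes the partial outputs and raises :class:`PipelineError`
    naming the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load"
    try:
        dataset = _load_input(config)

        stage = "subset"
        if config.sphere is not None:
            geometry = read_xyz(config.sphere["xyz"])
            subset = sphere_select(
                geometry, config.sphere["center"], float(config.sphere["radius"])
            )
            dataset = filter_terms(dataset, subset)
        elif config.atoms is not None:
            dataset = filter_terms(dataset, config.atoms)

        stage = "recovery"
        recovery = recovery_error(dataset).as_dict() if dataset.n_terms else None
        path = outdir / "recovery.json"
        _dump_json(recovery, path)
        written.append(path)

        stage = "segmentation"
        segments = split_segments(dataset)
        path = outdir / "segments.json"
        _dump_json([seg.as_dict() for seg in segments], path)
        written.append(path)

        stage = "rdp-selection"
        profile = Polyline(x=dataset.s, y=dataset.e_total)
        scan_lines = ["segment_id,epsilon,n_retained,rmse,retained"]
        per_segment: list[dict] = []
        selected: set[int] = set()
        if config.rdp_per_segment:
            targets = [
                (i, seg.start_index, Polyline(x=dataset.s[seg.slice], y=dataset.e_total[seg.slice]))
                for i, seg in enumerate(segments)
            ]
        else:
            targets = [(0, 0, profile)]
        for seg_id, offset, poly in targets:
            sel = select_points(
                poly,
                config.rdp_tolerance,
                step=config.rdp_step,
                normalize_x=config.rdp_normalize_x,
            )
            entry = sel.as_dict()
            entry["segment_id"] = seg_id
            entry["global_indices"] = [offset + i for i in sel.indices]
            per_segment.append(entry)
            selected.update(entry["global_indices"])
            for row in sel.scan:
                scan_lines.append(
                    f"{seg_id},{row.epsilon:.6g},{len(row.retained)},{row.rmse:.6g},"
                    + " ".join(str(i) for i in row.retained)
                )
        selected_indices = sorted(selected)
        selection = {
            "per_segment": per_segment,
            "selected_indices": selected_indices,
            "n_selected": len(selected_indices),
            "n_original": dataset.n_points,
            "tolerance": config.rdp_tolerance,
        }
        path = outdir / "rdp_selection.json"
        _dump_json(selection, path)
        written.append(path)
        path = outdir / "rdp_scan.csv"
        path.write_text("\n".join(scan_lines) + "\n")
        written.append(path)

        stage = "reg"
        idx = np.asarray(selected_indices, dtype=int)
        reduced = Dataset(
            s=dataset.s[idx],
            e_total=dataset.e_total[idx],
            terms={label: v[idx] for label, v in dataset.terms.items()},
            unit=dataset.unit,
            source=f"{dataset.source} | {len(idx)}/{dataset.n_points} selected points",
        )
        reg_results = analyze(reduced, r_threshold=config.r_threshold)
        path = outdir / "reg.json"
        _dump_json([res.as_dict() for res in reg_results], path)
        written.append(path)
        for res in reg_results:
            lines = ["rank,label,reg,pearson,discarded"]
            for entry in res.entries:
                rank = "" if entry.rank is None else str(entry.rank)
                lines.append(
                    f"{rank},{entry.label},{entry.reg:.6g},{entry.pearson:.6g},"
                    f"{str(entry.discarded).lower()}"
                )
            path = outdir / f"reg_segment_{res.segment_id}.csv"
            path.write_text("\n".join(lines) + "\n")
            written.append(path)

        stage = "log"
        log = {
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "n_points": dataset.n_points,
            "n_terms": dataset.n_terms,
            "n_selected_points": len(selected_indices),
            "min3_overrides": [e["segment_id"] for e in per_segment if e["min3_override"]],
            "discarded_terms": {
                str(res.segment_id): sum(1 for e in res.entries if e.discarded)
                for res in reg_results
            },
            "segment_errors": {
                str(res.segment_id): res.error for res in reg_results if res.error
            },
        }
        path = outdir / "run_log.json"
        _dump_json(log, path)
        written.append(path)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return RunReport(
        output_dir=outdir,
        dataset=dataset,
        recovery=recovery,
        segments=segments,
        selection=selection,
        reg_results=reg_results,
        files=written,
    )
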