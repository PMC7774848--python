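"""End-to-end orchestration: geometry -> BEM -> panel field -> vortex ->
flight exposure -> threshold comparison, with serialized outputs.

The pipeline is deterministic: identical configuration and fixtures produce
byte-identical CSV/JSON outputs (floats are written with 6 significant
digits; the JSON report keeps full precision).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .exposure import BatProperties, ExposureSummary, exposure_summary
from .fixtures import FixtureSet, data_path, reference_fixture_set
from .geometry import CUT_IN_WIND_SPEED, CUT_OUT_WIND_SPEED
from .thresholds import build_report

__all__ = ["RunConfig", "ConfigError", "PipelineError", "load_config", "run_pipeline", "write_outputs"]

FLOAT_FORMAT = "%.6g"


class ConfigError(ValueError):
    """Raised for an invalid run configuration."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and cause."""


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    wind_speeds: tuple[float, ...] = (5.0, 7.5, 10.0)
    bat_speeds: tuple[float, ...] = (0.0, 5.0, -5.0, 10.0, -10.0)
    band_fraction: float = 0.05
    n_paths: int = 6
    path_spacing: float = 0.020  # m
    max_offset: float = 0.100  # m
    min_clearance_target: float = 0.001  # m
    core_growth: float = 1.0
    fixtures: str = "reference"
    output_dir: str = "scratch/run"
    log_level: str = "info"

    def __post_init__(self) -> None:
        if not self.wind_speeds:
            raise ConfigError("at least one wind speed is required")
        for u in self.wind_speeds:
            if not CUT_IN_WIND_SPEED <= u <= CUT_OUT_WIND_SPEED:
                raise ConfigError(
                    f"wind speed {u} m/s outside the operating envelope "
                    f"[{CUT_IN_WIND_SPEED}, {CUT_OUT_WIND_SPEED}] m/s"
                )
        for s in self.bat_speeds:
            if abs(s) > 10.0:
                raise ConfigError(f"bat speed {s} m/s outside the canonical +-10 m/s range")
        if not 0 < self.band_fraction < 1:
            raise ConfigError(f"band fraction must lie in (0, 1), got {self.band_fraction}")
        for name in ("path_spacing", "max_offset", "min_clearance_target"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_paths < 1:
            raise ConfigError("n_paths must be at least 1")
        if self.core_growth < 1:
            raise ConfigError("core growth multiplier must be >= 1")
        if self.fixtures != "reference":
            raise ConfigError(f"unknown fixture set {self.fixtures!r}")


def load_config(path: str | Path | None) -> RunConfig:
    """Read a YAML config file; defaults applied, unknown keys rejected."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("wind_speeds", "bat_speeds"):
        if key in raw:
            raw[key] = tuple(float(v) for v in raw[key])
    return RunConfig(**raw)


@dataclass
class RunBundle:
    """In-memory result of a pipeline run."""

    config: RunConfig
    summary: pd.DataFrame
    exposure: ExposureSummary
    report: dict
    traces: pd.DataFrame
    paths: pd.DataFrame
    log_lines: list[str] = field(default_factory=list)


def _fixture_checksums() -> dict[str, str]:
    data_dir = data_path("MANIFEST.txt").parent
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        for p in sorted(data_dir.iterdir())
    }


def run_pipeline(config: RunConfig, fixture_set: FixtureSet | None = None) -> RunBundle:
    """Execute every stage and collect the artifact bundle."""
    log: list[str] = []

    def stage(name: str):
        log.append(f"stage {name} started")
        return time.perf_counter()

    def done(name: str, t0: float):
        log.append(f"stage {name} finished in {time.perf_counter() - t0:.2f} s")

    try:
        t0 = stage("fixtures")
        fx = fixture_set or reference_fixture_set()
        done("fixtures", t0)
    except Exception as exc:
        raise PipelineError(f"stage fixtures failed: {exc}") from exc

    try:
        t0 = stage("exposure")
        exp = exposure_summary(
            config.wind_speeds,
            fx.planform,
            fx.polars,
            fx.section_shape,
            bat=BatProperties(),
            flight_speeds=config.bat_speeds,
            band_fraction=config.band_fraction,
            core_growth=config.core_growth,
            n_paths=config.n_paths,
            spacing=config.path_spacing,
            max_offset=config.max_offset,
        )
        done("exposure", t0)
    except Exception as exc:
        raise PipelineError(f"stage exposure failed: {exc}") from exc

    try:
        t0 = stage("thresholds")
        report = build_report(exp.table, fx.decompression, fx.blast)
        done("thresholds", t0)
    except Exception as exc:
        raise PipelineError(f"stage thresholds failed: {exc}") from exc

    trace_rows = []
    path_rows = []
    for r in exp.results:
        pid = f"u{r.wind_speed:g}_{r.side}_s{r.bat_speed:+g}_o{r.offset * 1000:.1f}mm"
        tr = r.trace
        for t, p in zip(tr.t[::8], tr.p[::8]):
            trace_rows.append({"path_id": pid, "t_s": t, "p_Pa": p})
        fp = r.path
        for t, (x, y) in zip(fp.t[::8], fp.positions[::8]):
            path_rows.append({"path_id": pid, "t_s": t, "x_m": x, "y_m": y})
    traces = pd.DataFrame(trace_rows)
    paths = pd.DataFrame(path_rows)

    for name, digest in _fixture_checksums().items():
        log.append(f"input {name} sha256:{digest}")

    return RunBundle(
        config=config,
        summary=exp.table,
        exposure=exp,
        report=report,
        traces=traces,
        paths=paths,
        log_lines=log,
    )


def write_outputs(bundle: RunBundle, out_dir: str | Path) -> list[Path]:
    """Serialize the bundle: exposure_summary.csv, traces.csv, paths.csv,
    report.json, run_log.txt.  Numeric CSV columns use fixed 6-significant-
    digit formatting so repeated runs are byte-identical; partial outputs are
    removed if any write fails."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        p = out / "exposure_summary.csv"
        bundle.summary.to_csv(p, index=False, float_format=FLOAT_FORMAT)
        written.append(p)
        p = out / "traces.csv"
        bundle.traces.to_csv(p, index=False, float_format=FLOAT_FORMAT)
        written.append(p)
        p = out / "paths.csv"
        bundle.paths.to_csv(p, index=False, float_format=FLOAT_FORMAT)
        written.append(p)
        p = out / "report.json"
        payload = {"config": asdict(bundle.config), **bundle.report}
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(p)
        p = out / "run_log.txt"
        p.write_text("\n".join(bundle.log_lines) + "\n")
        written.append(p)
    except OSError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return written
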