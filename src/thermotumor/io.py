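"""Configuration files, CSV/JSON result writers and run metadata."""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import ValidationError

from .config import ModelConfig, validate_config
from .results import DamageProfile, SpatiotemporalField

__all__ = ["load_config", "save_config", "write_results", "write_damage", "RunMetadata"]

_CSV_HEADER = (
    "# thermotumor results: r_m [m], t_s [s], T_C [degC], u_m [m], "
    "e [-], sigma_rr_Pa [Pa], q_r_Wm2 [W/m^2]\n"
)


@dataclass
class RunMetadata:
    """Sidecar metadata making a run reproducible bit-for-bit.

    The embedded configuration snapshot can be re-loaded with
    :func:`load_config` to reproduce the run exactly; the timestamp is the
    only field expected to differ between identical runs.
    """

    tool_version: str
    timestamp: str
    config: dict
    diagnostics: dict = dc_field(default_factory=dict)
    warnings: list = dc_field(default_factory=list)

    @classmethod
    def for_run(cls, field: SpatiotemporalField) -> "RunMetadata":
        from . import __version__

        diag = dict(field.diagnostics)
        return cls(
            tool_version=__version__,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            config=field.config_snapshot or {},
            diagnostics=diag,
            warnings=list(diag.pop("warnings", [])),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"
        )


def load_config(path: str | Path) -> ModelConfig:
    """Parse and fully validate a JSON scenario file.

    Keys mirror :class:`~thermotumor.config.ModelConfig` field names exactly;
    unknown keys are rejected with the offending name, and every violated
    range/ordering invariant is reported in one error.
    """
    text = Path(path).read_text()
    try:
        cfg = ModelConfig.model_validate_json(text)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ValueError(f"invalid configuration {path}: {details}") from None
    violations = validate_config(cfg)
    if violations:
        raise ValueError(
            f"invalid configuration {path}: " + "; ".join(violations)
        )
    return cfg


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a scenario as indented JSON (numeric fields round-trip exactly)."""
    Path(path).write_text(config.model_dump_json(indent=2) + "\n")


def write_results(
    field: SpatiotemporalField | Sequence[SpatiotemporalField],
    prefix: str | Path,
    sweep_info: tuple[str, Sequence[float]] | None = None,
) -> list[Path]:
    """Write a run (or sweep) to ``<prefix>.csv`` + ``<prefix>.meta.json``.

    The CSV has a fixed column order, a '#' unit-comment first line, UTF-8,
    Unix newlines and full double precision (values survive a read round
    trip exactly).  Returns the written paths.
    """
    prefix = Path(prefix)
    if isinstance(field, SpatiotemporalField):
        df = field.to_frame()
        meta = RunMetadata.for_run(field)
    else:
        from .simulate import sweep_frame

        parameter, values = sweep_info if sweep_info else ("run", range(len(field)))
        df = sweep_frame(list(field), parameter, list(values))
        meta = RunMetadata.for_run(field[0])
    csv_path = prefix.with_suffix(".csv")
    with open(csv_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_CSV_HEADER)
        df.to_csv(fh, index=False, lineterminator="\n")
    meta_path = prefix.with_suffix(".meta.json")
    meta.write(meta_path)
    return [csv_path, meta_path]


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV written by :func:`write_results` (exact floats)."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_damage(profiles: Sequence[DamageProfile], prefix: str | Path) -> Path:
    """Write damage profiles to ``<prefix>.csv`` (columns r_m, t_s, omega)."""
    prefix = Path(prefix)
    df = pd.concat([p.to_frame() for p in profiles], ignore_index=True)
    csv_path = prefix.with_suffix(".csv")
    with open(csv_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# thermotumor damage: r_m [m], t_s [s], omega [-]\n")
        df.to_csv(fh, index=False, lineterminator="\n")
    return csv_path
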