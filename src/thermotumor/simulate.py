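"""Scenario orchestration: variants, full runs and parameter sweeps."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ModelConfig, ModelVariant
from .inversion import invert_field
from .laplace import transformed_fields
from .results import SpatiotemporalField

__all__ = ["run", "run_variant", "variant_config", "sweep", "sweep_frame"]

log = logging.getLogger(__name__)


def variant_config(config: ModelConfig, variant: ModelVariant | str) -> ModelConfig:
    """Scenario with the constitutive model reduced to the requested variant.

    * ``LS_THERMOELASTIC`` — the full model; the perfusion coefficient is
      forced to zero (the generalized model carries no perfusion term).
    * ``CATTANEO_VERNOTTE`` — thermal moduli zeroed (no dilatation
      coupling), relaxation times kept, no perfusion.
    * ``CLASSICAL_PENNES`` — thermal moduli and relaxation times zeroed;
      the configured perfusion coefficient is honored.
    """
    variant = ModelVariant(variant)
    cfg = config.model_copy(deep=True)
    cfg.model_variant = variant
    if variant is ModelVariant.LS_THERMOELASTIC:
        cfg.perfusion_coeff = 0.0
        return cfg
    cfg.tumor.thermal_modulus = 0.0
    cfg.tissue.thermal_modulus = 0.0
    if variant is ModelVariant.CATTANEO_VERNOTTE:
        cfg.perfusion_coeff = 0.0
    else:  # CLASSICAL_PENNES
        cfg.tumor.relaxation_time = 0.0
        cfg.tissue.relaxation_time = 0.0
    return cfg


def run(
    config: ModelConfig,
    radii: Sequence[float] | None = None,
    times: Sequence[float] | None = None,
) -> SpatiotemporalField:
    """Full pipeline: modal roots → interface amplitudes → fields → inversion."""
    cfg = variant_config(config, config.model_variant)
    r = np.asarray(radii, float) if radii is not None else cfg.geometry.radii()
    t = np.asarray(times, float) if times is not None else cfg.geometry.times()
    log.info(
        "run: variant=%s, %d radii, %d times, t in [%g, %g] s",
        cfg.model_variant.value, len(r), len(t), t.min(), t.max(),
    )
    fields = transformed_fields(cfg)
    out = invert_field(fields, r, t, cfg.inversion)
    diag = out.diagnostics
    log.info(
        "inversion: %d transform evaluations, error estimate %.2e, "
        "conjugate-symmetry residue %.2e",
        diag["n_function_evals"], diag["max_rel_err_estimate"],
        diag["conj_symmetry_residue"],
    )
    for w in diag["warnings"]:
        log.warning("%s", w)
    return out


def run_variant(
    config: ModelConfig,
    variant: ModelVariant | str,
    radii: Sequence[float] | None = None,
    times: Sequence[float] | None = None,
) -> SpatiotemporalField:
    """Run the scenario under a reduced (or the full) constitutive model."""
    return run(variant_config(config, variant), radii, times)


def sweep(
    config: ModelConfig,
    parameter: str,
    values: Sequence[float],
) -> list[SpatiotemporalField]:
    """One run per value of ``parameter`` with everything else fixed.

    ``parameter`` is one of ``"time"`` (evaluation instants — a single run
    evaluated at the given times), ``"irradiance"`` (laser irradiance,
    W·cm⁻²) or ``"relaxation_time"`` (τ0, s, applied to both media).
    """
    values = list(values)
    if not values:
        raise ValueError("sweep requires at least one value")
    if parameter == "time":
        field = run(config, times=np.asarray(sorted(values), float))
        return [field]
    out = []
    for v in values:
        cfg = config.model_copy(deep=True)
        if parameter == "irradiance":
            cfg.source.irradiance = float(v)
        elif parameter == "relaxation_time":
            cfg.tumor.relaxation_time = float(v)
            cfg.tissue.relaxation_time = float(v)
        else:
            raise ValueError(
                "parameter must be 'time', 'irradiance' or 'relaxation_time'"
            )
        log.info("sweep: %s = %g", parameter, v)
        out.append(run(cfg))
    return out


def sweep_frame(
    fields: list[SpatiotemporalField], parameter: str, values: Sequence[float]
) -> pd.DataFrame:
    """Tidy long-format table of a sweep, one row per (value, r, t) point."""
    if len(fields) == 1 and parameter == "time":
        df = fields[0].to_frame()
        df.insert(0, "sweep_parameter", parameter)
        df.insert(1, "sweep_value", df["t_s"])
        return df
    frames = []
    for v, f in zip(values, fields):
        df = f.to_frame()
        df.insert(0, "sweep_parameter", parameter)
        df.insert(1, "sweep_value", float(v))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
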