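"""Tabular/JSON input-output, run configuration and result serialization.

All interchange is plain text: R1ρ datasets as TSV/CSV (either raw decay
intensities or precomputed R1ρ ± error), fit/pKa/flux results as
schema-versioned JSON that records the seed and configuration used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ParseError, ValidationError
from .flux_model import FluxResult
from .pka_titration import PkaFit, TitrationSeries
from .rd_fitting import FitResult, RDDataset, RDRecord
from .spin_dynamics import (
    DEFAULT_ALIGNMENT_THRESHOLD,
    DEFAULT_LARMOR_MHZ,
    DecayCurve,
    ExchangeModel,
    SpinLockCondition,
    fit_monoexponential,
)

__all__ = [
    "RunConfig",
    "load_config",
    "read_rd_table",
    "write_rd_table",
    "read_titration_table",
    "write_results",
    "read_results",
    "exchange_model_to_dict",
    "exchange_model_from_dict",
]

logger = logging.getLogger("wclike")

_INTENSITY_COLS = {"nucleus", "spinlock_hz", "offset_hz", "delay_s", "intensity"}
_R1RHO_COLS = {"nucleus", "spinlock_hz", "offset_hz", "r1rho", "r1rho_err"}


@dataclass
class RunConfig:
    """Pipeline-wide settings; every numeric knob the stages consume."""

    larmor_mhz: float = DEFAULT_LARMOR_MHZ
    alignment_threshold: float = DEFAULT_ALIGNMENT_THRESHOLD
    mc_iterations: int = 500
    seed: int = 0
    ph: float = 7.4
    slope_a: float = float(np.log(10.0))
    max_nfev: int = 400
    delays: tuple[float, ...] = (0.0, 0.04, 0.08, 0.12)

    def __post_init__(self) -> None:
        if self.larmor_mhz <= 0 or self.alignment_threshold <= 0:
            raise ValidationError("larmor_mhz and alignment_threshold must be positive")
        if self.mc_iterations < 0 or self.max_nfev <= 0:
            raise ValidationError("iteration counts must be positive")


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON) config file into a RunConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"unknown config keys: {sorted(unknown)}")
    if "delays" in raw:
        raw["delays"] = tuple(raw["delays"])
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# R1ρ tables
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc


def read_rd_table(
    path: str | Path,
    larmor_mhz: float = DEFAULT_LARMOR_MHZ,
    delays: tuple[float, ...] = (0.0, 0.04, 0.08, 0.12),
    mc_iterations: int = 200,
    seed: int = 0,
) -> RDDataset:
    """Read an R1ρ dataset from TSV/CSV.

    Two schemas are accepted: per-delay decay intensities (columns
    ``nucleus, spinlock_hz, offset_hz, delay_s, intensity[, noise_sd]``),
    which are mono-exponentially fitted per condition here, or precomputed
    rates (``nucleus, spinlock_hz, offset_hz, r1rho, r1rho_err``).  Duplicate
    (nucleus, power, offset) rows in the precomputed schema are kept and
    flagged as replicates.
    """
    df = _read_table(path)
    cols = set(df.columns)
    rng = np.random.default_rng(seed)
    records: list[RDRecord] = []
    if _INTENSITY_COLS <= cols:
        for (nuc, pw, off), grp in df.groupby(
            ["nucleus", "spinlock_hz", "offset_hz"], sort=True
        ):
            noise = None
            if "noise_sd" in cols and grp["noise_sd"].notna().any():
                noise = float(grp["noise_sd"].iloc[0])
            curve = DecayCurve(
                grp["delay_s"].to_numpy(float),
                grp["intensity"].to_numpy(float),
                noise_sd=noise,
            )
            r1rho, sd = fit_monoexponential(curve, mc_iterations, rng)
            cond = SpinLockCondition(float(pw), float(off), delays=tuple(curve.delays),
                                     larmor_mhz=larmor_mhz)
            records.append(RDRecord(str(nuc), cond, float(r1rho), float(max(sd, 1e-6))))
    elif _R1RHO_COLS <= cols:
        bad = df.index[df["r1rho_err"] <= 0]
        if len(bad):
            raise ValidationError(
                f"non-positive r1rho_err at line {int(bad[0]) + 2} of {path}"
            )
        dup = df.duplicated(subset=["nucleus", "spinlock_hz", "offset_hz"], keep=False)
        if dup.any():
            logger.info("%d replicate rows in %s (kept)", int(dup.sum()), path)
        for i, row in df.iterrows():
            try:
                cond = SpinLockCondition(float(row["spinlock_hz"]),
                                         float(row["offset_hz"]),
                                         delays=delays, larmor_mhz=larmor_mhz)
                records.append(RDRecord(str(row["nucleus"]), cond,
                                        float(row["r1rho"]), float(row["r1rho_err"])))
            except (TypeError, ValueError) as exc:
                raise ParseError(f"malformed row at line {int(i) + 2} of {path}: {exc}")
    else:
        missing_a = sorted(_INTENSITY_COLS - cols)
        missing_b = sorted(_R1RHO_COLS - cols)
        raise ParseError(
            f"{path}: header matches neither schema "
            f"(intensity schema missing {missing_a}; rate schema missing {missing_b})"
        )
    ds = RDDataset(records, metadata={"source": str(path)})
    logger.info("read %d records for nuclei %s from %s", len(records), ds.nuclei, path)
    return ds


def write_rd_table(dataset: RDDataset, path: str | Path) -> None:
    """Write a dataset in the precomputed-R1ρ schema (TSV)."""
    dataset.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_titration_table(path: str | Path) -> TitrationSeries:
    """Read a titration series (columns pH, shift_13C_ppm, shift_15N_ppm)."""
    df = _read_table(path)
    need = {"pH", "shift_13C_ppm", "shift_15N_ppm"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    return TitrationSeries(
        ph=df["pH"].to_numpy(float),
        shift_13c=df["shift_13C_ppm"].to_numpy(float),
        shift_15n=df["shift_15N_ppm"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def exchange_model_to_dict(model: ExchangeModel) -> dict:
    return {
        "states": list(model.states),
        "populations": list(model.populations),
        "kex": {f"{a}:{b}": v for (a, b), v in model.kex.items()},
        "delta_omega": {n: dict(t) for n, t in model.delta_omega.items()},
        "r1": model.r1,
        "r2": model.r2,
    }


def exchange_model_from_dict(d: dict) -> ExchangeModel:
    return ExchangeModel(
        states=tuple(d["states"]),
        populations=tuple(d["populations"]),
        kex={tuple(k.split(":")): v for k, v in d.get("kex", {}).items()},
        delta_omega=d.get("delta_omega", {}),
        r1=d.get("r1", 2.0),
        r2=d.get("r2", 16.0),
    )


_KINDS = {"FitResult": FitResult, "PkaFit": PkaFit, "FluxResult": FluxResult}


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_results(result, path: str | Path, *, seed: int | None = None,
                  config: RunConfig | None = None) -> dict:
    """Serialize a FitResult / PkaFit / FluxResult to schema-versioned JSON.

    The payload always records the package version as the schema version and
    the seed/config under which the result was produced; it round-trips
    through :func:`read_results`.
    """
    kind = type(result).__name__
    if kind not in _KINDS:
        raise ValidationError(f"cannot serialize {kind}; expected one of {sorted(_KINDS)}")
    doc = {
        "schema_version": __version__,
        "kind": kind,
        "seed": seed,
        "config": asdict(config) if config is not None else None,
        "payload": _to_jsonable(asdict(result)),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return doc


def read_results(path: str | Path):
    """Reconstruct the result object written by :func:`write_results`."""
    with open(path) as fh:
        doc = json.load(fh)
    kind = doc.get("kind")
    if kind not in _KINDS:
        raise ParseError(f"{path}: unknown result kind {kind!r}")
    payload = doc["payload"]
    cls = _KINDS[kind]
    if kind == "PkaFit":
        payload["residuals"] = np.asarray(payload["residuals"], dtype=float)
    return cls(**payload)
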