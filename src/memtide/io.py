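"""CSV dialects and JSON fit reports.

Titration CSV: columns ``titrant_conc`` (M), ``signal``, optional
``blank``; comma-separated, '.' decimal, header row required.
ITC CSV: columns ``injection_volume_uL``, ``heat_uJ``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import TitrationSeries
from .itc import ITCExperiment
from .spectro import background_subtract

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_itc_csv",
    "write_itc_csv",
    "write_report",
]

TITRATION_COLUMNS = ("titrant_conc", "signal")
ITC_COLUMNS = ("injection_volume_uL", "heat_uJ")


def read_titration_csv(
    path,
    mode: str,
    fixed_species_total: float,
    label: str = "",
) -> TitrationSeries:
    """Read the titration CSV dialect; blank column is subtracted if present."""
    df = pd.read_csv(path)
    missing = [c for c in TITRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found "
            f"{list(df.columns)}"
        )
    signal = df["signal"].to_numpy(dtype=float)
    if "blank" in df.columns:
        signal, _ = background_subtract(
            signal, df["blank"].to_numpy(dtype=float)
        )
    return TitrationSeries(
        mode=mode,
        fixed_species_total=fixed_species_total,
        titrant_totals=df["titrant_conc"].to_numpy(dtype=float),
        signal=signal,
        label=label or str(path),
    )


def write_titration_csv(path, series: TitrationSeries) -> None:
    pd.DataFrame({
        "titrant_conc": series.titrant_totals,
        "signal": series.signal,
    }).to_csv(path, index=False)


def read_itc_csv(
    path,
    peptide_cell_conc: float,
    cell_volume: float = 170e-6,
    syringe_lipid_total: float = 8e-3,
    temperature: float = 298.15,
) -> ITCExperiment:
    df = pd.read_csv(path)
    missing = [c for c in ITC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found "
            f"{list(df.columns)}"
        )
    return ITCExperiment(
        peptide_cell_conc=peptide_cell_conc,
        cell_volume=cell_volume,
        syringe_lipid_total=syringe_lipid_total,
        injection_volumes=df["injection_volume_uL"].to_numpy(float) * 1e-6,
        integrated_heats=df["heat_uJ"].to_numpy(float) * 1e-6,
        temperature=temperature,
    )


def write_itc_csv(path, experiment: ITCExperiment) -> None:
    pd.DataFrame({
        "injection_volume_uL": experiment.injection_volumes * 1e6,
        "heat_uJ": experiment.integrated_heats * 1e6,
    }).to_csv(path, index=False)


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def write_report(path, payload: dict) -> None:
    """Write a self-describing JSON report (dataclasses serialized)."""
    Path(path).write_text(json.dumps(_jsonify(payload), indent=2) + "\n")
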