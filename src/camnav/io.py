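"""Delimited-text readers and writers shared by the CLI and the pipeline.

All on-disk tables are plain CSV with headers.  Concentration columns carry
explicit units in their names (``kd_nM``, ``ca_M`` ...) and are converted to
molar at this boundary; everything in memory is molar.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .ephys import UncagingRecord
from .equilibria import (
    SPECIES,
    SPECIES_WITH_FREE,
    CTermAffinityTable,
    PopulationSurface,
)
from .itc import Thermogram, TitrationProtocol

__all__ = [
    "load_reference_affinities",
    "read_affinity_tables",
    "write_affinity_tables",
    "read_thermogram",
    "write_thermogram",
    "read_uncaging_record",
    "write_uncaging_record",
    "surface_to_frame",
    "write_surface",
]

PathLike = Union[str, Path]

NM_TO_M = 1e-9

_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}


def parse_concentration(value: float, unit: str) -> float:
    """Convert a concentration with an explicit unit label to molar."""
    try:
        return float(value) * _UNIT_FACTORS[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


def _tables_from_frame(df: pd.DataFrame) -> dict[tuple[str, str], CTermAffinityTable]:
    required = {"isoform", "construct", "species", "kd_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"affinity table missing columns: {sorted(missing)}")
    tables: dict[tuple[str, str], CTermAffinityTable] = {}
    for (isoform, construct), group in df.groupby(["isoform", "construct"], sort=False):
        kd = dict(zip(group["species"], group["kd_nM"].astype(float) * NM_TO_M))
        if set(kd) != set(SPECIES):
            raise ValueError(
                f"{isoform}/{construct}: need one row per species {SPECIES}, got {sorted(kd)}"
            )
        tables[(isoform, construct)] = CTermAffinityTable(
            isoform=isoform,
            construct=construct,
            kd_apo=kd["apo"],
            kd_2n=kd["2N"],
            kd_2c=kd["2C"],
            kd_4=kd["4"],
        )
    return tables


def load_reference_affinities(
    as_frame: bool = False,
) -> Union[dict[tuple[str, str], CTermAffinityTable], pd.DataFrame]:
    """The bundled CTerm affinity table (four CaM species x two isoforms x
    Long/Short constructs), measured by ITC.

    Returns a mapping ``(isoform, construct) -> CTermAffinityTable``, or the
    raw :class:`~pandas.DataFrame` (which also carries the measurement errors
    and the published binding free energies) when ``as_frame`` is true.
    """
    with resources.files("camnav.data").joinpath("cterm_affinities.csv").open() as fh:
        df = pd.read_csv(fh)
    return df if as_frame else _tables_from_frame(df)


def read_affinity_tables(path: PathLike) -> dict[tuple[str, str], CTermAffinityTable]:
    """Read affinity tables from CSV (columns: isoform, construct, species, kd_nM)."""
    return _tables_from_frame(pd.read_csv(path))


def write_affinity_tables(
    tables: dict[tuple[str, str], CTermAffinityTable] | list[CTermAffinityTable],
    path: PathLike,
) -> None:
    if isinstance(tables, dict):
        tables = list(tables.values())
    rows = [
        {
            "isoform": t.isoform,
            "construct": t.construct,
            "species": s,
            "kd_nM": t.kds()[i] / NM_TO_M,
        }
        for t in tables
        for i, s in enumerate(SPECIES)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_thermogram(thermogram: Thermogram, path: PathLike) -> None:
    """CSV with a ``#``-prefixed protocol sidecar header followed by
    injection_index, injection_volume_uL, heat_ucal columns."""
    protocol = thermogram.protocol
    lines = [
        f"# cell_volume_L={protocol.cell_volume!r}",
        f"# cell_conc_M={protocol.cell_conc!r}",
        f"# syringe_conc_M={protocol.syringe_conc!r}",
    ]
    df = pd.DataFrame(
        {
            "injection_index": np.arange(1, protocol.n_injections + 1),
            "injection_volume_uL": np.asarray(protocol.injection_volumes) * 1e6,
            "heat_ucal": thermogram.heats,
        }
    )
    Path(path).write_text("\n".join(lines) + "\n" + df.to_csv(index=False))


def _read_sidecar(path: PathLike) -> dict[str, float]:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").strip().partition("=")
            meta[key] = float(value)
    return meta


def read_thermogram(path: PathLike) -> Thermogram:
    meta = _read_sidecar(path)
    df = pd.read_csv(path, comment="#")
    protocol = TitrationProtocol(
        cell_volume=meta["cell_volume_L"],
        cell_conc=meta["cell_conc_M"],
        syringe_conc=meta["syringe_conc_M"],
        injection_volumes=tuple(df["injection_volume_uL"].astype(float) * 1e-6),
    )
    return Thermogram(protocol, tuple(df["heat_ucal"].astype(float)))


def write_uncaging_record(
    record: UncagingRecord, path: PathLike, sweep_interval_s: float = 5.0
) -> None:
    """CSV of sweep_index, time_s, peak_current_pA with uncage_index/n_tail header lines."""
    lines = [f"# uncage_index={record.uncage_index}", f"# n_tail={record.n_tail}"]
    n = len(record.peak_currents)
    df = pd.DataFrame(
        {
            "sweep_index": np.arange(n),
            "time_s": np.arange(n) * sweep_interval_s,
            "peak_current_pA": record.peak_currents,
        }
    )
    Path(path).write_text("\n".join(lines) + "\n" + df.to_csv(index=False))


def read_uncaging_record(path: PathLike) -> UncagingRecord:
    meta = _read_sidecar(path)
    df = pd.read_csv(path, comment="#")
    # Inward (negative) currents are recorded as magnitudes.
    peaks = tuple(abs(float(p)) for p in df["peak_current_pA"])
    return UncagingRecord(
        peaks, uncage_index=int(meta["uncage_index"]), n_tail=int(meta["n_tail"])
    )


def surface_to_frame(surface: PopulationSurface) -> pd.DataFrame:
    """Long-format view of a population surface: ca_M, cam_M, species, fraction."""
    rows = []
    for i, ca in enumerate(surface.ca_grid):
        for j, cam in enumerate(surface.cam_grid):
            for s in SPECIES_WITH_FREE:
                rows.append(
                    {
                        "ca_M": ca,
                        "cam_M": cam,
                        "species": s,
                        "fraction": surface.fractions[s][i, j],
                    }
                )
    return pd.DataFrame(rows)


def write_surface(surface: PopulationSurface, path: PathLike) -> None:
    """Write the long-format table plus a ``<path>.summary.json`` sidecar with
    the model inputs and grid extents."""
    path = Path(path)
    surface_to_frame(surface).to_csv(path, index=False)
    summary = {
        "metadata": surface.metadata,
        "ca_grid_M": {
            "min": float(surface.ca_grid[0]),
            "max": float(surface.ca_grid[-1]),
            "points": int(surface.ca_grid.size),
        },
        "cam_grid_M": {
            "min": float(surface.cam_grid[0]),
            "max": float(surface.cam_grid[-1]),
            "points": int(surface.cam_grid.size),
        },
    }
    path.with_suffix(path.suffix + ".summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
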