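"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` names everything a run depends on -- thermodynamic
constants, which lobe-energy input set to use (``evans_shea`` or ``linse``),
the affinity table (bundled fixture by default, or a CSV path), the
concentration grids, an output directory and a seed.  :func:`run_pipeline`
executes populations -> surface -> dominance scan, writes every table, and
stamps each run with a provenance block (constants, seed, package version,
config hash) so reruns of the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .equilibria import (
    LOBE_ENERGY_SETS,
    CTermAffinityTable,
    ThermoConstants,
    cterm_occupancy,
    dominant_species,
    population_surface,
)
from .io import load_reference_affinities, read_affinity_tables, write_surface

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("camnav")


@dataclass
class RunConfig:
    gas_constant: float = 1.9872e-3
    temperature: float = 298.15
    lobe_energy_source: str = "evans_shea"
    affinity_table_path: Optional[str] = None  # None -> bundled reference table
    isoforms: tuple[str, ...] = ("NaV1.4", "NaV1.5")
    construct: str = "Long"
    ca_min: float = 1e-8
    ca_max: float = 1e-3
    ca_points: int = 50
    cam_min: float = 1e-7
    cam_max: float = 1e-4
    cam_points: int = 50
    cam_fixed: float = 1e-5  # [CaM] for the dominance scan
    output_dir: str = "camnav_out"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.lobe_energy_source not in LOBE_ENERGY_SETS:
            raise ValueError(
                f"unknown lobe-energy source {self.lobe_energy_source!r}; "
                f"choose from {sorted(LOBE_ENERGY_SETS)}"
            )
        self.isoforms = tuple(self.isoforms)
        if self.affinity_table_path is not None and not Path(self.affinity_table_path).exists():
            raise FileNotFoundError(self.affinity_table_path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def constants(self) -> ThermoConstants:
        return ThermoConstants(self.gas_constant, self.temperature)

    def tables(self) -> dict[tuple[str, str], CTermAffinityTable]:
        if self.affinity_table_path is None:
            return load_reference_affinities()
        return read_affinity_tables(self.affinity_table_path)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def ca_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.ca_min), np.log10(self.ca_max), self.ca_points)

    def cam_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.cam_min), np.log10(self.cam_max), self.cam_points)


def run_pipeline(config: RunConfig) -> dict:
    """Populations, surfaces and a dominance scan for every configured isoform.

    Returns the report document (also written to ``report.json`` in the
    output directory).  Any stage failure aborts with a stage-attributed
    logged error.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    constants = config.constants()
    energies = LOBE_ENERGY_SETS[config.lobe_energy_source]
    tables = config.tables()

    provenance = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "seed": config.seed,
        "gas_constant_kcal_per_mol_K": constants.gas_constant,
        "temperature_K": constants.temperature,
        "lobe_energies": {"dg_n": energies.dg_n, "dg_c": energies.dg_c,
                          "source": energies.source_label},
    }
    report: dict = {"provenance": provenance, "stages": {}}

    ca_grid, cam_grid = config.ca_grid(), config.cam_grid()
    for isoform in config.isoforms:
        key = (isoform, config.construct)
        if key not in tables:
            raise KeyError(f"no affinity table for {key}")
        table = tables[key]
        tag = f"{isoform.replace('.', '')}_{config.construct}".lower()

        stage = "populations"
        try:
            occ = cterm_occupancy(config.cam_fixed, config.cam_fixed, table, energies, constants)
            report["stages"].setdefault(stage, {})[isoform] = occ.as_dict()
        except Exception:
            logger.exception("stage %s failed for %s", stage, isoform)
            raise

        stage = "surface"
        try:
            surface = population_surface(ca_grid, cam_grid, table, energies, constants)
            surface.metadata["config_hash"] = provenance["config_hash"]
            write_surface(surface, outdir / f"surface_{tag}.csv")
            report["stages"].setdefault(stage, {})[isoform] = str(outdir / f"surface_{tag}.csv")
        except Exception:
            logger.exception("stage %s failed for %s", stage, isoform)
            raise

        stage = "dominance"
        try:
            scan = []
            for ca in ca_grid:
                occ = cterm_occupancy(ca, config.cam_fixed, table, energies, constants)
                scan.append({"ca_M": float(ca), "dominant": dominant_species(occ)})
            crossovers = [
                {"ca_M": scan[i]["ca_M"], "from": scan[i - 1]["dominant"],
                 "to": scan[i]["dominant"]}
                for i in range(1, len(scan))
                if scan[i]["dominant"] != scan[i - 1]["dominant"]
            ]
            report["stages"].setdefault(stage, {})[isoform] = {
                "cam_M": config.cam_fixed,
                "crossovers": crossovers,
                "dominant_at_extremes": {
                    "low_ca": scan[0]["dominant"],
                    "high_ca": scan[-1]["dominant"],
                },
            }
        except Exception:
            logger.exception("stage %s failed for %s", stage, isoform)
            raise

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    logger.info("pipeline complete: %s", outdir / "report.json")
    return report
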