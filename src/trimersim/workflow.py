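"""Config-driven orchestration of the five simulation pipelines.

A :class:`RunConfig` (loadable from YAML/JSON) selects one of the pipelines:

* ``sim1`` -- minimum FAP per fibroblast for a target effect vs affinity;
* ``sim2`` -- percent of each indication's patients above those thresholds;
* ``sim3`` -- exposure windows vs affinity at a fixed FAP expression;
* ``sim4`` -- per-indication effect distributions at constant 4-1BB;
* ``sim5`` -- clinical dose/schedule grid.

Every output CSV carries a header comment with the config hash and seed, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binding, clinical, effect, population
from .binding import BispecificMolecule, InVitroSystem, reference_molecule
from .clinical import (
    PKParams,
    SCHEDULES,
    dose_schedule_grid,
    sample_patients,
    summarize_optima,
)
from .effect import calibrate_avidity
from .population import (
    INDICATION_PRESETS,
    indication_population,
    population_coverage_table,
    simulate_population,
)

logger = logging.getLogger("trimersim")

SIMULATIONS = ("sim1", "sim2", "sim3", "sim4", "sim5")


@dataclass(frozen=True)
class RunConfig:
    """One reproducible simulation run.

    ``kd_pair`` holds the (reference, enhanced) FAP KDs in nM; ``kd_scan``
    optionally replaces it with a scan range for sim1/sim3.
    """

    simulation: str
    seed: int = 0
    out_dir: str = "results"
    calibration_mode: str = "window-anchor"
    kd_pair: tuple[float, float] = (0.7, 0.07)
    kd_scan: tuple[float, float, int] | None = None  # (lo, hi, n), nM
    target_pct: float = 90.0
    window_pct: float = 50.0
    fap_per_fibroblast: float = binding.COLON_MEDIAN_FAP
    indications: tuple[str, ...] | None = None
    n_virtual: int = 5_000
    n_patients: int = 1_000
    doses: tuple[float, ...] | None = None
    schedules: tuple[str, ...] = ("qw", "q2w", "q3w")
    avidity_factor: float | None = None  # overrides calibration when set

    def __post_init__(self) -> None:
        if self.simulation not in SIMULATIONS:
            raise ValueError(
                f"unknown simulation {self.simulation!r}; expected one of "
                f"{SIMULATIONS}")
        if self.calibration_mode not in ("tc-anchor", "window-anchor"):
            raise ValueError("calibration_mode must be 'tc-anchor' or "
                             "'window-anchor'")
        if self.kd_scan is not None:
            lo, hi, _ = self.kd_scan
            if not 0.001 <= lo < hi <= 10.0:
                raise ValueError("kd_scan must lie within 0.001-10 nM")
        for kd in self.kd_pair:
            if not 0.001 <= kd <= 10.0:
                raise ValueError("kd_pair values must lie within 0.001-10 nM")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML (or JSON) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("kd_pair", "kd_scan", "indications", "doses", "schedules"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def molecule_from_config(raw: dict) -> BispecificMolecule:
    """Build a molecule from a mapping with the type's field names."""
    return BispecificMolecule(**raw)


def system_from_config(raw: dict) -> InVitroSystem:
    raw = dict(raw)
    if "r41bb_profile" in raw and isinstance(raw["r41bb_profile"], dict):
        raw["r41bb_profile"] = binding.FourOneBBProfile(**raw["r41bb_profile"])
    return InVitroSystem(**raw)


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = (f"# trimersim simulation={config.simulation} "
              f"config_sha={config.config_hash()} seed={config.seed}\n")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, lineterminator="\n")
    logger.info("wrote %s (%d rows)", path, len(df))


def _molecules(config: RunConfig) -> dict[str, BispecificMolecule]:
    avidity = (config.avidity_factor if config.avidity_factor is not None
               else calibrate_avidity(config.calibration_mode))
    ref_kd, enh_kd = config.kd_pair
    return {
        "reference": BispecificMolecule(kd_fap=ref_kd,
                                        avidity_factor=avidity),
        "enhanced": BispecificMolecule(kd_fap=enh_kd,
                                       avidity_factor=avidity),
    }


def _scan_folds(config: RunConfig) -> np.ndarray:
    if config.kd_scan is not None:
        lo, hi, n = config.kd_scan
        return 0.7 / np.geomspace(hi, lo, int(n))
    return 0.7 / np.geomspace(10.0, 0.001, 17)


def run_simulation(config: RunConfig) -> dict[str, Path]:
    """Dispatch one simulation pipeline; returns the written file paths."""
    out = Path(config.out_dir)
    mols = _molecules(config)
    avidity = mols["reference"].avidity_factor
    written: dict[str, Path] = {}
    logger.info("running %s (calibration=%s, avidity=%.4g, seed=%d)",
                config.simulation, config.calibration_mode, avidity,
                config.seed)

    if config.simulation == "sim1":
        table = effect.min_fap_scan(
            target_pct=config.target_pct, folds=_scan_folds(config),
            base=reference_molecule(avidity))
        path = out / "sim1_min_fap.csv"
        _write_csv(table, path, config)
        written["min_fap"] = path

    elif config.simulation == "sim2":
        thresholds = {
            label: effect.min_fap_for_effect(mol, target_pct=config.target_pct)
            for label, mol in mols.items()}
        names = config.indications or tuple(INDICATION_PRESETS)
        samples = []
        for i, name in enumerate(names):
            pop = indication_population(name, n_virtual=config.n_virtual,
                                        seed=config.seed + i)
            df = simulate_population(pop)
            df.insert(0, "indication", name)
            samples.append(df)
        samples_path = out / "sim2_virtual_patients.csv"
        _write_csv(pd.concat(samples, ignore_index=True), samples_path,
                   config)
        table = population_coverage_table(
            thresholds, indications=names,
            n_virtual=config.n_virtual, seed=config.seed)
        path = out / "sim2_population_coverage.csv"
        _write_csv(table, path, config)
        written["virtual_patients"] = samples_path
        written["coverage"] = path

    elif config.simulation == "sim3":
        table = effect.window_table(
            _scan_folds(config), config.fap_per_fibroblast,
            target_pct=config.window_pct, base=reference_molecule(avidity))
        path = out / "sim3_exposure_windows.csv"
        _write_csv(table, path, config)
        written["windows"] = path

    elif config.simulation == "sim4":
        names = config.indications or tuple(INDICATION_PRESETS)
        rows = []
        for i, name in enumerate(names):
            pop = indication_population(name, n_virtual=config.n_virtual,
                                        seed=config.seed + i)
            fap = simulate_population(pop)["avg_fap"].to_numpy()
            for label, mol in mols.items():
                summary = population.effect_distribution(fap, mol)
                rows.append({"indication": name, "molecule": label,
                             **summary})
        path = out / "sim4_effect_distribution.csv"
        _write_csv(pd.DataFrame(rows), path, config)
        written["distribution"] = path

    elif config.simulation == "sim5":
        pop = indication_population("colon", n_virtual=config.n_patients,
                                    seed=config.seed)
        fap = simulate_population(pop)["avg_fap"].to_numpy()
        patients = sample_patients(config.n_patients, fap, PKParams(),
                                   seed=config.seed + 1)
        schedules = {k: SCHEDULES[k] for k in config.schedules}
        doses = (np.asarray(config.doses, float) if config.doses is not None
                 else clinical.default_dose_grid())
        grid = dose_schedule_grid(mols, patients, doses, schedules)
        grid_path = out / "sim5_dose_schedule_grid.csv"
        _write_csv(grid, grid_path, config)
        optima = summarize_optima(grid)
        optima_path = out / "sim5_optima.csv"
        _write_csv(optima, optima_path, config)
        written["grid"] = grid_path
        written["optima"] = optima_path

    manifest = out / f"{config.simulation}_manifest.json"
    manifest.parent.mkdir(parents=True, exist_ok=True)
    manifest.write_text(json.dumps(
        {"config": asdict(config), "config_sha": config.config_hash(),
         "avidity_factor": avidity,
         "outputs": {k: str(v) for k, v in written.items()}},
        indent=2, sort_keys=True, default=str) + "\n")
    written["manifest"] = manifest
    return written


def generate_fixtures(seed: int = 0, out_dir: str | Path = "fixtures"
                      ) -> dict[str, Path]:
    """Write small example inputs: a 3-indication preset file and a
    50-patient toy cohort for fast end-to-end runs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    presets = {name: INDICATION_PRESETS[name]
               for name in ("bladder", "colon", "pancreas")}
    preset_path = out / "indication_presets.yaml"
    with open(preset_path, "w") as fh:
        yaml.safe_dump(presets, fh, sort_keys=True)

    pop = indication_population("colon", n_virtual=50, seed=seed)
    cohort = simulate_population(pop)
    cohort.insert(0, "patient_id", np.arange(len(cohort)))
    cohort_path = out / "toy_cohort_colon.csv"
    cohort.to_csv(cohort_path, index=False, lineterminator="\n")
    return {"presets": preset_path, "cohort": cohort_path}
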