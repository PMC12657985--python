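"""Validated table I/O, run manifests and the top-level pipeline.

Interchange dialect: RFC-4180 CSV, UTF-8, "." decimal; YAML for configs;
JSON for manifests and diagnostics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .config import McmcConfig, PriorConfig, SimulationConfig, config_hash
from .qpcr import validate_plate_table, ParseReport
from .synth import COUNT_COLUMNS, METADATA_COLUMNS, SyntheticDataset, simulate_dataset

log = logging.getLogger("airedna")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_inputs(
    counts_path=None, metadata_path=None, plates_path=None
) -> tuple[pd.DataFrame | None, pd.DataFrame | None, pd.DataFrame, ParseReport]:
    """Read and schema-validate the three input tables.

    The plate table is required; counts and metadata are optional (their
    absence triggers reduced model variants downstream).  Cross-references
    from environmental plate rows to metadata are resolved here; a missing
    ``sample_id`` is an itemized error.  Returns the validated tables plus
    a parse report of coerced values.
    """
    if plates_path is None:
        raise ValueError("a plate table is required")
    plates_raw = pd.read_csv(plates_path)
    plates, report = validate_plate_table(plates_raw)

    counts = None
    if counts_path is not None and Path(counts_path).exists():
        counts = pd.read_csv(counts_path)
        missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
        if missing:
            raise ValueError(f"counts table missing columns: {missing}")
        if (counts["N"] < 0).any() or (counts["E"] < 0).any():
            raise ValueError("counts table: N and E must be non-negative")

    metadata = None
    if metadata_path is not None and Path(metadata_path).exists():
        metadata = pd.read_csv(metadata_path)
        missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
        if missing:
            raise ValueError(f"metadata table missing columns: {missing}")

    env = plates["sample_class"].isin(["water", "air"])
    if env.any():
        if metadata is None:
            raise ValueError(
                "plate table contains environmental wells but no metadata "
                "table was provided"
            )
        known = set(metadata["sample_id"])
        unknown = plates.loc[env & ~plates["sample_id"].isin(known)]
        if len(unknown):
            first = unknown.iloc[0]
            raise ValueError(
                f"plate row {unknown.index[0]} (column sample_id): "
                f"{first['sample_id']!r} not present in metadata"
            )
    return counts, metadata, plates, report


def write_manifest(outdir: Path, *, seed: int, configs: dict, inputs: dict) -> Path:
    """Write a run manifest sufficient to re-run bit-reproducibly."""
    import airedna

    manifest = {
        "seed": seed,
        "config_hashes": {k: config_hash(v) for k, v in configs.items()},
        "input_checksums": {k: _sha256(Path(p)) for k, p in inputs.items()},
        "versions": {
            "airedna": airedna.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    try:
        import emcee

        manifest["versions"]["emcee"] = emcee.__version__
    except ImportError:
        pass
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_priors(path) -> PriorConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(PriorConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown prior fields: {sorted(unknown)}")
    kw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
    return PriorConfig(**kw)


def load_mcmc(path, seed: int | None = None) -> McmcConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if seed is not None:
        raw["seed"] = seed
    return McmcConfig(**raw)


def load_sim_config(path, seed: int | None = None) -> SimulationConfig:
    import yaml

    from .config import QpcrCalibration, SampleDesign

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if seed is not None:
        raw["seed"] = seed
    if "calib" in raw:
        raw["calib"] = QpcrCalibration(**{
            k: (np.asarray(v) if k == "beta1" else v)
            for k, v in raw["calib"].items()
        })
    if "design" in raw:
        raw["design"] = SampleDesign(**raw["design"])
    if "standard_series" in raw and raw["standard_series"] is not None:
        raw["standard_series"] = {float(k): int(v) for k, v in raw["standard_series"].items()}
    if "samplers" in raw:
        raw["samplers"] = tuple(raw["samplers"])
    return SimulationConfig(**raw)


def run_pipeline(
    outdir,
    *,
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
    data_dir=None,
    priors: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
    phi: float = 20.0,
) -> Path:
    """simulate (optional) -> fit -> diagnose -> summarize.

    Either ``sim_config`` (forward-simulate the inputs) or ``data_dir``
    (read existing tables) must be given.  All randomness flows from
    ``seed``.  Each stage logs with a machine-parsable prefix and failures
    halt with stage-scoped context.
    """
    from . import derived as drv
    from . import inference

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig.reduced(seed=seed)

    log.info("[stage:simulate] start")
    if sim_config is not None:
        sim_config = dataclasses.replace(sim_config, seed=seed)
        dataset = simulate_dataset(sim_config)
        data_dir = outdir / "data"
        paths = dataset.write(data_dir)
    elif data_dir is not None:
        data_dir = Path(data_dir)
        paths = {
            "counts": data_dir / "counts.csv",
            "metadata": data_dir / "metadata.csv",
            "plate_table": data_dir / "plate_table.csv",
        }
    else:
        raise ValueError("either sim_config or data_dir is required")

    counts, metadata, plates, report = read_inputs(
        paths.get("counts"), paths.get("metadata"), paths["plate_table"]
    )
    if metadata is None or not (plates["sample_class"] == "air").any():
        warnings.warn(
            "no air samples found: fitting the count+water-only model variant"
        )
    if not report.clean:
        log.warning("[stage:ingest] parse report: %s", dataclasses.asdict(report))

    log.info("[stage:fit] start")
    fit = inference.fit((counts, metadata, plates), priors, mcmc, phi=phi)
    fit.summary().to_csv(outdir / "posterior_summary.csv")

    log.info("[stage:diagnose] start")
    ppc = inference.posterior_predictive_check(fit, seed=seed)
    sens = inference.prior_sensitivity(fit)
    diagnostics = {
        "rhat_max": float(np.nanmax(list(fit.rhat().values()))),
        "ess_min": float(np.nanmin(list(fit.ess().values()))),
        "n_divergent": fit.n_divergent,
        "treedepth_saturations": fit.treedepth_saturations,
        "passes": fit.passes(),
        "ppc_coverage": {
            k: (None if v is None else round(v, 4))
            for k, v in ppc.coverage().items()
        },
    }
    (outdir / "diagnostics.json").write_text(
        json.dumps(diagnostics, indent=2, sort_keys=True)
    )
    sens.to_csv(outdir / "prior_sensitivity.csv")

    log.info("[stage:summarize] start")
    drv.table1_style(fit).to_csv(outdir / "summary.csv")
    drv.trajectory_summary(fit).to_csv(outdir / "trajectory.csv")

    write_manifest(
        outdir,
        seed=seed,
        configs={"priors": priors, "mcmc": mcmc},
        inputs={k: p for k, p in paths.items() if Path(p).suffix == ".csv"},
    )
    log.info("[stage:done] artifacts in %s", outdir)
    return outdir
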