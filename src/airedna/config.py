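"""Configuration objects shared across the pipeline.

The study design being emulated: a six-week salmon-spawning season sampled
at six weekly events.  At each event hatchery staff count the fish that
accumulated since the previous gate opening (effort ``E_t`` days, with the
first event carrying ``E=0``), one litre of river water is filtered, and
four passive air collectors are deployed for 24 h — gelatin and PTFE filters
in duplicate, a single air-suspended MCE filter, and a single open tray of
deionized water.  Every sample is assayed by qPCR alongside a standard
dilution series.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

# Canonical sampler order (matches the reporting table of the field study):
# gelatin and PTFE run in biological duplicate, the air-suspended MCE filter
# and the DI-water tray as single collectors.
SAMPLERS: tuple[str, ...] = ("gelatin", "ptfe", "mce_air", "mce_di")
REPLICATED_SAMPLERS: tuple[str, ...] = ("gelatin", "ptfe")
#: active collection surface (cm^2): 47-mm filter disks vs the open tray.
SAMPLER_SURFACE_CM2: dict[str, float] = {
    "gelatin": 16.0,
    "ptfe": 16.0,
    "mce_air": 16.0,
    "mce_di": 750.0,
}


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample normalization constants mapping medium concentrations to
    per-reaction concentrations.

    Parameters
    ----------
    F_l : filtered water volume in litres (water samples).
    V_ul : qPCR reaction volume in microlitres (all samples).
    P_days : passive deployment duration in days (air samples).
    extraction_efficiency : optional multiplier on the recovered template
        fraction (defaults to 1, i.e. the normalizations are used exactly
        as stated; extraction/elution losses are not modelled).
    """

    F_l: float = 1.0
    V_ul: float = 10.0
    P_days: float = 1.0
    extraction_efficiency: float = 1.0

    def __post_init__(self) -> None:
        for name in ("F_l", "V_ul", "P_days", "extraction_efficiency"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SampleDesign.{name} must be strictly positive")

    def surface_cm2(self, sampler: str) -> float:
        return SAMPLER_SURFACE_CM2[sampler]


@dataclass
class QpcrCalibration:
    """qPCR observation-model parameters.

    ``theta`` is the per-copy detection rate: a reaction holding ``K``
    copies/µL amplifies with probability ``1 - exp(-K*theta)``.  Conditional
    on amplification the cycle threshold is Normal with mean
    ``beta0 + beta1[p]*ln K`` (plate-specific slope ``p``) and standard
    deviation ``exp(gamma0 + gamma1*ln K)``.
    """

    theta: float = 1.0
    beta0: float = 38.0
    beta1: np.ndarray = field(default_factory=lambda: np.array([-1.4427, -1.38]))
    gamma0: float = -1.0
    gamma1: float = -0.08

    def __post_init__(self) -> None:
        self.beta1 = np.atleast_1d(np.asarray(self.beta1, dtype=float))
        if self.theta <= 0:
            raise ValueError("theta must be strictly positive")
        if np.any(self.beta1 >= 0):
            import warnings

            warnings.warn(
                "beta1 >= 0: Ct should decrease with concentration in a "
                "functioning assay",
                stacklevel=2,
            )

    @property
    def n_plates(self) -> int:
        return len(self.beta1)


@dataclass
class PriorConfig:
    """Weakly informative priors, centred on qPCR physics.

    Each entry is (location, scale) for a Normal unless noted.  ``tau`` and
    ``rho`` carry half-Cauchy(0, scale) priors — the standard weakly
    informative choice for variance-component scales estimated from few
    levels (here six events per sampler), whose heavy tail avoids
    over-shrinking large residual scales.  ``theta`` is Exponential with
    the given mean.
    """

    log_x: tuple[float, float] = (5.0, 3.0)
    omega_log: tuple[float, float] = (0.0, 10.0)
    eta: tuple[float, float] = (0.0, 5.0)
    tau_scale: float = 1.0
    rho_scale: float = 1.0
    theta_mean: float = 1.0
    beta0: tuple[float, float] = (40.0, 5.0)
    beta1: tuple[float, float] = (-1.44, 0.5)
    gamma0: tuple[float, float] = (0.0, 2.0)
    gamma1: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("log_x", "omega_log", "eta", "beta0", "beta1", "gamma0", "gamma1"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"prior scale for {name} must be positive")
        if self.tau_scale <= 0 or self.rho_scale <= 0 or self.theta_mean <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class McmcConfig:
    """Sampler run configuration.

    ``n_warmup``/``n_sampling`` count iterations per chain; the blocked-Gibbs
    backend lays them out as scans over a bank of parallel replicate
    sub-chains (``n_walkers`` of them; leave None for the default).
    ``n_chains`` fully independent chains are run so that split-R-hat
    compares genuinely independent runs.  ``target_accept`` and
    ``max_tree_depth`` are accepted for interface compatibility with
    Hamiltonian backends and ignored here.
    """

    n_chains: int = 4
    n_warmup: int = 5000
    n_sampling: int = 5000
    seed: int = 0
    n_walkers: int | None = None  # parallel Gibbs replicates per chain
    target_accept: float | None = None
    max_tree_depth: int | None = None

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for R-hat")
        if self.n_warmup <= 0 or self.n_sampling <= 0:
            raise ValueError("iteration counts must be positive")

    @classmethod
    def reduced(cls, seed: int = 0, **kw) -> "McmcConfig":
        """Scaled-down profile: 4 x (500 warmup + 500 sampling)."""
        kw.setdefault("n_chains", 4)
        kw.setdefault("n_warmup", 500)
        kw.setdefault("n_sampling", 500)
        return cls(seed=seed, **kw)


def _default_true_x() -> np.ndarray:
    # A realistic spawning run: first arrivals, a mid-season peak near 286
    # fish/day, tailing off to ~80 fish/day; season mean ~160 fish/day.
    return np.array([78.0, 286.0, 240.0, 160.0, 110.0, 88.0])


@dataclass
class SimulationConfig:
    """Ground truth for the forward simulator (the study conditions)."""

    n_timepoints: int = 6
    efforts: np.ndarray = field(
        default_factory=lambda: np.array([0, 7, 7, 7, 7, 7])
    )
    true_X: np.ndarray = field(default_factory=_default_true_x)
    omega_log: float = 9.578
    eta: np.ndarray = field(
        default_factory=lambda: np.array([-10.45, -9.53, -10.91, -9.95])
    )
    tau: np.ndarray = field(
        default_factory=lambda: np.array([0.473, 0.570, 0.949, 1.780])
    )
    rho: np.ndarray = field(default_factory=lambda: np.array([0.386, 0.154]))
    phi: float = 20.0
    calib: QpcrCalibration = field(default_factory=QpcrCalibration)
    design: SampleDesign = field(default_factory=SampleDesign)
    samplers: tuple[str, ...] = SAMPLERS
    n_tech_reps: int = 3
    n_ntc_per_plate: int = 3
    standard_series: dict[float, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.efforts = np.asarray(self.efforts)
        self.true_X = np.asarray(self.true_X, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if len(self.true_X) != self.n_timepoints:
            raise ValueError("true_X length must equal n_timepoints")
        if len(self.efforts) != self.n_timepoints:
            raise ValueError("efforts length must equal n_timepoints")
        if np.any(self.true_X <= 0):
            raise ValueError("true_X must be strictly positive")
        if np.any(self.efforts < 0):
            raise ValueError("efforts must be non-negative")
        if len(self.eta) != len(self.samplers):
            raise ValueError("eta must have one entry per sampler")
        if len(self.tau) != len(self.samplers):
            raise ValueError("tau must have one entry per sampler")
        n_rep = sum(s in REPLICATED_SAMPLERS for s in self.samplers)
        if len(self.rho) != n_rep:
            raise ValueError("rho must have one entry per replicated sampler")
        if np.any(self.tau <= 0) or np.any(self.rho <= 0) or self.phi <= 0:
            raise ValueError("tau, rho and phi must be strictly positive")

    @property
    def replicated(self) -> tuple[str, ...]:
        return tuple(s for s in self.samplers if s in REPLICATED_SAMPLERS)

    def to_jsonable(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {k: conv(v) for k, v in dataclasses.asdict(x).items()}
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, tuple):
                return list(x)
            return x

        return {
            f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)
        }


def child_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2^31.

    One root seed drives the whole pipeline; each stage (counts, air, qpcr,
    chain-0, ...) derives its own stream from a hash of its name so stages
    stay independent yet reproducible.
    """
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def config_hash(obj) -> str:
    """Stable short hash of a configuration object (for run manifests)."""
    if hasattr(obj, "to_jsonable"):
        payload = obj.to_jsonable()
    elif dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        payload = json.loads(json.dumps(dataclasses.asdict(obj), default=str))
    else:
        payload = obj
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
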