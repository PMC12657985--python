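"""Forward simulator for every input the pipeline consumes.

Generates, with the exact statistical structure the joint model assumes:
the fish-count series (Negative Binomial around ``X_t * E_t``), the water
eDNA concentration (``W_t = X_t * exp(omega_log)``, deterministic), the air
deposition concentrations (log-linear in water with sampler intercepts and
lognormal noise, plus replicate deviations), and qPCR plates — standards
dilution series, environmental wells, and no-template controls.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    REPLICATED_SAMPLERS,
    SimulationConfig,
    QpcrCalibration,
    child_seed,
)
from .qpcr import PLATE_COLUMNS, detection_probability, ct_moments

#: default standards replication: copies/µL -> replicate count
DEFAULT_STANDARD_SERIES: dict[float, int] = {
    1e5: 3,
    1e4: 3,
    1e3: 3,
    1e2: 4,
    1e1: 3,
}
#: designation of the quantified stock the series is diluted from
STANDARD_STOCK_COPIES_PER_UL = 1e6

METADATA_COLUMNS = [
    "sample_id", "sample_class", "t", "sampler", "bio_rep",
    "F_l", "V_ul", "S_cm2", "P_days",
]
COUNT_COLUMNS = ["t", "N", "E"]


def simulate_counts(true_X, efforts, phi: float, seed: int) -> np.ndarray:
    """Draw visual counts ``N_t ~ NegBin(mean X_t*E_t, overdispersion phi)``.

    The Negative Binomial is parameterized by mean ``lam`` and ``phi`` so
    that the variance is ``lam + lam^2/phi``.  Zero-effort rows (no days
    between gate openings) deterministically return 0.
    """
    true_X = np.asarray(true_X, dtype=float)
    efforts = np.asarray(efforts, dtype=float)
    if np.any(true_X <= 0):
        raise ValueError("true_X must be strictly positive")
    if np.any(efforts < 0):
        raise ValueError("efforts must be non-negative")
    if phi <= 0:
        raise ValueError("phi must be strictly positive")
    rng = np.random.default_rng(seed)
    lam = true_X * efforts
    out = np.zeros(len(lam), dtype=int)
    pos = lam > 0
    # numpy's negative_binomial(n, p): n=phi, p=phi/(phi+lam) gives mean lam
    p = phi / (phi + lam[pos])
    out[pos] = rng.negative_binomial(phi, p)
    return out


def simulate_water(true_X, omega_log: float) -> np.ndarray:
    """Water eDNA concentration ``W_t = X_t * exp(omega_log)`` (copies/L).

    ``omega_log`` is the integrated eDNA factor on the natural-log scale:
    it aggregates per-fish shedding, decay, transport and dilution into one
    conversion from fish/day to copies/L.  The map is deterministic — all
    stochasticity enters through the observation models.
    """
    true_X = np.asarray(true_X, dtype=float)
    if np.any(true_X <= 0):
        raise ValueError("true_X must be strictly positive")
    return true_X * np.exp(omega_log)


def simulate_air(
    W,
    eta,
    tau,
    rho,
    seed: int,
    samplers=None,
) -> pd.DataFrame:
    """Air deposition concentrations per (time, sampler, replicate).

    ``ln A_tj = eta_j + ln W_t + eps_tj`` with ``eps_tj ~ N(0, tau_j)``;
    replicated samplers additionally receive independent per-replicate
    deviations ``delta_tjb ~ N(0, rho_j)`` (generation draws them i.i.d.;
    the sum-to-zero constraint is an inference-side identification device).

    Returns a frame with columns t, sampler, bio_rep, A (copies/cm^2/day).
    """
    from .config import SAMPLERS

    W = np.asarray(W, dtype=float)
    eta = np.asarray(eta, dtype=float)
    tau = np.asarray(tau, dtype=float)
    rho = np.asarray(rho, dtype=float)
    samplers = tuple(samplers) if samplers is not None else SAMPLERS
    if np.any(W <= 0):
        raise ValueError("W must be strictly positive")
    if len(eta) != len(samplers) or len(tau) != len(samplers):
        raise ValueError("eta/tau must have one entry per sampler")
    replicated = [s for s in samplers if s in REPLICATED_SAMPLERS]
    if len(rho) != len(replicated):
        raise ValueError("rho must have one entry per replicated sampler")
    if np.any(tau <= 0) or np.any(rho <= 0):
        raise ValueError("tau and rho must be strictly positive")

    rng = np.random.default_rng(seed)
    rows = []
    lnW = np.log(W)
    for j, s in enumerate(samplers):
        eps = rng.normal(0.0, tau[j], size=len(W))
        lnA = eta[j] + lnW + eps
        if s in replicated:
            r = replicated.index(s)
            delta = rng.normal(0.0, rho[r], size=(len(W), 2))
            for t in range(len(W)):
                for b in range(2):
                    rows.append((t, s, b + 1, float(np.exp(lnA[t] + delta[t, b]))))
        else:
            for t in range(len(W)):
                rows.append((t, s, 1, float(np.exp(lnA[t]))))
    return pd.DataFrame(rows, columns=["t", "sampler", "bio_rep", "A"])


def make_standard_series(override: dict[float, int] | None = None) -> pd.DataFrame:
    """Standard dilution series: known concentration vs replicate count.

    Default scheme: 1e5, 1e4, 1e3 copies/µL in triplicate, 1e2 in
    quadruplicate, 1e1 in triplicate (16 reactions), diluted from a stock
    designated 1e6 copies/µL.  ``override`` replaces replicate counts per
    level (and may add/remove levels).
    """
    series = dict(DEFAULT_STANDARD_SERIES)
    if override is not None:
        series.update(override)
        series = {k: v for k, v in series.items() if v > 0}
    levels = sorted(series, reverse=True)
    df = pd.DataFrame(
        {"K": levels, "n_reps": [int(series[k]) for k in levels]}
    )
    df.attrs["stock_copies_per_ul"] = STANDARD_STOCK_COPIES_PER_UL
    return df


def simulate_qpcr(
    concs_per_reaction,
    calib: QpcrCalibration,
    n_tech_reps: int,
    seed: int,
    plate_ids=None,
) -> pd.DataFrame:
    """Amplification flags and Ct values for a vector of reaction concentrations.

    Each concentration yields ``n_tech_reps`` wells: ``Z ~ Bernoulli(psi)``
    with ``psi = 1 - exp(-K*theta)``; where Z=1 the Ct is Normal with the
    calibration's concentration-dependent mean and sd; where Z=0 the Ct is
    missing (NaN), never a sentinel.  K=0 (controls) never amplifies.
    """
    K = np.asarray(concs_per_reaction, dtype=float)
    if np.any(K < 0):
        raise ValueError("concentrations must be non-negative")
    if calib.theta <= 0:
        raise ValueError("theta must be strictly positive")
    plate_ids = (
        np.zeros(len(K), dtype=int)
        if plate_ids is None
        else np.asarray(plate_ids, dtype=int)
    )
    rng = np.random.default_rng(seed)
    rows = []
    for i, k in enumerate(K):
        psi = float(detection_probability(k, calib.theta)) if k > 0 else 0.0
        for r in range(n_tech_reps):
            z = int(rng.random() < psi)
            if z and k > 0:
                mu, sigma = ct_moments(k, calib, plate_ids[i])
                y = float(rng.normal(mu, sigma))
            else:
                y = np.nan
            rows.append((i, int(plate_ids[i]), r + 1, z, y))
    return pd.DataFrame(rows, columns=["conc_idx", "plate", "tech_rep", "Z", "Ct"])


@dataclass
class SyntheticDataset:
    """The three pipeline input tables plus the generating truth."""

    counts: pd.DataFrame
    metadata: pd.DataFrame
    plates: pd.DataFrame
    truth: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("counts", self.counts),
            ("metadata", self.metadata),
            ("plate_table", self.plates),
        ):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        tp = outdir / "truth.json"
        tp.write_text(json.dumps(self.truth.to_jsonable(), indent=2, sort_keys=True))
        paths["truth"] = tp
        return paths


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generative model and assemble the three input tables."""
    cfg = config
    root = cfg.seed
    T = cfg.n_timepoints
    n_plates = cfg.calib.n_plates

    # --- latent processes ------------------------------------------------
    N = simulate_counts(cfg.true_X, cfg.efforts, cfg.phi, child_seed(root, "counts"))
    counts = pd.DataFrame({"t": np.arange(T), "N": N, "E": cfg.efforts})

    W = simulate_water(cfg.true_X, cfg.omega_log)
    air = simulate_air(
        W, cfg.eta, cfg.tau, cfg.rho, child_seed(root, "air"), cfg.samplers
    )

    # --- sample metadata --------------------------------------------------
    d = cfg.design
    meta_rows = []
    sample_conc: dict[str, float] = {}  # per-reaction copies/µL
    sample_plate: dict[str, int] = {}
    for t in range(T):
        plate = t * n_plates // T
        sid = f"w_t{t}"
        meta_rows.append((sid, "water", t, "", 1, d.F_l, d.V_ul, np.nan, np.nan))
        sample_conc[sid] = W[t] * d.F_l / d.V_ul * d.extraction_efficiency
        sample_plate[sid] = plate
    for _, row in air.iterrows():
        t, s, b, A = int(row["t"]), row["sampler"], int(row["bio_rep"]), row["A"]
        plate = t * n_plates // T
        sid = f"a_t{t}_{s}_b{b}"
        S = d.surface_cm2(s)
        meta_rows.append((sid, "air", t, s, b, np.nan, d.V_ul, S, d.P_days))
        sample_conc[sid] = A * S * d.P_days / d.V_ul * d.extraction_efficiency
        sample_plate[sid] = plate
    metadata = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)

    # --- qPCR plates ------------------------------------------------------
    std = make_standard_series(cfg.standard_series)
    plate_rows = []
    for p in range(n_plates):
        for _, lv in std.iterrows():
            K, n_reps = float(lv["K"]), int(lv["n_reps"])
            wells = simulate_qpcr(
                [K], cfg.calib, n_reps,
                child_seed(root, f"qpcr-std-p{p}-K{K:g}"), plate_ids=[p],
            )
            for _, w in wells.iterrows():
                plate_rows.append(
                    (f"std_p{p}_K{K:g}", "standard", p, int(w["tech_rep"]),
                     K, int(w["Z"]), w["Ct"])
                )
        ntc = simulate_qpcr(
            [0.0], cfg.calib, cfg.n_ntc_per_plate,
            child_seed(root, f"qpcr-ntc-p{p}"), plate_ids=[p],
        )
        for _, w in ntc.iterrows():
            plate_rows.append(
                (f"ntc_p{p}", "control", p, int(w["tech_rep"]), 0.0,
                 int(w["Z"]), np.nan)
            )
    for sid, conc in sample_conc.items():
        p = sample_plate[sid]
        cls = "water" if sid.startswith("w_") else "air"
        wells = simulate_qpcr(
            [conc], cfg.calib, cfg.n_tech_reps,
            child_seed(root, f"qpcr-{sid}"), plate_ids=[p],
        )
        for _, w in wells.iterrows():
            plate_rows.append(
                (sid, cls, p, int(w["tech_rep"]), np.nan, int(w["Z"]), w["Ct"])
            )
    plates = pd.DataFrame(plate_rows, columns=PLATE_COLUMNS)
    return SyntheticDataset(counts=counts, metadata=metadata, plates=plates, truth=cfg)
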