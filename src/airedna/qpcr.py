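"""qPCR observation model shared between standards and environmental samples.

A reaction holding ``K`` copies/µL of template amplifies with probability
``psi = 1 - exp(-K * theta)`` (each copy independently seeds amplification
at rate ``theta``).  Conditional on amplification, the cycle threshold Ct is
Normal with mean ``beta0 + beta1[p] * ln K`` (plate-specific slope) and
standard deviation ``exp(gamma0 + gamma1 * ln K)`` — noisier at low template.
Non-amplified wells carry no Ct.  The same five parameters tie the standard
curve to the latent environmental concentrations, which is what lets the
model propagate observation-level uncertainty instead of applying fixed
LOD/LOQ cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QpcrCalibration

_LOG2PI = float(np.log(2.0 * np.pi))

#: canonical plate-table columns
PLATE_COLUMNS = ["sample_id", "sample_class", "plate", "tech_rep", "K", "Z", "Ct"]
SAMPLE_CLASSES = ("standard", "water", "air", "control")


def detection_probability(K, theta):
    """Probability that a reaction with ``K`` copies/µL amplifies.

    ``psi = 1 - exp(-K*theta)``: in [0, 1), strictly increasing in K,
    approaching 1 as K grows.
    """
    K = np.asarray(K, dtype=float)
    if np.any(K < 0):
        raise ValueError("concentration K must be non-negative")
    if theta <= 0:
        raise ValueError("theta must be strictly positive")
    return -np.expm1(-K * theta)


def ct_moments(K, calib: QpcrCalibration, plate_id: int = 0):
    """Mean and sd of the Ct for a well at concentration ``K`` on a plate."""
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("ct_moments requires K > 0")
    beta1 = calib.beta1[plate_id]  # raises IndexError/KeyError for unknown plate
    lnK = np.log(K)
    mu = calib.beta0 + beta1 * lnK
    sigma = np.exp(calib.gamma0 + calib.gamma1 * lnK)
    return mu, sigma


def detection_curve(calib: QpcrCalibration, K_grid) -> pd.DataFrame:
    """Tabulate the detection-probability curve over a concentration grid."""
    K_grid = np.asarray(K_grid, dtype=float)
    return pd.DataFrame(
        {"K": K_grid, "psi": detection_probability(K_grid, calib.theta)}
    )


def _bernoulli_logterms(K, theta, Z):
    """log P(Z | psi(K, theta)) with exact tail expressions.

    Z=0 wells contribute ``-K*theta`` (= log(1-psi)); Z=1 wells contribute
    ``log(-expm1(-K*theta))``.
    """
    Kt = np.asarray(K, dtype=float) * theta
    with np.errstate(divide="ignore", invalid="ignore"):
        log_psi = np.log(-np.expm1(-Kt))
    return np.where(np.asarray(Z) == 1, log_psi, -Kt)


def _normal_logpdf(y, mu, sigma):
    return -0.5 * _LOG2PI - np.log(sigma) - 0.5 * ((y - mu) / sigma) ** 2


def observation_loglik(records: pd.DataFrame, concs, calib: QpcrCalibration) -> float:
    """Joint log-likelihood of a set of plate wells.

    Parameters
    ----------
    records : plate table (``PLATE_COLUMNS`` schema).
    concs : per-row concentration in copies/µL of reaction — the known ``K``
        for standards, zero for controls, or the latent per-reaction
        concentration for environmental wells.  Scalar or array aligned with
        ``records``.
    calib : shared calibration parameters.

    Returns the sum over wells of the Bernoulli amplification term plus,
    for amplified wells, the Normal Ct term.  Additive over records; an
    empty record set scores 0.
    """
    if len(records) == 0:
        return 0.0
    K = np.broadcast_to(np.asarray(concs, dtype=float), (len(records),))
    Z = records["Z"].to_numpy(dtype=int)
    if np.any((Z == 1) & ~np.isfinite(records["Ct"].to_numpy(dtype=float))):
        raise ValueError("amplified well (Z=1) with missing Ct")
    total = float(np.sum(_bernoulli_logterms(K, calib.theta, Z)))
    amp = Z == 1
    if amp.any():
        plates = records["plate"].to_numpy(dtype=int)[amp]
        lnK = np.log(K[amp])
        mu = calib.beta0 + calib.beta1[plates] * lnK
        sigma = np.exp(calib.gamma0 + calib.gamma1 * lnK)
        total += float(np.sum(_normal_logpdf(records["Ct"].to_numpy(dtype=float)[amp], mu, sigma)))
    return total


@dataclass
class ParseReport:
    """What ingest had to coerce or flag."""

    coerced_ct: list[str] = field(default_factory=list)
    contaminated_controls: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.coerced_ct or self.contaminated_controls)


def validate_plate_table(df: pd.DataFrame) -> tuple[pd.DataFrame, ParseReport]:
    """Schema-validate a plate table, coercing instrument quirks.

    Non-numeric Ct strings (e.g. "Undetermined") are mapped to a missing Ct
    with Z=0 and listed in the parse report.  Control wells that amplified
    raise a contamination *warning* (the assay's controls are expected to
    show no amplification) but ingest proceeds.
    """
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    df = df.copy()
    report = ParseReport()

    ct_raw = df["Ct"]
    ct_num = pd.to_numeric(ct_raw, errors="coerce")
    bad = ct_num.isna() & ct_raw.notna() & (ct_raw.astype(str).str.strip() != "")
    for idx in df.index[bad]:
        report.coerced_ct.append(
            f"row {idx}: Ct '{ct_raw.loc[idx]}' coerced to missing (Z set to 0)"
        )
    df["Ct"] = ct_num
    df.loc[bad, "Z"] = 0
    df["Z"] = df["Z"].astype(int)
    df["plate"] = df["plate"].astype(int)
    df["K"] = pd.to_numeric(df["K"], errors="coerce")

    unknown = set(df["sample_class"].unique()) - set(SAMPLE_CLASSES)
    if unknown:
        raise ValueError(f"unknown sample_class values: {sorted(unknown)}")

    z1 = df["Z"] == 1
    if (z1 & df["Ct"].isna()).any():
        rows = list(df.index[z1 & df["Ct"].isna()])
        raise ValueError(f"amplified wells with missing Ct at rows {rows}")

    std = df["sample_class"] == "standard"
    if (std & ~(df["K"] > 0)).any():
        rows = list(df.index[std & ~(df["K"] > 0)])
        raise ValueError(f"standard wells need known K > 0 at rows {rows}")

    contaminated = (df["sample_class"] == "control") & z1
    if contaminated.any():
        ids = df.loc[contaminated, "sample_id"].tolist()
        report.contaminated_controls.extend(ids)
        warnings.warn(
            f"control wells amplified (possible contamination): {ids}",
            stacklevel=2,
        )
    return df, report


def fit_standards_start(df: pd.DataFrame) -> QpcrCalibration:
    """Quick non-Bayesian calibration estimate from standards alone.

    Used to initialize MCMC: per-plate least-squares Ct ~ ln K with a shared
    intercept, residual sd for gamma0, and a 1-D grid MLE for theta.
    """
    std = df[df["sample_class"] == "standard"]
    if len(std) == 0:
        return QpcrCalibration(beta1=np.array([-1.44]))
    plates = np.sort(df["plate"].unique())
    amp = std[std["Z"] == 1]
    beta1 = np.full(len(plates), -1.44)
    beta0, gamma0 = 38.0, -1.0
    if len(amp) >= 3:
        lnK = np.log(amp["K"].to_numpy(dtype=float))
        y = amp["Ct"].to_numpy(dtype=float)
        p_idx = np.searchsorted(plates, amp["plate"].to_numpy(dtype=int))
        X = np.zeros((len(amp), 1 + len(plates)))
        X[:, 0] = 1.0
        X[np.arange(len(amp)), 1 + p_idx] = lnK
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        beta0 = float(coef[0])
        fitted = X @ coef
        resid_sd = max(float(np.std(y - fitted)), 0.05)
        gamma0 = float(np.log(resid_sd))
        for i in range(len(plates)):
            if np.any(p_idx == i):
                beta1[i] = coef[1 + i]
    # 1-D grid MLE for theta over a broad log-range
    K = std["K"].to_numpy(dtype=float)
    Z = std["Z"].to_numpy(dtype=int)
    grid = np.exp(np.linspace(-8, 3, 400))
    ll = np.array([np.sum(_bernoulli_logterms(K, th, Z)) for th in grid])
    theta = float(grid[np.argmax(ll)])
    return QpcrCalibration(
        theta=theta, beta0=beta0, beta1=beta1, gamma0=gamma0, gamma1=0.0
    )
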