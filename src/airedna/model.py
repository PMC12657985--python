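"""Latent ecological / cross-medium transfer process and the joint density.

The chain of quantities, per sampling event t:

* ``X_t`` — latent fish accumulation rate (fish/day); counts observe
  ``N_t ~ NegBin(X_t * E_t, phi)`` over the ``E_t`` days since the previous
  gate opening (rows with ``E_t = 0`` carry no count likelihood).
* ``W_t = X_t * exp(omega_log)`` — water eDNA concentration (copies/L);
  ``omega_log`` is the integrated eDNA factor on the natural-log scale.
* ``ln A_tj = eta_j + ln W_t + eps_tj`` — air deposition concentration
  (copies/cm^2/day) for sampler type j, slope fixed at 1; ``eta_j`` is the
  water-to-air transfer (dilution) intercept, ``eps_tj ~ N(0, tau_j)``.
* replicated samplers split ``ln A_tjb = ln A_tj ± d_tj`` (sum-to-zero
  pair); the free half-difference has sd ``rho_j / sqrt(2)`` so that
  ``rho_j`` is the sd of an individual replicate's deviation.
* unit normalizations into per-reaction copies/µL: ``U_t = W_t * F/V`` for
  water and ``Q_tjb = A_tjb * S * P / V`` for air, which then enter the
  shared qPCR observation model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import PriorConfig, QpcrCalibration, SAMPLERS, REPLICATED_SAMPLERS
from .qpcr import _normal_logpdf, observation_loglik  # noqa: F401 (re-export path)

_LOG2PI = float(np.log(2.0 * np.pi))
_SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# elementary process operations
# ---------------------------------------------------------------------------

def expected_count(X_t, E_t):
    """Expected accumulated count ``lambda_t = X_t * E_t`` (fish)."""
    return np.asarray(X_t, dtype=float) * np.asarray(E_t, dtype=float)


def count_loglik(N, lam, phi):
    """Negative Binomial log-pmf in the mean/overdispersion parameterization.

    ``var = lam + lam^2/phi``.  Rows with ``lam <= 0`` are degenerate and
    must be excluded upstream (zero-effort gate openings).
    """
    N = np.asarray(N, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("count_loglik requires lam > 0; drop zero-effort rows")
    if phi <= 0:
        raise ValueError("phi must be strictly positive")
    return (
        gammaln(N + phi)
        - gammaln(phi)
        - gammaln(N + 1.0)
        + phi * np.log(phi / (phi + lam))
        + N * np.log(lam / (phi + lam))
    )


def water_concentration(X, omega_log):
    """``W = X * exp(omega_log)`` in copies/L."""
    return np.asarray(X, dtype=float) * np.exp(omega_log)


def air_log_mean(W, eta_j):
    """``ln A_tj = eta_j + ln W`` — the unit slope is structural."""
    W = np.asarray(W, dtype=float)
    if np.any(W <= 0):
        raise ValueError("W must be strictly positive")
    return eta_j + np.log(W)


def replicate_log_conc(logA_tj, delta_pair):
    """Per-replicate log concentrations ``ln A_tjb = ln A_tj + delta_b``.

    ``delta_pair`` must sum to zero (the b=2 deviation is the negative of
    b=1); the replicate mean then equals ``logA_tj`` exactly.
    """
    delta_pair = np.asarray(delta_pair, dtype=float)
    if not np.allclose(delta_pair.sum(axis=-1), 0.0, atol=1e-12):
        raise AssertionError("replicate deviations must sum to zero")
    return np.asarray(logA_tj, dtype=float)[..., None] + delta_pair


def reaction_conc_water(W, F, V):
    """``U = W * F / V`` (copies/µL of reaction)."""
    return np.asarray(W, dtype=float) * F / V


def reaction_conc_air(A, S, P, V):
    """``Q = A * S * P / V`` (copies/µL of reaction)."""
    return np.asarray(A, dtype=float) * S * P / V


# ---------------------------------------------------------------------------
# compiled data
# ---------------------------------------------------------------------------

_KIND = {"standard": 0, "water": 1, "air": 2, "control": 3}


@dataclass
class ModelData:
    """Input tables compiled to flat arrays for fast likelihood evaluation."""

    T: int
    N: np.ndarray          # (T,) counts
    E: np.ndarray          # (T,) efforts in days
    include: np.ndarray    # (T,) bool: E > 0 rows enter the count likelihood
    phi: float
    samplers: tuple[str, ...]
    replicated: tuple[str, ...]
    plates: np.ndarray     # sorted unique plate ids
    # per-well arrays
    kind: np.ndarray       # codes from _KIND
    t_idx: np.ndarray
    j_idx: np.ndarray      # sampler index (air wells)
    r_idx: np.ndarray      # replicated-sampler index (air wells), -1 otherwise
    sign: np.ndarray       # +1/-1 replicate half-difference sign, 0 otherwise
    plate_idx: np.ndarray
    K_known: np.ndarray    # standards' K, 0 for controls, nan otherwise
    m_norm: np.ndarray     # multiplier medium-conc -> reaction copies/µL
    Z: np.ndarray
    Y: np.ndarray
    well_ids: list = field(default_factory=list)

    @property
    def n_wells(self) -> int:
        return len(self.Z)

    @property
    def has_counts(self) -> bool:
        return bool(self.include.any())

    @property
    def has_process(self) -> bool:
        return self.T > 0

    @classmethod
    def from_tables(
        cls,
        counts: pd.DataFrame | None,
        metadata: pd.DataFrame | None,
        plates: pd.DataFrame,
        phi: float = 20.0,
        include_counts: bool = True,
    ) -> "ModelData":
        counts = counts if counts is not None else pd.DataFrame(columns=["t", "N", "E"])
        metadata = (
            metadata
            if metadata is not None
            else pd.DataFrame(columns=["sample_id", "sample_class", "t", "sampler",
                                       "bio_rep", "F_l", "V_ul", "S_cm2", "P_days"])
        )
        t_max = -1
        if len(counts):
            t_max = max(t_max, int(counts["t"].max()))
        if len(metadata):
            t_max = max(t_max, int(metadata["t"].max()))
        T = t_max + 1

        N = np.zeros(T, dtype=float)
        E = np.zeros(T, dtype=float)
        if len(counts):
            N[counts["t"].to_numpy(dtype=int)] = counts["N"].to_numpy(dtype=float)
            E[counts["t"].to_numpy(dtype=int)] = counts["E"].to_numpy(dtype=float)
        include = (E > 0) if include_counts else np.zeros(T, dtype=bool)

        air_meta = metadata[metadata["sample_class"] == "air"]
        present = set(air_meta["sampler"].unique())
        samplers = tuple(s for s in SAMPLERS if s in present) + tuple(
            sorted(present - set(SAMPLERS))
        )
        max_rep = air_meta.groupby("sampler")["bio_rep"].max() if len(air_meta) else {}
        replicated = tuple(
            s for s in samplers
            if s in REPLICATED_SAMPLERS and len(air_meta) and max_rep.get(s, 1) >= 2
        )
        j_of = {s: j for j, s in enumerate(samplers)}
        r_of = {s: r for r, s in enumerate(replicated)}

        plate_ids = np.sort(plates["plate"].unique()) if len(plates) else np.array([0])
        p_of = {p: i for i, p in enumerate(plate_ids)}

        meta_by_id = metadata.set_index("sample_id") if len(metadata) else None
        kind, t_idx, j_idx, r_idx, sign, plate_idx = [], [], [], [], [], []
        K_known, m_norm, Z, Y, well_ids = [], [], [], [], []
        for row_i, row in plates.iterrows():
            cls_name = row["sample_class"]
            if cls_name not in _KIND:
                raise ValueError(f"row {row_i}: unknown sample_class {cls_name!r}")
            code = _KIND[cls_name]
            t = j = -1
            r, sg, m = -1, 0.0, np.nan
            K = np.nan
            if code == 0:
                K = float(row["K"])
            elif code == 3:
                K = 0.0
            else:
                sid = row["sample_id"]
                if meta_by_id is None or sid not in meta_by_id.index:
                    raise ValueError(
                        f"plate row {row_i}: sample_id {sid!r} not found in metadata"
                    )
                meta = meta_by_id.loc[sid]
                t = int(meta["t"])
                if code == 1:
                    m = float(meta["F_l"]) / float(meta["V_ul"])
                else:
                    s = meta["sampler"]
                    j = j_of[s]
                    m = float(meta["S_cm2"]) * float(meta["P_days"]) / float(meta["V_ul"])
                    if s in r_of:
                        r = r_of[s]
                        b = int(meta["bio_rep"])
                        sg = 1.0 if b == 1 else -1.0
            kind.append(code)
            t_idx.append(t)
            j_idx.append(j)
            r_idx.append(r)
            sign.append(sg)
            plate_idx.append(p_of[int(row["plate"])])
            K_known.append(K)
            m_norm.append(m)
            Z.append(int(row["Z"]))
            Y.append(float(row["Ct"]) if pd.notna(row["Ct"]) else np.nan)
            well_ids.append(row["sample_id"])

        return cls(
            T=T, N=N, E=E, include=include, phi=phi,
            samplers=samplers, replicated=replicated, plates=plate_ids,
            kind=np.array(kind), t_idx=np.array(t_idx), j_idx=np.array(j_idx),
            r_idx=np.array(r_idx), sign=np.array(sign),
            plate_idx=np.array(plate_idx), K_known=np.array(K_known),
            m_norm=np.array(m_norm), Z=np.array(Z), Y=np.array(Y),
            well_ids=well_ids,
        )


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

class ParamIndex:
    """Maps the unconstrained sampling vector to named blocks.

    Positivity-constrained scales (tau, rho, theta) are sampled on the log
    scale.  The latent state is sampled in data-pinned coordinates: the log
    water concentration ``log_W[t]`` and the air/water log anomaly
    ``alpha[t,j] = ln A_tj - ln W_t``, from which ``log X = log W - omega``
    and ``eps = alpha - eta`` are derived.  This is a unit-Jacobian linear
    shear of the natural parameterization chosen because the qPCR wells pin
    (W, A) per sample tightly while the scientific parameters (omega, eta,
    tau, rho) only touch them through smooth Gaussian terms — the geometry
    is then close to separable, which generic ensemble moves handle well.
    """

    def __init__(self, data: ModelData):
        self.data = data
        J, R, T, P = (
            len(data.samplers),
            len(data.replicated),
            data.T,
            len(data.plates),
        )
        self.J, self.R, self.P = J, R, P
        blocks: list[tuple[str, int]] = []
        if data.has_process:
            blocks.append(("log_W", T))
            blocks.append(("omega_log", 1))
        if J:
            blocks += [("eta", J), ("log_tau", J)]
        if R:
            blocks.append(("log_rho", R))
        if J:
            blocks.append(("alpha", T * J))
        if R:
            blocks.append(("delta", T * R))
        blocks += [
            ("log_theta", 1), ("beta0", 1), ("beta1", P),
            ("gamma0", 1), ("gamma1", 1),
        ]
        self.slices: dict[str, slice] = {}
        pos = 0
        for name, size in blocks:
            self.slices[name] = slice(pos, pos + size)
            pos += size
        self.ndim = pos

    def names(self) -> list[str]:
        out = []
        d = self.data
        for name, sl in self.slices.items():
            n = sl.stop - sl.start
            if name == "eta" or name == "log_tau":
                out += [f"{name}[{s}]" for s in d.samplers]
            elif name == "log_rho":
                out += [f"{name}[{s}]" for s in d.replicated]
            elif n == 1:
                out.append(name)
            else:
                out += [f"{name}[{i}]" for i in range(n)]
        return out

    def unpack(self, z: np.ndarray) -> dict[str, np.ndarray]:
        """Split a (..., ndim) array into named blocks (views)."""
        return {name: z[..., sl] for name, sl in self.slices.items()}


# ---------------------------------------------------------------------------
# joint density
# ---------------------------------------------------------------------------

@dataclass
class LatentProcess:
    """Natural-scale latent state for the public joint density."""

    X: np.ndarray                   # (T,) fish/day
    omega_log: float
    eta: np.ndarray                 # (J,)
    tau: np.ndarray                 # (J,)
    rho: np.ndarray                 # (R,)
    phi: float
    eps: np.ndarray                 # (T, J)
    delta_half: np.ndarray          # (T, R) free half-differences

    @property
    def delta(self) -> np.ndarray:
        """Replicate deviations (T, R, 2); sums to zero over b exactly."""
        return np.stack([self.delta_half, -self.delta_half], axis=-1)


def _halfcauchy_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    out = np.log(2.0 / np.pi) - np.log(scale) - np.log1p((x / scale) ** 2)
    return np.where(x > 0, out, -np.inf)


def _exponential_logpdf(x, mean):
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, -np.log(mean) - x / mean, -np.inf)


def _wells_loglik(K, Z, Y, plate_idx, theta, beta0, beta1, gamma0, gamma1):
    """Vectorized qPCR well log-likelihood.

    ``K`` has shape (..., n_wells); calibration parameters broadcast with a
    leading walker axis (theta, beta0, gamma0, gamma1 shaped (..., 1);
    beta1 (..., P) gathered per well).
    """
    Kt = K * theta
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        log_psi = np.log(-np.expm1(-Kt))
        bern = np.where(Z == 1, log_psi, -Kt)
        total = np.sum(bern, axis=-1)
        amp = Z == 1
        if amp.any():
            lnK = np.log(K[..., amp])
            b1 = beta1[..., plate_idx[amp]]
            mu = beta0 + b1 * lnK
            sigma = np.exp(gamma0 + gamma1 * lnK)
            total = total + np.sum(_normal_logpdf(Y[amp], mu, sigma), axis=-1)
    return total


def _normal_block(x, loc, scale):
    return np.sum(_normal_logpdf(np.asarray(x, dtype=float), loc, scale), axis=-1)


def joint_log_density(
    latent: LatentProcess,
    calib: QpcrCalibration,
    data: ModelData,
    priors: PriorConfig,
) -> float:
    """Log posterior density (up to a constant) at natural-scale parameters.

    The sum of four named pieces: the Negative Binomial count likelihood
    over included timepoints; the air-transfer terms (Normal eps and
    replicate half-difference deviations); the qPCR observation likelihood
    over every well with the unit normalizations mapping latent W/A to
    per-reaction concentrations; and the prior log-densities.  Calibration
    parameters are shared between the standards and environmental
    compartments.
    """
    d = data
    total = 0.0

    X = np.asarray(latent.X, dtype=float)
    W = water_concentration(X, latent.omega_log) if d.has_process else None

    # 1. counts
    if d.has_counts:
        lam = expected_count(X[d.include], d.E[d.include])
        total += float(np.sum(count_loglik(d.N[d.include], lam, latent.phi)))

    # 2. air transfer noise
    J, R = len(d.samplers), len(d.replicated)
    if J:
        total += float(
            np.sum(_normal_logpdf(latent.eps, 0.0, latent.tau[None, :]))
        )
    if R:
        total += float(
            np.sum(
                _normal_logpdf(latent.delta_half, 0.0, latent.rho[None, :] / _SQRT2)
            )
        )

    # 3. qPCR observations
    K = np.where(np.isnan(d.K_known), 0.0, d.K_known).astype(float)
    if d.has_process:
        water = d.kind == 1
        K[water] = W[d.t_idx[water]] * d.m_norm[water]
        air = d.kind == 2
        if air.any():
            lnA = (
                latent.eta[d.j_idx[air]]
                + np.log(W[d.t_idx[air]])
                + latent.eps[d.t_idx[air], d.j_idx[air]]
            )
            rep = d.r_idx[air] >= 0
            if rep.any():
                lnA = lnA + np.where(
                    rep,
                    d.sign[air]
                    * latent.delta_half[
                        d.t_idx[air], np.maximum(d.r_idx[air], 0)
                    ],
                    0.0,
                )
            K[air] = np.exp(lnA) * d.m_norm[air]
    total += _wells_loglik(
        K, d.Z, d.Y, d.plate_idx,
        calib.theta, calib.beta0, calib.beta1, calib.gamma0, calib.gamma1,
    )

    # 4. priors
    if d.has_process:
        total += _normal_block(np.log(X), *priors.log_x)
        total += _normal_block([latent.omega_log], *priors.omega_log)
    if J:
        total += _normal_block(latent.eta, *priors.eta)
        total += float(np.sum(_halfcauchy_logpdf(latent.tau, priors.tau_scale)))
    if R:
        total += float(np.sum(_halfcauchy_logpdf(latent.rho, priors.rho_scale)))
    total += float(_exponential_logpdf(calib.theta, priors.theta_mean))
    total += _normal_block([calib.beta0], *priors.beta0)
    total += _normal_block(calib.beta1, *priors.beta1)
    total += _normal_block([calib.gamma0], *priors.gamma0)
    total += _normal_block([calib.gamma1], *priors.gamma1)

    total = float(total)
    if not np.isfinite(total) and np.all(np.isfinite(X)):
        # finite inputs must give a finite density unless a support bound
        # (tau/rho/theta <= 0) was violated
        if (
            np.all(latent.tau > 0)
            and np.all(np.asarray(latent.rho) > 0)
            and calib.theta > 0
        ):
            raise AssertionError("non-finite joint density at finite inputs")
    return total


def make_log_prob(
    data: ModelData, priors: PriorConfig, pidx: ParamIndex | None = None
):
    """Vectorized unconstrained log-posterior for the ensemble sampler.

    Accepts a (n_walkers, ndim) matrix; returns (n_walkers,).  Equivalent to
    :func:`joint_log_density` after the change of variables (log scales for
    tau/rho/theta with their Jacobians; non-centered raw air deviates).
    """
    d = data
    pidx = pidx or ParamIndex(d)
    J, R, T = pidx.J, pidx.R, d.T
    water = d.kind == 1
    air = d.kind == 2
    K_base = np.where(np.isnan(d.K_known), 0.0, d.K_known).astype(float)
    inc = d.include
    air_t, air_j = d.t_idx[air], d.j_idx[air]
    air_r = np.maximum(d.r_idx[air], 0)
    air_rep = d.r_idx[air] >= 0
    air_sign = d.sign[air]
    air_m = d.m_norm[air]
    water_t, water_m = d.t_idx[water], d.m_norm[water]

    def log_prob(z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        nw = z.shape[0]
        b = pidx.unpack(z)
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            total = np.zeros(nw)

            theta = np.exp(np.clip(b["log_theta"], -40, 40))
            beta0 = b["beta0"]
            beta1 = b["beta1"]
            gamma0 = b["gamma0"]
            gamma1 = b["gamma1"]

            K = np.broadcast_to(K_base, (nw, d.n_wells)).copy()

            if d.has_process:
                lnW = b["log_W"]
                omega = b["omega_log"]
                logX = lnW - omega  # (nw, T)
                if d.has_counts:
                    lam = np.exp(logX[:, inc]) * d.E[inc]
                    total += np.sum(
                        gammaln(d.N[inc] + d.phi)
                        - gammaln(d.phi)
                        - gammaln(d.N[inc] + 1.0)
                        + d.phi * np.log(d.phi / (d.phi + lam))
                        + d.N[inc] * np.log(lam / (d.phi + lam)),
                        axis=-1,
                    )
                K[:, water] = np.exp(np.clip(lnW[:, water_t], -700, 700)) * water_m
                if J:
                    eta = b["eta"]
                    tau = np.exp(np.clip(b["log_tau"], -40, 40))
                    alpha = b["alpha"].reshape(nw, T, J)
                    lnA = lnW[:, air_t] + alpha[:, air_t, air_j]
                    if R:
                        rho = np.exp(np.clip(b["log_rho"], -40, 40))
                        delta = b["delta"].reshape(nw, T, R)
                        dhalf = delta[:, air_t, air_r]
                        lnA = lnA + np.where(air_rep, air_sign * dhalf, 0.0)
                    K[:, air] = np.exp(np.clip(lnA, -700, 700)) * air_m
                    # transfer terms: eps = alpha - eta ~ N(0, tau)
                    total += np.sum(
                        _normal_logpdf(
                            alpha - eta[:, None, :], 0.0, tau[:, None, :]
                        ),
                        axis=(-2, -1),
                    )
                    if R:
                        total += np.sum(
                            _normal_logpdf(
                                delta, 0.0, rho[:, None, :] / _SQRT2
                            ),
                            axis=(-2, -1),
                        )
                # priors on the process block
                total += _normal_block(logX, *priors.log_x)
                total += _normal_block(omega, *priors.omega_log)
                if J:
                    total += _normal_block(eta, *priors.eta)
                    # half-Cauchy prior + log-scale Jacobian
                    total += np.sum(
                        _halfcauchy_logpdf(tau, priors.tau_scale) + np.log(tau),
                        axis=-1,
                    )
                    if R:
                        total += np.sum(
                            _halfcauchy_logpdf(rho, priors.rho_scale) + np.log(rho),
                            axis=-1,
                        )

            total += _wells_loglik(
                K, d.Z, d.Y, d.plate_idx, theta, beta0, beta1, gamma0, gamma1
            )

            total += (
                _exponential_logpdf(theta[:, 0], priors.theta_mean)
                + np.clip(b["log_theta"][:, 0], -40, 40)
            )
            total += _normal_block(beta0, *priors.beta0)
            total += _normal_block(beta1, *priors.beta1)
            total += _normal_block(gamma0, *priors.gamma0)
            total += _normal_block(gamma1, *priors.gamma1)

        return np.where(np.isfinite(total), total, -np.inf)

    return log_prob
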