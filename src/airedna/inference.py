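"""MCMC fitting and the diagnostic protocol.

The joint posterior is defined once as a log-density (:mod:`airedna.model`)
and sampled by blocked Gibbs: every coordinate of the model has an exact
full conditional — conjugate Normal for the transfer intercepts and the
standard-curve coefficients, one-dimensional on fine data-centred grids for
everything else — so each chain is a bank of independent systematic-scan
Gibbs replicates.  ``n_chains`` fully independent chains are run and each
is thinned to ``n_sampling`` draws, so split-R-hat compares independent
runs.  Divergent-transition and tree-depth counters exist for interface
parity with Hamiltonian backends and are structurally zero for this
sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import McmcConfig, PriorConfig, child_seed
from .model import ModelData, ParamIndex, make_log_prob, _SQRT2

class FitError(RuntimeError):
    """Raised when sampler initialization fails after bounded retries."""


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _calib_init(d: ModelData) -> dict[str, float | np.ndarray]:
    """Crude calibration estimate from standard wells (least squares + grid)."""
    std = d.kind == 0
    P = len(d.plates)
    beta1 = np.full(P, -1.44)
    beta0, gamma0 = 38.0, -1.0
    amp = std & (d.Z == 1)
    if amp.sum() >= 3:
        lnK = np.log(d.K_known[amp])
        y = d.Y[amp]
        p_idx = d.plate_idx[amp]
        X = np.zeros((amp.sum(), 1 + P))
        X[:, 0] = 1.0
        X[np.arange(amp.sum()), 1 + p_idx] = lnK
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        beta0 = float(coef[0])
        gamma0 = float(np.log(max(np.std(y - X @ coef), 0.05)))
        for p in range(P):
            if np.any(p_idx == p):
                beta1[p] = coef[1 + p]
    theta = 1.0
    if std.any():
        grid = np.exp(np.linspace(-8, 3, 300))
        K, Z = d.K_known[std], d.Z[std]
        with np.errstate(divide="ignore"):
            ll = [
                float(
                    np.sum(
                        np.where(Z == 1, np.log(-np.expm1(-K * th)), -K * th)
                    )
                )
                for th in grid
            ]
        theta = float(grid[int(np.argmax(ll))])
    return {"theta": theta, "beta0": beta0, "beta1": beta1, "gamma0": gamma0,
            "gamma1": 0.0}


def initial_point(d: ModelData, priors: PriorConfig, pidx: ParamIndex) -> np.ndarray:
    """Data-informed starting point on the unconstrained scale."""
    z0 = np.zeros(pidx.ndim)
    b = pidx.slices
    cal = _calib_init(d)
    beta1_bar = float(np.mean(cal["beta1"]))

    z0[b["log_theta"]] = np.log(cal["theta"])
    z0[b["beta0"]] = cal["beta0"]
    z0[b["beta1"]] = cal["beta1"]
    z0[b["gamma0"]] = cal["gamma0"]
    z0[b["gamma1"]] = cal["gamma1"]

    if not d.has_process:
        return z0

    T = d.T

    def invert_ct(mask):
        """Mean per-t latent log medium concentration from amplified Cts."""
        out = np.full(T, np.nan)
        for t in range(T):
            sel = mask & (d.t_idx == t) & (d.Z == 1)
            if sel.any():
                lnK = (d.Y[sel] - cal["beta0"]) / beta1_bar
                out[t] = float(np.mean(lnK - np.log(d.m_norm[sel])))
        return out

    lnW = invert_ct(d.kind == 1)
    lnX_counts = np.full(T, np.nan)
    inc = d.include
    lnX_counts[inc] = np.log(np.maximum(d.N[inc] / np.maximum(d.E[inc], 1e-9), 0.5))

    both = np.isfinite(lnW) & np.isfinite(lnX_counts)
    if both.any():
        omega = float(np.mean(lnW[both] - lnX_counts[both]))
    else:
        omega = float(priors.omega_log[0])

    if np.isfinite(lnW).any():
        lnW_fill = np.where(np.isfinite(lnW), lnW, np.nanmean(lnW))
    else:
        lnW_fill = np.where(
            np.isfinite(lnX_counts), lnX_counts, priors.log_x[0]
        ) + omega
    z0[b["log_W"]] = lnW_fill
    z0[b["omega_log"]] = omega

    if pidx.J:
        air = d.kind == 2
        # per-(t, j) mean of Ct-inverted log air concentrations
        lnA_tj = np.full((T, pidx.J), np.nan)
        for j in range(pidx.J):
            for t in range(T):
                sel = air & (d.j_idx == j) & (d.t_idx == t) & (d.Z == 1)
                if sel.any():
                    lnA = (d.Y[sel] - cal["beta0"]) / beta1_bar - np.log(d.m_norm[sel])
                    lnA_tj[t, j] = float(np.mean(lnA))
        with np.errstate(invalid="ignore"):
            eta_tj = lnA_tj - lnW_fill[:, None]
        eta0 = np.nanmean(eta_tj, axis=0)
        found = np.isfinite(eta0)
        if found.any() and (~found).any():
            eta0[~found] = float(np.mean(eta0[found]))
        eta0[~np.isfinite(eta0)] = 0.0
        z0[b["eta"]] = eta0
        z0[b["log_tau"]] = np.log(0.7)
        alpha0 = np.where(np.isfinite(eta_tj), eta_tj, eta0[None, :])
        z0[b["alpha"]] = alpha0.reshape(-1)
        if pidx.R:
            z0[b["log_rho"]] = np.log(0.3)
            # delta starts at zero; walker scatter explores the pair split
    return z0


_SCATTER = {
    "log_W": 0.15, "omega_log": 0.3, "eta": 0.5, "log_tau": 0.3,
    "log_rho": 0.3, "alpha": 0.3, "delta": 0.2,
    "log_theta": 0.3, "beta0": 0.3, "beta1": 0.1, "gamma0": 0.3, "gamma1": 0.1,
}


def _scatter_vector(pidx: ParamIndex) -> np.ndarray:
    s = np.empty(pidx.ndim)
    for name, sl in pidx.slices.items():
        s[sl] = _SCATTER[name]
    return s


# ---------------------------------------------------------------------------
# FitResult
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Posterior draws plus the diagnostic bundle."""

    z: np.ndarray                      # (chains, draws, ndim) unconstrained
    pidx: ParamIndex
    data: ModelData
    priors: PriorConfig
    mcmc: McmcConfig
    log_posterior: np.ndarray          # (chains, draws)
    acceptance: np.ndarray             # per-chain mean acceptance fraction
    n_divergent: int = 0
    treedepth_saturations: int = 0
    _rhat: dict | None = field(default=None, repr=False)
    _ess: dict | None = field(default=None, repr=False)

    # -- natural-scale draws ------------------------------------------------
    def draws(self) -> dict[str, np.ndarray]:
        """Posterior draws on the natural scale, keyed by symbol."""
        b = self.pidx.unpack(self.z)
        out: dict[str, np.ndarray] = {}
        if self.data.has_process:
            out["W"] = np.exp(b["log_W"])
            out["omega_log"] = b["omega_log"][..., 0]
            out["X"] = np.exp(b["log_W"] - b["omega_log"])
        if self.pidx.J:
            out["eta"] = b["eta"]
            out["tau"] = np.exp(b["log_tau"])
            T, J = self.data.T, self.pidx.J
            alpha = b["alpha"].reshape(*self.z.shape[:2], T, J)
            out["eps"] = alpha - b["eta"][..., None, :]
        if self.pidx.R:
            out["rho"] = np.exp(b["log_rho"])
            T, R = self.data.T, self.pidx.R
            out["delta_half"] = b["delta"].reshape(*self.z.shape[:2], T, R)
        out["theta"] = np.exp(b["log_theta"][..., 0])
        out["beta0"] = b["beta0"][..., 0]
        out["beta1"] = b["beta1"]
        out["gamma0"] = b["gamma0"][..., 0]
        out["gamma1"] = b["gamma1"][..., 0]
        return out

    def replicate_deltas(self) -> np.ndarray:
        """Replicate deviations (chains, draws, T, R, 2); zero-sum over b."""
        dh = self.draws()["delta_half"]
        return np.stack([dh, -dh], axis=-1)

    def _scalar_draws(self) -> dict[str, np.ndarray]:
        """Interpretable scalar series (chains, draws) keyed by name."""
        d = self.draws()
        out: dict[str, np.ndarray] = {}
        data = self.data
        if "X" in d:
            for t in range(data.T):
                out[f"X[{t}]"] = d["X"][..., t]
            out["omega_log"] = d["omega_log"]
        if "eta" in d:
            for j, s in enumerate(data.samplers):
                out[f"eta[{s}]"] = d["eta"][..., j]
                out[f"tau[{s}]"] = d["tau"][..., j]
        if "rho" in d:
            for r, s in enumerate(data.replicated):
                out[f"rho[{s}]"] = d["rho"][..., r]
        out["theta"] = d["theta"]
        out["beta0"] = d["beta0"]
        for p in range(self.pidx.P):
            out[f"beta1[{p}]"] = d["beta1"][..., p]
        out["gamma0"] = d["gamma0"]
        out["gamma1"] = d["gamma1"]
        return out

    # -- diagnostics ---------------------------------------------------------
    def rhat(self, free: bool = True) -> dict[str, float]:
        """Rank-normalized split R-hat per free parameter."""
        if self._rhat is None:
            names = self.pidx.names() if free else list(self._scalar_draws())
            series = (
                {n: self.z[..., i] for i, n in enumerate(names)}
                if free
                else self._scalar_draws()
            )
            self._rhat = {n: compute_rhat(v) for n, v in series.items()}
        return self._rhat

    def ess(self, free: bool = True) -> dict[str, float]:
        """Bulk effective sample size per free parameter."""
        if self._ess is None:
            names = self.pidx.names() if free else list(self._scalar_draws())
            series = (
                {n: self.z[..., i] for i, n in enumerate(names)}
                if free
                else self._scalar_draws()
            )
            self._ess = {n: compute_ess(v) for n, v in series.items()}
        return self._ess

    def passes(self, rhat_max: float = 1.05, ess_min: float = 1000.0) -> bool:
        """Convergence protocol: R-hat, ESS, divergences, tree depth."""
        r = np.array(list(self.rhat().values()), dtype=float)
        e = np.array(list(self.ess().values()), dtype=float)
        return bool(
            np.all(r[np.isfinite(r)] < rhat_max)
            and np.all(e[np.isfinite(e)] > ess_min)
            and self.n_divergent == 0
            and self.treedepth_saturations == 0
        )

    def summary(self) -> pd.DataFrame:
        """Posterior summary table on the natural scale.

        R-hat/ESS are computed on each natural-scale series directly (rank
        statistics are invariant under the monotone log transforms).
        """
        rows = []
        for name, v in self._scalar_draws().items():
            flat = v.reshape(-1)
            rows.append({
                "param": name,
                "mean": float(np.mean(flat)),
                "sd": float(np.std(flat)),
                "q2.5": float(np.quantile(flat, 0.025)),
                "q50": float(np.quantile(flat, 0.5)),
                "q97.5": float(np.quantile(flat, 0.975)),
                "rhat": compute_rhat(v),
                "ess": compute_ess(v),
            })
        return pd.DataFrame(rows).set_index("param")

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        flat = self._scalar_draws()[name].reshape(-1)
        a = (1.0 - level) / 2.0
        return float(np.quantile(flat, a)), float(np.quantile(flat, 1 - a))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _grid_draw(logpdf: np.ndarray, grid: np.ndarray, rng) -> np.ndarray:
    """Inverse-CDF draw from a discretized 1-D conditional, per row.

    ``logpdf`` has shape (..., G) over ``grid`` (possibly non-uniform); the
    draw picks a grid cell by its probability mass (density times cell
    width) and jitters uniformly within it.  Grids are fine near the mass
    so the residual discretization error is far below Monte Carlo error.
    """
    widths = np.gradient(grid)
    m = logpdf.max(axis=-1, keepdims=True)
    w = np.exp(logpdf - m) * widths
    c = np.cumsum(w, axis=-1)
    u = rng.random(c.shape[:-1] + (1,)) * c[..., -1:]
    idx = np.minimum((c < u).sum(axis=-1), len(grid) - 1)
    return grid[idx] + (rng.random(idx.shape) - 0.5) * widths[idx]


def _sinh_grid(center: float, half_width: float, n: int, stretch: float = 3.0):
    """Grid concentrated near ``center``: fine in the middle, coarse at the
    edges (resolution ratio ~ cosh(stretch))."""
    u = np.linspace(-stretch, stretch, n)
    return center + half_width * np.sinh(u) / np.sinh(stretch)


class _GibbsKernel:
    """Per-walker blocked-Gibbs pass over the latent air state and the
    hierarchy scalars, interleaved with the ensemble moves.

    Generic ensemble proposals move all coordinates at once, so narrow or
    funnel-shaped directions (each air sample's log anomaly alpha, the
    replicate half-differences delta, and the scales tau/rho) decorrelate
    slowly.  Their full conditionals are closed-form Normal (eta) or
    one-dimensional (alpha, delta, log tau, log rho, omega), so this kernel
    refreshes them exactly — leaving the posterior invariant — on fixed,
    data-centred grids built once per fit.
    """

    def __init__(self, d: ModelData, priors: PriorConfig, pidx: ParamIndex,
                 z0: np.ndarray):
        self.d, self.priors, self.pidx = d, priors, pidx
        b = pidx.slices
        T = d.T
        self.omega_grid = None
        if d.has_process:
            om0 = float(z0[b["omega_log"]][0])
            mo, so = priors.omega_log
            # fine around the data-informed start, coarse across the prior
            fine = np.linspace(om0 - 6.0, om0 + 6.0, 800)
            coarse = np.linspace(mo - 4.0 * so, mo + 4.0 * so, 400)
            self.omega_grid = np.unique(np.concatenate([fine, coarse]))
        air = d.kind == 2
        # per-(t, j) cells: well indices and an alpha grid centred at the
        # data-informed starting anomaly (fixed, hence a valid kernel).
        # Cells with no wells at all are marked prior-only: they drop out of
        # the eta/tau conditionals analytically (partially collapsed Gibbs)
        # and are redrawn from N(eta, tau) exactly.
        self.alpha_cells = []
        self.alpha_obs = np.zeros((T, max(pidx.J, 1)), dtype=bool)
        if pidx.J:
            alpha0 = z0[b["alpha"]].reshape(T, pidx.J)
            for t in range(T):
                for j in range(pidx.J):
                    sel = np.flatnonzero(air & (d.t_idx == t) & (d.j_idx == j))
                    if not len(sel):
                        continue
                    self.alpha_obs[t, j] = True
                    # cells whose wells never amplified are weakly informed:
                    # the grid must span the eta prior, not just the data
                    half = (
                        4.0 if d.Z[sel].any()
                        else max(10.0, 8.0 * priors.eta[1])
                    )
                    grid = _sinh_grid(float(alpha0[t, j]), half, 161)
                    self.alpha_cells.append((t, j, sel, grid))
        # per-(t, r) replicate pairs for delta; same prior-only collapse
        self.delta_cells = []
        self.delta_obs = np.zeros((T, max(pidx.R, 1)), dtype=bool)
        if pidx.R:
            j_of_r = [d.samplers.index(s) for s in d.replicated]
            for r in range(pidx.R):
                for t in range(T):
                    sel = np.flatnonzero(air & (d.t_idx == t) & (d.r_idx == r))
                    if not len(sel):
                        continue
                    self.delta_obs[t, r] = True
                    self.delta_cells.append(
                        (t, r, j_of_r[r], sel, _sinh_grid(0.0, 2.5, 161))
                    )
        self.scale_grid = np.linspace(np.log(0.02), np.log(12.0), 300)
        self.w_line_grid = _sinh_grid(0.0, 1.5, 161, stretch=4.0)
        # per-t cells for log_W: the water wells plus every air well at t
        self.w_cells = []
        if d.has_process:
            lnW0 = z0[b["log_W"]]
            water = d.kind == 1
            for t in range(T):
                sel = np.flatnonzero((water | air) & (d.t_idx == t))
                self.w_cells.append(
                    (t, sel, _sinh_grid(float(lnW0[t]), 3.5, 161))
                )
        # theta: all wells enter; controls (K=0) contribute nothing
        self.theta_grid = np.linspace(np.log(1e-4), np.log(20.0), 140)
        self.theta_z1 = np.flatnonzero((d.Z == 1) & (d.kind != 3))
        self.theta_z0 = np.flatnonzero(d.Z == 0)
        # Ct log-sd coefficients: fixed grids spanning their priors
        g0m, g0s = priors.gamma0
        g1m, g1s = priors.gamma1
        self.gamma0_grid = np.linspace(g0m - 3.5 * g0s, g0m + 3.5 * g0s, 800)
        # fixed centring constant and grid for the gamma long-axis line
        # draw; together with the gamma0-axis update it spans the
        # near-collinear (gamma0, gamma1) plane with exact conditionals
        std_amp = (d.kind == 0) & (d.Z == 1)
        self.lnK_bar = (
            float(np.mean(np.log(d.K_known[std_amp]))) if std_amp.any() else 7.0
        )
        self.gamma_line_grid = _sinh_grid(0.0, 3.5 * g1s, 241, stretch=4.0)
        # direction constants for the calibration/latent long-axis move:
        # beta0 += s with every latent log concentration += s/|beta1|
        b1_init = z0[b["beta1"]]
        self.b1_mag = float(np.mean(np.abs(b1_init))) or 1.44
        self.beta_line_grid = _sinh_grid(0.0, 1.0, 241, stretch=4.0)

    def _well_terms(self, lnK, sel, calib):
        """Sum over wells ``sel`` of Bernoulli + Normal terms; lnK has a
        trailing wells axis."""
        d = self.d
        theta, beta0, beta1, gamma0, gamma1 = calib
        K = np.exp(np.clip(lnK, -700, 700))
        Kt = K * theta[:, :, None]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            ll = np.where(d.Z[sel] == 1, np.log(-np.expm1(-Kt)), -Kt)
            ll = np.where(np.isfinite(ll), ll, -1e12)
            amp = d.Z[sel] == 1
            if amp.any():
                mu = beta0[:, :, None] + beta1[:, d.plate_idx[sel]][:, None, :] * lnK
                sig = np.exp(gamma0[:, :, None] + gamma1[:, :, None] * lnK)
                norm = -np.log(sig) - 0.5 * ((d.Y[sel] - mu) / sig) ** 2
                ll = ll + np.where(amp[None, None, :], norm, 0.0)
        return ll.sum(axis=-1)

    def __call__(self, z: np.ndarray, rng) -> np.ndarray:
        d, priors, pidx = self.d, self.priors, self.pidx
        z = z.copy()
        b = pidx.slices
        nw = z.shape[0]
        T = d.T
        lg = self.scale_grid
        calib = (
            np.exp(z[:, b["log_theta"]]), z[:, b["beta0"]],
            z[:, b["beta1"]], z[:, b["gamma0"]], z[:, b["gamma1"]],
        )
        lnW = alpha = delta = omega = None
        if d.has_process:
            lnW = z[:, b["log_W"]].copy()
            omega = z[:, b["omega_log"]][:, 0]
        if pidx.J:
            alpha = z[:, b["alpha"]].reshape(nw, T, pidx.J).copy()
        if pidx.R:
            delta = z[:, b["delta"]].reshape(nw, T, pidx.R).copy()

        if d.has_process:
            # log_W_t | rest — the water and air wells at t, the count term
            # through log X = log W - omega, and the log X prior
            mx, sx = priors.log_x
            for t, sel, grid in self.w_cells:
                lnXg = grid[None, :] - omega[:, None]
                logp = -0.5 * ((lnXg - mx) / sx) ** 2
                if d.include[t]:
                    lam = np.exp(np.clip(lnXg, -700, 700)) * d.E[t]
                    logp = logp + (
                        d.phi * np.log(d.phi / (d.phi + lam))
                        + d.N[t] * np.log(lam / (d.phi + lam))
                    )
                if len(sel):
                    off = np.broadcast_to(
                        np.log(d.m_norm[sel]), (nw, len(sel))
                    ).copy()
                    is_air = d.kind[sel] == 2
                    if is_air.any():
                        aj = d.j_idx[sel[is_air]]
                        off[:, is_air] += alpha[:, t, aj]
                        if pidx.R:
                            rr = d.r_idx[sel[is_air]]
                            rep = rr >= 0
                            if rep.any():
                                sg = d.sign[sel[is_air]][rep]
                                cols = np.flatnonzero(is_air)[rep]
                                off[:, cols] += sg[None, :] * delta[:, t, rr[rep]]
                    lnK = grid[None, :, None] + off[:, None, :]
                    logp = logp + self._well_terms(lnK, sel, calib)
                lnW[:, t] = _grid_draw(logp, grid, rng)
            z[:, b["log_W"]] = lnW

        if pidx.J:
            J = pidx.J
            eta = z[:, b["eta"]]
            tau = np.exp(z[:, b["log_tau"]])

            # alpha_tj | rest
            for t, j, sel, grid in self.alpha_cells:
                logp = -0.5 * (
                    (grid[None, :] - eta[:, j : j + 1]) / tau[:, j : j + 1]
                ) ** 2
                if len(sel):
                    shift = np.zeros(len(sel))
                    if pidx.R and (d.r_idx[sel] >= 0).all():
                        r = int(d.r_idx[sel][0])
                        shift = d.sign[sel][None, None, :] * \
                            delta[:, t, r][:, None, None]
                    lnK = (
                        lnW[:, t][:, None, None]
                        + grid[None, :, None]
                        + np.log(d.m_norm[sel])[None, None, :]
                        + shift
                    )
                    logp = logp + self._well_terms(lnK, sel, calib)
                alpha[:, t, j] = _grid_draw(logp, grid, rng)

            # (log W_t, alpha_t.) long axis: the air wells pin the sums
            # log W + alpha, so the pair is near-collinear; draw exactly
            # along the fixed line log W_t += u, alpha_tj -= u (air wells
            # invariant; water wells, transfer terms, counts and the log X
            # prior inform u)
            ug = self.w_line_grid
            mx, sx = priors.log_x
            water = d.kind == 1
            for t in range(T):
                logp = -0.5 * (
                    ((lnW[:, t, None] + ug[None, :] - omega[:, None]) - mx)
                    / sx
                ) ** 2
                if d.include[t]:
                    lam = np.exp(
                        np.clip(
                            lnW[:, t, None] + ug[None, :] - omega[:, None],
                            -700, 700,
                        )
                    ) * d.E[t]
                    logp = logp + (
                        d.phi * np.log(d.phi / (d.phi + lam))
                        + d.N[t] * np.log(lam / (d.phi + lam))
                    )
                # transfer terms for the shifted alphas
                logp = logp - 0.5 * np.sum(
                    (
                        (alpha[:, t, :][:, None, :] - ug[None, :, None]
                         - eta[:, None, :])
                        / tau[:, None, :]
                    ) ** 2,
                    axis=-1,
                )
                sel = np.flatnonzero(water & (d.t_idx == t))
                if len(sel):
                    lnK = (
                        lnW[:, t][:, None, None]
                        + ug[None, :, None]
                        + np.log(d.m_norm[sel])[None, None, :]
                    )
                    logp = logp + self._well_terms(lnK, sel, calib)
                u = _grid_draw(logp, ug, rng)
                lnW[:, t] = lnW[:, t] + u
                alpha[:, t, :] = alpha[:, t, :] - u[:, None]
            z[:, b["log_W"]] = lnW

            # eta_j | alpha_obs, tau — conjugate Normal over the cells that
            # carry wells (well-less cells are integrated out exactly)
            obs = self.alpha_obs[:, :J]
            n_obs = obs.sum(axis=0)                              # (J,)
            m_eta, s_eta = priors.eta
            prec = n_obs / tau**2 + 1.0 / s_eta**2
            a_sum = (alpha * obs[None, :, :]).sum(axis=1)
            mean = (a_sum / tau**2 + m_eta / s_eta**2) / prec
            eta = mean + rng.standard_normal((nw, J)) / np.sqrt(prec)
            z[:, b["eta"]] = eta

            # log tau_j | alpha_obs, eta — half-Cauchy prior + Jacobian
            ss = np.sum(((alpha - eta[:, None, :]) ** 2) * obs[None, :, :],
                        axis=1)
            tg = np.exp(lg)
            logp = (
                -n_obs[None, :, None] * lg[None, None, :]
                - ss[..., None] / (2.0 * tg[None, None, :] ** 2)
                - np.log1p((tg[None, None, :] / priors.tau_scale) ** 2)
                + lg[None, None, :]
            )
            z[:, b["log_tau"]] = _grid_draw(logp, lg, rng)
            tau = np.exp(z[:, b["log_tau"]])

            # prior-only cells: exact conditional draw alpha ~ N(eta, tau)
            if (~obs).any():
                for t, j in zip(*np.nonzero(~obs)):
                    alpha[:, t, j] = (
                        eta[:, j] + tau[:, j] * rng.standard_normal(nw)
                    )
            z[:, b["alpha"]] = alpha.reshape(nw, T * J)

            if pidx.R:
                # delta_tr | rest — the two replicates' wells enter with
                # opposite signs; Gibbs refreshes prevent the funnel where
                # small rho freezes the half-differences and vice versa
                rho = np.exp(z[:, b["log_rho"]])
                for t, r, j, sel, grid in self.delta_cells:
                    logp = -(grid[None, :] ** 2) / (rho[:, r : r + 1] ** 2)
                    if len(sel):
                        lnK = (
                            (lnW[:, t] + alpha[:, t, j])[:, None, None]
                            + d.sign[sel][None, None, :] * grid[None, :, None]
                            + np.log(d.m_norm[sel])[None, None, :]
                        )
                        logp = logp + self._well_terms(lnK, sel, calib)
                    delta[:, t, r] = _grid_draw(logp, grid, rng)

                # log rho_r | delta_obs — well-less pairs integrated out
                dobs = self.delta_obs[:, :pidx.R]
                n_dobs = dobs.sum(axis=0)
                ss = np.sum((delta**2) * dobs[None, :, :], axis=1)
                rg = np.exp(lg)
                var = rg**2 / 2.0
                logp = (
                    -n_dobs[None, :, None] * 0.5 * np.log(var)[None, None, :]
                    - ss[..., None] / (2.0 * var[None, None, :])
                    - np.log1p((rg[None, None, :] / priors.rho_scale) ** 2)
                    + lg[None, None, :]
                )
                z[:, b["log_rho"]] = _grid_draw(logp, lg, rng)
                rho = np.exp(z[:, b["log_rho"]])
                if (~dobs).any():
                    for t, r in zip(*np.nonzero(~dobs)):
                        delta[:, t, r] = (
                            rho[:, r] / _SQRT2
                        ) * rng.standard_normal(nw)
                z[:, b["delta"]] = delta.reshape(nw, T * pidx.R)

        if d.has_process and self.omega_grid is not None:
            lnW = z[:, b["log_W"]]
            og = self.omega_grid
            mx, sx = priors.log_x
            mo, so = priors.omega_log
            logp = -0.5 * ((og[None, :] - mo) / so) ** 2
            lnX = lnW[:, None, :] - og[None, :, None]           # (nw, G, T)
            logp = logp - 0.5 * np.sum(((lnX - mx) / sx) ** 2, axis=-1)
            if d.has_counts:
                inc = d.include
                lam = np.exp(np.clip(lnX[..., inc], -700, 700)) * d.E[inc]
                phi = d.phi
                logp = logp + np.sum(
                    phi * np.log(phi / (phi + lam))
                    + d.N[inc] * np.log(lam / (phi + lam)),
                    axis=-1,
                )
            z[:, b["omega_log"]] = _grid_draw(logp, og, rng)[:, None]

        # log theta | rest — every well's Bernoulli term (Ct terms do not
        # involve theta); amplified-control wells would be theta-independent
        # and are excluded
        K = np.broadcast_to(
            np.where(np.isnan(d.K_known), 0.0, d.K_known), (nw, d.n_wells)
        ).copy()
        if d.has_process:
            water = d.kind == 1
            K[:, water] = np.exp(
                np.clip(lnW[:, d.t_idx[water]], -700, 700)
            ) * d.m_norm[water]
            air = d.kind == 2
            if air.any():
                at, aj = d.t_idx[air], d.j_idx[air]
                lnA = lnW[:, at] + alpha[:, at, aj]
                if pidx.R:
                    ar = np.maximum(d.r_idx[air], 0)
                    lnA = lnA + np.where(
                        d.r_idx[air] >= 0, d.sign[air] * delta[:, at, ar], 0.0
                    )
                K[:, air] = np.exp(np.clip(lnA, -700, 700)) * d.m_norm[air]
        tg = np.exp(self.theta_grid)
        s0 = K[:, self.theta_z0].sum(axis=1)
        logp = -tg[None, :] * s0[:, None]
        if len(self.theta_z1):
            with np.errstate(divide="ignore", over="ignore"):
                Kt = K[:, None, self.theta_z1] * tg[None, :, None]
                lp1 = np.log(-np.expm1(-Kt))
                logp = logp + np.where(np.isfinite(lp1), lp1, -1e12).sum(axis=-1)
        logp = logp - tg[None, :] / priors.theta_mean + self.theta_grid[None, :]
        z[:, b["log_theta"]] = _grid_draw(logp, self.theta_grid, rng)[:, None]

        # calibration | rest — the Ct terms of all amplified wells.  The
        # intercept and the plate slopes are drawn JOINTLY from their exact
        # multivariate-Normal conditional: ln K sits far from zero, so
        # (beta0, beta1p) are near-perfectly correlated and coordinate-wise
        # scans would crawl
        z1 = self.theta_z1
        if len(z1):
            lnK = np.log(np.maximum(K[:, z1], 1e-300))          # (nw, n1)
            Y1 = d.Y[z1]
            p1 = d.plate_idx[z1]
            gamma0 = z[:, b["gamma0"]][:, 0]
            gamma1 = z[:, b["gamma1"]][:, 0]
            inv2 = np.exp(-2.0 * (gamma0[:, None] + gamma1[:, None] * lnK))

            m0, s0 = priors.beta0
            m1, s1 = priors.beta1
            P = len(d.plates)
            dim = 1 + P
            A = np.zeros((nw, dim, dim))
            rhs = np.zeros((nw, dim))
            A[:, 0, 0] = inv2.sum(axis=1) + 1.0 / s0**2
            rhs[:, 0] = (inv2 * Y1).sum(axis=1) + m0 / s0**2
            for p in range(P):
                on = p1 == p
                if not on.any():
                    A[:, 1 + p, 1 + p] = 1.0 / s1**2
                    rhs[:, 1 + p] = m1 / s1**2
                    continue
                x = lnK[:, on]
                w2 = inv2[:, on]
                A[:, 0, 1 + p] = A[:, 1 + p, 0] = (x * w2).sum(axis=1)
                A[:, 1 + p, 1 + p] = (x**2 * w2).sum(axis=1) + 1.0 / s1**2
                rhs[:, 1 + p] = (x * w2 * Y1[on]).sum(axis=1) + m1 / s1**2
            mean = np.linalg.solve(A, rhs[..., None])[..., 0]
            cov = np.linalg.inv(A)
            L = np.linalg.cholesky(cov)
            draw = mean + np.einsum(
                "wij,wj->wi", L, rng.standard_normal((nw, dim))
            )
            beta0 = draw[:, 0]
            beta1 = draw[:, 1:]
            z[:, b["beta0"]] = beta0[:, None]
            z[:, b["beta1"]] = beta1

            resid = Y1 - beta0[:, None] - beta1[:, p1] * lnK     # (nw, n1)
            n1 = len(z1)

            # gamma0 | rest factorizes: sum_w [-(g + g1*lnK) -
            # r^2 e^{-2 g1 lnK} e^{-2g}/2] = -n*g - e^{-2g} * S / 2 + const,
            # with S a per-walker sufficient statistic
            g = self.gamma0_grid
            gamma1 = z[:, b["gamma1"]][:, 0]
            S = (resid**2 * np.exp(-2.0 * gamma1[:, None] * lnK)).sum(axis=1)
            mg, sg = priors.gamma0
            logp = (
                -n1 * g[None, :]
                - 0.5 * S[:, None] * np.exp(-2.0 * g)[None, :]
                - 0.5 * ((g[None, :] - mg) / sg) ** 2
            )
            z[:, b["gamma0"]] = _grid_draw(logp, g, rng)[:, None]

            # (gamma0, gamma1) are near-collinear because ln K is far from
            # zero; the gamma0-axis update above plus an exact draw along
            # the fixed line (gamma0 - lnKbar*t, gamma1 + t) — the long
            # axis — span the plane
            mg, sg = priors.gamma1
            gamma0 = z[:, b["gamma0"]][:, 0]
            gamma1 = z[:, b["gamma1"]][:, 0]
            tgrid = self.gamma_line_grid
            mbar = self.lnK_bar
            base = gamma0[:, None, None] + gamma1[:, None, None] * lnK[:, None, :]
            lsd = base + tgrid[None, :, None] * (lnK[:, None, :] - mbar)
            logp = (
                -lsd - 0.5 * resid[:, None, :] ** 2 * np.exp(-2.0 * lsd)
            ).sum(axis=-1)
            m0g, s0g = priors.gamma0
            logp = logp - 0.5 * (
                ((gamma0[:, None] - mbar * tgrid[None, :]) - m0g) / s0g
            ) ** 2
            logp = logp - 0.5 * (
                ((gamma1[:, None] + tgrid[None, :]) - mg) / sg
            ) ** 2
            t_draw = _grid_draw(logp, tgrid, rng)
            z[:, b["gamma0"]] = (gamma0 - mbar * t_draw)[:, None]
            z[:, b["gamma1"]] = (gamma1 + t_draw)[:, None]

        if len(z1) and d.has_process:
            # calibration/latent long axis: the Ct intercept trades off
            # against every latent log concentration (only the standards,
            # whose K are known, pin the combination).  Draw exactly along
            # the fixed line beta0 += s, log W_t += s/|beta1_init|,
            # omega += s/|beta1_init|; log X and the transfer terms are
            # invariant along it
            sgrid = self.beta_line_grid
            b1m = self.b1_mag
            envm = ((d.kind == 1) | (d.kind == 2)).astype(float)
            theta = np.exp(z[:, b["log_theta"]])[:, :, None]
            beta0 = z[:, b["beta0"]][:, 0]
            beta1 = z[:, b["beta1"]]
            gamma0 = z[:, b["gamma0"]][:, 0]
            gamma1 = z[:, b["gamma1"]][:, 0]
            shift = sgrid[None, :, None] * envm[None, None, :] / b1m
            with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
                Ks = K[:, None, :] * np.exp(shift)
                Kt = Ks * theta
                bern = np.where(
                    d.Z[None, None, :] == 1, np.log(-np.expm1(-Kt)), -Kt
                )
                bern = np.where(np.isfinite(bern), bern, -1e12)
                logp = bern.sum(axis=-1)
                amp = d.Z == 1
                lnKs = np.log(np.maximum(K[:, amp], 1e-300))[:, None, :] \
                    + shift[..., amp]
                mu = (
                    (beta0[:, None] + sgrid[None, :])[:, :, None]
                    + beta1[:, d.plate_idx[amp]][:, None, :] * lnKs
                )
                sig = np.exp(
                    gamma0[:, None, None] + gamma1[:, None, None] * lnKs
                )
                logp = logp + (
                    -np.log(sig) - 0.5 * ((d.Y[amp] - mu) / sig) ** 2
                ).sum(axis=-1)
            mo, so = priors.omega_log
            m0, s0 = priors.beta0
            omega_cur = z[:, b["omega_log"]][:, 0]
            logp = logp - 0.5 * (
                ((omega_cur[:, None] + sgrid[None, :] / b1m) - mo) / so
            ) ** 2
            logp = logp - 0.5 * (
                ((beta0[:, None] + sgrid[None, :]) - m0) / s0
            ) ** 2
            s_draw = _grid_draw(logp, sgrid, rng)
            z[:, b["beta0"]] = (beta0 + s_draw)[:, None]
            z[:, b["log_W"]] = z[:, b["log_W"]] + (s_draw / b1m)[:, None]
            z[:, b["omega_log"]] = (omega_cur + s_draw / b1m)[:, None]
        return z

def _as_model_data(data, phi: float, include_counts: bool) -> ModelData:
    if isinstance(data, ModelData):
        return data
    if hasattr(data, "counts") and hasattr(data, "plates"):
        return ModelData.from_tables(
            data.counts, data.metadata, data.plates, phi=phi,
            include_counts=include_counts,
        )
    counts, metadata, plates = data
    return ModelData.from_tables(
        counts, metadata, plates, phi=phi, include_counts=include_counts
    )


#: parallel replicate sub-chains per chain; scan counts divide by this
_REPLICATES = 20
#: minimum warmup scans regardless of the iteration budget
_MIN_WARMUP_SCANS = 30


def fit(
    data,
    priors: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
    phi: float = 20.0,
    include_counts: bool = True,
) -> FitResult:
    """Sample the joint posterior by parallel blocked-Gibbs scans.

    ``data`` may be a :class:`~airedna.synth.SyntheticDataset`, a
    ``(counts, metadata, plates)`` tuple of tables, or a pre-compiled
    :class:`ModelData`.

    Every coordinate has an exact (conjugate or fine-grid 1-D) full
    conditional in :class:`_GibbsKernel`, so each chain runs a bank of
    independent systematic-scan Gibbs replicates; per chain,
    ``mcmc.n_warmup`` and ``mcmc.n_sampling`` iterations are laid out as
    ``iterations / replicates`` scans over ``_REPLICATES`` replicate
    sub-chains, and the retained scan states are thinned to exactly
    ``n_sampling`` draws.  Deterministic given ``mcmc.seed``.  Convergence
    is not guaranteed — inspect the diagnostics.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig.reduced()
    d = _as_model_data(data, phi, include_counts)
    pidx = ParamIndex(d)
    log_prob = make_log_prob(d, priors, pidx)
    z0 = initial_point(d, priors, pidx)
    scatter = _scatter_vector(pidx)
    ndim = pidx.ndim
    R = mcmc.n_walkers or _REPLICATES
    warm_scans = max(_MIN_WARMUP_SCANS, -(-mcmc.n_warmup // R))
    keep_scans = max(-(-mcmc.n_sampling // R), 1)
    kernel = _GibbsKernel(d, priors, pidx, z0)

    chains, lp_chains = [], []
    for c in range(mcmc.n_chains):
        seed_c = child_seed(mcmc.seed, f"chain-{c}")
        rng = np.random.default_rng(seed_c)
        state = z0 + scatter * rng.standard_normal((R, ndim))
        lp0 = log_prob(state)
        for _retry in range(20):
            bad = ~np.isfinite(lp0)
            if not bad.any():
                break
            state[bad] = z0 + 0.1 * scatter * rng.standard_normal(
                (bad.sum(), ndim)
            )
            lp0 = log_prob(state)
        else:
            raise FitError(
                f"chain {c}: could not find finite starting points "
                f"({(~np.isfinite(lp0)).sum()}/{R} replicates non-finite)"
            )
        kept = np.empty((keep_scans, R, ndim))
        for scan in range(warm_scans + keep_scans):
            state = kernel(state, rng)
            if scan >= warm_scans:
                kept[scan - warm_scans] = state
        # replicate-major layout keeps each sub-chain's scans adjacent so
        # autocorrelation-based diagnostics see the true dependence
        flat = kept.transpose(1, 0, 2).reshape(R * keep_scans, ndim)
        idx = (np.arange(mcmc.n_sampling) * len(flat)) // mcmc.n_sampling
        draws = flat[idx]
        chains.append(draws)
        lp_chains.append(log_prob(draws))

    return FitResult(
        z=np.stack(chains), pidx=pidx, data=d, priors=priors, mcmc=mcmc,
        log_posterior=np.stack(lp_chains),
        acceptance=np.ones(mcmc.n_chains),  # Gibbs scans always accept
    )


# ---------------------------------------------------------------------------
# convergence statistics
# ---------------------------------------------------------------------------

def compute_rhat(draws: np.ndarray) -> float:
    """Rank-normalized split R-hat for a (chains, draws) array.

    Returns NaN (missing) for degenerate constant chains, where the
    statistic is undefined.
    """
    import arviz as az

    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("compute_rhat needs a (chains>=2, draws) array")
    if np.allclose(draws, draws.reshape(-1)[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(draws, method="rank"))


def compute_ess(draws: np.ndarray) -> float:
    """Autocorrelation-based bulk ESS for a (chains, draws) array."""
    import arviz as az

    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("compute_ess needs a (chains>=2, draws) array")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(draws, method="bulk"))


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

@dataclass
class StreamCheck:
    n: int
    coverage: float | None
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    observed: np.ndarray | None = None

    @property
    def empty(self) -> bool:
        return self.n == 0


@dataclass
class PpcReport:
    streams: dict[str, StreamCheck]

    def coverage(self) -> dict[str, float | None]:
        return {k: v.coverage for k, v in self.streams.items()}


def _predictive_K(fit: FitResult, zflat: np.ndarray) -> np.ndarray:
    """Per-reaction concentrations (n_draws, n_wells) implied by draws."""
    d = fit.data
    b = fit.pidx.unpack(zflat)
    n = zflat.shape[0]
    K = np.broadcast_to(
        np.where(np.isnan(d.K_known), 0.0, d.K_known), (n, d.n_wells)
    ).copy()
    if d.has_process:
        lnW = b["log_W"]
        water = d.kind == 1
        K[:, water] = np.exp(lnW[:, d.t_idx[water]]) * d.m_norm[water]
        air = d.kind == 2
        if air.any():
            T, J, R = d.T, fit.pidx.J, fit.pidx.R
            alpha = b["alpha"].reshape(n, T, J)
            at, aj = d.t_idx[air], d.j_idx[air]
            lnA = lnW[:, at] + alpha[:, at, aj]
            if R:
                dh = b["delta"].reshape(n, T, R)
                ar = np.maximum(d.r_idx[air], 0)
                lnA = lnA + np.where(
                    d.r_idx[air] >= 0, d.sign[air] * dh[:, at, ar], 0.0
                )
            K[:, air] = np.exp(np.clip(lnA, -700, 700)) * d.m_norm[air]
    return K


def posterior_predictive_check(
    fit: FitResult, n_draws: int = 400, seed: int = 0
) -> PpcReport:
    """Replicate data from the fitted model and score 95% interval coverage.

    Streams: visual counts; water and air Ct values (wells that amplified);
    water and air amplification flags.  Streams with no observations are
    reported as empty markers, not errors.
    """
    d = fit.data
    rng = np.random.default_rng(child_seed(seed, "ppc"))
    zflat = fit.z.reshape(-1, fit.pidx.ndim)
    pick = rng.choice(len(zflat), size=min(n_draws, len(zflat)), replace=False)
    zsub = zflat[pick]
    n = len(zsub)
    b = fit.pidx.unpack(zsub)
    streams: dict[str, StreamCheck] = {}

    # counts
    if d.has_counts:
        inc = d.include
        lam = np.exp(b["log_W"][:, inc] - b["omega_log"]) * d.E[inc]
        p = d.phi / (d.phi + lam)
        N_rep = rng.negative_binomial(d.phi, p)
        lo = np.quantile(N_rep, 0.025, axis=0)
        hi = np.quantile(N_rep, 0.975, axis=0)
        obs = d.N[inc]
        cov = float(np.mean((obs >= lo) & (obs <= hi)))
        streams["counts"] = StreamCheck(int(inc.sum()), cov, lo, hi, obs)
    else:
        streams["counts"] = StreamCheck(0, None)

    K = _predictive_K(fit, zsub)
    theta = np.exp(b["log_theta"])
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        lnK = np.where(K > 0, np.log(np.maximum(K, 1e-300)), np.nan)
        mu = b["beta0"] + np.take_along_axis(
            b["beta1"], np.broadcast_to(d.plate_idx, (n, d.n_wells)), axis=1
        ) * lnK
        sigma = np.exp(b["gamma0"] + b["gamma1"] * lnK)
        Y_rep = rng.normal(mu, sigma)
        psi = -np.expm1(-K * theta)
        Z_rep = (rng.random((n, d.n_wells)) < psi).astype(int)

    for label, code in (("water", 1), ("air", 2)):
        wells = d.kind == code
        amp = wells & (d.Z == 1)
        if amp.any():
            lo = np.quantile(Y_rep[:, amp], 0.025, axis=0)
            hi = np.quantile(Y_rep[:, amp], 0.975, axis=0)
            obs = d.Y[amp]
            cov = float(np.mean((obs >= lo) & (obs <= hi)))
            streams[f"{label}_ct"] = StreamCheck(int(amp.sum()), cov, lo, hi, obs)
        else:
            streams[f"{label}_ct"] = StreamCheck(0, None)
        if wells.any():
            lo = np.quantile(Z_rep[:, wells], 0.025, axis=0)
            hi = np.quantile(Z_rep[:, wells], 0.975, axis=0)
            obs = d.Z[wells]
            cov = float(np.mean((obs >= lo) & (obs <= hi)))
            streams[f"{label}_amp"] = StreamCheck(int(wells.sum()), cov, lo, hi, obs)
        else:
            streams[f"{label}_amp"] = StreamCheck(0, None)
    return PpcReport(streams=streams)


# ---------------------------------------------------------------------------
# prior sensitivity
# ---------------------------------------------------------------------------

def overlap_coefficient(a, b, grid_size: int = 512) -> float:
    """Distributional overlap OVL = integral of min(p, q), in [0, 1].

    Symmetric in its two arguments; each may be a sample array (KDE is
    used) or a callable pdf.
    """
    from scipy.stats import gaussian_kde

    def as_pdf_and_range(x):
        if callable(x):
            return x, None
        x = np.asarray(x, dtype=float)
        if np.std(x) < 1e-12:
            x = x + 1e-9 * np.random.default_rng(0).standard_normal(len(x))
        kde = gaussian_kde(x)
        span = (float(np.min(x)), float(np.max(x)))
        pad = 0.5 * (span[1] - span[0] + 1e-9)
        return kde, (span[0] - pad, span[1] + pad)

    pa, ra = as_pdf_and_range(a)
    pb, rb = as_pdf_and_range(b)
    ranges = [r for r in (ra, rb) if r is not None]
    if not ranges:
        raise ValueError("at least one argument must be a sample array")
    lo = min(r[0] for r in ranges)
    hi = max(r[1] for r in ranges)
    grid = np.linspace(lo, hi, grid_size)
    fa = np.asarray(pa(grid), dtype=float).ravel()
    fb = np.asarray(pb(grid), dtype=float).ravel()
    return float(np.trapezoid(np.minimum(fa, fb), grid))


def _prior_pdf(name: str, priors: PriorConfig):
    from scipy import stats

    if name.startswith("X["):
        # prior on ln X; overlap computed on the log scale
        loc, scale = priors.log_x
        return lambda g: stats.norm.pdf(g, loc, scale), True
    table = {
        "omega_log": ("norm", priors.omega_log),
        "beta0": ("norm", priors.beta0),
        "gamma0": ("norm", priors.gamma0),
        "gamma1": ("norm", priors.gamma1),
    }
    if name in table:
        kind, (loc, scale) = table[name]
        return lambda g: stats.norm.pdf(g, loc, scale), False
    if name.startswith("eta["):
        loc, scale = priors.eta
        return lambda g: stats.norm.pdf(g, loc, scale), False
    if name.startswith("beta1["):
        loc, scale = priors.beta1
        return lambda g: stats.norm.pdf(g, loc, scale), False
    if name.startswith("tau["):
        return lambda g: stats.halfcauchy.pdf(g, scale=priors.tau_scale), False
    if name.startswith("rho["):
        return lambda g: stats.halfcauchy.pdf(g, scale=priors.rho_scale), False
    if name == "theta":
        return lambda g: stats.expon.pdf(g, scale=priors.theta_mean), False
    return None, False


def prior_sensitivity(fit: FitResult, priors: PriorConfig | None = None) -> pd.DataFrame:
    """Prior-vs-posterior overlap per parameter.

    Overlap near 1 flags a parameter the data did not update (a
    "data-uninformed" warning above 0.9); informative updates show small
    overlap.
    """
    priors = priors or fit.priors
    rows = []
    for name, v in fit._scalar_draws().items():
        pdf, on_log = _prior_pdf(name, priors)
        if pdf is None:
            continue
        samples = v.reshape(-1)
        if on_log:
            samples = np.log(samples)
        ovl = overlap_coefficient(samples, pdf)
        rows.append({
            "param": name,
            "overlap": ovl,
            "data_uninformed": ovl > 0.9,
        })
    return pd.DataFrame(rows).set_index("param")
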