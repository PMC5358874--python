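"""Two-state switching correlated random walk state-space model (DCRWS).

The model estimates a turtle's position and latent behavioural mode on a
regular 8-hour grid from irregular, error-prone Argos fixes.

Process (first-difference CRW, switching): with d_t = x_t - x_{t-1},

    d_t | d_{t-1}, b_t  ~  N( gamma_{b_t} R(theta_{b_t}) d_{t-1},  sigma_{b_t}^2 I )

where b_t in {migration, inter-nesting} follows a 2-state Markov chain with
row-stochastic transition matrix A. Migration is the persistent, directed
mode (large gamma); inter-nesting movement is restricted (small gamma).

Observation: a fix at fractional position w of interval [t_j, t_{j+1})
measures the linear interpolation (1-w) x_j + w x_{j+1} plus isotropic
Gaussian error whose scale is the fix's Argos location-class accuracy.

Inference is MCMC with exact conditional draws wherever the model allows:

* positions x — the full conditional given modes is Gaussian with a banded
  precision matrix (each step term couples three consecutive grid points),
  so the whole position path is drawn exactly by a banded Cholesky solve;
* modes b — exact forward-filter backward-sample;
* switch probabilities — conjugate Beta;
* gamma, theta and the per-mode process scales sigma — random-walk
  Metropolis (uniform priors on gamma and theta, half-normal on sigma
  scaled by the empirical step distribution). Mode-specific process scales
  let the restricted mode differ from migration in displacement magnitude
  as well as persistence, which is what real inter-nesting movement does.

Label identifiability is enforced post hoc by relabelling every posterior
draw so the migration mode carries the larger gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve_banded, cholesky_banded, solve_banded

from .config import DEFAULT_LC_ERROR_KM, AnalysisParameters, McmcConfig
from .geometry import AzimuthalEquidistant
from .tracks import Track

_DIFFUSE_SD_KM = 50.0   # diffuse scale for the first step difference
_BW = 5                 # precision bandwidth: 3 coupled grid points x 2 coords


def regularize_time_grid(track: Track, step_hours: float = 8.0):
    """Build the regular state grid spanning a track and assign fixes.

    Returns ``(grid, assignment, n_empty)``: grid instants from the first
    fix to at least the last (inclusive ends), each fix assigned to its
    enclosing half-open interval [t_j, t_{j+1}) — a fix exactly on a grid
    instant belongs to the following interval — and the number of intervals
    containing no fix.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    t = track.fixes["timestamp"]
    span_h = (t.iloc[-1] - t.iloc[0]).total_seconds() / 3600.0
    if span_h < step_hours:
        raise ValueError("track shorter than one grid step")
    n_int = int(np.ceil(span_h / step_hours - 1e-9))
    grid = t.iloc[0] + pd.to_timedelta(np.arange(n_int + 1) * step_hours, unit="h")
    rel_h = (t - t.iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    assign = np.minimum((rel_h / step_hours).astype(int), n_int - 1)
    n_empty = n_int - len(np.unique(assign))
    return grid, assign, n_empty


@dataclass
class SsmFit:
    """Result of a DCRWS fit; ``success`` is False on failed preconditions
    or non-convergence (R-hat > 1.1), in which case the caller should fall
    back to heuristic segmentation."""

    success: bool
    reason: str | None
    states: pd.DataFrame | None = None        # time, lon, lat, ci, b_hat, mode
    params: pd.DataFrame | None = None        # posterior summaries
    rhat: dict | None = None
    draws: dict | None = None
    n_empty_intervals: int = 0


def _rotations(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _step_loglik(D, b, gamma, theta, sigma):
    """Log-likelihood of step differences for given modes (terms t >= 2).

    ``sigma`` is the per-mode process scale pair.
    """
    G0, G1 = gamma[0] * _rotations(theta[0]), gamma[1] * _rotations(theta[1])
    pred = np.where(b[1:, None] == 0, D[:-1] @ G0.T, D[:-1] @ G1.T)
    resid = D[1:] - pred
    s = np.asarray(sigma)[b[1:]]
    return float(-0.5 * np.sum(resid ** 2 / s[:, None] ** 2)
                 - 2.0 * np.sum(np.log(s)))


def _mode_logliks(D, gamma, theta, sigma):
    """Per-step per-mode log-likelihoods, shape (nsteps, 2); row 0 is flat."""
    out = np.zeros((len(D), 2))
    for m in range(2):
        G = gamma[m] * _rotations(theta[m])
        resid = D[1:] - D[:-1] @ G.T
        out[1:, m] = (-0.5 * np.sum(resid ** 2, axis=1) / sigma[m] ** 2
                      - 2.0 * np.log(sigma[m]))
    return out


def _ffbs_modes(D, gamma, theta, sigma, A, rng):
    """Exact draw of the mode sequence by forward filtering, backward sampling."""
    ll = _mode_logliks(D, gamma, theta, sigma)
    n = len(D)
    alpha = np.empty((n, 2))
    w = np.array([0.5, 0.5]) * np.exp(ll[0] - ll[0].max())
    alpha[0] = w / w.sum()
    for t in range(1, n):
        pred = alpha[t - 1] @ A
        w = pred * np.exp(ll[t] - ll[t].max())
        s = w.sum()
        alpha[t] = w / s if s > 0 else np.array([0.5, 0.5])
    b = np.empty(n, dtype=int)
    b[-1] = rng.random() < alpha[-1, 1]
    for t in range(n - 2, -1, -1):
        w = alpha[t] * A[:, b[t + 1]]
        b[t] = rng.random() < w[1] / w.sum()
    return b


def _position_precision(T, b, gamma, theta, sigma, obs):
    """Assemble banded precision (upper form) and rhs for the position path.

    ``obs`` is (j, w, tau, y) arrays: interval index, interpolation weight,
    error scale, observed km coordinates.
    """
    n = 2 * T
    ab = np.zeros((_BW + 1, n))           # ab[_BW + i - j, j] for i <= j
    h = np.zeros(n)

    def add_block(C, base_cols):
        # C: (k,k) symmetric block; base_cols: array of leading variable indices
        k = C.shape[0]
        for p in range(k):
            for q in range(p, k):
                np.add.at(ab[_BW + p - q], base_cols + q, C[p, q])

    # diffuse first-difference term: (x_1 - x_0) / sigma0
    M = np.zeros((2, 4))
    M[:, :2] = -np.eye(2)
    M[:, 2:] = np.eye(2)
    add_block(M.T @ M / _DIFFUSE_SD_KM ** 2, np.array([0]))

    # process terms t = 2..T-1, grouped by mode (block depends only on mode)
    for m in range(2):
        tt = np.flatnonzero(b[1:] == m) + 2     # absolute step index t
        if tt.size == 0:
            continue
        G = gamma[m] * _rotations(theta[m])
        M = np.zeros((2, 6))
        M[:, :2] = G
        M[:, 2:4] = -(np.eye(2) + G)
        M[:, 4:] = np.eye(2)
        add_block(M.T @ M / sigma[m] ** 2, 2 * (tt - 2))

    # observation terms
    j, w, tau, y = obs
    iv2 = 1.0 / tau ** 2
    base = 2 * j
    for comp in range(2):
        c = base + comp
        np.add.at(ab[_BW], c, (1 - w) ** 2 * iv2)
        np.add.at(ab[_BW], c + 2, w ** 2 * iv2)
        np.add.at(ab[_BW - 2], c + 2, (1 - w) * w * iv2)
        np.add.at(h, c, (1 - w) * y[:, comp] * iv2)
        np.add.at(h, c + 2, w * y[:, comp] * iv2)

    ab[_BW] += 1e-9
    return ab, h


def _draw_positions(T, b, gamma, theta, sigma, obs, rng):
    ab, h = _position_precision(T, b, gamma, theta, sigma, obs)
    cb = cholesky_banded(ab, lower=False)
    mu = cho_solve_banded((cb, False), h)
    z = rng.standard_normal(2 * T)
    x = mu + solve_banded((0, _BW), cb, z)
    return x.reshape(T, 2)


def fit_dcrws(track: Track,
              mcmc: McmcConfig = McmcConfig(),
              lc_scales: dict | None = None,
              params: AnalysisParameters = AnalysisParameters(),
              mode_cutoff: float = 1.5,
              uncertain_band: tuple | None = None) -> SsmFit:
    """Fit the switching CRW state-space model to a filtered Argos track.

    Runs ``mcmc.n_chains`` independent chains; posterior samples are the
    ``mcmc.n_iter`` post-burn-in iterations thinned by ``mcmc.thin``.
    Tracks with fewer than 20 fixes or spanning fewer than 10 grid steps
    are declared not robust enough and returned as a failure, as is any fit
    whose split R-hat exceeds 1.1 on a monitored parameter.
    """
    lc_scales = dict(DEFAULT_LC_ERROR_KM if lc_scales is None else lc_scales)
    if len(track) < 20:
        return SsmFit(False, f"only {len(track)} fixes (< 20)")
    grid, assign, n_empty = regularize_time_grid(track, params.ssm_step_hours)
    T = len(grid)
    if T - 1 < 10:
        return SsmFit(False, f"track spans only {T - 1} grid steps (< 10)")

    proj = AzimuthalEquidistant(float(np.median(track.lon)), float(np.median(track.lat)))
    ox, oy = proj.forward(track.lon, track.lat)
    y_obs = np.column_stack([ox, oy])
    rel_h = (track.fixes["timestamp"] - grid[0]).dt.total_seconds().to_numpy() / 3600.0
    w = rel_h / params.ssm_step_hours - assign
    tau = np.array([max(lc_scales.get(str(lc), 10.0), 0.05)
                    for lc in track.fixes["lc"]])
    obs = (assign, w, tau, y_obs)

    # initial path: linear interpolation of fixes onto the grid
    grid_h = np.arange(T) * params.ssm_step_hours
    x_init = np.column_stack([np.interp(grid_h, rel_h, y_obs[:, 0]),
                              np.interp(grid_h, rel_h, y_obs[:, 1])])
    emp_sd = max(float(np.std(np.diff(x_init, axis=0))), 0.5)

    total_iter = mcmc.burn_in + mcmc.n_iter
    keep_every = mcmc.thin
    chains = {"gamma": [], "sigma": [], "A": [], "theta": [], "b": [], "x": []}

    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(mcmc.seed), c, 11]))
        gamma = np.clip(np.array([0.8, 0.2]) + rng.normal(0, 0.05, 2), 0.01, 0.99)
        theta = np.zeros(2)
        sigma = np.array([emp_sd * 1.2, emp_sd * 0.8])
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        x = x_init + rng.normal(0, 0.1, x_init.shape)
        D = np.diff(x, axis=0)
        b = (rng.random(T - 1) < 0.5).astype(int)
        step_g, step_t, step_s = 0.07, 0.15, 0.12

        kept = {k: [] for k in chains}
        for it in range(total_iter):
            b = _ffbs_modes(D, gamma, theta, sigma, A, rng)

            # conjugate Beta update of the transition rows
            for m in range(2):
                n_m0 = int(np.sum((b[:-1] == m) & (b[1:] == 0)))
                n_m1 = int(np.sum((b[:-1] == m) & (b[1:] == 1)))
                A[m, 0] = rng.beta(1 + n_m0, 1 + n_m1)
                A[m, 1] = 1.0 - A[m, 0]

            # Metropolis: per-mode gamma and theta
            for m in range(2):
                cur = _step_loglik(D, b, gamma, theta, sigma)
                prop = gamma.copy()
                prop[m] = gamma[m] + rng.normal(0, step_g)
                if 0.0 <= prop[m] <= 1.0:
                    new = _step_loglik(D, b, prop, theta, sigma)
                    if np.log(rng.random()) < new - cur:
                        gamma = prop
                        cur = new
                tprop = theta.copy()
                tprop[m] = (theta[m] + rng.normal(0, step_t) + np.pi) % (2 * np.pi) - np.pi
                new = _step_loglik(D, b, gamma, tprop, sigma)
                if np.log(rng.random()) < new - cur:
                    theta = tprop

            # Metropolis on log sigma per mode, half-normal priors
            for m in range(2):
                sprop = sigma.copy()
                sprop[m] = sigma[m] * np.exp(rng.normal(0, step_s))
                cur = _step_loglik(D, b, gamma, theta, sigma) \
                    - 0.5 * (sigma[m] / emp_sd) ** 2 + np.log(sigma[m])
                new = _step_loglik(D, b, gamma, theta, sprop) \
                    - 0.5 * (sprop[m] / emp_sd) ** 2 + np.log(sprop[m])
                if np.log(rng.random()) < new - cur:
                    sigma = sprop

            # exact Gaussian draw of the whole position path
            x = _draw_positions(T, b, gamma, theta, sigma, obs, rng)
            D = np.diff(x, axis=0)

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % keep_every == 0:
                # canonical labels: migration (index 0) is the persistent mode
                if gamma[1] > gamma[0]:
                    g, th, sg = gamma[::-1].copy(), theta[::-1].copy(), sigma[::-1].copy()
                    Ac = A[::-1, ::-1].copy()
                    bc = 1 - b
                else:
                    g, th, sg = gamma.copy(), theta.copy(), sigma.copy()
                    Ac, bc = A.copy(), b.copy()
                kept["gamma"].append(g)
                kept["theta"].append(th)
                kept["sigma"].append(sg)
                kept["A"].append(Ac)
                kept["b"].append(bc)
                kept["x"].append(x.copy())

        for k in chains:
            chains[k].append(np.array(kept[k]))

    # convergence: split R-hat on gamma, sigma and the diagonal of A
    monitored = {
        "gamma_migration": [c[:, 0] for c in chains["gamma"]],
        "gamma_internesting": [c[:, 1] for c in chains["gamma"]],
        "sigma_migration": [c[:, 0] for c in chains["sigma"]],
        "sigma_internesting": [c[:, 1] for c in chains["sigma"]],
        "A_stay_migration": [c[:, 0, 0] for c in chains["A"]],
        "A_stay_internesting": [c[:, 1, 1] for c in chains["A"]],
    }
    rhat = {k: _split_rhat(v) for k, v in monitored.items()}

    g_all = np.concatenate(chains["gamma"])
    th_all = np.concatenate(chains["theta"])
    s_all = np.concatenate(chains["sigma"])
    A_all = np.concatenate(chains["A"])
    b_all = np.concatenate(chains["b"])          # (ndraw, T-1)
    x_all = np.concatenate(chains["x"])          # (ndraw, T, 2)

    b_state = np.concatenate([b_all[:, :1], b_all], axis=1)   # state t <- step t
    b_hat = 1.0 + b_state.mean(axis=0)
    xm = x_all.mean(axis=0)
    lo = np.quantile(x_all, 0.025, axis=0)
    hi = np.quantile(x_all, 0.975, axis=0)
    lon, lat = proj.inverse(xm[:, 0], xm[:, 1])
    states = pd.DataFrame({
        "time": grid, "lon": lon, "lat": lat,
        "ci_halfwidth_x_km": (hi[:, 0] - lo[:, 0]) / 2,
        "ci_halfwidth_y_km": (hi[:, 1] - lo[:, 1]) / 2,
        "b_hat": b_hat,
    })
    states = classify_modes(states, cutoff=mode_cutoff, uncertain_band=uncertain_band)

    def _summ(name, v):
        return {"parameter": name, "mean": float(np.mean(v)),
                "sd": float(np.std(v)),
                "q2.5": float(np.quantile(v, 0.025)),
                "q97.5": float(np.quantile(v, 0.975))}

    psum = pd.DataFrame([
        _summ("gamma_migration", g_all[:, 0]),
        _summ("gamma_internesting", g_all[:, 1]),
        _summ("theta_migration", th_all[:, 0]),
        _summ("theta_internesting", th_all[:, 1]),
        _summ("sigma_migration_km", s_all[:, 0]),
        _summ("sigma_internesting_km", s_all[:, 1]),
        _summ("A_stay_migration", A_all[:, 0, 0]),
        _summ("A_stay_internesting", A_all[:, 1, 1]),
    ])

    bad = {k: v for k, v in rhat.items() if not np.isfinite(v) or v > 1.1}
    if bad:
        return SsmFit(False, f"non-convergence: R-hat > 1.1 for {sorted(bad)}",
                      states=states, params=psum, rhat=rhat,
                      n_empty_intervals=n_empty)
    draws = {"gamma": g_all, "theta": th_all, "sigma": s_all, "A": A_all,
             "b": b_all}
    return SsmFit(True, None, states=states, params=psum, rhat=rhat,
                  draws=draws, n_empty_intervals=n_empty)


def _split_rhat(chain_list) -> float:
    """Split R-hat (potential scale reduction) over a list of 1-D chains."""
    halves = []
    for c in chain_list:
        c = np.asarray(c, dtype=float)
        h = len(c) // 2
        if h < 2:
            return np.inf
        halves.extend([c[:h], c[h:2 * h]])
    m = len(halves)
    n = len(halves[0])
    means = np.array([h.mean() for h in halves])
    variances = np.array([h.var(ddof=1) for h in halves])
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def classify_modes(states: pd.DataFrame, cutoff: float = 1.5,
                   uncertain_band: tuple | None = None) -> pd.DataFrame:
    """Label each state from its posterior mean mode index b_hat in [1, 2].

    b_hat strictly above ``cutoff`` is "internesting", otherwise
    "migration". With an ``uncertain_band`` (lo, hi), b_hat inside the open
    band is labeled "uncertain".
    """
    out = states.copy()
    b = out["b_hat"].to_numpy()
    mode = np.where(b > cutoff, "internesting", "migration")
    if uncertain_band is not None:
        lo, hi = uncertain_band
        mode = np.where((b > lo) & (b < hi), "uncertain", mode)
    out["mode"] = mode
    return out


def label_fixes(track: Track, states: pd.DataFrame,
                params: AnalysisParameters = AnalysisParameters()) -> Track:
    """Attach each Argos fix the mode label of its enclosing interval's state."""
    grid, assign, _ = regularize_time_grid(track, params.ssm_step_hours)
    state_modes = states["mode"].to_numpy()
    fix_modes = state_modes[np.minimum(assign + 1, len(state_modes) - 1)]
    fixes = track.fixes.copy()
    fixes["mode"] = fix_modes
    return track.with_fixes(fixes)
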