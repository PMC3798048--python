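"""Forward hemodynamic model and blind deconvolution.

The hemodynamic forward model is the balloon–Windkessel differential
system: a hidden neuronal drive ``h`` excites a vasodilatory signal
``s``, which drives blood inflow ``f``; inflow inflates venous volume
``v`` and washes out deoxyhemoglobin ``q``; the BOLD signal is the
classical nonlinear readout of ``(v, q)``.  At rest
``(s, f, v, q) = (0, 1, 1, 1)`` and the BOLD output is zero.

Blind deconvolution jointly estimates the neuronal series and the
hemodynamic parameters from an observed BOLD series with a square-root
cubature Kalman filter (CKF) over the augmented state
``[h, s, f, v, q, log θ]``, followed by a Rauch–Tung–Striebel-type
cubature smoother.  The filter runs on a fine time grid (default ten
steps per TR), so the recovered neuronal series has a temporal
resolution ten times finer than the acquisition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - type-only import
    from causalbold.cohort import ExogenousInput

#: Resting-state BOLD volume fraction and readout weights (classical values).
V0 = 0.04

#: Floor applied to flow/volume/deoxyhemoglobin to keep the ODE defined.
_STATE_FLOOR = 1e-3


@dataclass(frozen=True)
class HemodynamicParams:
    """Balloon-model parameters (defaults are the classical priors).

    signal_decay
        κ, decay rate of the vasodilatory signal (1/s).
    feedback
        γ, autoregulatory feedback rate (1/s).
    transit_time
        τ, mean venous transit time (s).
    stiffness
        α, Grubb vessel-stiffness exponent (dimensionless).
    oxygen_extraction
        E₀, resting oxygen extraction fraction, in (0, 1).

    Fields may be scalars or arrays (one value per ROI).
    """

    signal_decay: float | np.ndarray = 0.65
    feedback: float | np.ndarray = 0.41
    transit_time: float | np.ndarray = 0.98
    stiffness: float | np.ndarray = 0.32
    oxygen_extraction: float | np.ndarray = 0.34

    def __post_init__(self) -> None:
        for name in (
            "signal_decay",
            "feedback",
            "transit_time",
            "stiffness",
            "oxygen_extraction",
        ):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")
        if np.any(np.asarray(self.oxygen_extraction) >= 1):
            raise ValueError("oxygen_extraction must be < 1")

    def to_log_array(self) -> np.ndarray:
        """Scalar parameters as a log-vector (filter parameterization)."""
        return np.log(
            np.array(
                [
                    float(np.asarray(self.signal_decay).ravel()[0]),
                    float(np.asarray(self.feedback).ravel()[0]),
                    float(np.asarray(self.transit_time).ravel()[0]),
                    float(np.asarray(self.stiffness).ravel()[0]),
                    float(np.asarray(self.oxygen_extraction).ravel()[0]),
                ]
            )
        )

    @staticmethod
    def from_log_array(log_theta: np.ndarray) -> "HemodynamicParams":
        kappa, gamma, tau, alpha, e0 = np.exp(np.asarray(log_theta, dtype=float))
        return HemodynamicParams(
            signal_decay=kappa,
            feedback=gamma,
            transit_time=tau,
            stiffness=alpha,
            oxygen_extraction=min(e0, 0.95),
        )


@dataclass
class LatentState:
    """Neuronal drive plus the four physiological balloon states."""

    neuronal: float | np.ndarray = 0.0
    signal: float | np.ndarray = 0.0
    flow: float | np.ndarray = 1.0
    volume: float | np.ndarray = 1.0
    deoxy: float | np.ndarray = 1.0

    @staticmethod
    def rest() -> "LatentState":
        return LatentState()


@dataclass(frozen=True)
class CkfConfig:
    """Cubature-filter settings.

    The noise scales are standard deviations *per fine step*.  The
    measurement noise defaults to ``None``, in which case it is
    estimated from the first differences of the observed series
    (``var(diff(y)) / 2``), a robust noise floor when the underlying
    signal is smooth relative to the TR.
    """

    upsample_factor: int = 10
    tr: float = 1.0
    process_noise_neuronal: float = 0.1
    process_noise_physio: float = 1e-3
    process_noise_params: float = 5e-4
    measurement_noise: float | None = None
    n_iterations: int = 1
    neuronal_decay: float = 1.0   # 1/s, prior time constant of h
    input_gain: float = 1.0       # boxcar drive per second in the h equation
    prior_log_sd: float = 0.2     # prior spread of log-parameters
    seed: int = 0

    def __post_init__(self) -> None:
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")
        for name in (
            "process_noise_neuronal",
            "process_noise_physio",
            "process_noise_params",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.measurement_noise is not None and self.measurement_noise <= 0:
            raise ValueError("measurement_noise must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class DeconvolutionResult:
    """Output of :func:`ckf_deconvolve`."""

    neuronal_estimate: np.ndarray
    params_estimate: HemodynamicParams
    innovation_diagnostics: dict[str, np.ndarray | float] = field(default_factory=dict)
    fine_dt: float = 0.1


def _physio_derivatives(
    s: np.ndarray,
    f: np.ndarray,
    v: np.ndarray,
    q: np.ndarray,
    h: np.ndarray,
    kappa: np.ndarray,
    gamma: np.ndarray,
    tau: np.ndarray,
    alpha: np.ndarray,
    e0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Right-hand side of the balloon ODE system."""
    ds = h - kappa * s - gamma * (f - 1.0)
    df = s
    outflow = v ** (1.0 / alpha)
    dv = (f - outflow) / tau
    extraction = 1.0 - (1.0 - e0) ** (1.0 / f)
    dq = (f * extraction / e0 - outflow * q / v) / tau
    return ds, df, dv, dq


def balloon_transition(
    state: LatentState,
    neuronal_input: float | np.ndarray,
    u: float | np.ndarray,
    params: HemodynamicParams,
    dt: float,
) -> LatentState:
    """One Euler step of the hemodynamic system.

    ``neuronal_input`` replaces the neuronal component of the returned
    state (the neuronal series is supplied externally by the generator
    or estimated by the filter); ``u`` is accepted for signature
    compatibility with driven neuronal models and is unused here.  The
    resting state with zero input is a fixed point.  Non-positive
    flow/volume/deoxyhemoglobin values after the step are clipped with a
    warning.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = np.asarray(state.signal, dtype=float)
    f = np.asarray(state.flow, dtype=float)
    v = np.asarray(state.volume, dtype=float)
    q = np.asarray(state.deoxy, dtype=float)
    h = np.asarray(neuronal_input, dtype=float)  # drive applied this step
    ds, df, dv, dq = _physio_derivatives(
        s,
        f,
        v,
        q,
        h,
        np.asarray(params.signal_decay, dtype=float),
        np.asarray(params.feedback, dtype=float),
        np.asarray(params.transit_time, dtype=float),
        np.asarray(params.stiffness, dtype=float),
        np.asarray(params.oxygen_extraction, dtype=float),
    )
    f_new = f + dt * df
    v_new = v + dt * dv
    q_new = q + dt * dq
    if np.any(f_new <= 0) or np.any(v_new <= 0) or np.any(q_new <= 0):
        warnings.warn(
            "balloon step produced non-positive flow/volume/deoxyhemoglobin; "
            "clipping to a small positive floor",
            stacklevel=2,
        )
        f_new = np.maximum(f_new, _STATE_FLOOR)
        v_new = np.maximum(v_new, _STATE_FLOOR)
        q_new = np.maximum(q_new, _STATE_FLOOR)
    return LatentState(
        neuronal=np.asarray(neuronal_input, dtype=float),
        signal=s + dt * ds,
        flow=f_new,
        volume=v_new,
        deoxy=q_new,
    )


def bold_observation(state: LatentState, params: HemodynamicParams) -> np.ndarray:
    """Nonlinear BOLD readout; zero at the resting state."""
    e0 = np.asarray(params.oxygen_extraction, dtype=float)
    v = np.asarray(state.volume, dtype=float)
    q = np.asarray(state.deoxy, dtype=float)
    k1 = 7.0 * e0
    k2 = 2.0
    k3 = 2.0 * e0 - 0.2
    return V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


def balloon_forward(
    neuronal: np.ndarray,
    params: HemodynamicParams,
    dt: float,
    tr: float,
    noise_variance: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Integrate neuronal series to a noisy BOLD series on the TR grid.

    ``neuronal`` is ``(T,)`` or ``(n_rois, T)`` on the fine grid with
    step ``dt``; ``dt`` must divide ``tr``.  The BOLD value assigned to
    each volume is the model output at the final fine step of that TR.
    Gaussian measurement noise of ``noise_variance`` is added per
    volume.  Divergent trajectories raise with the offending parameters.
    """
    was_1d = np.asarray(neuronal).ndim == 1
    neuronal = np.atleast_2d(np.asarray(neuronal, dtype=float))
    upsample = int(round(tr / dt))
    if abs(upsample * dt - tr) > 1e-9 or upsample < 1:
        raise ValueError(f"dt={dt} must divide tr={tr}")
    k, n_fine = neuronal.shape
    n_vol = n_fine // upsample

    kappa = np.broadcast_to(np.asarray(params.signal_decay, dtype=float), (k,))
    gamma = np.broadcast_to(np.asarray(params.feedback, dtype=float), (k,))
    tau = np.broadcast_to(np.asarray(params.transit_time, dtype=float), (k,))
    alpha = np.broadcast_to(np.asarray(params.stiffness, dtype=float), (k,))
    e0 = np.broadcast_to(np.asarray(params.oxygen_extraction, dtype=float), (k,))

    s = np.zeros(k)
    f = np.ones(k)
    v = np.ones(k)
    q = np.ones(k)
    bold = np.zeros((k, n_vol))
    for t in range(n_vol * upsample):
        h = neuronal[:, t]
        ds, df, dv, dq = _physio_derivatives(s, f, v, q, h, kappa, gamma, tau, alpha, e0)
        s = s + dt * ds
        f = np.maximum(f + dt * df, _STATE_FLOOR)
        v = np.maximum(v + dt * dv, _STATE_FLOOR)
        q = np.maximum(q + dt * dq, _STATE_FLOOR)
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(q))):
            raise FloatingPointError(
                f"balloon forward model diverged at fine step {t} with {params}"
            )
        if (t + 1) % upsample == 0:
            vol = (t + 1) // upsample - 1
            k1 = 7.0 * e0
            k3 = 2.0 * e0 - 0.2
            bold[:, vol] = V0 * (k1 * (1.0 - q) + 2.0 * (1.0 - q / v) + k3 * (1.0 - v))
    if noise_variance > 0:
        if rng is None or isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        bold = bold + rng.normal(0.0, np.sqrt(noise_variance), size=bold.shape)
    return bold[0] if was_1d else bold


def cubature_points(mean: np.ndarray, covariance_sqrt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Third-degree spherical-radial cubature points.

    Returns ``(points, weights)`` where ``points`` has shape ``(2n, n)``:
    ``mean ± sqrt(n) * column_i(covariance_sqrt)``, all with equal
    weight ``1 / (2n)``.
    """
    mean = np.asarray(mean, dtype=float)
    sqrt = np.asarray(covariance_sqrt, dtype=float)
    if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(sqrt))):
        raise ValueError("non-finite mean or covariance square root")
    n = mean.shape[0]
    if sqrt.shape != (n, n):
        raise ValueError("covariance_sqrt must be square and match the mean")
    offsets = np.sqrt(n) * sqrt.T  # row i = sqrt(n) * column i of S
    points = np.vstack([mean + offsets, mean - offsets])
    weights = np.full(2 * n, 1.0 / (2 * n))
    return points, weights


# ---------------------------------------------------------------------------
# Square-root cubature Kalman filter / smoother
# ---------------------------------------------------------------------------

_N_PHYSIO = 5  # h, s, f, v, q
_N_PARAMS = 5
_DIM = _N_PHYSIO + _N_PARAMS


def _propagate_points(
    points: np.ndarray,
    u_t: float,
    dt: float,
    config: CkfConfig,
) -> np.ndarray:
    """Transition applied to cubature points (rows)."""
    out = points.copy()
    h = points[:, 0]
    s = points[:, 1]
    f = np.maximum(points[:, 2], _STATE_FLOOR)
    v = np.maximum(points[:, 3], _STATE_FLOOR)
    q = np.maximum(points[:, 4], _STATE_FLOOR)
    theta = np.exp(np.clip(points[:, _N_PHYSIO:], -5.0, 3.0))
    kappa, gamma, tau, alpha, e0 = (theta[:, i] for i in range(_N_PARAMS))
    e0 = np.clip(e0, 0.05, 0.95)
    alpha = np.maximum(alpha, 0.05)
    tau = np.maximum(tau, 0.05)
    out[:, 0] = h + dt * (-config.neuronal_decay * h + config.input_gain * u_t)
    ds, df, dv, dq = _physio_derivatives(s, f, v, q, h, kappa, gamma, tau, alpha, e0)
    out[:, 1] = s + dt * ds
    out[:, 2] = np.maximum(f + dt * df, _STATE_FLOOR)
    out[:, 3] = np.maximum(v + dt * dv, _STATE_FLOOR)
    out[:, 4] = np.maximum(q + dt * dq, _STATE_FLOOR)
    return out


def _observe_points(points: np.ndarray) -> np.ndarray:
    """BOLD readout applied to cubature points (rows)."""
    v = np.maximum(points[:, 3], _STATE_FLOOR)
    q = np.maximum(points[:, 4], _STATE_FLOOR)
    e0 = np.clip(np.exp(np.clip(points[:, _N_PHYSIO + 4], -5.0, 3.0)), 0.05, 0.95)
    k1 = 7.0 * e0
    k3 = 2.0 * e0 - 0.2
    return V0 * (k1 * (1.0 - q) + 2.0 * (1.0 - q / v) + k3 * (1.0 - v))


def _tria(block: np.ndarray) -> np.ndarray:
    """Lower-triangular square root of ``block @ block.T`` via QR."""
    r = np.linalg.qr(block.T, mode="r")
    return r.T


def _safe_sqrt_factor(p: np.ndarray) -> np.ndarray:
    """Cholesky factor with re-conditioning on failure (warned)."""
    p = 0.5 * (p + p.T)
    try:
        return np.linalg.cholesky(p)
    except np.linalg.LinAlgError:
        warnings.warn(
            "filter covariance lost positive definiteness; re-conditioning",
            stacklevel=2,
        )
        eigval, eigvec = np.linalg.eigh(p)
        eigval = np.maximum(eigval, 1e-10)
        p = eigvec @ np.diag(eigval) @ eigvec.T
        return np.linalg.cholesky(0.5 * (p + p.T))


def ckf_deconvolve(
    bold: np.ndarray,
    u: "ExogenousInput | np.ndarray",
    config: CkfConfig | None = None,
    initial_params: HemodynamicParams | None = None,
) -> DeconvolutionResult:
    """Blind deconvolution of one BOLD series.

    Runs a square-root cubature Kalman filter over the augmented state
    ``[h, s, f, v, q, log θ]`` on the fine grid (measurement updates at
    each TR), then a cubature RTS smoother, optionally iterating the
    pass with the re-estimated parameters as the new prior.  The
    returned neuronal estimate has length
    ``len(bold) * config.upsample_factor``.

    Parameters
    ----------
    bold:
        Observed series, length >= 50.
    u:
        Exogenous boxcar on the fine grid (an :class:`~causalbold.cohort.\
ExogenousInput` or a plain array of length ``len(bold) * upsample``).
    """
    from causalbold.cohort import ExogenousInput  # local to avoid cycle

    config = config or CkfConfig()
    bold = np.asarray(bold, dtype=float).ravel()
    if len(bold) < 50:
        raise ValueError(f"bold series too short ({len(bold)} < 50)")
    up = config.upsample_factor
    n_fine = len(bold) * up
    if isinstance(u, ExogenousInput):
        u_fine = u.values
    else:
        u_fine = np.asarray(u, dtype=float).ravel()
    if len(u_fine) < n_fine:
        raise ValueError(
            f"exogenous input defined on {len(u_fine)} fine steps; need {n_fine}"
        )
    u_fine = u_fine[:n_fine]
    baseline = float(np.mean(bold))
    y = bold - baseline

    if config.measurement_noise is None:
        r_var = float(np.var(np.diff(y)) / 2.0)
        r_var = max(r_var, 1e-10)
    else:
        r_var = float(config.measurement_noise)
    sqrt_r = np.sqrt(r_var)

    dt = config.tr / up  # seconds per fine step

    init = initial_params or HemodynamicParams()
    log_theta0 = init.to_log_array()

    q_diag = np.concatenate(
        [
            [config.process_noise_neuronal],
            np.full(4, config.process_noise_physio),
            np.full(_N_PARAMS, config.process_noise_params),
        ]
    )
    sq = np.diag(q_diag)

    result = None
    for _ in range(config.n_iterations):
        result = _ckf_single_pass(y, u_fine, up, dt, log_theta0, sq, sqrt_r, config)
        log_theta0 = result["log_theta"]

    assert result is not None
    params_estimate = HemodynamicParams.from_log_array(result["log_theta"])
    return DeconvolutionResult(
        neuronal_estimate=result["neuronal"],
        params_estimate=params_estimate,
        innovation_diagnostics={
            "innovations": result["innovations"],
            "innovation_variance": result["innovation_variance"],
            "nis": result["nis"],
            "mean_nis": float(np.mean(result["nis"])),
            "measurement_noise": r_var,
        },
        fine_dt=dt,
    )


def _ckf_single_pass(
    y: np.ndarray,
    u_fine: np.ndarray,
    up: int,
    dt: float,
    log_theta0: np.ndarray,
    sq: np.ndarray,
    sqrt_r: float,
    config: CkfConfig,
) -> dict[str, np.ndarray]:
    n_fine = len(y) * up
    dim = _DIM
    sqrt_n = np.sqrt(dim)
    w = 1.0 / (2 * dim)

    m = np.zeros(dim)
    m[2:5] = 1.0  # f, v, q at rest
    m[_N_PHYSIO:] = log_theta0
    p0 = np.concatenate(
        [[0.25, 0.01], np.full(3, 0.01), np.full(_N_PARAMS, config.prior_log_sd**2)]
    )
    s_factor = np.diag(np.sqrt(p0))

    m_filt = np.empty((n_fine, dim))
    p_filt = np.empty((n_fine, dim, dim))
    m_pred = np.empty((n_fine, dim))
    p_pred = np.empty((n_fine, dim, dim))
    cross = np.empty((n_fine, dim, dim))

    innovations = np.empty(len(y))
    innovation_var = np.empty(len(y))

    for t in range(n_fine):
        # --- time update -------------------------------------------------
        offsets = sqrt_n * s_factor.T
        pts = np.vstack([m + offsets, m - offsets])
        prop = _propagate_points(pts, u_fine[t], dt, config)
        m_new = prop.mean(axis=0)
        dev_prev = (pts - m) * np.sqrt(w)
        dev_prop = (prop - m_new) * np.sqrt(w)
        cross[t] = dev_prev.T @ dev_prop
        s_new = _tria(np.hstack([dev_prop.T, sq]))
        m_pred[t] = m_new
        p_pred[t] = s_new @ s_new.T

        # --- measurement update at the end of each TR --------------------
        if (t + 1) % up == 0:
            vol = (t + 1) // up - 1
            offsets = sqrt_n * s_new.T
            pts = np.vstack([m_new + offsets, m_new - offsets])
            z = _observe_points(pts)
            z_hat = z.mean()
            z_dev = (z - z_hat) * np.sqrt(w)
            x_dev = (pts - m_new) * np.sqrt(w)
            s_z2 = float(z_dev @ z_dev) + sqrt_r**2
            p_xz = x_dev.T @ z_dev
            gain = p_xz / s_z2
            nu = y[vol] - z_hat
            m_new = m_new + gain * nu
            block = np.hstack(
                [x_dev.T - np.outer(gain, z_dev), (gain * sqrt_r)[:, None]]
            )
            s_new = _tria(block)
            innovations[vol] = nu
            innovation_var[vol] = s_z2
        m = m_new
        if np.any(~np.isfinite(s_new)):
            s_new = _safe_sqrt_factor(p_pred[t])
        s_factor = s_new
        m_filt[t] = m
        p_filt[t] = s_factor @ s_factor.T

    # --- cubature RTS smoother -------------------------------------------
    m_smooth = m_filt[-1].copy()
    p_smooth = p_filt[-1].copy()
    neuronal = np.empty(n_fine)
    theta_sum = np.zeros(_N_PARAMS)
    neuronal[-1] = m_smooth[0]
    theta_sum += m_smooth[_N_PHYSIO:]
    for t in range(n_fine - 2, -1, -1):
        pp = p_pred[t + 1]
        gain = np.linalg.solve(pp + 1e-12 * np.eye(_DIM), cross[t + 1].T).T
        m_smooth = m_filt[t] + gain @ (m_smooth - m_pred[t + 1])
        p_smooth = p_filt[t] + gain @ (p_smooth - pp) @ gain.T
        neuronal[t] = m_smooth[0]
        theta_sum += m_smooth[_N_PHYSIO:]

    nis = innovations**2 / innovation_var
    return {
        "neuronal": neuronal,
        "log_theta": theta_sum / n_fine,
        "innovations": innovations,
        "innovation_variance": innovation_var,
        "nis": nis,
    }
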