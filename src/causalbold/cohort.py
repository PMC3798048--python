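"""Synthetic task-fMRI cohort generator.

Generates cohorts of two groups (labelled ``ASD`` and ``TD``) with a
known ground-truth directed neuronal network so that every downstream
stage — deconvolution, MVAR estimation, classification and QC — can be
exercised and validated without real data.

The generative model is:

* a latent neuronal series per ROI following a stable lag-1 linear
  recursion on a fine time grid (``dt = TR / 10``), driven by the task
  boxcar and Gaussian innovations;
* group-specific coefficient matrices that differ only on a designated
  set of "discriminative" directed paths, where the TD-group weight
  exceeds the ASD-group weight by ``effect_size`` times the within-group
  spread, with the weaker weights in the ASD-labelled group;
* per-subject weight jitter around the group matrix (the within-group
  spread), per-subject/ROI hemodynamic parameter jitter, and white
  measurement noise scaled to a target variance-ratio SNR;
* head-motion traces as bounded random walks, and behaviour scores
  (AQ down, RME up) coupled to the subject's mean discriminative-path
  weight through a Gaussian copula with uniform marginals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from causalbold.hemodynamics import HemodynamicParams, balloon_forward
from causalbold.qc import MotionTrace
from causalbold.rois import roi_labels

logger = logging.getLogger(__name__)

#: Fine-grid samples discarded before recording each neuronal series.
BURN_IN_STEPS = 200

#: Behaviour-score marginal ranges (min, max) used by the Gaussian copula.
AQ_RANGE = (4.0, 38.0)
RME_RANGE = (15.0, 24.0)
FA_RANGE = (0.30, 0.60)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Parameters
    ----------
    n_per_group:
        Subjects per group (two groups).
    n_rois, n_volumes, tr:
        ROI count, volumes per run and repetition time in seconds.
    n_discriminative_paths:
        Number of directed paths whose weight differs between groups.
    effect_size:
        Standardized group difference on each discriminative path:
        (TD weight − ASD weight) / within-group spread.
    snr_target:
        Target variance-ratio SNR of the observed BOLD
        (total variance over noise variance).
    hrf_jitter:
        Fractional (log-normal) spread of hemodynamic parameters across
        subjects and ROIs.
    motion_magnitude:
        Excursion scale (mm for translations, degrees for rotations) of
        the simulated head-motion random walks.
    upsample_factor:
        Fine-grid steps per TR for the latent neuronal series.
    self_coupling:
        Lag-1 diagonal of the neuronal recursion on the fine grid
        (0.8 at dt = 0.1 s ≈ a 0.5 s neuronal time constant).
    path_weight_sd:
        Within-group spread (s.d.) of individual path weights around the
        group-level matrix.
    neuronal_noise_sd:
        Innovation s.d. of the neuronal recursion per fine step.
    input_gain:
        Boxcar drive per fine step; with ``self_coupling=0.9`` the
        evoked neuronal plateau is ``input_gain / (1 - 0.9)``.
    behaviour_coupling:
        Copula correlation between the mean discriminative weight and
        the behaviour scores (AQ negatively, RME positively).  The mean
        weight aggregates the group effect over all designated paths, so
        even a modest coupling yields clearly significant behaviour
        correlations at n = 30 while keeping the scores weaker
        classification features than the individual paths, as observed
        in task-fMRI classification studies.
    """

    n_per_group: int = 15
    n_rois: int = 18
    n_volumes: int = 460
    tr: float = 1.0
    n_discriminative_paths: int = 19
    effect_size: float = 1.5
    snr_target: float = 2.0
    hrf_jitter: float = 0.1
    motion_magnitude: float = 0.2
    seed: int = 0
    upsample_factor: int = 10
    self_coupling: float = 0.8
    path_weight_sd: float = 0.06
    neuronal_noise_sd: float = 0.1
    input_gain: float = 0.15
    behaviour_coupling: float = 0.3

    def __post_init__(self) -> None:
        for name in ("n_per_group", "n_rois", "n_volumes", "upsample_factor"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_discriminative_paths < 0:
            raise ValueError("n_discriminative_paths must be >= 0")
        if self.n_discriminative_paths > self.n_rois * (self.n_rois - 1):
            raise ValueError(
                "n_discriminative_paths cannot exceed the number of "
                f"directed paths {self.n_rois * (self.n_rois - 1)}"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.snr_target <= 1:
            raise ValueError("snr_target must be > 1 (variance-ratio definition)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def fine_dt(self) -> float:
        return self.tr / self.upsample_factor

    @property
    def n_fine(self) -> int:
        return self.n_volumes * self.upsample_factor

    @property
    def labels(self) -> tuple[str, ...]:
        return roi_labels(self.n_rois)


@dataclass(frozen=True)
class ExogenousInput:
    """Task boxcar on the fine neuronal grid (values in {0, 1})."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("exogenous input values must be 0 or 1")
        object.__setattr__(self, "values", values)
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.values)

    def at_acquisition_grid(self, upsample_factor: int) -> np.ndarray:
        """Stimulation mask on the TR grid (1 if any fine step in the TR is on)."""
        n_vol = len(self.values) // upsample_factor
        trimmed = self.values[: n_vol * upsample_factor]
        return (trimmed.reshape(n_vol, upsample_factor).max(axis=1) > 0).astype(float)


@dataclass(frozen=True)
class GroundTruth:
    """Group-level generative truth of a cohort."""

    weights_by_group: dict[str, np.ndarray]
    discriminative_paths: list[tuple[int, int]]
    coupling_aq: float
    coupling_rme: float
    path_weight_sd: float

    def __post_init__(self) -> None:
        for group, w in self.weights_by_group.items():
            w = np.asarray(w, dtype=float)
            if w.ndim != 2 or w.shape[0] != w.shape[1]:
                raise ValueError(f"weight matrix for {group} must be square")
            if spectral_radius(w) >= 1.0:
                raise ValueError(f"weight matrix for {group} is not stationary")
        if self.coupling_aq > 0:
            raise ValueError("coupling_aq must be <= 0 (AQ rises as weights fall)")
        if self.coupling_rme < 0:
            raise ValueError("coupling_rme must be >= 0")

    @property
    def n_rois(self) -> int:
        return self.weights_by_group["TD"].shape[0]


@dataclass
class SubjectRecord:
    """One synthetic subject.

    ``neuronal_truth`` and ``true_weights`` are generative ground truth
    retained for validation; a real dataset would not contain them.
    """

    subject_id: str
    group: str
    roi_series: np.ndarray        # (n_rois, n_volumes) observed BOLD
    neuronal_truth: np.ndarray    # (n_rois, n_fine) latent neuronal series
    true_weights: np.ndarray      # (n_rois, n_rois) subject lag-1 matrix
    motion: MotionTrace
    aq: float
    rme: float
    fa: float
    roi_labels: tuple[str, ...] = field(default_factory=tuple)
    hemodynamic_params: HemodynamicParams | None = None


def spectral_radius(matrix: np.ndarray) -> float:
    """Largest absolute eigenvalue of a lag-1 coefficient matrix."""
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(matrix, dtype=float)))))


def generate_boxcar(
    events: list[tuple[float, float]],
    total_duration: float,
    dt: float,
) -> ExogenousInput:
    """Build a 0/1 boxcar from ``(onset, duration)`` events in seconds.

    Sample times ``k * dt`` falling inside any ``[onset, onset + duration)``
    interval are set to 1.  Overlapping events are merged with a log
    message; events extending past ``total_duration`` raise.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(total_duration / dt))
    values = np.zeros(n)
    times = np.arange(n) * dt
    intervals = sorted((float(onset), float(onset) + float(dur)) for onset, dur in events)
    for onset, end in intervals:
        if onset < 0 or end > total_duration + 1e-9:
            raise ValueError(
                f"event [{onset}, {end}) falls outside [0, {total_duration})"
            )
    merged: list[list[float]] = []
    for onset, end in intervals:
        if merged and onset < merged[-1][1]:
            logger.info("merging overlapping events at t=%.3f s", onset)
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([onset, end])
    for onset, end in merged:
        values[(times >= onset - 1e-9) & (times < end - 1e-9)] = 1.0
    return ExogenousInput(values=values, dt=dt)


def default_event_schedule(
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """Event-related schedule of 11 s vignettes separated by jittered fixation.

    Trials of 11 s are laid down from t = 10 s with inter-trial fixation
    jittered uniformly between 4 and 8 s, filling the run.
    """
    rng = rng or np.random.default_rng(0)
    duration = 11.0
    run_length = config.n_volumes * config.tr
    events: list[tuple[float, float]] = []
    t = 10.0
    while t + duration <= run_length - 5.0:
        events.append((t, duration))
        t += duration + rng.uniform(4.0, 8.0)
    return events


def generate_ground_truth_networks(config: CohortConfig) -> GroundTruth:
    """Draw the two group-level lag-1 matrices and the discriminative paths.

    Both matrices share a sparse random background network and the
    ``self_coupling`` diagonal; they differ only on the
    ``n_discriminative_paths`` designated entries, where the TD weight
    exceeds the ASD weight by ``effect_size * path_weight_sd``.  If the
    requested effect destabilizes either process the off-diagonal part is
    rescaled with a warning.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6E657477]))
    k = config.n_rois
    base = np.zeros((k, k))
    off_diag = [(i, j) for i in range(k) for j in range(k) if i != j]
    # sparse background connectivity (~15% of directed pairs)
    n_background = max(1, int(round(0.15 * len(off_diag))))
    bg_idx = rng.choice(len(off_diag), size=n_background, replace=False)
    for idx in bg_idx:
        i, j = off_diag[idx]
        base[i, j] = rng.normal(0.0, 0.04)
    np.fill_diagonal(base, config.self_coupling)

    # (source, sink) pairs; matrix entry [sink, source] carries source -> sink.
    # The designated paths respect a random feed-forward hierarchy (no
    # directed cycles among them): strong recurrent loops would push the
    # spectral radius of the recursion towards instability, whereas an
    # acyclic set of strong paths adds nothing to it.
    hierarchy = rng.permutation(k)
    rank = np.empty(k, dtype=int)
    rank[hierarchy] = np.arange(k)
    forward_pairs = [(i, j) for (i, j) in off_diag if rank[i] < rank[j]]
    if config.n_discriminative_paths > len(forward_pairs):
        raise ValueError("too many discriminative paths for the ROI count")
    chosen = rng.choice(len(forward_pairs), size=config.n_discriminative_paths, replace=False)
    paths = [(forward_pairs[idx][0], forward_pairs[idx][1]) for idx in chosen]

    delta = config.effect_size * config.path_weight_sd
    w_td = base.copy()
    w_asd = base.copy()
    for source, sink in paths:
        mid = 0.10  # shared positive baseline weight on designated paths
        w_td[sink, source] = mid + delta / 2.0
        w_asd[sink, source] = mid - delta / 2.0

    # If the requested effect still destabilizes either process, shrink the
    # off-diagonal part of BOTH matrices by a common factor so the groups
    # stay identical off the designated paths.
    scale = 1.0
    while max(spectral_radius(w_td), spectral_radius(w_asd)) >= 0.97:
        scale *= 0.95
        for w in (w_td, w_asd):
            diag = np.diag(w).copy()
            w *= 0.95
            np.fill_diagonal(w, diag)
    if scale < 1.0:
        warnings.warn(
            f"rescaled off-diagonal weights of both group networks by "
            f"{scale:.3f} to keep the processes stationary",
            stacklevel=2,
        )

    return GroundTruth(
        weights_by_group={"TD": w_td, "ASD": w_asd},
        discriminative_paths=paths,
        coupling_aq=-config.behaviour_coupling,
        coupling_rme=config.behaviour_coupling,
        path_weight_sd=config.path_weight_sd,
    )


def _stabilize_inplace(w: np.ndarray, target: float = 0.97) -> float:
    """Shrink off-diagonal weights until the spectral radius is < ``target``.

    Returns the cumulative off-diagonal scale factor (1.0 when no
    rescaling was needed)."""
    diag = np.diag(w).copy()
    scale = 1.0
    while spectral_radius(w) >= target:
        scale *= 0.95
        off = (w - np.diag(diag)) * 0.95
        w[:] = off
        np.fill_diagonal(w, diag)
    return scale


def draw_subject_weights(
    truth: GroundTruth,
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Subject-level lag-1 matrix: group matrix plus off-diagonal jitter.

    The jitter s.d. is ``config.path_weight_sd`` on the network's active
    entries (background and designated paths), so the designated paths
    have within-group spread equal to the spread entering the
    effect-size definition; the remaining (null) paths receive a small
    jitter (one sixth of that) to keep them weakly individual without
    threatening stationarity.  Unstable draws are rescaled.
    """
    w = truth.weights_by_group[group].copy()
    k = w.shape[0]
    active = np.zeros((k, k), dtype=bool)
    for wg in truth.weights_by_group.values():
        active |= wg != 0
    np.fill_diagonal(active, False)
    sd = np.where(active, config.path_weight_sd, config.path_weight_sd / 6.0)
    jitter = rng.normal(0.0, 1.0, size=(k, k)) * sd
    np.fill_diagonal(jitter, 0.0)
    w = w + jitter
    _stabilize_inplace(w, target=0.995)
    return w


def simulate_neuronal_series(
    weights: np.ndarray,
    u: ExogenousInput,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Run the lag-1 neuronal recursion with boxcar drive and innovations.

    ``h_t = W h_{t-1} + g u_t + w_t`` on the fine grid; a burn-in of
    :data:`BURN_IN_STEPS` steps is simulated and discarded.
    """
    k = weights.shape[0]
    n = len(u.values)
    drive = config.input_gain * u.values
    noise = rng.normal(0.0, config.neuronal_noise_sd, size=(BURN_IN_STEPS + n, k))
    h = np.zeros((BURN_IN_STEPS + n, k))
    state = np.zeros(k)
    for t in range(BURN_IN_STEPS + n):
        d = drive[t - BURN_IN_STEPS] if t >= BURN_IN_STEPS else 0.0
        state = weights @ state + d + noise[t]
        h[t] = state
    return h[BURN_IN_STEPS:].T.copy()  # (n_rois, n_fine)


def simulate_neuronal_subject(
    truth: GroundTruth,
    group: str,
    u: ExogenousInput,
    config: CohortConfig,
    seed: int,
) -> np.ndarray:
    """Latent neuronal series for one subject of ``group`` (fine grid).

    Draws the subject's individual weight matrix around the group matrix
    and runs :func:`simulate_neuronal_series`; deterministic in ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed, 0x73696D]))
    weights = draw_subject_weights(truth, group, config, rng)
    return simulate_neuronal_series(weights, u, config, rng)


def generate_motion_trace(
    n_volumes: int,
    magnitude: float,
    seed: int | np.random.Generator,
) -> MotionTrace:
    """Six-parameter motion trace as bounded (mean-reverting) random walks.

    Translations (mm) and rotations (degrees) follow an AR(1) process
    with stationary s.d. ``magnitude / 2``, so excursions stay within
    roughly ``±1.5 * magnitude``.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rho = 0.95
    sd = magnitude / 2.0
    innovations = rng.normal(0.0, 1.0, size=(n_volumes, 6))
    data = np.zeros((n_volumes, 6))
    if sd > 0:
        scale = sd * np.sqrt(1.0 - rho**2)
        # start at zero: volumes are realigned to the first frame
        state = np.zeros(6)
        for t in range(1, n_volumes):
            state = rho * state + scale * innovations[t]
            data[t] = state
    return MotionTrace(data=data)


def generate_scalar_features(
    subject_weights: np.ndarray,
    truth: GroundTruth,
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Draw (AQ, RME, FA) for one subject.

    AQ and RME have uniform marginals over their configured ranges and
    are coupled to the subject's mean discriminative-path weight through
    a Gaussian copula: AQ falls and RME rises with stronger weights.  FA
    is uniform in its range with a group shift proportional to
    ``effect_size`` (ASD lower), so a null cohort carries no FA signal.
    """
    paths = truth.discriminative_paths
    if paths:
        w_bar = float(np.mean([subject_weights[sink, source] for source, sink in paths]))
        centre = float(
            np.mean(
                [
                    np.mean([w[sink, source] for source, sink in paths])
                    for w in truth.weights_by_group.values()
                ]
            )
        )
        spread = truth.path_weight_sd / np.sqrt(len(paths))
        # total spread includes the group offset delta/2 around the centre
        delta = abs(
            np.mean([truth.weights_by_group["TD"][s2, s1] for s1, s2 in paths])
            - np.mean([truth.weights_by_group["ASD"][s2, s1] for s1, s2 in paths])
        )
        total_sd = float(np.hypot(spread, delta / 2.0))
        z = (w_bar - centre) / total_sd if total_sd > 0 else 0.0
    else:
        z = 0.0
    c_aq = truth.coupling_aq
    c_rme = truth.coupling_rme
    lat_aq = c_aq * z + np.sqrt(max(0.0, 1 - c_aq**2)) * rng.normal()
    lat_rme = c_rme * z + np.sqrt(max(0.0, 1 - c_rme**2)) * rng.normal()
    aq = AQ_RANGE[0] + (AQ_RANGE[1] - AQ_RANGE[0]) * norm.cdf(lat_aq)
    rme = RME_RANGE[0] + (RME_RANGE[1] - RME_RANGE[0]) * norm.cdf(lat_rme)
    fa = rng.uniform(*FA_RANGE)
    fa_shift = 0.01 * config.effect_size
    fa += -fa_shift / 2.0 if group == "ASD" else fa_shift / 2.0
    fa = float(np.clip(fa, 0.0, 1.0))
    return float(aq), float(rme), fa


def _jittered_params(
    config: CohortConfig, rng: np.random.Generator
) -> HemodynamicParams:
    """Per-ROI hemodynamic parameters with log-normal jitter."""
    base = HemodynamicParams()
    jitter = config.hrf_jitter

    def draw(value: float) -> np.ndarray:
        return value * np.exp(rng.normal(0.0, jitter, size=config.n_rois))

    e0 = np.clip(draw(base.oxygen_extraction), 0.05, 0.95)
    return HemodynamicParams(
        signal_decay=draw(base.signal_decay),
        feedback=draw(base.feedback),
        transit_time=draw(base.transit_time),
        stiffness=draw(base.stiffness),
        oxygen_extraction=e0,
    )


def generate_cohort(
    config: CohortConfig,
    events: list[tuple[float, float]] | None = None,
) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate a full two-group cohort; reproducible from ``config.seed``.

    For each subject the latent neuronal series is simulated from the
    subject's individual weight matrix, pushed through the balloon
    forward model with jittered hemodynamic parameters, downsampled to
    the TR grid, and corrupted with white noise scaled so that the
    variance-ratio SNR of each ROI series is ``snr_target``.
    """
    root = np.random.SeedSequence([config.seed, 0x636F686F])
    schedule_rng = np.random.default_rng(root.spawn(1)[0])
    if events is None:
        events = default_event_schedule(config, schedule_rng)
    u = generate_boxcar(events, config.n_volumes * config.tr, config.fine_dt)

    truth = generate_ground_truth_networks(config)
    subjects: list[SubjectRecord] = []
    index = 0
    for group in ("ASD", "TD"):
        for within in range(config.n_per_group):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 0x73756266, index])
            )
            weights = draw_subject_weights(truth, group, config, rng)
            neuronal = simulate_neuronal_series(weights, u, config, rng)
            params = _jittered_params(config, rng)
            clean = balloon_forward(
                neuronal,
                params,
                dt=config.fine_dt,
                tr=config.tr,
                noise_variance=0.0,
                rng=rng,
            )
            noise_var = clean.var(axis=1) / (config.snr_target - 1.0)
            noise_sd = np.sqrt(np.maximum(noise_var, 1e-12))
            bold = clean + rng.normal(size=clean.shape) * noise_sd[:, None]
            motion = generate_motion_trace(config.n_volumes, config.motion_magnitude, rng)
            aq, rme, fa = generate_scalar_features(weights, truth, config, group, rng)
            subjects.append(
                SubjectRecord(
                    subject_id=f"sub-{index + 1:03d}",
                    group=group,
                    roi_series=bold,
                    neuronal_truth=neuronal,
                    true_weights=weights,
                    motion=motion,
                    aq=aq,
                    rme=rme,
                    fa=fa,
                    roi_labels=config.labels,
                    hemodynamic_params=params,
                )
            )
            index += 1
    return subjects, truth


def cohort_exogenous_input(
    config: CohortConfig,
    events: list[tuple[float, float]] | None = None,
) -> ExogenousInput:
    """The boxcar a cohort generated from ``config`` was driven with."""
    root = np.random.SeedSequence([config.seed, 0x636F686F])
    schedule_rng = np.random.default_rng(root.spawn(1)[0])
    if events is None:
        events = default_event_schedule(config, schedule_rng)
    return generate_boxcar(events, config.n_volumes * config.tr, config.fine_dt)


def null_config(config: CohortConfig) -> CohortConfig:
    """A copy of ``config`` with no group effect and no behaviour coupling."""
    return replace(config, effect_size=0.0, behaviour_coupling=0.0)
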