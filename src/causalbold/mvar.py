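"""Multivariate autoregressive (MVAR) connectivity estimation.

The model for ``l`` z-scored neuronal series ``h(t)`` combines a
zero-diagonal instantaneous coefficient matrix ``a(0)`` with lagged
matrices ``a(1..p)``:

    h(t) = a(0) h(t) + sum_j a(j) h(t - j) + e(t)

The lagged coefficients carry the Granger-causal (time-lagged,
directed) influences; the instantaneous matrix absorbs zero-lag
correlation so that it does not leak into the causal terms.  Estimation
is per-target ordinary least squares over all regressors jointly.

Directed "causal path weight" features are the lag-1 coefficients
``a_sink,source(1)`` for every ordered ROI pair; functional-connectivity
features are Fisher-z transformed Pearson correlations per unordered
pair, conventionally computed on the TR-grid BOLD series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from causalbold.rois import pair_name, path_name, roi_labels

#: Clamp on |r| before the Fisher transform, keeping z finite.
_FISHER_CLAMP = 1.0 - 1e-12


@dataclass
class MvarModel:
    """Fitted MVAR model with instantaneous and lagged coefficients."""

    instantaneous: np.ndarray          # (l, l), zero diagonal
    lagged: list[np.ndarray]           # p matrices of shape (l, l)
    order: int
    residuals: np.ndarray              # (l, T - p)
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(np.diag(self.instantaneous) != 0):
            raise ValueError("instantaneous matrix must have a zero diagonal")
        if len(self.lagged) != self.order:
            raise ValueError("number of lagged matrices must equal the order")


@dataclass
class EffectiveConnectivityFeatures:
    """Directed causal path weights, one per ordered ROI pair."""

    names: list[str]
    values: np.ndarray
    order: int = 1

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


@dataclass
class FunctionalConnectivityFeatures:
    """Fisher-z correlations, one per unordered ROI pair."""

    names: list[str]
    values: np.ndarray

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def mvar_coefficient_count(k: int, p: int) -> int:
    """Number of lagged MVAR coefficients, ``k**2 * p``.

    The model is estimable only when this count is smaller than the
    number of time points per series.
    """
    if k < 1 or p < 1:
        raise ValueError("k and p must be >= 1")
    return k * k * p


def _check_estimable(k: int, p: int, t: int) -> None:
    count = mvar_coefficient_count(k, p)
    if count >= t:
        raise ValueError(
            f"MVAR not estimable: k^2*p = {count} must be < T = {t} time points"
        )


def fit_mvar(
    series: np.ndarray,
    p: int = 1,
    include_instantaneous: bool = True,
    labels: tuple[str, ...] | None = None,
) -> MvarModel:
    """Least-squares fit of the MVAR model with optional a(0) term.

    Parameters
    ----------
    series:
        ``(l, T)`` matrix of time series (rows are ROIs).
    p:
        Model order; ``k**2 * p < T`` is enforced.
    include_instantaneous:
        Include the zero-diagonal instantaneous matrix.

    Each target series is regressed jointly on the other series at lag 0
    (when enabled) and on all series at lags 1..p.  Deterministic.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a 2-D (l, T) array")
    l, t = series.shape
    _check_estimable(l, p, t)
    variances = series.var(axis=1)
    if np.any(variances <= 0):
        bad = int(np.argmin(variances))
        raise ValueError(f"series row {bad} has zero variance")
    labels = labels or roi_labels(l)

    lag_blocks = [series[:, p - j : t - j].T for j in range(1, p + 1)]  # (T-p, l) each
    lagged_design = np.hstack(lag_blocks)
    current = series[:, p:].T  # (T-p, l)

    a0 = np.zeros((l, l))
    lagged = [np.zeros((l, l)) for _ in range(p)]
    residuals = np.zeros((l, t - p))
    for target in range(l):
        others = [j for j in range(l) if j != target]
        if include_instantaneous:
            design = np.hstack([current[:, others], lagged_design])
        else:
            design = lagged_design
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise ValueError(
                f"rank-deficient regressor matrix for target {labels[target]}"
            )
        coef, _, _, _ = np.linalg.lstsq(design, current[:, target], rcond=None)
        offset = 0
        if include_instantaneous:
            a0[target, others] = coef[: l - 1]
            offset = l - 1
        for j in range(p):
            lagged[j][target, :] = coef[offset + j * l : offset + (j + 1) * l]
        residuals[target] = current[:, target] - design @ coef
    return MvarModel(
        instantaneous=a0,
        lagged=lagged,
        order=p,
        residuals=residuals,
        roi_labels=tuple(labels),
    )


def select_model_order(
    series: np.ndarray,
    p_max: int,
    criterion: str = "bic",
    include_instantaneous: bool = False,
) -> int:
    """Model order in ``1..p_max`` minimizing an information criterion.

    The criterion is evaluated on the common sample ``t = p_max..T`` so
    that all candidate orders see the same data:
    ``ln det(Sigma_e) + penalty * k^2 p / T'`` with penalty ``ln T'``
    (BIC, default) or 2 (AIC).
    """
    series = np.asarray(series, dtype=float)
    l, t = series.shape
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    _check_estimable(l, p_max, t)
    if p_max == 1:
        return 1
    t_eff = t - p_max
    scores = []
    for p in range(1, p_max + 1):
        model = fit_mvar(
            series[:, p_max - p :], p, include_instantaneous=include_instantaneous
        )
        resid = model.residuals[:, -t_eff:]
        sigma = resid @ resid.T / t_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            logdet = np.log(np.linalg.eigvalsh(sigma).clip(1e-300)).sum()
        n_par = mvar_coefficient_count(l, p)
        penalty = np.log(t_eff) if criterion.lower() == "bic" else 2.0
        scores.append(logdet + penalty * n_par / t_eff)
    return int(np.argmin(scores)) + 1


def causal_weight_features(model: MvarModel) -> EffectiveConnectivityFeatures:
    """Directed lag-1 path weights ``SRC->SNK`` for all ordered pairs.

    The feature for source ``i`` and sink ``j`` is the lag-1 coefficient
    ``a_ji(1)``; self-paths are excluded, giving ``l*(l-1)`` features in
    source-major order.
    """
    labels = model.roi_labels
    a1 = model.lagged[0]
    names: list[str] = []
    values: list[float] = []
    for i, source in enumerate(labels):
        for j, sink in enumerate(labels):
            if i == j:
                continue
            names.append(path_name(source, sink))
            values.append(float(a1[j, i]))
    return EffectiveConnectivityFeatures(
        names=names, values=np.array(values), order=model.order
    )


def functional_connectivity_features(
    series: np.ndarray,
    labels: tuple[str, ...] | None = None,
) -> FunctionalConnectivityFeatures:
    """Fisher-z Pearson correlations ``A<->B`` for all unordered pairs."""
    series = np.asarray(series, dtype=float)
    l = series.shape[0]
    labels = labels or roi_labels(l)
    variances = series.var(axis=1)
    if np.any(variances <= 0):
        bad = labels[int(np.argmin(variances))]
        raise ValueError(f"zero-variance series for ROI {bad}")
    corr = np.corrcoef(series)
    names: list[str] = []
    values: list[float] = []
    for i in range(l):
        for j in range(i + 1, l):
            r = float(np.clip(corr[i, j], -_FISHER_CLAMP, _FISHER_CLAMP))
            names.append(pair_name(labels[i], labels[j]))
            values.append(float(np.arctanh(r)))
    return FunctionalConnectivityFeatures(names=names, values=np.array(values))


def zscore_rows(series: np.ndarray) -> np.ndarray:
    """Variance-normalize each row (used before MVAR fitting)."""
    series = np.asarray(series, dtype=float)
    mean = series.mean(axis=1, keepdims=True)
    sd = series.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot z-score a zero-variance series")
    return (series - mean) / sd
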