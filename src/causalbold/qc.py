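"""Head-motion / signal quality control and nonparametric group statistics.

Covers the motion summaries (per-parameter RMS, framewise displacement
with rotations converted to arc length on a 50 mm sphere), the
variance-ratio SNR of deconvolved series, and the statistical tests the
analysis reports: Mann–Whitney U (equivalently Wilcoxon rank-sum),
Spearman correlation with an exact small-sample mode, two-sample t from
printed summary statistics, per-path group comparisons with Bonferroni
correction, and the QC–connectivity screen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

#: Column order of a six-parameter motion trace.
MOTION_COLUMNS = ("x", "y", "z", "pitch", "roll", "yaw")

#: Default head-radius (mm) for converting rotations to displacements.
DEFAULT_SPHERE_RADIUS = 50.0


@dataclass(frozen=True)
class MotionTrace:
    """Rigid-body motion parameters per volume.

    ``data`` has one row per volume and six columns: translations
    ``x, y, z`` in millimetres and rotations ``pitch, roll, yaw`` in
    degrees (the on-disk SPM ``rp_*.txt`` dialect stores rotations in
    radians; conversion happens in :mod:`causalbold.io`).
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] != 6:
            raise ValueError("motion trace must have shape (n_volumes, 6)")
        object.__setattr__(self, "data", data)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.data[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.data[:, 3:]

    def max_excursion(self) -> float:
        """Largest |value| over all six parameters (mm or degrees)."""
        return float(np.max(np.abs(self.data))) if self.n_volumes else 0.0


@dataclass(frozen=True)
class FdSeries:
    """Per-frame framewise displacement (mm); the first frame is 0."""

    values: np.ndarray
    sphere_radius: float = DEFAULT_SPHERE_RADIUS

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if np.any(values < 0):
            raise ValueError("FD values must be non-negative")
        object.__setattr__(self, "values", values)

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class GroupTestResult:
    """Outcome of one statistical test."""

    statistic: float
    p_value: float
    test_name: str
    z_value: float | None = None
    n_per_group: tuple[int, int] | None = None
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def framewise_displacement(
    trace: MotionTrace,
    sphere_radius: float = DEFAULT_SPHERE_RADIUS,
) -> FdSeries:
    """FD_i = |Δx| + |Δy| + |Δz| + r·(|Δpitch| + |Δroll| + |Δyaw|).

    Backward differences between consecutive volumes; rotations are
    converted from degrees to radians and then to arc length on a
    sphere of ``sphere_radius`` mm.  The first frame has FD = 0.
    """
    translations = trace.translations
    rotations_rad = np.deg2rad(trace.rotations_deg)
    d_trans = np.abs(np.diff(translations, axis=0)).sum(axis=1)
    d_rot = sphere_radius * np.abs(np.diff(rotations_rad, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], d_trans + d_rot])
    return FdSeries(values=fd, sphere_radius=sphere_radius)


def rms_motion(trace: MotionTrace) -> np.ndarray:
    """Root-mean-square per motion parameter (six values)."""
    return np.sqrt(np.mean(trace.data**2, axis=0))


def mann_whitney_u(
    group_a: np.ndarray,
    group_b: np.ndarray,
    exact: bool | None = None,
) -> GroupTestResult:
    """Mann–Whitney U test (min-U convention) with tie-corrected normal z.

    ``U = min(U_a, U_b)`` from midrank rank sums.  The two-sided p-value
    uses the normal approximation with tie and continuity corrections,
    or the exact distribution when ``exact`` is requested (or n <= 8 per
    group with no ties).  The reported ``z`` is the (non-positive)
    standardized min-U.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; U test degenerate", stacklevel=2)
        return GroupTestResult(
            statistic=a.size * b.size / 2.0,
            p_value=1.0,
            z_value=0.0,
            test_name="mann-whitney-u",
            n_per_group=(a.size, b.size),
        )
    n1, n2 = a.size, b.size
    has_ties = np.unique(pooled).size < pooled.size
    if exact is None:
        exact = (max(n1, n2) <= 8) and not has_ties

    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    u_a = float(res.statistic)
    u_min = min(u_a, n1 * n2 - u_a)

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    n = n1 + n2
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    mu = n1 * n2 / 2.0
    z = (u_min - mu + 0.5) / sigma if sigma > 0 else 0.0
    return GroupTestResult(
        statistic=u_min,
        p_value=float(res.pvalue),
        z_value=float(z),
        test_name="mann-whitney-u" + ("-exact" if exact else ""),
        n_per_group=(n1, n2),
    )


def wilcoxon_rank_sum(group_a: np.ndarray, group_b: np.ndarray) -> GroupTestResult:
    """Wilcoxon rank-sum comparison (same statistic family as the U test)."""
    result = mann_whitney_u(group_a, group_b)
    return GroupTestResult(
        statistic=result.statistic,
        p_value=result.p_value,
        z_value=result.z_value,
        test_name="wilcoxon-rank-sum",
        n_per_group=result.n_per_group,
    )


def snr_deconvolved(
    neuronal_estimate: np.ndarray,
    stimulation_mask: np.ndarray,
) -> float:
    """Variance-ratio SNR of a deconvolved series.

    Variance of the entire series divided by the variance during
    non-stimulation samples (mask value 0).
    """
    series = np.asarray(neuronal_estimate, dtype=float).ravel()
    mask = np.asarray(stimulation_mask).ravel()
    if len(mask) != len(series):
        raise ValueError("stimulation mask length must match the series")
    rest = series[mask == 0]
    if rest.size < 2:
        raise ValueError("need at least 2 non-stimulation samples")
    rest_var = float(np.var(rest))
    if rest_var == 0:
        raise ValueError("zero variance during non-stimulation phases")
    return float(np.var(series)) / rest_var


def spearman_correlation(
    x: np.ndarray,
    y: np.ndarray,
    exact: bool | None = None,
) -> GroupTestResult:
    """Spearman rank correlation with midrank ties.

    Two-sided p-value from the t approximation, or by exhaustive
    permutation of one variable when ``exact`` is requested (default for
    n <= 9, where full enumeration is cheap).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.var(rx) == 0 or np.var(ry) == 0:
        raise ValueError("zero rank variance (constant input)")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact is None:
        exact = n <= 9
    if exact:
        ry_c = (ry - ry.mean()) / ry.std()
        rx_c = (rx - rx.mean()) / rx.std()
        perms = np.array(list(permutations(range(n))))
        rhos = (rx_c[perms] * ry_c[None, :]).mean(axis=1)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        name = "spearman-exact"
    else:
        res = stats.spearmanr(x, y)
        p = float(res.pvalue)
        name = "spearman"
    return GroupTestResult(
        statistic=rho, p_value=p, test_name=name, n_per_group=(n, n)
    )


def two_sample_t_from_summary(
    mean_a: float, se_a: float, mean_b: float, se_b: float
) -> float:
    """|t| for a two-group comparison from printed means and standard errors.

    ``t = |mean_a - mean_b| / sqrt(se_a**2 + se_b**2)``; with equal group
    sizes this equals the pooled two-sample t statistic.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    return abs(mean_a - mean_b) / math.hypot(se_a, se_b)


def path_group_comparison(
    weights_by_group: dict[str, np.ndarray],
    path_names: list[str],
    alpha: float = 0.05,
    n_corrected: int | None = None,
) -> list[GroupTestResult]:
    """Two-sample t per directed path with Bonferroni correction.

    ``weights_by_group`` maps each of the two group labels to a
    ``(n_subjects, n_paths)`` matrix.  ``n_corrected`` is the number of
    comparisons used for the Bonferroni threshold (defaults to the
    number of paths).  Each result records the t statistic, raw and
    corrected p, the direction (which group is larger) and the flag.
    """
    groups = list(weights_by_group)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    wa = np.atleast_2d(np.asarray(weights_by_group[groups[0]], dtype=float))
    wb = np.atleast_2d(np.asarray(weights_by_group[groups[1]], dtype=float))
    if wa.shape[0] < 2 or wb.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if wa.shape[1] != len(path_names) or wb.shape[1] != len(path_names):
        raise ValueError("weight matrices must have one column per path")
    m = n_corrected if n_corrected is not None else len(path_names)
    results = []
    for idx, name in enumerate(path_names):
        t_stat, p = stats.ttest_ind(wa[:, idx], wb[:, idx], equal_var=True)
        if math.isnan(t_stat):  # identical samples
            t_stat, p = 0.0, 1.0
        p_adj = min(1.0, float(p) * m)
        direction = groups[0] if wa[:, idx].mean() > wb[:, idx].mean() else groups[1]
        if wa[:, idx].mean() == wb[:, idx].mean():
            direction = "equal"
        results.append(
            GroupTestResult(
                statistic=float(t_stat),
                p_value=float(p),
                test_name="two-sample-t",
                n_per_group=(wa.shape[0], wb.shape[0]),
                extra={
                    "path": name,
                    "p_adjusted": p_adj,
                    "significant": p_adj < alpha,
                    "larger_group": direction,
                },
            )
        )
    return results


def qc_connectivity_screen(
    mean_fd_per_subject: np.ndarray,
    feature_subset: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> list[GroupTestResult]:
    """Spearman correlation of each connectivity feature with mean FD.

    Returns one result per feature with a significance flag at
    ``alpha``; constant features surface the underlying error message in
    the result's ``extra`` field rather than aborting the screen.
    """
    fd = np.asarray(mean_fd_per_subject, dtype=float)
    results = []
    for name, values in feature_subset.items():
        values = np.asarray(values, dtype=float)
        if values.shape != fd.shape:
            raise ValueError(f"feature {name} is not aligned with FD values")
        try:
            res = spearman_correlation(fd, values)
        except ValueError as err:
            results.append(
                GroupTestResult(
                    statistic=float("nan"),
                    p_value=float("nan"),
                    test_name="spearman",
                    extra={"feature": name, "error": str(err)},
                )
            )
            continue
        results.append(
            GroupTestResult(
                statistic=res.statistic,
                p_value=res.p_value,
                test_name=res.test_name,
                n_per_group=res.n_per_group,
                extra={"feature": name, "significant": res.p_value < alpha},
            )
        )
    return results
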