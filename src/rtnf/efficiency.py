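"""Offline ROI GLM: training efficiency per run and best-run selection.

The regulation success of a neurofeedback run is summarized by the
*training efficiency* TE = PSC_target − PSC_background, where each PSC
is the percent-signal-change equivalent of a GLM contrast estimate on
the ROI-averaged raw time course.  The parallel paradigm is modeled
with a single "think" regressor (count is the implicit baseline,
so the contrast reads "think > count"); the serial paradigm models
"think" and "count" explicitly and contrasts think > count.

Contrast estimates (raw-intensity units per unit regressor) are
converted to PSC by scaling with the peak height of the contrasted
regressor and dividing by the run mean intensity — the unit-peak-
regressor convention, configurable through ``peak_height``.

The run with the highest TE among a subject's 18 training runs is the
most efficient training run (mETR), ties broken by chronology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .paradigm import ParadigmSchedule

__all__ = [
    "HRFParams",
    "double_gamma_hrf",
    "DesignMatrix",
    "build_design",
    "fit_ols",
    "contrast_to_psc",
    "training_efficiency",
    "select_metr",
    "EfficiencyResult",
    "SubjectSummary",
    "run_efficiency",
    "DEFAULT_CONTRASTS",
]


# ---------------------------------------------------------------------------
# hemodynamic response function

@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF parameters.

    Response peaking at 6 s with a 16-s undershoot weighted 1/6,
    both with 1 s^2 dispersion; kernel support 32 s.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0


def double_gamma_hrf(dt: float, params: HRFParams | None = None) -> np.ndarray:
    """Sample the double-gamma HRF at resolution ``dt`` (unit peak).

    The kernel is the difference of two gamma densities with shape
    ``delay/dispersion`` and scale ``dispersion``, normalized so the
    main lobe peaks at 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params or HRFParams()
    t = np.arange(0, p.length + dt / 2, dt)
    # gamma density with scale s has its mode at (shape-1)*s, so shape is
    # chosen as delay/dispersion + 1 to put the mode at the stated delay
    peak = gamma_dist.pdf(
        t, p.peak_delay / p.peak_dispersion + 1, scale=p.peak_dispersion
    )
    under = gamma_dist.pdf(
        t, p.undershoot_delay / p.undershoot_dispersion + 1,
        scale=p.undershoot_dispersion,
    )
    h = peak - p.undershoot_ratio * under
    return h / h.max()


def condition_regressor(
    schedule: ParadigmSchedule,
    condition: str,
    dt: float | None = None,
    hrf_params: HRFParams | None = None,
    blocks: list[int] | None = None,
) -> np.ndarray:
    """Unit-height boxcar for ``condition`` convolved with the HRF,
    sampled at volume times (length ``n_volumes``).

    ``dt`` sets the convolution grid (defaults to TR).  ``blocks``
    restricts the boxcar to the given block indices (for least-squares-
    all single-repetition regressors).
    """
    dt = schedule.tr if dt is None else dt
    n_fine = int(round(schedule.total_duration / dt))
    box = np.zeros(n_fine)
    for i, blk in enumerate(schedule.blocks):
        if blk.condition != condition:
            continue
        if blocks is not None and i not in blocks:
            continue
        a = int(round(blk.onset / dt))
        b = int(round(blk.end / dt))
        box[a:b] = 1.0
    hrf = double_gamma_hrf(dt, hrf_params)
    conv = np.convolve(box, hrf)[:n_fine]
    step = int(round(schedule.tr / dt))
    return conv[::step][: schedule.n_volumes].copy()


# ---------------------------------------------------------------------------
# design matrix and OLS

@dataclass
class DesignMatrix:
    """GLM design: condition regressors plus intercept.

    ``peak_heights`` records the pre-scaling max |value| of each
    condition regressor, used by the PSC conversion.
    """

    names: list[str]
    X: np.ndarray
    peak_heights: dict[str, float]
    condition_names: list[str]

    @property
    def n_volumes(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]


#: Contrast weights on condition columns, per paradigm.
DEFAULT_CONTRASTS = {"parallel": {"think": 1.0}, "serial": {"think": 1.0, "count": -1.0}}


def build_design(
    schedule: ParadigmSchedule,
    conditions: set[str] | list[str] | tuple[str, ...],
    hrf_params: HRFParams | None = None,
    dt: float | None = None,
) -> DesignMatrix:
    """Boxcar-convolved condition regressors + intercept, at TR resolution."""
    conditions = list(conditions)
    if not conditions:
        raise ValueError("condition set must be non-empty")
    missing = set(conditions) - schedule.conditions
    if missing:
        raise ValueError(f"conditions {sorted(missing)} not in schedule")
    cols, peaks = [], {}
    for cond in conditions:
        reg = condition_regressor(schedule, cond, dt=dt, hrf_params=hrf_params)
        if not reg.any():
            raise ValueError(f"all-zero regressor for condition {cond!r}")
        peaks[cond] = float(np.abs(reg).max())
        cols.append(reg)
    cols.append(np.ones(schedule.n_volumes))
    X = np.column_stack(cols)
    return DesignMatrix(conditions + ["intercept"], X, peaks, conditions)


def fit_ols(design: DesignMatrix | np.ndarray, ts: np.ndarray):
    """Ordinary least squares; returns (coefficients, residual variance).

    Residual variance uses dof = n − p.  Raises on rank deficiency,
    naming collinear columns where the design carries names.
    """
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, float)
    y = np.asarray(ts, float)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"design has {X.shape[0]} rows, series has {y.shape[0]}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if isinstance(design, DesignMatrix):
            # identify columns involved in the collinearity via QR pivoting
            from scipy.linalg import qr

            _, r, piv = qr(X, pivoting=True)
            bad = sorted(design.names[j] for j in piv[rank:])
            raise np.linalg.LinAlgError(f"design is rank deficient; collinear columns: {bad}")
        raise np.linalg.LinAlgError("design is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid / dof) if dof > 0 else math.nan
    return beta, sigma2


def contrast_to_psc(
    coefficients: np.ndarray,
    contrast: dict[str, float] | np.ndarray,
    design: DesignMatrix,
    ts_mean: float,
) -> float:
    """Convert a contrast of condition coefficients to percent signal change.

    PSC = 100 · (c·β) · peak / mean, where *peak* is the max |value| of
    the positively weighted part of the contrast-combined regressor
    (for a think > count contrast, the peak of the think response).
    Using the positive part keeps the parallel "think" contrast and the
    serial "think > count" contrast on the same scale, which is what
    makes TE comparable across paradigms.
    """
    if ts_mean <= 0:
        raise ValueError("ts_mean must be positive")
    if isinstance(contrast, dict):
        w = np.array([contrast.get(c, 0.0) for c in design.condition_names])
    else:
        w = np.asarray(contrast, float)
        if w.size != len(design.condition_names):
            raise ValueError("contrast length must match condition columns")
    cond_cols = design.X[:, : len(design.condition_names)]
    w_pos = np.where(w > 0, w, 0.0)
    effective = cond_cols @ (w_pos if w_pos.any() else w)
    peak = float(np.abs(effective).max())
    cbeta = float(w @ np.asarray(coefficients)[: len(design.condition_names)])
    return 100.0 * cbeta * peak / ts_mean


def training_efficiency(psc_target: float, psc_background: float) -> float:
    """TE = PSC_target − PSC_background (percent)."""
    return psc_target - psc_background


def select_metr(te_per_run) -> tuple[int, float]:
    """1-based index of the run with maximal TE (earliest on ties), and its TE."""
    te = np.asarray(te_per_run, float)
    finite = np.isfinite(te)
    if not finite.any():
        raise ValueError("no finite TE values")
    te_masked = np.where(finite, te, -np.inf)
    idx = int(np.argmax(te_masked))  # argmax returns the first maximum
    return idx + 1, float(te[idx])


# ---------------------------------------------------------------------------
# per-run pipeline

@dataclass(frozen=True)
class EfficiencyResult:
    psc_target: float
    psc_background: float

    @property
    def te(self) -> float:
        return training_efficiency(self.psc_target, self.psc_background)


@dataclass(frozen=True)
class SubjectSummary:
    group: str
    te_per_run: tuple[float, ...]
    metr_index: int
    metr_te: float

    @classmethod
    def from_te(cls, group: str, te_per_run) -> "SubjectSummary":
        idx, te = select_metr(te_per_run)
        return cls(group, tuple(float(v) for v in te_per_run), idx, te)


def run_efficiency(
    target_ts: np.ndarray,
    background_ts: np.ndarray,
    schedule: ParadigmSchedule,
    design: DesignMatrix | None = None,
) -> EfficiencyResult:
    """Fit the paradigm's ROI GLM to both time courses and return the PSC pair.

    Passing a prebuilt ``design`` (from :func:`build_design`) skips the
    per-call regressor convolution, which matters in simulation loops.
    """
    paradigm = schedule.name
    if design is None:
        conds = ["think"] if paradigm == "parallel" else ["think", "count"]
        design = build_design(schedule, conds)
    contrast = DEFAULT_CONTRASTS.get(paradigm, {"think": 1.0})
    pscs = []
    for ts in (target_ts, background_ts):
        ts = np.asarray(ts, float)
        beta, _ = fit_ols(design, ts)
        pscs.append(contrast_to_psc(beta, contrast, design, float(ts.mean())))
    return EfficiencyResult(pscs[0], pscs[1])
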