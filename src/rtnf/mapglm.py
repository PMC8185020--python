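"""Desk-scale whole-brain GLM analysis.

Implements the map-level analysis chain on small synthetic grids:
Gaussian smoothing (FWHM in mm), discrete-cosine high-pass filtering
(0.01 Hz cutoff), motion-based subject exclusion (displacement/task
correlation above Q1 + 1.5*IQR), a first-level least-squares-all GLM
(one regressor per "think" repetition, combined count and feedback
regressors, temporal derivatives, standard or extended motion
confounds), a group one-sample model, cluster-level FWE thresholding
by sign-flip permutation, and minimum-statistic conjunction plus
exclusively masked disjunction.

The group model is voxelwise OLS with t statistics Gaussianized to z
by matched upper-tail quantiles, and the cluster correction is a
sign-flip max-cluster-size permutation test. These replace the
mixed-effects + random-field machinery of large-scale neuroimaging
suites with procedures that are exact at the problem sizes this
package targets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .efficiency import HRFParams, condition_regressor, fit_ols
from .paradigm import ParadigmSchedule

__all__ = [
    "StatMap",
    "MotionRecord",
    "gaussian_smooth",
    "highpass",
    "dct_basis",
    "motion_exclude",
    "build_lsa_design",
    "first_level_lsa",
    "FirstLevelResult",
    "group_one_sample",
    "cluster_threshold",
    "conjunction",
    "disjunction",
    "t_to_z",
]

Z_CAP = 40.0  # |z| ceiling where upper-tail probabilities underflow

#: face (6-neighbor) connectivity for cluster labeling
FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


@dataclass
class StatMap:
    """A voxelwise statistic volume with mask and grid geometry."""

    values: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    stat_type: str = "z"
    threshold_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.mask = np.asarray(self.mask, bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share the grid")
        if not np.isfinite(self.values[self.mask]).all():
            raise ValueError("non-finite statistic inside mask")

    def same_grid(self, other: "StatMap") -> bool:
        return self.values.shape == other.values.shape

    def masked(self) -> np.ndarray:
        return self.values[self.mask]


def _require_same_grid(a: StatMap, b: StatMap) -> None:
    if not a.same_grid(b):
        raise ValueError(f"grid mismatch: {a.values.shape} vs {b.values.shape}")


# ---------------------------------------------------------------------------
# preprocessing operators

def gaussian_smooth(
    volume: np.ndarray,
    fwhm: float = 8.0,
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> np.ndarray:
    """Separable Gaussian smoothing with FWHM given in mm.

    4D input is smoothed spatially, frame by frame.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return np.asarray(volume, float).copy()
    sigma_mm = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / v for v in voxel_size]
    vol = np.asarray(volume, float)
    if vol.ndim == 4:
        sigma = sigma_vox + [0.0]
    elif vol.ndim == 3:
        sigma = sigma_vox
    else:
        raise ValueError("expected a 3D or 4D volume")
    return ndimage.gaussian_filter(vol, sigma=sigma, mode="reflect")


def dct_basis(n: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Drift basis: a linear trend plus discrete-cosine components with
    frequency below cutoff.

    DCT component k (k >= 1) is cos(pi*k*(2i+1)/(2n)) with frequency
    k/(2*n*tr); the constant term is excluded (handled by mean
    removal).  The explicit linear term makes the filter null out
    linear scanner drift exactly, which a truncated cosine set alone
    only approximates.
    """
    k_max = int(np.floor(2.0 * n * tr * cutoff_hz))
    i = np.arange(n)
    cols = [i - i.mean()]
    cols += [np.cos(np.pi * k * (2 * i + 1) / (2.0 * n)) for k in range(1, k_max + 1)]
    return np.column_stack(cols)


def highpass(ts: np.ndarray, cutoff_hz: float = 0.01, tr: float = 2.0) -> np.ndarray:
    """High-pass filter by projecting out slow drift components.

    Removes the mean, a linear trend, and all DCT components slower
    than ``cutoff_hz``.  Works on 1D series or along the last axis of
    an array.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff_hz > 0.5 / tr:
        raise ValueError("cutoff above Nyquist frequency")
    x = np.asarray(ts, float)
    n = x.shape[-1]
    out = x - x.mean(axis=-1, keepdims=True)
    basis = dct_basis(n, tr, cutoff_hz)
    if basis.size:
        q, _ = np.linalg.qr(basis)
        flat = out.reshape(-1, n)
        out = (flat - (flat @ q) @ q.T).reshape(x.shape)
    return out


# ---------------------------------------------------------------------------
# motion-based exclusion

@dataclass
class MotionRecord:
    subject: str
    displacement_ts: np.ndarray
    event_correlation: float = np.nan
    excluded: bool = False
    needs_review: bool = False


def motion_exclude(
    records: list[tuple[str, np.ndarray]] | list[MotionRecord],
    task_regressor: np.ndarray,
    fence: str = "q1",
) -> list[MotionRecord]:
    """Flag subjects whose displacement trace tracks the task.

    The per-subject Pearson correlation between scan-to-scan
    displacement and the task regressor is compared against
    Q1 + 1.5*IQR of the group's correlations (the printed rule;
    ``fence='q3'`` switches to the conventional upper fence).
    Constant displacement traces have no defined correlation and are
    flagged for manual review instead.
    """
    if len(records) < 4:
        raise ValueError("need at least 4 subjects for meaningful quartiles")
    if fence not in ("q1", "q3"):
        raise ValueError("fence must be 'q1' or 'q3'")
    task = np.asarray(task_regressor, float)
    out: list[MotionRecord] = []
    for rec in records:
        if isinstance(rec, MotionRecord):
            subject, disp = rec.subject, np.asarray(rec.displacement_ts, float)
        else:
            subject, disp = rec[0], np.asarray(rec[1], float)
        if disp.std() == 0:
            out.append(MotionRecord(subject, disp, np.nan, False, True))
        else:
            r = float(np.corrcoef(disp, task)[0, 1])
            out.append(MotionRecord(subject, disp, r))
    rs = np.array([m.event_correlation for m in out if not m.needs_review])
    q1, q3 = np.percentile(rs, [25, 75])
    iqr = q3 - q1
    threshold = (q1 if fence == "q1" else q3) + 1.5 * iqr
    for m in out:
        if not m.needs_review:
            m.excluded = m.event_correlation > threshold
    return out


# ---------------------------------------------------------------------------
# first-level least-squares-all GLM

def _temporal_derivative(reg: np.ndarray, tr: float) -> np.ndarray:
    return np.gradient(reg, tr)


def extend_motion_params(motion: np.ndarray) -> np.ndarray:
    """24-parameter expansion: params, squares, 1-frame lags, lagged squares."""
    m = np.asarray(motion, float)
    lag = np.vstack([np.zeros((1, m.shape[1])), m[:-1]])
    return np.column_stack([m, m**2, lag, lag**2])


def build_lsa_design(
    schedule: ParadigmSchedule,
    motion_params: np.ndarray | None = None,
    extended_motion: bool = True,
    hrf_params: HRFParams | None = None,
):
    """Least-squares-all design for the whole-brain model.

    One regressor per "think" repetition, a combined "count" regressor,
    and (serial) a combined "feedback" regressor; temporal derivatives
    of all regressors of interest; motion confounds; intercept.
    Returns (names, X, interest_names).
    """
    think_blocks = [
        i for i, b in enumerate(schedule.blocks) if b.condition == "think"
    ]
    names: list[str] = []
    cols: list[np.ndarray] = []
    for rep, bi in enumerate(think_blocks, start=1):
        names.append(f"think_{rep:02d}")
        cols.append(
            condition_regressor(schedule, "think", hrf_params=hrf_params, blocks=[bi])
        )
    names.append("count")
    cols.append(condition_regressor(schedule, "count", hrf_params=hrf_params))
    if "feedback_think" in schedule.conditions:
        fb = condition_regressor(
            schedule, "feedback_think", hrf_params=hrf_params
        ) + condition_regressor(schedule, "feedback_count", hrf_params=hrf_params)
        names.append("feedback")
        cols.append(fb)
    interest = list(names)
    for nm in interest:
        names.append(f"{nm}_deriv")
        cols.append(_temporal_derivative(cols[interest.index(nm)], schedule.tr))
    if motion_params is not None:
        mp = extend_motion_params(motion_params) if extended_motion else np.asarray(
            motion_params, float
        )
        for j in range(mp.shape[1]):
            names.append(f"motion_{j:02d}")
            cols.append(mp[:, j])
    names.append("intercept")
    cols.append(np.ones(schedule.n_volumes))
    return names, np.column_stack(cols), interest


def default_contrasts(schedule: ParadigmSchedule, names: list[str]) -> dict[str, np.ndarray]:
    """Contrast vectors: count enters at -1; positive weights sum to 1."""
    think_cols = [n for n in names if n.startswith("think_") and "deriv" not in n]
    contrasts: dict[str, dict[str, float]] = {}
    k = len(think_cols)
    think_w = {n: 1.0 / k for n in think_cols}
    contrasts["think"] = {**think_w, "count": -1.0}
    if "feedback" in names:
        contrasts["feedback"] = {"feedback": 1.0, "count": -1.0}
        overall = {n: 0.5 / k for n in think_cols}
        overall["feedback"] = 0.5
        overall["count"] = -1.0
        contrasts["overall"] = overall
    out = {}
    for cname, wmap in contrasts.items():
        w = np.array([wmap.get(n, 0.0) for n in names])
        out[cname] = w
    return out


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Gaussianize t statistics by matched upper-tail quantiles (sign-symmetric)."""
    t = np.asarray(t, float)
    z = np.empty_like(t)
    pos = t >= 0
    z[pos] = stats.norm.isf(stats.t.sf(t[pos], df))
    z[~pos] = -stats.norm.isf(stats.t.sf(-t[~pos], df))
    return np.clip(z, -Z_CAP, Z_CAP)


@dataclass
class FirstLevelResult:
    names: list[str]
    betas: np.ndarray           # (p, nx, ny, nz)
    copes: dict[str, StatMap]   # contrast effect maps
    zmaps: dict[str, StatMap]
    df: int


def first_level_lsa(
    volume4d: np.ndarray,
    schedule: ParadigmSchedule,
    motion_params: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    extended_motion: bool = True,
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> FirstLevelResult:
    """Voxelwise least-squares-all GLM with the paradigm's contrasts.

    ``volume4d`` is expected to be preprocessed (smoothed/high-passed);
    the model includes its own intercept, so mean removal is harmless.
    """
    vol = np.asarray(volume4d, float)
    if vol.ndim != 4 or vol.shape[-1] != schedule.n_volumes:
        raise ValueError("volume4d must be (x, y, z, n_volumes)")
    names, X, _ = build_lsa_design(
        schedule, motion_params, extended_motion=extended_motion
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient first-level design")
    grid = vol.shape[:3]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    Y = vol[mask].T                       # (n, v)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y                       # (p, v)
    resid = Y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    contrasts = default_contrasts(schedule, names)
    copes, zmaps = {}, {}
    for cname, w in contrasts.items():
        cope = w @ beta
        var = sigma2 * float(w @ xtx_inv @ w)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(var > 0, cope / np.sqrt(var), 0.0)
        z = t_to_z(tval, df)
        cmap = np.zeros(grid)
        zmap = np.zeros(grid)
        cmap[mask] = cope
        zmap[mask] = z
        copes[cname] = StatMap(cmap, mask, voxel_size, "contrast")
        zmaps[cname] = StatMap(zmap, mask, voxel_size, "z")
    beta_vol = np.zeros((X.shape[1],) + grid)
    beta_vol[:, mask] = beta
    return FirstLevelResult(names, beta_vol, copes, zmaps, df)


# ---------------------------------------------------------------------------
# group model and cluster inference

def _one_sample_z(data: np.ndarray) -> np.ndarray:
    """data (n_subjects, v) -> z per voxel via one-sample t.

    Voxels with zero between-subject variance and nonzero mean have
    t -> infinity and are assigned the z cap directly.
    """
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(~degenerate, mean / (sd / np.sqrt(n)), 0.0)
    z = t_to_z(t, n - 1)
    z[degenerate] = np.sign(mean[degenerate]) * Z_CAP
    return z


def group_one_sample(maps: list[StatMap]) -> StatMap:
    """Voxelwise one-sample t across subject contrast maps, Gaussianized to z.

    An ordinary-least-squares group model: the between-subject variance
    is the only variance component (a deliberate simplification of
    mixed-effects group modeling, paired with permutation inference).
    """
    if len(maps) < 3:
        raise ValueError("group model needs at least 3 subject maps")
    for m in maps[1:]:
        _require_same_grid(maps[0], m)
    mask = maps[0].mask.copy()
    data = np.stack([m.values[mask] for m in maps])
    z = np.zeros(mask.shape)
    z[mask] = _one_sample_z(data)
    return StatMap(z, mask, maps[0].voxel_size, "z")


def _cluster_sizes(supra: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    labels, n = ndimage.label(supra, structure=FACE_STRUCTURE)
    if n == 0:
        return labels, 0, np.array([], dtype=int)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels, n, sizes.astype(int)


def _sign_patterns(n_subjects: int, n_perm: int, rng: np.random.Generator):
    """(patterns, exhaustive): all 2^n sign patterns when that is no more
    work than n_perm random draws, else Monte-Carlo draws."""
    if 2**n_subjects <= n_perm:
        pats = [np.array(p) for p in itertools.product((1.0, -1.0), repeat=n_subjects)]
        return pats, True
    return [rng.choice([1.0, -1.0], size=n_subjects) for _ in range(n_perm)], False


def max_cluster_null(
    subject_maps: list[StatMap],
    z_form: float,
    n_perm: int = 1000,
    seed: int = 0,
    subject_maps_b: list[StatMap] | None = None,
) -> np.ndarray:
    """Null distribution of the maximum supra-threshold cluster size
    under sign flipping of subject contrast maps.

    Returns ``(maxima, exhaustive)``.  With two map lists the statistic
    is the voxelwise minimum of the two group z maps (conjunction
    null); groups are flipped independently.  All 2^n sign patterns are
    enumerated whenever that is no more work than ``n_perm`` random
    draws, in which case the corrected p-values are exact.
    """
    rng = np.random.default_rng(seed)
    mask = subject_maps[0].mask
    data_a = np.stack([m.values[mask] for m in subject_maps])
    patterns_a, exhaustive = _sign_patterns(data_a.shape[0], n_perm, rng)
    if subject_maps_b is not None:
        data_b = np.stack([m.values[mask] for m in subject_maps_b])
        patterns_b, exh_b = _sign_patterns(data_b.shape[0], n_perm, rng)
        exhaustive = exhaustive and exh_b
    maxima = []
    for i, signs in enumerate(patterns_a):
        z = _one_sample_z(signs[:, None] * data_a)
        if subject_maps_b is not None:
            zb = _one_sample_z(patterns_b[i % len(patterns_b)][:, None] * data_b)
            z = np.minimum(z, zb)
        supra = np.zeros(mask.shape, dtype=bool)
        supra[mask] = z > z_form
        _, _, sizes = _cluster_sizes(supra)
        maxima.append(sizes.max() if sizes.size else 0)
    return np.asarray(maxima), exhaustive


def cluster_threshold(
    zmap: StatMap,
    z_form: float = 3.1,
    alpha: float = 0.05,
    subject_maps: list[StatMap] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    subject_maps_b: list[StatMap] | None = None,
    extra_mask: np.ndarray | None = None,
) -> tuple[StatMap, pd.DataFrame]:
    """Cluster-forming threshold + cluster-level FWE by sign-flip permutation.

    Returns the thresholded map (non-surviving voxels zeroed) and a
    cluster table (id, size, peak z, peak coordinates, corrected p).
    Without ``subject_maps`` no permutation null is available and all
    supra-threshold clusters are reported with p = NaN.
    """
    if z_form <= 0:
        raise ValueError("cluster-forming threshold must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    mask = zmap.mask.copy()
    if extra_mask is not None:
        mask &= extra_mask
    supra = np.zeros(zmap.values.shape, dtype=bool)
    supra[mask] = zmap.values[mask] > z_form
    labels, n, sizes = _cluster_sizes(supra)
    meta = {"z_form": z_form, "alpha": alpha, "method": "sign-flip max-cluster FWE"}
    out_values = np.zeros_like(zmap.values)
    rows = []
    if n > 0:
        if subject_maps is not None:
            null, exhaustive = max_cluster_null(
                subject_maps, z_form, n_perm, seed, subject_maps_b
            )
            n_null = len(null)
        for cid in range(1, n + 1):
            in_cluster = labels == cid
            size = int(sizes[cid - 1])
            peak_flat = np.argmax(np.where(in_cluster, zmap.values, -np.inf))
            peak = np.unravel_index(peak_flat, zmap.values.shape)
            if subject_maps is not None:
                # the exhaustive enumeration already contains the identity
                # pattern, so no +1 correction is applied there
                if exhaustive:
                    p_corr = float((null >= size).sum() / n_null)
                else:
                    p_corr = float((1 + (null >= size).sum()) / (1 + n_null))
            else:
                p_corr = np.nan
            keep = (p_corr <= alpha) if np.isfinite(p_corr) else True
            rows.append({
                "cluster_id": cid, "size": size,
                "peak_z": float(zmap.values[peak]),
                "peak_x": peak[0], "peak_y": peak[1], "peak_z_coord": peak[2],
                "p_fwe": p_corr, "survives": keep,
            })
            if keep:
                out_values[in_cluster] = zmap.values[in_cluster]
    table = pd.DataFrame(
        rows, columns=["cluster_id", "size", "peak_z", "peak_x", "peak_y",
                       "peak_z_coord", "p_fwe", "survives"],
    )
    thr = StatMap(out_values, mask, zmap.voxel_size, "z", meta)
    return thr, table


def conjunction(
    z1: StatMap,
    z2: StatMap,
    z_form: float = 2.3,
    alpha: float = 0.01,
    subject_maps1: list[StatMap] | None = None,
    subject_maps2: list[StatMap] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[StatMap, pd.DataFrame]:
    """Minimum-statistic conjunction, then cluster thresholding.

    A voxel counts as jointly active only if both z maps exceed the
    cluster-forming threshold there (the min of the two statistics is
    thresholded).
    """
    _require_same_grid(z1, z2)
    mask = z1.mask & z2.mask
    vals = np.zeros_like(z1.values)
    vals[mask] = np.minimum(z1.values[mask], z2.values[mask])
    zmin = StatMap(vals, mask, z1.voxel_size, "z")
    return cluster_threshold(
        zmin, z_form, alpha, subject_maps1, n_perm, seed,
        subject_maps_b=subject_maps2,
    )


def disjunction(
    zmap: StatMap,
    conjunction_map: StatMap,
    z_form: float = 3.1,
    alpha: float = 0.05,
    subject_maps: list[StatMap] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[StatMap, pd.DataFrame]:
    """Exclusively mask out conjunction voxels, then re-threshold."""
    _require_same_grid(zmap, conjunction_map)
    exclusive = ~(conjunction_map.values != 0)
    return cluster_threshold(
        zmap, z_form, alpha, subject_maps, n_perm, seed, extra_mask=exclusive
    )
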