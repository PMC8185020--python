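"""Synthetic neurofeedback data with known ground truth.

Generates ROI time courses, small 4D volumes, motion traces, template
network maps and multi-subject groups that emulate the statistical
structure of a block-design neurofeedback study: condition-locked BOLD
responses through a double-gamma HRF, low-frequency drift, serially
correlated (AR(1)) noise, a multiplicative global fluctuation shared
across regions, and scan-to-scan displacement traces optionally
coupled to the task.

Signal model for a region with baseline intensity ``B``::

    s_t = B * (1 + drift_t + global_t) * (1 + sum_c a_c/100 * (boxcar_c (*) HRF)_t) + e_t

with AR(1) noise ``e`` scaled to ``noise_sd`` percent of baseline.
Because the global term is multiplicative and shared, the online
feedback signal (target PSC minus background PSC) cancels it exactly,
which makes the feedback computation testable against an algebraic
identity.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.signal import lfilter

from .efficiency import (
    HRFParams,
    build_design,
    condition_regressor,
    run_efficiency,
)
from .paradigm import ParadigmSchedule

#: convolution grid for simulated responses (finer than the TR so the
#: simulated hemodynamics are not trivially identical to the analysis
#: regressors sampled at TR resolution)
SIM_DT = 0.2

RUNS_PER_SUBJECT = 18


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth generative parameters for one run.

    Amplitudes are percent of baseline, keyed ``{roi: {condition: amp}}``
    with ROIs ``target`` and ``background``.  ``noise_sd``,
    ``drift_amplitude`` and ``global_sd`` are percent of baseline;
    ``ar1_coef`` is the lag-1 autocorrelation of the noise.
    """

    baseline_intensity: float = 1000.0
    amplitudes: dict = field(
        default_factory=lambda: {"target": {"think": 2.0}, "background": {}}
    )
    noise_sd: float = 0.5
    ar1_coef: float = 0.3
    drift_amplitude: float = 0.5
    global_sd: float = 0.3
    motion_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")
        for name in ("noise_sd", "drift_amplitude", "global_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")

    def with_think_amplitude(self, amp: float) -> "SimulationParams":
        amps = {roi: dict(d) for roi, d in self.amplitudes.items()}
        amps.setdefault("target", {})["think"] = float(amp)
        return replace(self, amplitudes=amps)


@dataclass
class RunData:
    """One simulated (or loaded) neurofeedback run."""

    target_ts: np.ndarray
    background_ts: np.ndarray
    displacement_ts: np.ndarray
    truth: SimulationParams | None = None
    volume4d: np.ndarray | None = None

    @property
    def n_volumes(self) -> int:
        return len(self.target_ts)


@dataclass
class TemplateSet:
    """Spatial weight maps on a common grid (template network set)."""

    maps: list[np.ndarray]
    mask: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        for m in self.maps:
            if m.shape != self.mask.shape:
                raise ValueError("all template maps must share the mask grid")
            if np.var(m[self.mask]) == 0:
                raise ValueError("template map has zero variance within mask")


# ---------------------------------------------------------------------------
# cached clean responses

@functools.lru_cache(maxsize=64)
def _clean_response(schedule: ParadigmSchedule, condition: str) -> np.ndarray:
    """Unit-peak convolved response for one condition, cached.

    The response is normalized to unit peak so that an injected
    amplitude of ``a`` percent produces a peak intensity change of
    exactly ``a`` percent of baseline.  Schedules are frozen/hashable,
    so identical schedules share the convolution work across the many
    runs of a group simulation.
    """
    reg = condition_regressor(schedule, condition, dt=SIM_DT)
    return reg / np.abs(reg).max()


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    w = rng.standard_normal(n) * sd * np.sqrt(1 - phi**2)
    return lfilter([1.0], [1.0, -phi], w)


def _drift(rng: np.random.Generator, n: int, tr: float, amplitude_pct: float,
           period_s: float = 120.0) -> np.ndarray:
    """Slow cosine plus linear trend, peak amplitude ``amplitude_pct`` percent."""
    if amplitude_pct == 0:
        return np.zeros(n)
    t = np.arange(n) * tr
    phase = rng.uniform(0, 2 * np.pi)
    slope = rng.uniform(-1, 1)
    d = 0.5 * np.cos(2 * np.pi * t / period_s + phase) + 0.5 * slope * (2 * t / t[-1] - 1)
    return amplitude_pct / 100.0 * d


def _global_fluctuation(rng: np.random.Generator, n: int, sd_pct: float) -> np.ndarray:
    if sd_pct == 0:
        return np.zeros(n)
    g = gaussian_filter1d(rng.standard_normal(n), sigma=2.0, mode="reflect")
    g = g / g.std() if g.std() > 0 else g
    return sd_pct / 100.0 * g


def _roi_signal(
    schedule: ParadigmSchedule,
    amplitudes: dict[str, float],
    params: SimulationParams,
    rng: np.random.Generator,
    drift: np.ndarray,
    global_fluct: np.ndarray,
) -> np.ndarray:
    n = schedule.n_volumes
    task = np.ones(n)
    for cond, amp in amplitudes.items():
        if amp:
            task = task + amp / 100.0 * _clean_response(schedule, cond)
    clean = params.baseline_intensity * (1.0 + drift + global_fluct) * task
    noise = _ar1_noise(
        rng, n, params.noise_sd / 100.0 * params.baseline_intensity, params.ar1_coef
    )
    return clean + noise


def _displacement(
    schedule: ParadigmSchedule, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    n = schedule.n_volumes
    base = gaussian_filter1d(rng.standard_normal(n), sigma=1.5, mode="reflect")
    sd = base.std()
    if sd > 0:
        base = base / sd
    disp = 0.05 * base
    if params.motion_coupling:
        think = _clean_response(schedule, "think")
        disp = disp + params.motion_coupling * 0.05 * think
    return disp - disp.min()  # displacement is non-negative


def simulate_roi_run(
    schedule: ParadigmSchedule, params: SimulationParams, seed: int | None = None
) -> RunData:
    """Simulate target and background ROI time courses for one run."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    drift = _drift(rng, schedule.n_volumes, schedule.tr, params.drift_amplitude)
    glob = _global_fluctuation(rng, schedule.n_volumes, params.global_sd)
    target = _roi_signal(
        schedule, params.amplitudes.get("target", {}), params, rng, drift, glob
    )
    background = _roi_signal(
        schedule, params.amplitudes.get("background", {}), params, rng, drift, glob
    )
    disp = _displacement(schedule, params, rng)
    return RunData(target, background, disp, truth=params)


def simulate_subject(
    schedule: ParadigmSchedule,
    amplitude_trajectory,
    params: SimulationParams,
    seed: int,
) -> tuple[list[RunData], int]:
    """Simulate the 18 training runs of one subject.

    Per-run target "think" amplitudes follow ``amplitude_trajectory``;
    all other parameters are shared.  Returns the runs and the 1-based
    ground-truth best-run index (argmax amplitude, earliest on ties).
    """
    amps = np.asarray(amplitude_trajectory, float)
    if amps.size != RUNS_PER_SUBJECT:
        raise ValueError(f"expected {RUNS_PER_SUBJECT} amplitudes, got {amps.size}")
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(amps.size)]
    runs = [
        simulate_roi_run(schedule, params.with_think_amplitude(a), seed=s)
        for a, s in zip(amps, run_seeds)
    ]
    truth_index = int(np.argmax(amps)) + 1
    return runs, truth_index


# ---------------------------------------------------------------------------
# group simulation calibrated to target TE distributions

@functools.lru_cache(maxsize=16)
def te_calibration(schedule: ParadigmSchedule) -> float:
    """Noise-free TE produced by a 1% injected think amplitude.

    TE is linear in the injected amplitude (the GLM is linear), so a
    single factor maps a desired TE to the amplitude that produces it.
    """
    params = SimulationParams(
        amplitudes={"target": {"think": 1.0}, "background": {}},
        noise_sd=0.0, drift_amplitude=0.0, global_sd=0.0,
    )
    run = simulate_roi_run(schedule, params, seed=0)
    return run_efficiency(run.target_ts, run.background_ts, schedule).te


@functools.lru_cache(maxsize=16)
def te_estimation_sd(schedule: ParadigmSchedule, noise_sd: float,
                     ar1_coef: float, n_rep: int = 40) -> float:
    """Monte-Carlo SD of the TE estimate at zero amplitude and the given noise."""
    params = SimulationParams(
        amplitudes={"target": {}, "background": {}},
        noise_sd=noise_sd, ar1_coef=ar1_coef,
        drift_amplitude=0.0, global_sd=0.0,
    )
    design = build_design(
        schedule, ["think"] if schedule.name == "parallel" else ["think", "count"]
    )
    tes = []
    for i in range(n_rep):
        run = simulate_roi_run(schedule, params, seed=10_000 + i)
        tes.append(
            run_efficiency(run.target_ts, run.background_ts, schedule, design=design).te
        )
    return float(np.std(tes, ddof=1))


def simulate_group(
    n_parallel: int,
    n_serial: int,
    te_mean_sd: dict[str, tuple[float, float]],
    seed: int,
    params: SimulationParams | None = None,
    margin: float = 1.0,
    spread: float = 1.0,
) -> dict[str, list[tuple[list[RunData], int]]]:
    """Simulate two paradigm groups with target best-run TE distributions.

    The requested mean/SD are treated as *sample* statistics (that is
    what a study table prints): normal draws of the per-subject
    best-run TE are standardized so each group's sample mean and SD
    match the request exactly, with the draw spread deflated by the
    TE estimation SD so the realized (estimated) TEs carry the
    requested spread.  The injected amplitude is the desired TE
    divided by the noise-free calibration factor.  Non-best runs sit
    at least ``margin`` percent (amplitude units) below the best run.
    """
    from .paradigm import get_schedule

    for group, (mu, sd) in te_mean_sd.items():
        if sd < 0:
            raise ValueError(f"negative SD for group {group!r}")
    if min(n_parallel, n_serial) < 2:
        raise ValueError("need at least 2 subjects per group")
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    out: dict[str, list] = {}
    for group, n_subj in (("parallel", n_parallel), ("serial", n_serial)):
        schedule = get_schedule(group)
        mu, sd = te_mean_sd[group]
        k = te_calibration(schedule)
        est_sd = te_estimation_sd(schedule, params.noise_sd, params.ar1_coef)
        draw_sd = np.sqrt(max(sd**2 - est_sd**2, 0.0))
        draws = rng.normal(size=n_subj)
        if draw_sd > 0 and draws.std(ddof=1) > 0:
            te_targets = mu + (draws - draws.mean()) / draws.std(ddof=1) * draw_sd
        else:
            te_targets = np.full(n_subj, mu)
        subjects = []
        for te_target in te_targets:
            best_amp = te_target / k
            best_idx = rng.integers(0, RUNS_PER_SUBJECT)
            others = best_amp - margin - rng.uniform(0, spread, RUNS_PER_SUBJECT - 1)
            traj = np.insert(others, best_idx, best_amp)
            subj_seed = int(rng.integers(0, 2**31))
            subjects.append(simulate_subject(schedule, traj, params, subj_seed))
        out[group] = subjects
    return out


# ---------------------------------------------------------------------------
# volumetric simulation

def simulate_volume_run(
    grid_shape: tuple[int, int, int],
    roi_layout: dict[str, tuple[np.ndarray, dict[str, float]]],
    schedule: ParadigmSchedule,
    params: SimulationParams,
    seed: int | None = None,
    smooth_noise_sigma: float = 0.0,
) -> RunData:
    """Simulate a small 4D volume run.

    ``roi_layout`` maps region names to ``(boolean mask, {condition:
    amplitude_pct})``.  Voxels outside all regions carry baseline-only
    signal.  Noise is voxelwise AR(1), optionally spatially smoothed;
    drift and the global fluctuation are shared by all voxels.
    """
    nx, ny, nz = grid_shape
    n = schedule.n_volumes
    for name, (mask, _) in roi_layout.items():
        if mask.shape != tuple(grid_shape):
            raise ValueError(f"roi_layout region {name!r} outside grid")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    drift = _drift(rng, n, schedule.tr, params.drift_amplitude)
    glob = _global_fluctuation(rng, n, params.global_sd)
    shared = params.baseline_intensity * (1.0 + drift + glob)

    task = np.ones((nx, ny, nz, n))
    for _, (mask, amps) in roi_layout.items():
        factor = np.ones(n)
        for cond, amp in amps.items():
            if amp:
                factor = factor + amp / 100.0 * _clean_response(schedule, cond)
        task[mask] = factor
    vol = task * shared

    if params.noise_sd > 0:
        sd = params.noise_sd / 100.0 * params.baseline_intensity
        w = rng.standard_normal((nx, ny, nz, n)) * sd * np.sqrt(1 - params.ar1_coef**2)
        noise = lfilter([1.0], [1.0, -params.ar1_coef], w, axis=-1)
        if smooth_noise_sigma > 0:
            noise = gaussian_filter(noise, sigma=(smooth_noise_sigma,) * 3 + (0,))
        vol = vol + noise

    if "target" in roi_layout:
        target_ts = vol[roi_layout["target"][0]].mean(axis=0)
    else:
        target_ts = vol.reshape(-1, n).mean(axis=0)
    background_ts = vol.reshape(-1, n).mean(axis=0)
    disp = _displacement(schedule, params, rng)
    return RunData(target_ts, background_ts, disp, truth=params, volume4d=vol)


# ---------------------------------------------------------------------------
# templates and atlases

def make_template_set(
    grid_shape: tuple[int, int, int], n_templates: int, seed: int,
    smooth_sigma: float = 1.5,
) -> TemplateSet:
    """Smooth, approximately decorrelated template weight maps."""
    if n_templates < 2:
        raise ValueError("need at least 2 templates")
    rng = np.random.default_rng(seed)
    mask = np.ones(grid_shape, dtype=bool)
    maps = []
    for _ in range(n_templates):
        m = gaussian_filter(rng.standard_normal(grid_shape), smooth_sigma)
        m = (m - m[mask].mean()) / m[mask].std()
        maps.append(m)
    labels = [f"template_{i:02d}" for i in range(n_templates)]
    return TemplateSet(maps, mask, labels)


def make_probabilistic_atlas(
    grid_shape: tuple[int, int, int], n_regions: int, seed: int,
    width: float = 3.0,
) -> tuple[list[np.ndarray], list[str]]:
    """Partition-style probabilistic atlas: Gaussian bumps normalized so
    region probabilities sum to at most 1 at every voxel."""
    rng = np.random.default_rng(seed)
    coords = np.indices(grid_shape).astype(float)
    bumps = []
    for _ in range(n_regions):
        center = [rng.uniform(0.2 * s, 0.8 * s) for s in grid_shape]
        d2 = sum((coords[i] - center[i]) ** 2 for i in range(3))
        bumps.append(np.exp(-d2 / (2 * width**2)))
    total = np.maximum(sum(bumps), 1.0)
    probs = [b / total for b in bumps]
    labels = [f"region_{i:02d}" for i in range(n_regions)]
    return probs, labels


# ---------------------------------------------------------------------------
# run I/O (TSV time series, NIfTI volumes, JSON manifest)

def save_run(run: RunData, directory: str | Path, name: str = "run") -> Path:
    """Write a run as TSV series (+ optional NIfTI volume) with a manifest."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ts_path = directory / f"{name}_timeseries.tsv"
    header = "frame\ttarget\tbackground\tdisplacement_mm"
    rows = [
        f"{i}\t{t:.10g}\t{b:.10g}\t{d:.10g}"
        for i, (t, b, d) in enumerate(
            zip(run.target_ts, run.background_ts, run.displacement_ts)
        )
    ]
    ts_path.write_text(header + "\n" + "\n".join(rows) + "\n")
    manifest = {
        "name": name,
        "timeseries": ts_path.name,
        "n_volumes": run.n_volumes,
        "truth": None,
    }
    if run.truth is not None:
        manifest["truth"] = {
            "baseline_intensity": run.truth.baseline_intensity,
            "amplitudes": run.truth.amplitudes,
            "noise_sd": run.truth.noise_sd,
            "ar1_coef": run.truth.ar1_coef,
            "drift_amplitude": run.truth.drift_amplitude,
            "global_sd": run.truth.global_sd,
            "motion_coupling": run.truth.motion_coupling,
            "seed": run.truth.seed,
        }
    if run.volume4d is not None:
        vol_path = directory / f"{name}_bold.nii"
        nib.save(nib.Nifti1Image(run.volume4d.astype(np.float32), np.eye(4)), vol_path)
        manifest["volume4d"] = vol_path.name
    man_path = directory / f"{name}_manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return man_path


def load_run(manifest_path: str | Path) -> RunData:
    import nibabel as nib

    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    directory = manifest_path.parent
    rows = (directory / manifest["timeseries"]).read_text().strip().splitlines()[1:]
    cols = np.array([[float(v) for v in r.split("\t")] for r in rows])
    truth = None
    if manifest.get("truth"):
        truth = SimulationParams(**manifest["truth"])
    vol = None
    if manifest.get("volume4d"):
        vol = np.asarray(nib.load(directory / manifest["volume4d"]).dataobj, float)
    return RunData(cols[:, 1], cols[:, 2], cols[:, 3], truth=truth, volume4d=vol)
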