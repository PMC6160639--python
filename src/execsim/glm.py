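"""Design matrices, mass-univariate OLS and executive contrast maps.

The high-pass filter is implemented as a DCT basis inside the design
matrix (so degrees of freedom stay exact) and estimation is plain OLS;
no autoregressive prewhitening is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.ndimage import gaussian_filter
from scipy.special import gammaln
from scipy import stats

from execsim.core import (
    ATTENTION_TASK_CONDITIONS,
    COND_INSTRUCTION,
    NBACK_LEVELS,
    AcquisitionSpec,
    Volume4D,
    shift_event_onsets,
)

logger = logging.getLogger(__name__)

HRF_DURATION_SECONDS = 32.0
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
GROUP_T_CAP = 1e6

# double-gamma parameters: response peaking near 5 s with a late undershoot
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_DISPERSION = 1.0
HRF_UNDERSHOOT_DISPERSION = 1.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0


def _gamma_pdf(t, shape, scale):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp / scale - gammaln(shape) - shape * np.log(scale)
    )
    return out


@lru_cache(maxsize=8)
def _hrf_peak_value(peak_delay, undershoot_delay, dispersion, u_dispersion, ratio):
    grid = np.arange(0.0, HRF_DURATION_SECONDS, 0.001)
    vals = _gamma_pdf(grid, peak_delay / dispersion, dispersion) - ratio * _gamma_pdf(
        grid, undershoot_delay / u_dispersion, u_dispersion
    )
    return float(vals.max())


def canonical_hrf(
    t,
    peak_delay: float = HRF_PEAK_DELAY,
    undershoot_delay: float = HRF_UNDERSHOOT_DELAY,
    dispersion: float = HRF_DISPERSION,
    undershoot_dispersion: float = HRF_UNDERSHOOT_DISPERSION,
    undershoot_ratio: float = HRF_UNDERSHOOT_RATIO,
):
    """Unit-peak double-gamma hemodynamic response at time(s) ``t`` (s)."""
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("the response is only defined for t >= 0")
    vals = _gamma_pdf(t, peak_delay / dispersion, dispersion) - undershoot_ratio * (
        _gamma_pdf(t, undershoot_delay / undershoot_dispersion, undershoot_dispersion)
    )
    vals = vals / _hrf_peak_value(
        peak_delay,
        undershoot_delay,
        dispersion,
        undershoot_dispersion,
        undershoot_ratio,
    )
    return float(vals[0]) if scalar else vals


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def drop_dummies(vol: Volume4D, n_dummy: int, events: pd.DataFrame = None):
    """Remove initial frames; shift event onsets to the retained clock."""
    if n_dummy >= vol.n_frames:
        raise ValueError(
            f"cannot drop {n_dummy} dummy frames from a {vol.n_frames}-frame run"
        )
    out = Volume4D(
        vol.data[..., n_dummy:], vol.affine.copy(), vol.tr_seconds, vol.mask.copy()
    )
    if events is None:
        return out
    return out, shift_event_onsets(events, n_dummy * vol.tr_seconds)


def smooth_gaussian(vol: Volume4D, fwhm_mm: float) -> Volume4D:
    """Per-frame 3D Gaussian smoothing with an mm-specified kernel."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return vol.copy()
    voxel_sizes = np.sqrt((vol.affine[:3, :3] ** 2).sum(axis=0))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_sizes
    out = np.empty_like(vol.data)
    for t in range(vol.n_frames):
        out[..., t] = gaussian_filter(
            vol.data[..., t], sigma=sigma_vox, mode="nearest", truncate=6.0
        )
    return Volume4D(out, vol.affine.copy(), vol.tr_seconds, vol.mask.copy())


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    values: pd.DataFrame  # T x P, columns are labeled regressors
    convolved: dict  # label -> bool

    @property
    def n_frames(self):
        return self.values.shape[0]

    @property
    def labels(self):
        return list(self.values.columns)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def convolve_events(
    onsets, durations, n_frames: int, tr: float, dt: float = 0.1, normalize: bool = True
) -> np.ndarray:
    """HRF-convolved boxcar sampled at frame times (t = i * tr)."""
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    total = n_frames * tr + HRF_DURATION_SECONDS
    n_fine = int(np.ceil(total / dt)) + 1
    fine = np.zeros(n_fine)
    for o, d in zip(onsets, durations):
        i0 = int(round(o / dt))
        i1 = max(i0 + 1, int(round((o + d) / dt)))  # impulses get one bin
        fine[i0:i1] += 1.0
    hrf = canonical_hrf(np.arange(0.0, HRF_DURATION_SECONDS, dt))
    conv = np.convolve(fine, hrf * dt)[:n_fine]
    if normalize:
        # scale so one isolated event of this duration has unit peak
        d0 = max(float(durations[0]), dt) if len(durations) else dt
        single = np.convolve(
            np.ones(int(round(d0 / dt)) or 1), hrf * dt
        )
        peak = single.max()
        if peak > 0:
            conv = conv / peak
    idx = np.round(np.arange(n_frames) * tr / dt).astype(int)
    return conv[idx]


def dct_basis(n_frames: int, tr: float, hp_cutoff_seconds: float) -> np.ndarray:
    """Discrete cosine drift basis up to 1/cutoff Hz (intercept excluded)."""
    order = int(np.floor(2.0 * n_frames * tr / hp_cutoff_seconds))
    n = np.arange(n_frames)
    cols = [
        np.sqrt(2.0 / n_frames) * np.cos(np.pi * (2 * n + 1) * k / (2 * n_frames))
        for k in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_frames, 0))


_SWITCH_SHORT = {"pre_switch": "pre", "post_switch": "post", "nonswitch": "non"}
_MODALITY_SHORT = {"visual": "vis", "auditory": "aud"}


def condition_regressor_name(row) -> str:
    """Regressor label for one trial row, or None for unmodeled rows."""
    cond = row["condition"]
    if cond in ATTENTION_TASK_CONDITIONS:
        suffix = "con" if bool(row["congruent"]) else "inc"
        return f"{cond}|{suffix}"
    if cond in NBACK_LEVELS:
        sw = _SWITCH_SHORT.get(row["switch"], "non")
        mod = _MODALITY_SHORT.get(row["modality"], "vis")
        return f"{cond}|{sw}|{mod}"
    return None


def build_design_matrix(
    events: pd.DataFrame,
    acq,
    motion: np.ndarray = None,
    hp_cutoff_seconds: float = 128.0,
    dt: float = 0.1,
) -> DesignMatrix:
    """Condition + nuisance design sampled at frame times.

    ``events`` must already be on the retained-frame clock (dummies
    dropped).  ``acq`` is either an :class:`AcquisitionSpec` (frames =
    ``n_volumes - n_dummy``) or an ``(n_frames, tr)`` tuple.
    """
    if isinstance(acq, AcquisitionSpec):
        n_frames, tr = acq.n_volumes - acq.n_dummy, acq.tr_seconds
    else:
        n_frames, tr = int(acq[0]), float(acq[1])
    run_seconds = n_frames * tr
    ends = events["onset"].to_numpy(float) + events["duration"].to_numpy(float)
    if len(events) and ends.max() > run_seconds + 1e-9:
        raise ValueError("events extend past the end of the run")

    columns = {}
    convolved = {}

    trial_rows = events[events["task"].isin(["attention", "nback"])]
    names = trial_rows.apply(condition_regressor_name, axis=1) if len(trial_rows) else pd.Series(dtype=object)
    for name in sorted(set(names.dropna())) if len(trial_rows) else []:
        sel = trial_rows[names == name]
        columns[name] = convolve_events(
            sel["onset"].to_numpy(float),
            sel["duration"].to_numpy(float),
            n_frames,
            tr,
            dt=dt,
        )
        convolved[name] = True

    # expected-but-absent condition cells are omitted, not zero-filled
    present_tasks = set(trial_rows["task"]) if len(trial_rows) else set()
    if "nback" in present_tasks:
        for level in NBACK_LEVELS:
            for sw in ("pre", "post", "non"):
                for mod in ("vis", "aud"):
                    label = f"{level}|{sw}|{mod}"
                    if label not in columns:
                        logger.warning("design: no events for %s; column omitted", label)

    if len(trial_rows):
        resp_onsets = (
            trial_rows["onset"].to_numpy(float) + trial_rows["duration"].to_numpy(float)
        )
        columns["response"] = convolve_events(
            resp_onsets, np.zeros(len(resp_onsets)), n_frames, tr, dt=dt
        )
        convolved["response"] = True

    instr = events[events["condition"] == COND_INSTRUCTION]
    if len(instr):
        columns["instruction"] = convolve_events(
            instr["onset"].to_numpy(float),
            instr["duration"].to_numpy(float),
            n_frames,
            tr,
            dt=dt,
        )
        convolved["instruction"] = True

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_frames, 6):
            raise ValueError(
                f"motion table must be (n_frames, 6), got {motion.shape}"
            )
        for i in range(6):
            columns[f"motion_{i + 1}"] = motion[:, i]
            convolved[f"motion_{i + 1}"] = False

    drift = dct_basis(n_frames, tr, hp_cutoff_seconds)
    for k in range(drift.shape[1]):
        columns[f"dct_{k + 1}"] = drift[:, k]
        convolved[f"dct_{k + 1}"] = False

    columns["constant"] = np.ones(n_frames)
    convolved["constant"] = False

    values = pd.DataFrame(columns, index=np.arange(n_frames))
    return DesignMatrix(values=values, convolved=convolved)


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------


@dataclass
class GLMResult:
    betas: np.ndarray  # P x V
    sigma2: np.ndarray  # V
    df: float
    labels: list
    xtx_inv: np.ndarray
    mask: np.ndarray = None
    affine: np.ndarray = None


def _collinear_columns(x: np.ndarray, labels) -> list:
    _, r, piv = scipy.linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    bad = piv[np.flatnonzero(diag <= tol)]
    rank = int((diag > tol).sum())
    bad = list(piv[rank:])
    return sorted(labels[i] for i in bad)


def fit_glm_ols(vol, X: DesignMatrix) -> GLMResult:
    """Per-voxel OLS.  ``vol`` is a Volume4D or a (T, V) data matrix."""
    x = X.matrix()
    t_frames, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        bad = _collinear_columns(x, X.labels)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    mask = affine = None
    if isinstance(vol, Volume4D):
        mask, affine = vol.mask, vol.affine
        y = vol.data[mask].T  # T x V
    else:
        y = np.asarray(vol, dtype=float)
    if y.shape[0] != t_frames:
        raise ValueError("data and design matrix frame counts differ")

    xtx_inv = np.linalg.inv(x.T @ x)
    betas = xtx_inv @ x.T @ y
    resid = y - x @ betas
    df = t_frames - rank
    sigma2 = (resid**2).sum(axis=0) / df
    return GLMResult(
        betas=betas,
        sigma2=sigma2,
        df=float(df),
        labels=X.labels,
        xtx_inv=xtx_inv,
        mask=mask,
        affine=affine,
    )


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------


@dataclass
class ContrastSpec:
    name: str
    weights: pd.Series  # indexed by design-column label

    def vector(self, labels) -> np.ndarray:
        v = np.zeros(len(labels))
        for lab, w in self.weights.items():
            if lab not in labels:
                raise ValueError(f"contrast {self.name}: column {lab!r} not in design")
            v[labels.index(lab)] = w
        return v


@dataclass
class ContrastMap:
    t: np.ndarray  # 3D
    effect: np.ndarray  # 3D
    df: float
    level: str  # "participant" | "group"
    affine: np.ndarray
    mask: np.ndarray
    name: str = None


def _balanced_weights(plus, minus) -> pd.Series:
    w = {}
    for lab in plus:
        w[lab] = 1.0 / len(plus)
    for lab in minus:
        w[lab] = w.get(lab, 0.0) - 1.0 / len(minus)
    return pd.Series(w)


def _match(labels, prefixes=None, level=None, switch=None) -> list:
    out = []
    for lab in labels:
        parts = lab.split("|")
        if prefixes is not None and parts[0] in prefixes:
            out.append(lab)
        elif level is not None and parts[0] in level and len(parts) == 3:
            if parts[1] == switch:
                out.append(lab)
    return out


def make_executive_contrasts(X: DesignMatrix) -> dict:
    """The four executive contrasts, each side equally weighting its columns.

    DivA   : divided attention vs the three distracted conditions
    DistrA : distracted vs undistracted attention
    WM     : 1- and 2-back vs 0-back, nonswitch trials only
    ModSwi : post-switch vs pre-switch trials of the 1- and 2-back levels
    """
    labels = X.labels
    from execsim.core import DISTRACTED_CONDITIONS, UNDISTRACTED_CONDITIONS, COND_DIVIDED

    specs = {}

    def require(name, plus, minus):
        if not plus or not minus:
            raise ValueError(
                f"contrast {name}: missing member columns "
                f"(plus={len(plus)}, minus={len(minus)})"
            )
        specs[name] = ContrastSpec(name=name, weights=_balanced_weights(plus, minus))

    divided = _match(labels, prefixes={COND_DIVIDED})
    distracted = _match(labels, prefixes=set(DISTRACTED_CONDITIONS))
    undistracted = _match(labels, prefixes=set(UNDISTRACTED_CONDITIONS))
    if divided or distracted or undistracted:
        require("DivA", divided, distracted)
        require("DistrA", distracted, undistracted)

    wm_plus = _match(labels, level={"1back", "2back"}, switch="non")
    wm_minus = _match(labels, level={"0back"}, switch="non")
    post = _match(labels, level={"1back", "2back"}, switch="post")
    pre = _match(labels, level={"1back", "2back"}, switch="pre")
    if wm_plus or wm_minus or post or pre:
        require("WM", wm_plus, wm_minus)
        require("ModSwi", post, pre)

    if not specs:
        raise ValueError("no executive contrast is estimable from this design")
    return specs


def contrast_effect_variance(res: GLMResult, spec: ContrastSpec):
    """(effect, variance) per voxel for one contrast."""
    c = spec.vector(res.labels)
    effect = c @ res.betas
    var = res.sigma2 * float(c @ res.xtx_inv @ c)
    return effect, var


def contrast_map_from_runs(run_results, spec: ContrastSpec, name=None) -> ContrastMap:
    """Fixed-effects combination of one contrast across runs."""
    effects, variances, dfs = [], [], []
    mask = affine = None
    for res in run_results:
        if spec.name not in ("",) and any(
            lab not in res.labels for lab in spec.weights.index
        ):
            continue  # contrast not estimable in this run (other task)
        e, v = contrast_effect_variance(res, spec)
        effects.append(e)
        variances.append(v)
        dfs.append(res.df)
        mask, affine = res.mask, res.affine
    if not effects:
        raise ValueError(f"contrast {spec.name} is estimable in no run")
    effect = np.mean(effects, axis=0)
    var = np.sum(variances, axis=0) / len(effects) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, effect / np.sqrt(var), 0.0)
    t3 = np.zeros(mask.shape)
    e3 = np.zeros(mask.shape)
    t3[mask] = t
    e3[mask] = effect
    return ContrastMap(
        t=t3,
        effect=e3,
        df=float(sum(dfs)),
        level="participant",
        affine=affine,
        mask=mask,
        name=name or spec.name,
    )


def group_level_t(maps) -> ContrastMap:
    """Voxelwise one-sample t of participant contrast effects against 0."""
    maps = list(maps)
    if len(maps) < 2:
        raise ValueError("group analysis needs at least 2 participant maps")
    shape = maps[0].effect.shape
    for m in maps[1:]:
        if m.effect.shape != shape or not np.allclose(m.affine, maps[0].affine):
            raise ValueError("participant maps are not on a common grid")
    data = np.stack([m.effect for m in maps], axis=-1)
    n = data.shape[-1]
    mean = data.mean(axis=-1)
    sd = data.std(axis=-1, ddof=1)
    se = sd / np.sqrt(n)
    t = np.zeros(shape)
    nonzero = se > 0
    t[nonzero] = mean[nonzero] / se[nonzero]
    degenerate = (~nonzero) & (mean != 0)
    if degenerate.any():
        logger.warning(
            "group t: %d voxels with zero between-participant variance capped",
            int(degenerate.sum()),
        )
        t[degenerate] = np.sign(mean[degenerate]) * GROUP_T_CAP
    mask = maps[0].mask
    for m in maps[1:]:
        mask = mask & m.mask
    return ContrastMap(
        t=t,
        effect=mean,
        df=float(n - 1),
        level="group",
        affine=maps[0].affine,
        mask=mask,
        name=maps[0].name,
    )


def one_sample_t_pvalue(t: np.ndarray, df: float) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)
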