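"""Design-matrix construction and voxelwise GLM estimation.

Each task is modeled with HRF-convolved condition boxcars plus six motion
nuisance regressors and a constant:

* ``search``  — 11 task regressors per run: four 1-s cue regressors (one
  per target face), four 8-s delay regressors (one per cued face), and
  three 1-s display regressors (valid / invalid / error response).
* ``search_delay_split`` — exploratory variant splitting each 8-s delay
  regressor into two 4-s halves (15 task regressors).
* ``oneback`` — 17 task regressors per run: 1-s sample regressors for the
  four faces and four scene categories, 8-s delay regressors for each, and
  one 1-s regressor for repeat (1-back) events.
* ``localizer`` — six 4-s category block regressors.

The display is on screen for 0.25 s but is modeled with a 1-s boxcar,
matching the modeled durations of the other brief events.

Estimation is ordinary least squares per voxel (no prewhitening), which
keeps the forward model exactly invertible on noiseless data; optional
AR(1) prewhitening is available behind a flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HrfKernel",
    "DesignMatrix",
    "BetaMap",
    "ContrastMap",
    "canonical_hrf",
    "build_design_matrix",
    "fit_glm",
    "contrast",
    "scheme_task_columns",
    "parse_regressor_name",
]

# ---------------------------------------------------------------------------
# hemodynamic response function
# ---------------------------------------------------------------------------

#: SPM-convention double-gamma parameters.
HRF_PEAK_DELAY = 6.0        # s
HRF_UNDERSHOOT_DELAY = 16.0  # s
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_RATIO = 6.0              # peak : undershoot amplitude ratio
HRF_LENGTH = 32.0            # s of modeled response


@dataclass(frozen=True)
class HrfKernel:
    """Sampled canonical HRF, peak normalized to 1."""

    values: np.ndarray
    dt: float               # sampling step, s
    params: dict = field(default_factory=dict)

    @property
    def times(self):
        return np.arange(self.values.size) * self.dt


def canonical_hrf(tr: float, oversampling: int = 16) -> HrfKernel:
    """Double-gamma canonical HRF sampled at ``tr / oversampling``.

    Difference of two gamma densities (peak delay 6 s, undershoot delay
    16 s, unit dispersions, 1/6 undershoot ratio), truncated at 32 s and
    rescaled so the peak value is 1.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if oversampling < 1:
        raise ValueError("oversampling must be >= 1")
    dt = tr / oversampling
    t = np.arange(0.0, HRF_LENGTH + dt / 2, dt)
    h = (stats.gamma.pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP, scale=HRF_PEAK_DISP)
         - stats.gamma.pdf(t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP,
                           scale=HRF_UNDERSHOOT_DISP) / HRF_RATIO)
    h = h / h.max()
    return HrfKernel(values=h, dt=dt, params={
        "peak_delay_s": HRF_PEAK_DELAY,
        "undershoot_delay_s": HRF_UNDERSHOOT_DELAY,
        "peak_dispersion": HRF_PEAK_DISP,
        "undershoot_dispersion": HRF_UNDERSHOOT_DISP,
        "ratio": HRF_RATIO,
        "length_s": HRF_LENGTH,
    })


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _search_columns(split_delay: bool):
    cols = [(f"cue_face{f}", f"cue_face{f}", 1.0, 0.0) for f in range(1, 5)]
    if split_delay:
        for f in range(1, 5):
            cols.append((f"delay1_face{f}", f"delay_face{f}", 4.0, 0.0))
        for f in range(1, 5):
            cols.append((f"delay2_face{f}", f"delay_face{f}", 4.0, 4.0))
    else:
        cols += [(f"delay_face{f}", f"delay_face{f}", 8.0, 0.0) for f in range(1, 5)]
    cols += [("display_valid", "display_valid", 1.0, 0.0),
             ("display_invalid", "display_invalid", 1.0, 0.0),
             ("display_error", "display_error", 1.0, 0.0)]
    return cols


def _oneback_columns():
    cols = [(f"stim_face{f}", f"stim_face{f}", 1.0, 0.0) for f in range(1, 5)]
    cols += [(f"stim_scene{s}", f"stim_scene{s}", 1.0, 0.0) for s in range(1, 5)]
    cols += [(f"obdelay_face{f}", f"obdelay_face{f}", 8.0, 0.0) for f in range(1, 5)]
    cols += [(f"obdelay_scene{s}", f"obdelay_scene{s}", 8.0, 0.0) for s in range(1, 5)]
    cols.append(("repeat", "repeat", 1.0, 0.0))
    return cols


_LOCALIZER_CATEGORIES = ["faces", "houses", "corridors", "cars",
                         "instruments", "scrambled"]


def _localizer_columns():
    return [(f"loc_{c}", f"loc_{c}", 4.0, 0.0) for c in _LOCALIZER_CATEGORIES]


#: scheme -> list of (column name, event trial_type, modeled duration s,
#: onset shift s).  Modeled durations follow the GLM definition, not the
#: on-screen event duration.
_SCHEMES = {
    "search": _search_columns(split_delay=False),
    "search_delay_split": _search_columns(split_delay=True),
    "oneback": _oneback_columns(),
    "localizer": _localizer_columns(),
}

_REGRESSOR_RE = re.compile(
    r"^(cue|delay|delay1|delay2|stim|obdelay)_(face|scene)(\d)$")

#: map column prefix -> pattern-extraction period tag
_PERIOD_OF_PREFIX = {
    "cue": "cue",
    "delay": "delay",
    "delay1": "delay_early",
    "delay2": "delay_late",
    "stim": "stim",
    "obdelay": "oneback_delay",
}


def parse_regressor_name(name: str):
    """Return (period, modality, condition) for a condition regressor,
    or None for display/repeat/nuisance columns."""
    m = _REGRESSOR_RE.match(name)
    if m is None:
        return None
    prefix, modality, cond = m.groups()
    return _PERIOD_OF_PREFIX[prefix], modality, int(cond)


def scheme_task_columns(scheme: str):
    """Task-regressor names of a scheme, in design order."""
    if scheme not in _SCHEMES:
        raise ValueError(
            f"unknown scheme {scheme!r}; expected one of {sorted(_SCHEMES)}")
    return [c[0] for c in _SCHEMES[scheme]]


@dataclass
class DesignMatrix:
    """Scans x regressors matrix with named columns.

    Columns are ordered task regressors, then motion nuisance regressors,
    then the constant.
    """

    matrix: np.ndarray
    names: list
    tr: float
    n_task: int
    n_nuisance: int

    @property
    def n_scans(self):
        return self.matrix.shape[0]

    def column(self, name):
        return self.matrix[:, self.names.index(name)]

    def task_slice(self):
        return self.matrix[:, : self.n_task]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def build_design_matrix(events: pd.DataFrame, n_scans: int, tr: float,
                        motion: np.ndarray | None = None,
                        scheme: str = "search",
                        oversampling: int = 16,
                        hrf: HrfKernel | None = None) -> DesignMatrix:
    """HRF-convolved design matrix for one run.

    Parameters
    ----------
    events : DataFrame with columns ``onset``, ``duration``, ``trial_type``
        (BIDS-style). Only trial types belonging to ``scheme`` are modeled.
    n_scans, tr : scan grid; regressors are sampled at scan onsets
        t = i * tr after convolution on a grid of step tr/oversampling.
    motion : optional (n_scans, 6) array appended as nuisance columns.
        When omitted, no nuisance columns are added.
    scheme : one of ``search``, ``search_delay_split``, ``oneback``,
        ``localizer``.
    """
    cols = _SCHEMES.get(scheme)
    if cols is None:
        raise ValueError(
            f"unknown scheme {scheme!r}; expected one of {sorted(_SCHEMES)}")
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if hrf is None:
        hrf = canonical_hrf(tr, oversampling)
    dt = hrf.dt
    total = n_scans * tr
    if len(events):
        known = {c[1] for c in cols}
        modeled = events[events["trial_type"].isin(known)]
        if len(modeled):
            end = (modeled["onset"] + modeled["duration"]).max()
            if end > total + 1e-9:
                raise ValueError(
                    f"events overrun the scan duration: last event ends at "
                    f"{end:.2f}s but the run is {total:.2f}s")
    n_fine = int(np.ceil(total / dt)) + hrf.values.size
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)

    task = np.zeros((n_scans, len(cols)))
    names = []
    for k, (name, trial_type, dur, shift) in enumerate(cols):
        names.append(name)
        sel = events[events["trial_type"] == trial_type] if len(events) else events
        box = np.zeros(n_fine)
        if len(sel):
            for onset in np.asarray(sel["onset"], dtype=float):
                a = int(np.round((onset + shift) / dt))
                b = int(np.round((onset + shift + dur) / dt))
                box[a:b] = 1.0
            conv = np.convolve(box, hrf.values)[:n_fine]
            task[:, k] = conv[scan_idx]

    parts = [task]
    n_nuis = 0
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_scans, 6):
            raise ValueError(
                f"motion table must be (n_scans, 6); got {motion.shape}")
        parts.append(motion)
        names += [f"motion{j}" for j in range(1, 7)]
        n_nuis = 6
    parts.append(np.ones((n_scans, 1)))
    names.append("constant")
    return DesignMatrix(matrix=np.hstack(parts), names=names, tr=tr,
                        n_task=len(cols), n_nuisance=n_nuis)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

@dataclass
class BetaMap:
    """Voxelwise OLS coefficients for one run.

    ``betas`` is (n_regressors, n_voxels) in design-column order; voxels are
    whatever flattening the caller used (kept consistent by roi extraction).
    """

    betas: np.ndarray
    names: list
    resid_var: np.ndarray
    df: int

    def by_name(self, name):
        return self.betas[self.names.index(name)]


def _ar1_whiten(y, X, rho):
    n = y.shape[0]
    yw = y.copy()
    Xw = X.copy()
    yw[1:] = y[1:] - rho * y[:-1]
    Xw[1:] = X[1:] - rho * X[:-1]
    scale = np.sqrt(1.0 - rho ** 2)
    yw[0] *= scale
    Xw[0] *= scale
    return yw, Xw


def fit_glm(bold: np.ndarray, design: DesignMatrix,
            ar1_rho: float | None = None) -> BetaMap:
    """Ordinary least squares fit of ``design`` to ``bold``.

    ``bold`` is (n_scans, n_voxels) or a 4-D (i, j, k, n_scans) volume,
    which is flattened voxel-major. All-zero design columns (e.g. the
    error-display regressor in an error-free run) are excluded from
    estimation and reported with coefficient 0; genuine collinearity among
    the remaining columns raises with the offending column names.
    """
    if bold.ndim == 4:
        y = bold.reshape(-1, bold.shape[3]).T
    else:
        y = np.asarray(bold, dtype=float)
    X = design.matrix
    if y.shape[0] != X.shape[0]:
        raise ValueError(
            f"bold has {y.shape[0]} scans but design has {X.shape[0]} rows")
    if ar1_rho is not None:
        y, X = _ar1_whiten(y, X, float(ar1_rho))

    nonzero = ~np.all(X == 0.0, axis=0)
    Xa = X[:, nonzero]
    rank = np.linalg.matrix_rank(Xa)
    if rank < Xa.shape[1]:
        # name the columns involved in the dependency via QR pivoting
        from scipy.linalg import qr
        _, r, piv = qr(Xa, pivoting=True)
        bad = np.asarray(design.names)[nonzero][piv[rank:]]
        raise ValueError(
            f"design matrix is rank deficient; collinear columns: {list(bad)}")
    coef, _, _, _ = np.linalg.lstsq(Xa, y, rcond=None)
    betas = np.zeros((X.shape[1], y.shape[1]))
    betas[nonzero] = coef
    resid = y - Xa @ coef
    df = y.shape[0] - rank
    resid_var = (resid ** 2).sum(axis=0) / max(df, 1)
    return BetaMap(betas=betas, names=list(design.names),
                   resid_var=resid_var, df=df)


@dataclass
class ContrastMap:
    values: np.ndarray     # (n_voxels,) contrast of betas
    weights: np.ndarray
    name: str
    df: int = 0
    t_values: np.ndarray | None = None


def contrast(beta_map: BetaMap, weights, name: str = "contrast",
             task_names: list | None = None,
             design: DesignMatrix | None = None) -> ContrastMap:
    """Voxelwise weighted sum of task betas.

    ``weights`` must match the task regressors (optionally restricted to
    ``task_names``); nuisance and constant columns get weight 0. When
    ``design`` is given, voxelwise t statistics are computed as
    c'b / sqrt(c'(X'X)^-1 c * sigma^2) with the run's residual variance.
    """
    weights = np.asarray(weights, dtype=float)
    if task_names is None:
        task_names = [n for n in beta_map.names
                      if n != "constant" and not n.startswith("motion")]
    if weights.size != len(task_names):
        raise ValueError(
            f"{weights.size} weights for {len(task_names)} task regressors")
    full = np.zeros(len(beta_map.names))
    for w, n in zip(weights, task_names):
        full[beta_map.names.index(n)] = w
    values = full @ beta_map.betas
    tvals = None
    if design is not None:
        X = design.matrix
        nz = ~np.all(X == 0.0, axis=0)
        Xa = X[:, nz]
        c = full[nz]
        cvc = float(c @ np.linalg.solve(Xa.T @ Xa, c))
        se = np.sqrt(np.maximum(cvc * beta_map.resid_var, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, values / se, 0.0)
    return ContrastMap(values=values, weights=weights, name=name,
                       df=beta_map.df, t_values=tvals)
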