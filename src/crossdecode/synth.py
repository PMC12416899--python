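"""Synthetic study generator: task designs, ground-truth multivoxel BOLD,
ROI masks and behavior.

The generator emulates the study conditions the analysis was built for:
26 subjects; a cued face-search task of 8 runs x 16 trials (1 s face cue,
8 s blank delay, 0.25 s search display, 8.75 s inter-trial interval; 75%
of trials "scene-valid", i.e. the target appears on its associated scene);
a face/scene 1-back task of 4 runs (1 s sample, 8 s delay); TR 1.5 s on a
3 mm isotropic grid. Four faces are bijectively associated with four scene
categories; the core manipulation is that an informative ROI may carry
*face*-identity patterns or *associated-scene* patterns in the cue or
delay period.

Cross-decodable structure is created by reusing patterns across tasks: the
pattern for face f in the search task's cue (or delay) period is the same
pattern evoked by face f in the 1-back task, and the scene pattern evoked
during the search delay is the pattern of the *associated* scene category,
identical to the one evoked by that scene in the 1-back task. BOLD is the
design matrix times these true betas plus Gaussian noise (optionally
AR(1)), so a noiseless simulation is exactly invertible by the GLM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm as _glm
from .roi import RoiMask, VolumeGeometry

__all__ = [
    "SimConfig",
    "RoiSpec",
    "GroundTruth",
    "make_search_design",
    "make_oneback_design",
    "make_learning_design",
    "make_ground_truth",
    "simulate_bold_run",
    "simulate_subject",
    "simulate_behavior",
    "DEFAULT_ASSOCIATION",
]

EVENT_COLUMNS = ["run", "onset", "duration", "trial_type", "face_id",
                 "scene_category", "validity", "is_repeat"]

#: default face -> associated scene category bijection (faces and scene
#: categories are both coded 1..4; identity pairing without loss of
#: generality, since labels are arbitrary).
DEFAULT_ASSOCIATION = {1: 1, 2: 2, 3: 3, 4: 4}

#: the four cross-classification schemes an ROI can be informative for.
INFORMATIVE_SCHEMES = ("cue_face", "cue_scene", "delay_face", "delay_scene")


@dataclass(frozen=True)
class RoiSpec:
    """Axis-aligned box ROI inside the simulation grid."""

    label: str
    corner: tuple            # (i, j, k) of the low corner
    size: tuple              # voxels per axis

    def mask(self, geometry: VolumeGeometry) -> RoiMask:
        data = np.zeros(geometry.shape, dtype=bool)
        sl = tuple(slice(c, c + s) for c, s in zip(self.corner, self.size))
        hi = [c + s for c, s in zip(self.corner, self.size)]
        if any(h > dim for h, dim in zip(hi, geometry.shape)):
            raise ValueError(
                f"ROI {self.label!r} does not fit inside the grid")
        data[sl] = True
        return RoiMask(data=data, label=self.label, geometry=geometry)


def _default_rois():
    # disjoint boxes in a 16x16x10 grid; labels follow the regions whose
    # roles they emulate (face-selective, scene-selective, frontal, control)
    return (
        RoiSpec("FFA", (2, 2, 2), (3, 3, 3)),
        RoiSpec("PPA", (10, 2, 2), (3, 3, 3)),
        RoiSpec("IFJ", (2, 10, 5), (3, 3, 3)),
        RoiSpec("control", (10, 10, 5), (3, 3, 3)),
    )


def _default_information():
    # which schemes each ROI carries: emulates the study's double
    # dissociation (face identity at the cue in FFA; associated-scene
    # category in the delay in PPA and IFJ; nothing in the control ROI)
    return {
        "FFA": ("cue_face",),
        "PPA": ("delay_scene",),
        "IFJ": ("delay_scene",),
        "control": (),
    }


@dataclass
class SimConfig:
    """Study-level simulation parameters.

    Trial structure, counts, TR and voxel size default to the study
    conditions; grid shape and ROI boxes are desk-scale stand-ins for a
    whole brain. ``amplitude`` scales the informative condition patterns
    (response units, same scale as ``noise_std``); ``dz_behav`` is the
    standardized (Cohen's dz) scene-validity RT effect across subjects.
    """

    n_subjects: int = 26
    search_runs: int = 8
    trials_per_run: int = 16
    valid_fraction: float = 0.75
    oneback_runs: int = 4
    tr: float = 1.5
    grid_shape: tuple = (16, 16, 10)
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    rois: tuple = field(default_factory=_default_rois)
    information: dict = field(default_factory=_default_information)
    association: dict = field(default_factory=lambda: dict(DEFAULT_ASSOCIATION))
    amplitude: float = 2.0
    baseline: float = 100.0
    noise_std: float = 1.0
    ar1: float = 0.0
    oneback_iti: float = 8.75
    dz_behav: float = 0.678
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.valid_fraction <= 1.0:
            raise ValueError("valid_fraction must lie in [0, 1]")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        assoc = self.association
        if sorted(assoc) != [1, 2, 3, 4] or sorted(assoc.values()) != [1, 2, 3, 4]:
            raise ValueError("association must be a bijection on {1..4}")
        for roi, schemes in self.information.items():
            for s in schemes:
                if s not in INFORMATIVE_SCHEMES:
                    raise ValueError(
                        f"unknown information scheme {s!r} for ROI {roi!r}")

    @property
    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(shape=tuple(self.grid_shape),
                              voxel_size=tuple(self.voxel_size_mm))


# ---------------------------------------------------------------------------
# task designs
# ---------------------------------------------------------------------------

#: search-trial event structure, s
SEARCH_CUE_S = 1.0
SEARCH_DELAY_S = 8.0
SEARCH_DISPLAY_S = 0.25
SEARCH_ITI_S = 8.75
SEARCH_TRIAL_S = SEARCH_CUE_S + SEARCH_DELAY_S + SEARCH_DISPLAY_S + SEARCH_ITI_S

ONEBACK_SAMPLE_S = 1.0
ONEBACK_DELAY_S = 8.0


def make_search_design(n_runs: int = 8, trials_per_run: int = 16,
                       valid_fraction: float = 0.75, seed=0,
                       association: dict | None = None) -> pd.DataFrame:
    """Cued face-search task design.

    Per run: ``trials_per_run`` trials, each face cued exactly
    ``trials_per_run / 4`` times, exact valid/invalid counts
    (``trials_per_run * valid_fraction`` must be an integer), order
    pseudorandomized from ``seed``. Each trial emits a cue, a delay and a
    display event (1 / 8 / 0.25 s); the 8.75 s ITI is unmodeled baseline.
    Invalid trials record a scene category different from the cued face's
    associated category.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if trials_per_run % 4 != 0:
        raise ValueError(
            "trials_per_run must be divisible by 4 to counterbalance the "
            "four target faces")
    n_valid_f = trials_per_run * valid_fraction
    if abs(n_valid_f - round(n_valid_f)) > 1e-9:
        raise ValueError(
            f"trials_per_run * valid_fraction = {n_valid_f} is not an "
            f"integer; exact valid/invalid counts are required")
    n_valid = int(round(n_valid_f))
    assoc = dict(DEFAULT_ASSOCIATION) if association is None else association
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(1, n_runs + 1):
        faces = np.repeat(np.arange(1, 5), trials_per_run // 4)
        validity = np.array(["valid"] * n_valid
                            + ["invalid"] * (trials_per_run - n_valid))
        rng.shuffle(faces)
        rng.shuffle(validity)
        t = 0.0
        for face, val in zip(faces, validity):
            if val == "valid":
                scene = assoc[int(face)]
            else:
                others = [s for s in (1, 2, 3, 4) if s != assoc[int(face)]]
                scene = int(rng.choice(others))
            common = dict(run=run, face_id=int(face), scene_category=scene,
                          validity=val, is_repeat=False)
            rows.append(dict(onset=t, duration=SEARCH_CUE_S,
                             trial_type=f"cue_face{face}", **common))
            rows.append(dict(onset=t + SEARCH_CUE_S, duration=SEARCH_DELAY_S,
                             trial_type=f"delay_face{face}", **common))
            rows.append(dict(onset=t + SEARCH_CUE_S + SEARCH_DELAY_S,
                             duration=SEARCH_DISPLAY_S,
                             trial_type=f"display_{val}", **common))
            t += SEARCH_TRIAL_S
    return pd.DataFrame(rows)[EVENT_COLUMNS]


def make_oneback_design(n_runs: int = 4, seed=0,
                        iti: float = SEARCH_ITI_S) -> pd.DataFrame:
    """Face/scene 1-back task design.

    Per run: 4 trials for each of the 4 faces and 4 scene categories plus
    6 repeat (1-back) trials = 38 trials. Repeat trials are flagged
    ``is_repeat`` and modeled by a single repeat regressor; they are never
    decoding samples. Scene repeats use a different exemplar of the same
    category (exemplar indices tracked internally).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(1, n_runs + 1):
        stims = ([("face", f) for f in range(1, 5) for _ in range(4)]
                 + [("scene", s) for s in range(1, 5) for _ in range(4)])
        rng.shuffle(stims)
        # choose 6 positions after which a repeat trial is inserted
        repeat_after = sorted(rng.choice(len(stims), size=6, replace=False))
        seq = []
        used_exemplar = {}
        for k, stim in enumerate(stims):
            seq.append((stim, False))
            if k in repeat_after:
                seq.append((stim, True))
        t = 0.0
        for (modality, cond), is_rep in seq:
            exemplar = used_exemplar.get((modality, cond), 0) + 1
            used_exemplar[(modality, cond)] = exemplar
            common = dict(
                run=run,
                face_id=cond if modality == "face" else None,
                scene_category=cond if modality == "scene" else None,
                validity="n/a", is_repeat=bool(is_rep))
            if is_rep:
                rows.append(dict(onset=t, duration=ONEBACK_SAMPLE_S,
                                 trial_type="repeat", **common))
            else:
                rows.append(dict(onset=t, duration=ONEBACK_SAMPLE_S,
                                 trial_type=f"stim_{modality}{cond}", **common))
                rows.append(dict(onset=t + ONEBACK_SAMPLE_S,
                                 duration=ONEBACK_DELAY_S,
                                 trial_type=f"obdelay_{modality}{cond}",
                                 **common))
            t += ONEBACK_SAMPLE_S + ONEBACK_DELAY_S + iti
    return pd.DataFrame(rows)[EVENT_COLUMNS]


def make_learning_design(seed=0, association: dict | None = None) -> pd.DataFrame:
    """Pre-scan associative learning test: per face, 18 match trials
    (scene = associated category) and 9 nonmatch trials (3 exemplars from
    each of the 3 other categories); 108 trials, pseudorandom order."""
    assoc = dict(DEFAULT_ASSOCIATION) if association is None else association
    rng = np.random.default_rng(seed)
    rows = []
    for face in range(1, 5):
        for _ in range(18):
            rows.append(dict(face_id=face, scene_category=assoc[face],
                             match=True))
        for scene in (s for s in (1, 2, 3, 4) if s != assoc[face]):
            for _ in range(3):
                rows.append(dict(face_id=face, scene_category=scene,
                                 match=False))
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=np.random.RandomState(
        rng.integers(2 ** 31))).reset_index(drop=True)


# ---------------------------------------------------------------------------
# ground truth and forward BOLD model
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Per-ROI condition patterns and their assignment to design columns."""

    geometry: VolumeGeometry
    masks: dict                  # label -> RoiMask
    face_patterns: dict          # label -> (4, n_roi_vox)
    scene_patterns: dict         # label -> (4, n_roi_vox)
    information: dict            # label -> tuple of scheme names
    association: dict            # face -> scene bijection
    amplitude: float
    baseline: float
    seed: int

    def true_betas(self, names) -> np.ndarray:
        """(n_regressors, n_voxels) true coefficient matrix for design
        columns ``names`` (the forward model the GLM inverts)."""
        B = np.zeros((len(names), self.geometry.n_voxels))
        if "constant" in names:
            B[list(names).index("constant")] = self.baseline
        for label, schemes in self.information.items():
            idx = self.masks[label].flat_indices
            fp = self.face_patterns[label]
            sp = self.scene_patterns[label]
            for k, name in enumerate(names):
                parsed = _glm.parse_regressor_name(name)
                if parsed is None:
                    continue
                period, modality, cond = parsed
                add = np.zeros(idx.size)
                if "cue_face" in schemes:
                    if period == "cue" or (period == "stim" and modality == "face"):
                        add += self.amplitude * fp[cond - 1]
                if "cue_scene" in schemes:
                    if period == "cue":
                        add += self.amplitude * sp[self.association[cond] - 1]
                    elif period == "stim" and modality == "scene":
                        add += self.amplitude * sp[cond - 1]
                if "delay_face" in schemes:
                    if (period in ("delay", "delay_early", "delay_late")
                            or (period == "oneback_delay" and modality == "face")):
                        add += self.amplitude * fp[cond - 1]
                if "delay_scene" in schemes:
                    if period in ("delay", "delay_early", "delay_late"):
                        add += self.amplitude * sp[self.association[cond] - 1]
                    elif period == "oneback_delay" and modality == "scene":
                        add += self.amplitude * sp[cond - 1]
                if add.any():
                    B[k, idx] += add
        return B


def make_ground_truth(config: SimConfig, seed=None) -> GroundTruth:
    """Draw fixed random Gaussian condition patterns for every ROI."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    geom = config.geometry
    masks, fpat, spat = {}, {}, {}
    for spec in config.rois:
        m = spec.mask(geom)
        masks[spec.label] = m
        fpat[spec.label] = rng.standard_normal((4, m.n_voxels))
        spat[spec.label] = rng.standard_normal((4, m.n_voxels))
    used = config.seed if seed is None else seed
    return GroundTruth(geometry=geom, masks=masks, face_patterns=fpat,
                       scene_patterns=spat, information=dict(config.information),
                       association=dict(config.association),
                       amplitude=config.amplitude, baseline=config.baseline,
                       seed=int(used) if np.isscalar(used) else -1)


def _n_scans(events: pd.DataFrame, tr: float, tail_s: float = 18.0) -> int:
    end = float((events["onset"] + events["duration"]).max())
    return int(np.ceil((end + tail_s) / tr))


def simulate_bold_run(events: pd.DataFrame, truth: GroundTruth,
                      config: SimConfig, scheme: str, rng) -> tuple:
    """Forward-simulate one run: y = X @ B_true + noise.

    Returns (bold (n_scans, n_voxels), design). Deterministic given the
    rng state; ``noise_std = 0`` gives exactly invertible data.
    """
    n_scans = _n_scans(events, config.tr)
    design = _glm.build_design_matrix(events, n_scans=n_scans, tr=config.tr,
                                      scheme=scheme)
    B = truth.true_betas(design.names)
    y = design.matrix @ B
    if config.noise_std > 0:
        noise = rng.standard_normal(y.shape) * config.noise_std
        if config.ar1:
            rho = config.ar1
            for t in range(1, noise.shape[0]):
                noise[t] += rho * noise[t - 1]
            noise *= np.sqrt(1.0 - rho ** 2)
        y = y + noise
    return y, design


def simulate_subject(config: SimConfig, truth: GroundTruth | None = None,
                     subject_seed=None) -> dict:
    """Simulate all runs of both tasks for one subject.

    Returns a dict with keys ``search`` and ``oneback``, each a list of
    (bold, design, events) per run, plus ``truth``.
    """
    entropy = config.seed if subject_seed is None else subject_seed
    ss = entropy if isinstance(entropy, np.random.SeedSequence) \
        else np.random.SeedSequence(entropy)
    s_truth, s_design, s_noise = ss.spawn(3)
    if truth is None:
        truth = make_ground_truth(config, seed=s_truth)
    rng_noise = np.random.default_rng(s_noise)
    d_search, d_oneback = np.random.default_rng(s_design).integers(
        2 ** 31, size=2)
    search_events = make_search_design(config.search_runs,
                                       config.trials_per_run,
                                       config.valid_fraction, seed=d_search,
                                       association=config.association)
    oneback_events = make_oneback_design(config.oneback_runs, seed=d_oneback,
                                         iti=config.oneback_iti)
    out = {"search": [], "oneback": [], "truth": truth}
    for run in range(1, config.search_runs + 1):
        ev = search_events[search_events["run"] == run]
        out["search"].append(
            simulate_bold_run(ev, truth, config, "search", rng_noise) + (ev,))
    for run in range(1, config.oneback_runs + 1):
        ev = oneback_events[oneback_events["run"] == run]
        out["oneback"].append(
            simulate_bold_run(ev, truth, config, "oneback", rng_noise) + (ev,))
    return out


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

#: behavioral noise model (s): across-subject spread of the validity
#: effect and within-subject trial RT noise.
RT_BASE_MEAN = 0.85
RT_BASE_SD = 0.08
RT_EFFECT_SD = 0.05
RT_TRIAL_SD = 0.15
ACC_VALID = 0.97
ACC_INVALID = 0.90


def simulate_behavior(n_subjects: int, dz_behav: float = 0.678, seed=0,
                      n_valid: int = 96, n_invalid: int = 32) -> pd.DataFrame:
    """Per-trial RT/accuracy tables with a scene-validity effect.

    Each subject's invalid-minus-valid RT difference is drawn so that the
    across-subject standardized effect (Cohen's dz on subject mean
    differences) targets ``dz_behav``: subject effects are Normal with sd
    tau, trial noise adds variance, and the population mean effect is
    dz * sd(total difference). Accuracy is Bernoulli, higher on valid
    trials (independent of dz, which parameterizes RT only).
    """
    if dz_behav < 0:
        raise ValueError("dz_behav must be >= 0")
    import warnings
    if n_subjects < 2:
        warnings.warn("n_subjects < 2: group statistics will be undefined")
    rng = np.random.default_rng(seed)
    # sd of the per-subject mean difference including trial noise
    diff_sd = np.sqrt(RT_EFFECT_SD ** 2
                      + RT_TRIAL_SD ** 2 * (1.0 / n_valid + 1.0 / n_invalid))
    mu_effect = dz_behav * diff_sd
    rows = []
    for subj in range(1, n_subjects + 1):
        base = rng.normal(RT_BASE_MEAN, RT_BASE_SD)
        effect = rng.normal(mu_effect, RT_EFFECT_SD)
        for validity, n, shift, acc in (("valid", n_valid, 0.0, ACC_VALID),
                                        ("invalid", n_invalid, effect,
                                         ACC_INVALID)):
            rt = base + shift + rng.standard_normal(n) * RT_TRIAL_SD
            rt = np.maximum(rt, 0.15)
            correct = rng.random(n) < acc
            for k in range(n):
                rows.append(dict(subject=subj, trial=k + 1, validity=validity,
                                 correct=bool(correct[k]), rt=float(rt[k])))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BIDS-style export
# ---------------------------------------------------------------------------

def write_events_tsv(events: pd.DataFrame, path):
    """Write an events table as a BIDS-style TSV (onset/duration/trial_type
    first, attribute columns after)."""
    cols = ["onset", "duration", "trial_type"] + [
        c for c in events.columns if c not in ("onset", "duration", "trial_type")]
    events[cols].to_csv(path, sep="\t", index=False, na_rep="n/a")
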