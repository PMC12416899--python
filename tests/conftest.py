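"""Shared fixtures: small simulated cohorts and pattern-set builders.

Everything is generated programmatically and seeded; no data files.
"""

import numpy as np
import pytest

import crossdecode as cd
from crossdecode import inference as inf


@pytest.fixture(scope="session")
def identity_label_map():
    return cd.LabelMap({1: 1, 2: 2, 3: 3, 4: 4})


@pytest.fixture(scope="session")
def geom3mm():
    return cd.VolumeGeometry((16, 16, 10), (3.0, 3.0, 3.0))


def make_pattern_cohort(n_subjects, seed, n_runs_train=8, n_runs_test=4,
                        n_voxels=27, signal=0.0, label_map=None):
    """Raw-pattern cohort (no BOLD/GLM): Gaussian noise patterns with an
    optional condition signal shared between train and test."""
    rng = np.random.default_rng(seed)
    lm = label_map or cd.LabelMap({1: 1, 2: 2, 3: 3, 4: 4})
    subjects = []
    for _ in range(n_subjects):
        proto = rng.standard_normal((4, n_voxels)) * signal
        ctr = np.tile([1, 2, 3, 4], n_runs_train)
        rtr = np.repeat(np.arange(1, n_runs_train + 1), 4)
        Xtr = rng.standard_normal((ctr.size, n_voxels)) + proto[ctr - 1]
        cte = np.tile([1, 2, 3, 4], n_runs_test)
        rte = np.repeat(np.arange(1, n_runs_test + 1), 4)
        Xte = rng.standard_normal((cte.size, n_voxels)) + proto[cte - 1]
        tr = cd.PatternSet(Xtr, ctr, rtr, "cue", "face", "roi")
        te = cd.PatternSet(Xte, cte, rte, "stim", "face", "roi")
        subjects.append(inf.SubjectPatterns(tr, te, lm))
    return subjects


def simulate_decoding_cohort(seed, n_subjects=5, amplitude=3.0,
                             information=None, search_runs=4,
                             trials_per_run=8, oneback_runs=2,
                             grid_shape=(10, 10, 6), oneback_iti=2.0,
                             noise_std=1.0):
    """Full-forward-model cohort at desk scale: simulate BOLD, fit GLMs,
    return (per-subject fitted betas, ground truth, SimConfig)."""
    rois = (cd.RoiSpec("FFA", (1, 1, 0), (3, 3, 3)),
            cd.RoiSpec("PPA", (6, 1, 0), (3, 3, 3)),
            cd.RoiSpec("IFJ", (1, 6, 3), (3, 3, 3)),
            cd.RoiSpec("control", (6, 6, 3), (3, 3, 3)))
    info = information if information is not None else {
        "FFA": ("cue_face",), "PPA": ("delay_scene",),
        "IFJ": ("delay_scene",), "control": ()}
    sim = cd.SimConfig(n_subjects=n_subjects, search_runs=search_runs,
                       trials_per_run=trials_per_run,
                       oneback_runs=oneback_runs, grid_shape=grid_shape,
                       rois=rois, information=info, amplitude=amplitude,
                       noise_std=noise_std, oneback_iti=oneback_iti,
                       seed=seed)
    ss = np.random.SeedSequence(seed)
    fitted, truth = [], None
    for child in ss.spawn(n_subjects):
        d = cd.synth.simulate_subject(sim, subject_seed=child)
        truth = d["truth"]
        fitted.append({
            "search": [cd.fit_glm(b, de) for b, de, _ in d["search"]],
            "oneback": [cd.fit_glm(b, de) for b, de, _ in d["oneback"]],
        })
    return fitted, truth, sim


def subjects_for(fitted, truth, roi, scheme, label_map):
    sch = cd.mvpa.get_scheme(scheme)
    out = []
    for f in fitted:
        tr = cd.extract_patterns(f["search"], truth.masks[roi],
                                 sch.train_period, "face")
        te = cd.extract_patterns(f["oneback"], truth.masks[roi],
                                 sch.test_period, sch.test_modality)
        out.append(inf.SubjectPatterns(tr, te, label_map))
    return out


@pytest.fixture(scope="session")
def informative_cohort():
    """Five-subject cohort with cue-face signal in FFA and delay-scene
    signal in PPA/IFJ (the double-dissociation construction)."""
    return simulate_decoding_cohort(seed=202)
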