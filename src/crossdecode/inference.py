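"""Group-level statistics: permutation null distributions for decoding
accuracies, Bonferroni control, t-tests, effect sizes and the power
computation that sets the sample size.

The permutation null re-runs the cross-classification with training-
condition labels shuffled independently per subject *within runs* (so the
chunk structure is respected), and averages the per-subject accuracies
into one group value per iteration. Because the per-voxel normalization
statistics do not depend on the labels, normalization is computed once
and only the train/test stage is repeated — mathematically identical to
re-running the whole chain, and asserted so in the tests. The p-value is
the standard (n + 1) / (N + 1) exceedance proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import mvpa as _mvpa
from . import svm as _svm
from .mvpa import LabelMap, get_scheme
from .roi import PatternSet

__all__ = [
    "SubjectPatterns",
    "NullDistribution",
    "GroupStatResult",
    "observed_group_accuracy",
    "permutation_null",
    "permutation_pvalue",
    "bonferroni",
    "group_ttest_vs_chance",
    "paired_t_cohens_d",
    "power_sample_size",
]


@dataclass
class SubjectPatterns:
    """One subject's train/test material for a given scheme and ROI."""

    train: PatternSet
    test: PatternSet
    label_map: LabelMap | None = None
    subject: int | None = None


@dataclass
class NullDistribution:
    values: np.ndarray           # (n_perm,) group-mean accuracies
    scheme: str
    roi_label: str
    seed: int

    @property
    def n_perm(self):
        return self.values.size


@dataclass
class GroupStatResult:
    mean: float
    p: float
    t: float | None = None
    df: int | None = None
    dz: float | None = None
    p_bonferroni: float | None = None
    family_size: int | None = None
    note: str = ""


def _prepare(subj: SubjectPatterns, scheme, normalization="zscore"):
    """Normalize once and map test labels; returns (Xtr, ctr, runs, Xte, cte)."""
    scheme = get_scheme(scheme)
    tr, te = _mvpa.normalize_patterns(subj.train, subj.test,
                                      method=normalization)
    if scheme.test_modality == "scene":
        if subj.label_map is None:
            raise ValueError("scene schemes require a label map")
        cte = subj.label_map.faces_for_scenes(te.conditions)
    else:
        cte = te.conditions
    return tr.X, tr.conditions, tr.runs, te.X, cte


def observed_group_accuracy(subjects, scheme, cost: float = 1.0,
                            normalization: str = "zscore") -> float:
    """Group-mean cross-classification accuracy over subjects."""
    accs = [_mvpa.decode(s.train, s.test, scheme, label_map=s.label_map,
                         cost=cost, normalization=normalization).accuracy
            for s in subjects]
    return float(np.mean(accs))


def permutation_null(subjects, scheme, n_perm: int = 10000, seed=0,
                     cost: float = 1.0, tol: float = 1e-4,
                     normalization: str = "zscore") -> NullDistribution:
    """Group-level permuted-label null distribution.

    Per iteration, each subject's training labels are shuffled within
    runs, the train->cross-test chain re-run, and the accuracies averaged
    across subjects; subject streams are derived from ``seed`` and paired
    by iteration index.
    """
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for group inference")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    import warnings
    if 1.0 / (n_perm + 1) > 0.05:
        warnings.warn(
            f"n_perm={n_perm} cannot reach p < 0.05 "
            f"(minimum attainable p is {1.0 / (n_perm + 1):.3f})")
    scheme = get_scheme(scheme)
    ss = np.random.SeedSequence(seed)
    acc = np.zeros(n_perm)
    for child, subj in zip(ss.spawn(len(subjects)), subjects):
        Xtr, ctr, runs, Xte, cte = _prepare(subj, scheme, normalization)
        sub_seed = int(child.generate_state(1, np.uint32)[0])
        acc += _svm.permuted_null_accuracies(Xtr, ctr, runs, Xte, cte,
                                             n_perm, sub_seed, C=cost,
                                             tol=tol)
    acc /= len(subjects)
    return NullDistribution(values=acc, scheme=scheme.name,
                            roi_label=subjects[0].train.roi_label,
                            seed=int(seed) if np.isscalar(seed) else -1)


def permutation_pvalue(observed: float, null) -> float:
    """p = (#{null >= observed} + 1) / (N + 1), one-sided (high is
    significant)."""
    values = null.values if isinstance(null, NullDistribution) else \
        np.asarray(null, dtype=float)
    if values.size == 0:
        raise ValueError("empty null distribution")
    return float((np.sum(values >= observed) + 1) / (values.size + 1))


def bonferroni(p_values, family_size: int):
    """Multiply by the family size, cap at 1."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if family_size < p.size:
        raise ValueError(
            f"family_size {family_size} smaller than the number of tests "
            f"{p.size}")
    out = np.minimum(p * family_size, 1.0)
    return float(out) if np.isscalar(p_values) else out


def group_ttest_vs_chance(accuracies, chance: float = 0.5,
                          tails: int = 1) -> GroupStatResult:
    """One-sample t-test of group accuracies against chance.

    One-tailed by default (accuracies above chance are significant), as
    used for decoding maps.
    """
    x = np.asarray(accuracies, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    n = x.size
    sd = x.std(ddof=1)
    mean = x.mean()
    if sd == 0:
        if mean == chance:
            t = 0.0
            p = 0.5 if tails == 1 else 1.0
        else:
            t = np.inf if mean > chance else -np.inf
            p = 0.0 if mean > chance else 1.0
            if tails == 2:
                p = 0.0
        return GroupStatResult(mean=float(mean), p=float(p), t=float(t),
                               df=n - 1, note="zero variance")
    t = (mean - chance) / (sd / np.sqrt(n))
    if tails == 1:
        p = stats.t.sf(t, n - 1)
    else:
        p = 2 * stats.t.sf(abs(t), n - 1)
    return GroupStatResult(mean=float(mean), p=float(p), t=float(t), df=n - 1)


def paired_t_cohens_d(x, y) -> GroupStatResult:
    """Paired t-test with standardized effect dz = mean(d) / sd(d);
    two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with >= 2 values")
    d = x - y
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        return GroupStatResult(mean=float(d.mean()),
                               p=1.0 if d.mean() == 0 else 0.0,
                               t=0.0 if d.mean() == 0 else np.inf
                               * np.sign(d.mean()),
                               df=n - 1, dz=None,
                               note="zero-variance differences; dz undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return GroupStatResult(mean=float(d.mean()), p=float(p), t=float(t),
                           df=n - 1, dz=float(d.mean() / sd))


@dataclass(frozen=True)
class PowerSpec:
    dz: float
    alpha: float = 0.05
    power: float = 0.9
    tails: int = 2

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.dz <= 0:
            raise ValueError("dz must be positive")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


def _t_power(n: int, spec: PowerSpec) -> float:
    df = n - 1
    nc = spec.dz * np.sqrt(n)
    if spec.tails == 2:
        tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
        upper = stats.nct.sf(tcrit, df, nc)          # sf is stable at large nc
        lower = stats.nct.cdf(-tcrit, df, nc)
        if not np.isfinite(lower):                   # vanishing opposite tail
            lower = 0.0
        return float(upper + lower)
    tcrit = stats.t.ppf(1 - spec.alpha, df)
    return float(stats.nct.sf(tcrit, df, nc))


def power_sample_size(spec: PowerSpec, n_max: int = 100000) -> int:
    """Smallest n >= 2 at which the one-sample (paired-difference) t-test
    with noncentrality dz * sqrt(n) reaches the requested power."""
    for n in range(2, n_max + 1):
        if _t_power(n, spec) >= spec.power:
            return n
    raise ValueError(f"required n exceeds {n_max}")
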