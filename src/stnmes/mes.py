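"""Motor Error Score: a patient-specific scalar impairment measure.

A linear SVM is fit in the eight-dimensional metric space to separate a
patient's epochs from a pool of control epochs (subsampled to balance the
classes).  The signed normal distance of an epoch's standardized metric
vector to that hyperplane is the Motor Error Score (MES); the sign is
oriented so that higher MES means more impaired.  Classification quality
is summarized by held-out ROC AUC over 100 Monte Carlo folds with a 2:1
train/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import LinearSVC

from stnmes.behavior import METRICS, MetricMatrix

_SD_FLOOR = 1e-8


@dataclass
class MESModel:
    """A fitted separating hyperplane in standardized metric space."""

    w: np.ndarray  # (8,) metric weights
    b: float
    mean: np.ndarray  # (8,) training means per metric
    sd: np.ndarray  # (8,) training sds per metric (floor-clamped)
    cv_auc: float
    fold_aucs: np.ndarray
    n_folds: int
    split: tuple[int, int]
    metrics: tuple[str, ...] = METRICS

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


@dataclass
class MESeries:
    """Per-epoch Motor Error Scores aligned with a MetricMatrix."""

    times: np.ndarray  # (n, 2) epoch start/end
    mes: np.ndarray  # (n,), NaN where the epoch had missing metrics
    epoch_len: float
    subject_id: str = ""
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.mes.size

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.mes)


@dataclass
class SubtypeLabel:
    tremor_score: float
    pigd_score: float
    ratio: float
    label: str  # "TD" | "nTD" | "indeterminate"


def _standardizer(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    low = sd < _SD_FLOOR
    if low.any():
        warnings.warn(
            "zero-variance metric(s) %s; sd floor-clamped"
            % [METRICS[i] for i in np.where(low)[0]],
            stacklevel=3,
        )
        sd = np.where(low, _SD_FLOOR, sd)
    return mean, sd


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """ROC AUC of a score as a ranking statistic, midrank tie convention.

    Equals the Mann-Whitney U statistic normalized by n_pos * n_neg.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _split_counts(n: int, split: tuple[int, int]) -> int:
    """Number of test items for an a:b train:test split of n items."""
    a, b = split
    n_test = int(round(n * b / (a + b)))
    return min(max(n_test, 1), n - 1)


def fit_mes_model(
    pd_metrics: MetricMatrix,
    control_metrics: MetricMatrix,
    n_folds: int = 100,
    split: tuple[int, int] = (2, 1),
    C: float = 1.0,
    min_epochs: int = 30,
    seed: int = 0,
) -> MESModel:
    """Fit the patient-vs-control hyperplane with Monte Carlo cross-validation.

    Per fold the control pool is re-subsampled without replacement to match
    the patient epoch count, both classes are split 2:1, metrics are
    z-scored by training-fold statistics and a linear maximal-margin
    classifier is fit; held-out AUC is averaged into ``cv_auc``.  The
    returned hyperplane is refit once on the full balanced set (master-seed
    subsample) and oriented so patient epochs score positive.
    """
    x_pd = pd_metrics.complete_values()
    x_ct = control_metrics.complete_values()
    if len(x_pd) < min_epochs or len(x_ct) < min_epochs:
        raise ValueError(
            f"need at least {min_epochs} complete epochs per class; "
            f"got {len(x_pd)} patient / {len(x_ct)} control"
        )
    rng = np.random.default_rng(seed)
    n = len(x_pd)

    def balanced(r: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        if len(x_ct) > n:
            ct = x_ct[r.choice(len(x_ct), size=n, replace=False)]
        else:
            ct = x_ct
        return x_pd, ct

    fold_aucs = np.empty(n_folds)
    for k in range(n_folds):
        xp, xc = balanced(rng)
        te_p = _split_counts(len(xp), split)
        te_c = _split_counts(len(xc), split)
        perm_p = rng.permutation(len(xp))
        perm_c = rng.permutation(len(xc))
        tr = np.vstack([xp[perm_p[te_p:]], xc[perm_c[te_c:]]])
        y_tr = np.r_[np.ones(len(xp) - te_p), np.zeros(len(xc) - te_c)]
        mean, sd = _standardizer(tr)
        clf = LinearSVC(C=C, max_iter=20000)
        clf.fit((tr - mean) / sd, y_tr)
        d_p = clf.decision_function((xp[perm_p[:te_p]] - mean) / sd)
        d_c = clf.decision_function((xc[perm_c[:te_c]] - mean) / sd)
        fold_aucs[k] = _rank_auc(d_p, d_c)

    # Final hyperplane: one refit on the full balanced set.
    xp, xc = balanced(np.random.default_rng(seed))
    full = np.vstack([xp, xc])
    y = np.r_[np.ones(len(xp)), np.zeros(len(xc))]
    mean, sd = _standardizer(full)
    clf = LinearSVC(C=C, max_iter=20000)
    clf.fit((full - mean) / sd, y)
    w = clf.coef_.ravel().astype(float)
    b = float(clf.intercept_[0])
    d = (full - mean) / sd @ w + b
    if d[y == 1].mean() < d[y == 0].mean():  # orient positive toward patient
        w, b = -w, -b
    return MESModel(
        w=w,
        b=b,
        mean=mean,
        sd=sd,
        cv_auc=float(fold_aucs.mean()),
        fold_aucs=fold_aucs,
        n_folds=n_folds,
        split=split,
    )


def score_mes(model: MESModel, metrics: MetricMatrix) -> MESeries:
    """Signed normal distance of each epoch to the hyperplane.

    ``mes = (w . z + b) / ||w||`` with ``z`` the model-standardized metric
    vector; invariant to common rescaling of ``(w, b)``.  Epochs with
    missing cells get NaN.
    """
    if tuple(metrics.values.columns) != tuple(model.metrics):
        raise ValueError("metric columns do not match the fitted model")
    x = metrics.values.to_numpy()
    z = model.standardize(x)
    norm = np.linalg.norm(model.w)
    mes = (z @ model.w + model.b) / norm
    return MESeries(
        times=metrics.epochs,
        mes=mes,
        epoch_len=metrics.epoch_len,
        subject_id=metrics.subject_id,
    )


def mes_discriminability(pd_scores: MESeries, control_scores: MESeries) -> float:
    """ROC AUC of MES ranking patient vs control epochs (midrank ties)."""
    return _rank_auc(
        pd_scores.mes[pd_scores.valid], control_scores.mes[control_scores.valid]
    )


def autocorrelation(x: np.ndarray) -> np.ndarray:
    """Biased normalized autocorrelation of a mean-subtracted series."""
    a = np.asarray(x, dtype=float)
    a = a - a.mean()
    n = a.size
    ac = np.correlate(a, a, mode="full")[n - 1 :]
    if ac[0] <= 0:
        raise ValueError("zero-variance series has no autocorrelation")
    return ac / ac[0]


def mes_autocorr_timescale(
    series: MESeries,
    sigma_mult: float = 3.0,
    baseline_start: float = 30.0,
) -> float:
    """Width (s) of the significant central autocorrelation peak.

    Baseline mean and sd are estimated from lags in [``baseline_start``,
    max lag]; the width is the total span of contiguous lags around zero
    whose autocorrelation exceeds baseline mean + ``sigma_mult`` sd (the
    central run counted on both sides of zero, in units of the epoch
    length).
    """
    dt = series.epoch_len
    mes = series.mes[series.valid]
    if mes.size * dt < 2 * baseline_start:
        raise ValueError("series too short for the autocorrelation baseline")
    ac = autocorrelation(mes)
    k0 = int(np.ceil(baseline_start / dt))
    base = ac[k0:]
    thresh = base.mean() + sigma_mult * base.std(ddof=0)
    above = ac > thresh
    k = 0
    while k + 1 < ac.size and above[k + 1]:
        k += 1
    return float((2 * k + 1) * dt)


def classify_subtype(tremor_score: float, pigd_score: float) -> SubtypeLabel:
    """Tremor-dominant vs non-tremor-dominant by UPDRS sub-score ratio.

    TD iff tremor/PIGD ratio >= 1.5 (only the < 1.5 condition defines nTD;
    the boundary is inclusive).  Zero PIGD with positive tremor is TD;
    both zero is indeterminate.
    """
    if tremor_score < 0 or pigd_score < 0:
        raise ValueError("sub-scores must be non-negative")
    if pigd_score == 0:
        if tremor_score == 0:
            return SubtypeLabel(tremor_score, pigd_score, np.nan, "indeterminate")
        return SubtypeLabel(tremor_score, pigd_score, np.inf, "TD")
    ratio = tremor_score / pigd_score
    return SubtypeLabel(tremor_score, pigd_score, ratio, "TD" if ratio >= 1.5 else "nTD")
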