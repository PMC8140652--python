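"""Support-vector-regression decoding of the Motor Error Score from LFP
band-power features.

Accuracy is the Pearson r between held-out SVR predictions and the
observed MES, averaged over 100 Monte Carlo folds with 2:1 train/test
splits.  Beyond the single-recording decoder the module provides the
band-restricted comparisons (broadband vs canonical bands on shared
folds), shuffle controls, the performance-weighted "generic" decoder and
the cross-subject transfer matrix, and a timescale sweep over epoch
lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from stnmes import behavior as bhv
from stnmes import mes as mes_mod
from stnmes.mes import MESeries
from stnmes.spectral import (
    BandScheme,
    LFPRecording,
    SpectralFeatures,
    build_band_scheme,
    multi_epoch_spectral_features,
    preprocess_lfp,
)
from stnmes.weight_stats import max_normalize, rank_tests

log = logging.getLogger(__name__)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def aligned_xy(
    features: SpectralFeatures | np.ndarray,
    mes: MESeries | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Row-align features and MES, dropping epochs missing on either side."""
    if isinstance(features, SpectralFeatures):
        x = features.values.to_numpy()
        names = features.scheme.feature_names
    else:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        names = tuple(f"f{i}" for i in range(x.shape[1]))
    y = mes.mes if isinstance(mes, MESeries) else np.asarray(mes, dtype=float)
    n = min(len(x), y.size)
    if abs(len(x) - y.size) > 1:
        raise ValueError(
            f"feature epochs ({len(x)}) and MES epochs ({y.size}) do not align"
        )
    x, y = x[:n], y[:n]
    ok = np.isfinite(y) & np.all(np.isfinite(x), axis=1)
    return x[ok], y[ok], names


@dataclass
class DecodingResult:
    """Monte Carlo cross-validated SVR decoding of one recording."""

    kernel: str
    epsilon: float
    C: float
    mean_r: float
    fold_r: np.ndarray  # (n_folds,), NaN for excluded folds
    coefs: np.ndarray | None  # (n_folds, n_features), linear kernel only
    n_folds: int
    split: tuple[int, int]
    seed: int
    feature_names: tuple[str, ...]
    n_epochs: int
    subject_id: str = ""
    extra: dict = field(default_factory=dict)

    def mean_coef(self) -> np.ndarray:
        """Fold-mean linear coefficient vector."""
        if self.coefs is None:
            raise ValueError("coefficients exist only for the linear kernel")
        return np.nanmean(self.coefs, axis=0)


def _fold_splits(n: int, n_folds: int, split: tuple[int, int], seed: int):
    """Deterministic Monte Carlo 2:1 splits; same seed -> same folds."""
    rng = np.random.default_rng(seed)
    n_test = mes_mod._split_counts(n, split)
    for _ in range(n_folds):
        perm = rng.permutation(n)
        yield perm[n_test:], perm[:n_test]


def train_svr_decoder(
    features,
    mes,
    kernel: str = "linear",
    epsilon: float = 0.01,
    C: float = 0.1,
    n_folds: int = 100,
    split: tuple[int, int] = (2, 1),
    min_epochs: int = 30,
    seed: int = 0,
    subject_id: str = "",
) -> DecodingResult:
    """Decode MES from spectral features with Monte Carlo cross-validation.

    Per fold: random 2:1 split; features and target z-scored by training
    statistics; SVR fit (linear or RBF kernel, insensitivity ``epsilon``);
    accuracy is the Pearson r between held-out predictions and observed
    MES.  Folds whose test targets are constant are excluded with a log
    message.  Linear-kernel coefficient vectors are retained per fold (in
    standardized-feature units).

    The default cost ``C = 0.1`` is deliberately conservative: with the
    42-dimensional standardized feature bank and the ~10^2 epochs of a
    single session, C = 1 leaves the fit variance-dominated (held-out
    accuracy drops and coefficient estimates destabilize).
    """
    if kernel not in ("linear", "rbf"):
        raise ValueError("kernel must be 'linear' or 'rbf'")
    x, y, names = aligned_xy(features, mes)
    n = len(y)
    if n < min_epochs:
        raise ValueError(f"need at least {min_epochs} epochs; got {n}")
    fold_r = np.full(n_folds, np.nan)
    coefs = np.full((n_folds, x.shape[1]), np.nan) if kernel == "linear" else None
    for k, (tr, te) in enumerate(_fold_splits(n, n_folds, split, seed)):
        xm, xs = x[tr].mean(axis=0), x[tr].std(axis=0, ddof=0)
        xs = np.where(xs < 1e-12, 1.0, xs)
        ym, ys = y[tr].mean(), y[tr].std(ddof=0)
        if ys < 1e-12 or np.std(y[te]) < 1e-12:
            log.info("fold %d: constant MES; fold excluded", k)
            continue
        model = SVR(kernel=kernel, C=C, epsilon=epsilon)
        model.fit((x[tr] - xm) / xs, (y[tr] - ym) / ys)
        pred = model.predict((x[te] - xm) / xs) * ys + ym
        fold_r[k] = _pearson(pred, y[te])
        if coefs is not None:
            coefs[k] = model.coef_.ravel()
    return DecodingResult(
        kernel=kernel,
        epsilon=epsilon,
        C=C,
        mean_r=float(np.nanmean(fold_r)),
        fold_r=fold_r,
        coefs=coefs,
        n_folds=n_folds,
        split=split,
        seed=seed,
        feature_names=names,
        n_epochs=n,
        subject_id=subject_id,
    )


def band_mes_correlations(
    features: SpectralFeatures,
    mes: MESeries,
    q: float = 0.05,
    min_epochs: int = 20,
) -> pd.DataFrame:
    """Spearman correlation of MES with canonical-band power, BH-corrected.

    Canonical-band power is the mean of the band's seven sub-band
    features per epoch; p-values are corrected across the six bands at
    FDR ``q``.
    """
    from stnmes.weight_stats import bh_correct

    x, y, _ = aligned_xy(features, mes)
    if len(y) < min_epochs:
        raise ValueError(f"need at least {min_epochs} aligned epochs")
    scheme = features.scheme
    rows = []
    for name in scheme.band_names:
        cols = [features.scheme.feature_names.index(c) for c in scheme.band_columns(name)]
        band_power = x[:, cols].mean(axis=1)
        if np.std(band_power) < 1e-12:
            rows.append((name, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(band_power, y)
        rows.append((name, float(rho), float(p)))
    df = pd.DataFrame(rows, columns=["band", "rho", "p"])
    ok = df["p"].notna().to_numpy()
    reject = np.zeros(len(df), dtype=bool)
    adjusted = np.full(len(df), np.nan)
    if ok.any():
        rej, adj = bh_correct(df.loc[ok, "p"].to_numpy(), q=q)
        reject[ok] = rej
        adjusted[ok] = adj
    df["p_adj"] = adjusted
    df["significant"] = reject
    return df


@dataclass
class ShuffleControlResult:
    observed: DecodingResult
    null_mean_r: np.ndarray
    p_mannwhitney: float
    p_empirical: float


def shuffle_control(
    features,
    mes,
    n_shuffles: int = 100,
    seed: int = 0,
    **decoder_kwargs,
) -> ShuffleControlResult:
    """Null decoding distribution from MES-to-epoch shuffles.

    Each shuffle permutes the epoch order of the MES relative to the
    features and reruns the identical Monte Carlo CV decoding (same fold
    seed).  The observed fold accuracies are compared against the null
    mean accuracies by Mann-Whitney U; an add-one empirical p on the
    shuffle means is also reported.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be positive; an empty null is unusable")
    x, y, _ = aligned_xy(features, mes)
    observed = train_svr_decoder(x, y, seed=seed, **decoder_kwargs)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        y_sh = y[rng.permutation(y.size)]
        null[i] = train_svr_decoder(x, y_sh, seed=seed, **decoder_kwargs).mean_r
    obs_folds = observed.fold_r[np.isfinite(observed.fold_r)]
    _, p_mw = rank_tests(obs_folds, null, paired=False, alternative="greater")
    p_emp = (np.sum(null >= observed.mean_r) + 1.0) / (n_shuffles + 1.0)
    return ShuffleControlResult(
        observed=observed,
        null_mean_r=null,
        p_mannwhitney=p_mw,
        p_empirical=float(p_emp),
    )


def band_restricted_decoding(
    features: SpectralFeatures,
    mes,
    band: str,
    seed: int = 0,
    **decoder_kwargs,
) -> DecodingResult:
    """Decode from one canonical band's seven sub-band columns only.

    Uses the same fold seed as a broadband run so the folds pair up.
    """
    cols = features.scheme.band_columns(band)  # raises on unknown band
    x, y, _ = aligned_xy(features, mes)
    idx = [features.scheme.feature_names.index(c) for c in cols]
    res = train_svr_decoder(x[:, idx], y, seed=seed, **decoder_kwargs)
    res.feature_names = tuple(cols)
    return res


@dataclass
class BandComparison:
    band: str
    result: DecodingResult
    paired_diff: np.ndarray  # broadband minus band, per shared fold
    p_wilcoxon: float


def broadband_vs_band(
    features: SpectralFeatures,
    mes,
    seed: int = 0,
    **decoder_kwargs,
) -> tuple[DecodingResult, dict[str, BandComparison]]:
    """Broadband decoding vs each canonical band on identical fold splits.

    Per-band paired fold differences (broadband minus band-restricted)
    are tested with the Wilcoxon signed-rank test.
    """
    broadband = train_svr_decoder(features, mes, seed=seed, **decoder_kwargs)
    out: dict[str, BandComparison] = {}
    for name in features.scheme.band_names:
        res = band_restricted_decoding(features, mes, name, seed=seed, **decoder_kwargs)
        diff = broadband.fold_r - res.fold_r
        ok = np.isfinite(diff)
        if np.allclose(diff[ok], 0.0):
            p = 1.0
        else:
            _, p = rank_tests(
                broadband.fold_r[ok], res.fold_r[ok], paired=True, alternative="greater"
            )
        out[name] = BandComparison(band=name, result=res, paired_diff=diff, p_wilcoxon=p)
    return broadband, out


@dataclass
class GenericModel:
    """Population decoder: performance-weighted mean linear coefficients."""

    coef: np.ndarray
    intercept: float
    feature_names: tuple[str, ...]
    provenance: list[str]


def build_generic_model(
    results: list[DecodingResult],
) -> GenericModel:
    """Average max-normalized linear SVR coefficients across subjects.

    Per recording: fold-mean coefficients, max-normalized.  Per subject:
    accuracy-weighted mean over that subject's recordings with weights
    ``max(mean_r, 0)``.  The generic vector is the unweighted mean over
    subjects; its intercept is 0 because features and MES are
    standardized.
    """
    linear = [r for r in results if r.coefs is not None]
    if not linear:
        raise ValueError("generic model needs linear-kernel results")
    names = linear[0].feature_names
    by_subject: dict[str, list[DecodingResult]] = {}
    for r in linear:
        if r.feature_names != names:
            raise ValueError("feature schemes differ across results")
        by_subject.setdefault(r.subject_id, []).append(r)
    subject_vecs = []
    provenance = []
    for sid, rs in by_subject.items():
        vecs = np.vstack([max_normalize(r.mean_coef()) for r in rs])
        wts = np.array([max(r.mean_r, 0.0) for r in rs])
        if wts.sum() <= 0:
            log.info("subject %s: no recording with positive accuracy; skipped", sid)
            continue
        subject_vecs.append(wts @ vecs / wts.sum())
        provenance.append(sid)
    if not subject_vecs:
        raise ValueError("no subject contributed a usable linear model")
    return GenericModel(
        coef=np.mean(subject_vecs, axis=0),
        intercept=0.0,
        feature_names=names,
        provenance=provenance,
    )


def apply_generic(model: GenericModel, features, mes) -> float:
    """Accuracy (Pearson r) of the generic decoder on one recording.

    Features are z-scored within-recording before the dot product — the
    only frame in which a foreign weight vector is applicable.
    """
    x, y, names = aligned_xy(features, mes)
    if len(names) != model.coef.size:
        raise ValueError("feature dimensionality does not match the generic model")
    xs = x.std(axis=0, ddof=0)
    xs = np.where(xs < 1e-12, 1.0, xs)
    score = (x - x.mean(axis=0)) / xs @ model.coef + model.intercept
    return _pearson(score, y)


@dataclass
class CrossDecodeMatrix:
    subjects: list[str]
    r: np.ndarray  # (s, s); diagonal autologous, off-diagonal homologous
    provenance: np.ndarray  # (s, s) object array of best recording pairs

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.r)

    @property
    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(len(self.subjects), dtype=bool)
        return self.r[mask]


def _fit_full_svr(x, y, kernel, C, epsilon):
    xm, xs = x.mean(axis=0), x.std(axis=0, ddof=0)
    xs = np.where(xs < 1e-12, 1.0, xs)
    ym, ys = y.mean(), y.std(ddof=0)
    model = SVR(kernel=kernel, C=C, epsilon=epsilon)
    model.fit((x - xm) / xs, (y - ym) / ys)
    return model


def cross_decode(
    recordings: dict[str, list[tuple]],
    kernel: str = "linear",
    epsilon: float = 0.01,
    C: float = 0.1,
    n_folds: int = 100,
    seed: int = 0,
) -> CrossDecodeMatrix:
    """Train-on-one, test-on-another decoding across all subject pairs.

    ``recordings`` maps subject id to a list of ``(features, mes)``
    pairs.  Homologous cells fit an SVR on the full training recording
    (within-recording z-scored) and score the test recording; autologous
    cells use held-out Monte Carlo CV accuracy.  Each cell keeps the best
    r over available recording pairs.
    """
    subjects = list(recordings.keys())
    if len(subjects) < 1:
        raise ValueError("cross-decoding needs at least one subject")
    prepared: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    names_ref = None
    for sid, recs in recordings.items():
        prepared[sid] = []
        for feats, mseries in recs:
            x, y, names = aligned_xy(feats, mseries)
            if names_ref is None:
                names_ref = names
            elif names != names_ref:
                raise ValueError("feature schemes differ across subjects")
            prepared[sid].append((x, y))
    s = len(subjects)
    r_mat = np.full((s, s), -np.inf)
    prov = np.empty((s, s), dtype=object)
    for i, si in enumerate(subjects):
        for a, (xi, yi) in enumerate(prepared[si]):
            auto = train_svr_decoder(
                xi, yi, kernel=kernel, epsilon=epsilon, C=C, n_folds=n_folds, seed=seed
            ).mean_r
            if auto > r_mat[i, i]:
                r_mat[i, i] = auto
                prov[i, i] = (a, a)
            model = _fit_full_svr(xi, yi, kernel, C, epsilon)
            xm, xs = xi.mean(axis=0), xi.std(axis=0, ddof=0)
            xs = np.where(xs < 1e-12, 1.0, xs)
            for j, sj in enumerate(subjects):
                if j == i:
                    continue
                for b, (xj, yj) in enumerate(prepared[sj]):
                    xjm, xjs = xj.mean(axis=0), xj.std(axis=0, ddof=0)
                    xjs = np.where(xjs < 1e-12, 1.0, xjs)
                    pred = model.predict((xj - xjm) / xjs)
                    r = _pearson(pred, yj)
                    if np.isfinite(r) and r > r_mat[i, j]:
                        r_mat[i, j] = r
                        prov[i, j] = (a, b)
    return CrossDecodeMatrix(subjects=subjects, r=r_mat, provenance=prov)


def timescale_sweep(
    pd_cursor,
    pd_target,
    control_cursor,
    control_target,
    lfp: LFPRecording,
    epoch_lens=tuple(float(k) for k in range(1, 11)),
    scheme: BandScheme | None = None,
    kernel: str = "linear",
    n_folds: int = 100,
    mes_folds: int = 100,
    min_epochs: int = 30,
    preprocessed: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Decoding accuracy as a function of epoch length.

    For each epoch length the metric matrices, MES model and spectral
    features are recomputed on the shared epoch grid (one filter-bank
    pass serves all lengths) and the standard decoder is run.  Lengths
    with fewer than ``min_epochs`` usable epochs are skipped with a log
    message.
    """
    scheme = scheme or build_band_scheme()
    clean = lfp if preprocessed else preprocess_lfp(lfp)
    pd_inst = bhv.instantaneous_metrics(pd_cursor, pd_target)
    ct_inst = bhv.instantaneous_metrics(control_cursor, control_target)
    feats_by_len = multi_epoch_spectral_features(clean, list(epoch_lens), scheme=scheme)
    rows = []
    for el in epoch_lens:
        pd_mm = bhv.epoch_metrics(pd_inst, el, group="PD")
        ct_mm = bhv.epoch_metrics(ct_inst, el, group="control")
        n_usable = min(pd_mm.complete.sum(), len(feats_by_len[el]))
        if n_usable < min_epochs:
            log.info("epoch length %.3g s: only %d epochs; skipped", el, n_usable)
            continue
        model = mes_mod.fit_mes_model(pd_mm, ct_mm, n_folds=mes_folds, seed=seed)
        mseries = mes_mod.score_mes(model, pd_mm)
        res = train_svr_decoder(
            feats_by_len[el], mseries, kernel=kernel, n_folds=n_folds, seed=seed
        )
        rows.append((el, res.mean_r, res.n_epochs, model.cv_auc))
    return pd.DataFrame(rows, columns=["epoch_len", "mean_r", "n_epochs", "mes_cv_auc"])
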