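"""Recording-level motor-ability distributions and the BIMS maturity score.

A recording is summarized by its motor feature vector: the fraction of
retained (non-carried) frames spent in each fused posture (supine, prone,
side, crawl, sitting, standing), followed by, for each posture, the
fractions of that posture's frames in each fused movement class (still,
proto, elementary, fluent, pivot, roll, transition). Conditional blocks of
postures never observed are zero-filled and flagged unsupported.

The age-normative model fits, for every month-centered age bin between 4
and 16 months, a diagonal-covariance Gaussian over the feature vectors of
recordings within +/-1 month of the bin center (bins with fewer than 3
members absorb the nearest-age recordings until 3; ages above 16 months
pool into the 16-month bin; per-feature standard deviations are floored at
1e-4). A new recording's motor-ability age is the likelihood-weighted
average of the bin centers, and

    BIMS = (predicted_age_months - 4) * 100 / (16 - 4)

rescales it to a bounded 0-100 maturity score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .taxonomy import (
    FUSED_MOVEMENTS,
    FUSED_POSTURES,
    MOVEMENT_FUSE_MAP,
    MOVEMENTS,
    POSTURE_FUSE_MAP,
    POSTURES,
)

AGE_MIN = 4.0
AGE_MAX = 16.0

_POSTURE_TO_FUSED = np.array(
    [FUSED_POSTURES.index(POSTURE_FUSE_MAP[p]) for p in POSTURES])
_MOVEMENT_TO_FUSED = np.array(
    [FUSED_MOVEMENTS.index(MOVEMENT_FUSE_MAP[m]) for m in MOVEMENTS])

N_POST = len(FUSED_POSTURES)
N_MOV = len(FUSED_MOVEMENTS)
N_FEATURES = N_POST + N_POST * N_MOV


def bims_score(predicted_age_months: float) -> float:
    """Rescale a motor-ability age (months) to the bounded [0, 100] score."""
    return (predicted_age_months - AGE_MIN) * 100.0 / (AGE_MAX - AGE_MIN)


@dataclass
class MotorFeatureVector:
    """Posture + posture-conditional movement fractions of one recording."""

    values: np.ndarray          # [N_FEATURES], unsupported blocks zero-filled
    support: np.ndarray         # [N_POST] frames per posture (retained)
    n_retained: int

    def with_nan_unsupported(self) -> np.ndarray:
        """Feature vector with unsupported conditional blocks as NaN (the
        masked representation the normative model consumes)."""
        out = self.values.copy()
        for p in range(N_POST):
            if self.support[p] == 0:
                out[N_POST + p * N_MOV:N_POST + (p + 1) * N_MOV] = np.nan
        return out


def compute_distributions(posture_labels: np.ndarray, movement_labels: np.ndarray,
                          retained: np.ndarray | None = None) -> MotorFeatureVector:
    """Recording-level motor feature vector from per-frame (or per-second)
    hard labels in the full 7/9-class taxonomies.

    ``retained`` masks out frames flagged by carrying detection; fractions
    are over retained, labeled frames only. Left/right categories fuse.
    """
    posture_labels = np.asarray(posture_labels)
    movement_labels = np.asarray(movement_labels)
    if posture_labels.shape != movement_labels.shape:
        raise ValueError("posture/movement label arrays not aligned")
    keep = (posture_labels >= 0) & (movement_labels >= 0)
    if retained is not None:
        keep &= np.asarray(retained, bool)
    if not keep.any():
        raise ValueError("no retained labeled frames")
    p = _POSTURE_TO_FUSED[posture_labels[keep]]
    m = _MOVEMENT_TO_FUSED[movement_labels[keep]]
    n = len(p)

    post_counts = np.bincount(p, minlength=N_POST).astype(float)
    joint = np.zeros((N_POST, N_MOV))
    np.add.at(joint, (p, m), 1.0)

    values = np.zeros(N_FEATURES)
    values[:N_POST] = post_counts / n
    for pi in range(N_POST):
        if post_counts[pi] > 0:
            values[N_POST + pi * N_MOV:N_POST + (pi + 1) * N_MOV] = (
                joint[pi] / post_counts[pi])
    return MotorFeatureVector(values=values, support=post_counts.astype(int),
                              n_retained=n)


# --------------------------------------------------------------------------
# Normative Gaussian bin model
# --------------------------------------------------------------------------

@dataclass
class BinPrediction:
    """Per-bin likelihoods and the weighted-average prediction."""

    log_likelihoods: np.ndarray
    weights: np.ndarray
    predicted: float


class GaussianBinNormativeModel(BaseEstimator, RegressorMixin):
    """Diagonal-Gaussian normative model over binned target values.

    For each bin center, the per-feature mean and SD are estimated from the
    recordings whose target lies within ``window`` of the center (padded to
    ``min_members`` with the nearest-target recordings; ties toward the
    smaller target). Prediction is the likelihood-weighted average of bin
    centers, computed in log space with max-subtraction; the Gaussian
    normalization constants are included, so bins with tighter variances
    weigh more.
    """

    def __init__(self, centers=None, window: float = 1.0, min_members: int = 3,
                 sigma_floor: float = 1e-4, clip_max: float | None = None):
        self.centers = centers
        self.window = window
        self.min_members = min_members
        self.sigma_floor = sigma_floor
        self.clip_max = clip_max

    def _effective_targets(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, float)
        return np.minimum(y, self.clip_max) if self.clip_max is not None else y

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = self._effective_targets(y)
        if X.shape[0] < self.min_members:
            raise ValueError(f"need >= {self.min_members} recordings")
        centers = (np.asarray(self.centers, float) if self.centers is not None
                   else np.arange(np.floor(y.min()), np.ceil(y.max()) + 1))
        self.centers_ = centers
        n_bins, n_feat = len(centers), X.shape[1]
        self.means_ = np.full((n_bins, n_feat), np.nan)
        self.sigmas_ = np.full((n_bins, n_feat), np.nan)
        self.n_members_ = np.zeros(n_bins, int)
        for b, c in enumerate(centers):
            diff = np.abs(y - c)
            members = np.flatnonzero(diff <= self.window + 1e-9)
            if len(members) < self.min_members:
                # absorb nearest-target recordings (ties toward smaller target)
                order = sorted(range(len(y)), key=lambda i: (diff[i], y[i]))
                members = np.array(order[:self.min_members])
            sub = X[members]
            with np.errstate(invalid="ignore"):
                mu = np.nanmean(sub, axis=0)
                sd = np.nanstd(sub, axis=0)
            self.means_[b] = mu
            self.sigmas_[b] = np.maximum(sd, self.sigma_floor)
            self.n_members_[b] = len(members)
        return self

    def predict_one(self, x: np.ndarray) -> BinPrediction:
        x = np.asarray(x, float)
        # features usable in every bin and present in x (keeps bin
        # likelihoods dimensionally comparable)
        valid = np.isfinite(x) & np.all(np.isfinite(self.means_), axis=0)
        if not valid.any():
            raise ValueError("no usable features for prediction")
        xv = x[valid]
        mu = self.means_[:, valid]
        sd = self.sigmas_[:, valid]
        ll = (-0.5 * np.log(2 * np.pi) - np.log(sd)
              - 0.5 * ((xv[None, :] - mu) / sd) ** 2).sum(axis=1)
        if not np.any(np.isfinite(ll)):
            raise ValueError("degenerate model: all likelihoods vanish")
        w = np.exp(ll - ll.max())
        w /= w.sum()
        return BinPrediction(log_likelihoods=ll, weights=w,
                             predicted=float(w @ self.centers_))

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        return np.array([self.predict_one(x).predicted for x in X])


@dataclass
class BIMSPrediction:
    """Motor-ability age prediction with the rescaled BIMS score."""

    log_likelihoods: np.ndarray
    weights: np.ndarray
    predicted_age: float
    bims: float


class AgeNormativeModel(GaussianBinNormativeModel):
    """Age-binned normative model (centers at 1-month steps, 4..16 months;
    recordings older than 16 months pool into the 16-month bin)."""

    def __init__(self, window: float = 1.0, min_members: int = 3,
                 sigma_floor: float = 1e-4):
        super().__init__(centers=np.arange(AGE_MIN, AGE_MAX + 1.0),
                         window=window, min_members=min_members,
                         sigma_floor=sigma_floor, clip_max=AGE_MAX)

    def predict_bims(self, x: np.ndarray) -> BIMSPrediction:
        p = self.predict_one(x)
        return BIMSPrediction(log_likelihoods=p.log_likelihoods,
                              weights=p.weights, predicted_age=p.predicted,
                              bims=bims_score(p.predicted))


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

def loso_evaluate(subjects, ages, X, model_factory=AgeNormativeModel) -> dict:
    """Leave-one-subject-out evaluation of the normative age model.

    For each held-out subject the model is refit without any of that
    subject's recordings. Targets above 16 months evaluate against 16.
    Returns per-recording predictions, Pearson r and MAE (months).
    """
    subjects = list(subjects)
    ages = np.asarray(ages, float)
    X = np.asarray(X, float)
    if len(set(subjects)) < 4:
        raise ValueError("need >= 4 subjects for LOSO evaluation")
    preds = np.empty(len(ages))
    for subj in sorted(set(subjects)):
        test = np.array([s == subj for s in subjects])
        model = model_factory().fit(X[~test], ages[~test])
        preds[test] = model.predict(X[test])
    targets = np.minimum(ages, AGE_MAX)
    if np.var(targets) > 0 and np.var(preds) > 0:
        r, p = stats.pearsonr(targets, preds)
    else:
        r, p = np.nan, np.nan  # degenerate cohort: correlation undefined
    mae = float(np.abs(preds - targets).mean())
    return dict(predictions=preds, targets=targets, pearson_r=float(r),
                pearson_p=float(p), mae=mae)


def length_robustness(recordings: list[dict], model: GaussianBinNormativeModel,
                      lengths_min=tuple(range(10, 101, 10)), n_iter: int = 1000,
                      seed: int = 0, label_rate_hz: float = 1.0) -> dict:
    """Age-prediction error as a function of analyzed segment length.

    ``recordings`` are dicts with per-label-step ``posture``/``movement``
    hard labels, an optional ``retained`` mask, and ``age`` (months). For
    each segment length, ``n_iter`` random-start segments are drawn from
    each recording, the motor distributions recomputed, and the MAE of the
    model's age prediction against the (16-clipped) true age summarized
    with median, IQR and range. Segments longer than a recording are
    skipped with a warning.
    """
    import warnings

    rng = np.random.default_rng(seed)
    out: dict = {}
    # cumulative joint counts for O(1) segment distributions
    prepared = []
    for rec in recordings:
        p = _POSTURE_TO_FUSED[np.asarray(rec["posture"])]
        m = _MOVEMENT_TO_FUSED[np.asarray(rec["movement"])]
        retained = np.asarray(rec.get("retained", np.ones(len(p), bool)), bool)
        joint = np.zeros((len(p), N_POST * N_MOV))
        joint[np.arange(len(p)), p * N_MOV + m] = retained
        cum = np.concatenate([np.zeros((1, N_POST * N_MOV)), np.cumsum(joint, 0)])
        prepared.append((cum, float(rec["age"]), len(p)))

    for length in lengths_min:
        seg_steps = int(round(length * 60 * label_rate_hz))
        errors = []
        for cum, age, n in prepared:
            if seg_steps > n:
                warnings.warn(
                    f"segment of {length} min longer than recording; skipped")
                continue
            starts = rng.integers(0, n - seg_steps + 1, size=n_iter)
            target = min(age, AGE_MAX)
            for s in starts:
                counts = (cum[s + seg_steps] - cum[s]).reshape(N_POST, N_MOV)
                post = counts.sum(axis=1)
                tot = post.sum()
                if tot == 0:
                    continue
                x = np.full(N_FEATURES, np.nan)
                x[:N_POST] = post / tot
                for pi in range(N_POST):
                    if post[pi] > 0:
                        x[N_POST + pi * N_MOV:N_POST + (pi + 1) * N_MOV] = (
                            counts[pi] / post[pi])
                errors.append(abs(model.predict_one(x).predicted - target))
        if errors:
            e = np.asarray(errors)
            q1, med, q3 = np.percentile(e, [25, 50, 75])
            out[length] = dict(median=float(med), iqr=(float(q1), float(q3)),
                               range=(float(e.min()), float(e.max())),
                               mae=float(e.mean()), n=len(e))
    return out


def aims_predict(subjects, scores, X, bin_width: float = 5.0,
                 min_members: int = 3) -> dict:
    """LOSO prediction of a clinical motor score (e.g., AIMS) with the same
    likelihood-weighted normative machinery, using score bins of the given
    width in place of age bins."""
    scores = np.asarray(scores, float)
    X = np.asarray(X, float)
    if len(scores) < min_members:
        raise ValueError(f"need >= {min_members} scored recordings")
    centers = np.arange(scores.min(), scores.max() + bin_width / 2, bin_width)

    def factory():
        return GaussianBinNormativeModel(centers=centers, window=bin_width,
                                         min_members=min_members)

    subjects = list(subjects)
    preds = np.empty(len(scores))
    for subj in sorted(set(subjects)):
        test = np.array([s == subj for s in subjects])
        model = factory().fit(X[~test], scores[~test])
        preds[test] = model.predict(X[test])
    r, p = stats.pearsonr(scores, preds)
    return dict(predictions=preds, pearson_r=float(r), pearson_p=float(p),
                mae=float(np.abs(preds - scores).mean()))
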