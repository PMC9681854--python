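"""Dual random-forest classification of Globothalamea MOTU lifestyle.

Two complementary random forests are trained on MOTUs whose clade category
already determines lifestyle — the four holoplanktonic clades as
"planktonic", Monothalamea + Tubothalamea as "benthic" — and used to
predict the unlabeled Globothalamea MOTUs:

(i)  the *coefficient* model, whose features are exactly the per-MOTU
     logistic-occurrence coefficients (beta0, beta1);
(ii) the *profile* model, fed the station presence/absence vector directly.

Only MOTUs occurring in at least ``min_stations`` stations (default 5)
enter either set. A Globothalamea MOTU is called "putative planktonic" only
when both models vote planktonic — the consensus rule that controls false
positives; both-benthic yields "benthic", disagreement "unresolved".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .occurrence import LogisticFit, StationPresence
from .types import (
    Assignment,
    LIFESTYLE_BENTHIC,
    LIFESTYLE_PLANKTONIC,
    TARGET_CATEGORY,
    lifestyle_of,
)

DEFAULT_MIN_STATIONS = 5
DEFAULT_N_TREES = 500

CONSENSUS_PLANKTONIC = "putative_planktonic"
CONSENSUS_BENTHIC = "benthic"
CONSENSUS_UNRESOLVED = "unresolved"


@dataclass
class FeatureSet:
    """Aligned features for a set of MOTUs (training or prediction)."""

    motu_ids: list[str]
    station_ids: list[str]
    coeff_features: np.ndarray  # (n, 2): beta0, beta1; NaN if not estimable
    profile_features: np.ndarray  # (n, n_stations) binary
    coeff_ok: np.ndarray  # bool per MOTU: coefficients usable
    labels: np.ndarray | None = None  # lifestyle strings, training only

    def __len__(self) -> int:
        return len(self.motu_ids)


@dataclass
class ModelReport:
    """Cross-validated performance of one model."""

    model_id: str  # "coeff" | "profile"
    accuracy: float
    f1: float
    positive_class: str
    scheme: str
    seed: int


@dataclass(frozen=True)
class LifestyleCall:
    """Both model votes and the consensus for one Globothalamea MOTU."""

    motu_id: str
    pred_coeff: str | None
    pred_profile: str | None
    consensus: str

    def __post_init__(self) -> None:
        both_p = self.pred_coeff == self.pred_profile == LIFESTYLE_PLANKTONIC
        both_b = self.pred_coeff == self.pred_profile == LIFESTYLE_BENTHIC
        expected = (
            CONSENSUS_PLANKTONIC if both_p
            else CONSENSUS_BENTHIC if both_b
            else CONSENSUS_UNRESOLVED
        )
        if self.consensus != expected:
            raise ValueError(
                f"{self.motu_id}: consensus {self.consensus!r} inconsistent "
                f"with votes ({self.pred_coeff}, {self.pred_profile})"
            )


def build_training(
    assignments: Sequence[Assignment],
    presence: StationPresence,
    fits: Sequence[LogisticFit],
    min_stations: int = DEFAULT_MIN_STATIONS,
) -> tuple[FeatureSet, FeatureSet]:
    """Split assigned MOTUs into the labeled training set and the
    Globothalamea prediction set, applying the station filter.

    MOTUs with non-estimable logistic fits keep their profile features but
    are flagged unusable for the coefficient model.
    """
    fit_by_id = {f.motu_id: f for f in fits}
    midx = {m: i for i, m in enumerate(presence.motu_ids)}
    n_present = presence.n_stations_present

    def collect(ids: list[str], labels: list[str] | None) -> FeatureSet:
        coeff = np.full((len(ids), 2), np.nan)
        ok = np.zeros(len(ids), dtype=bool)
        prof = np.zeros((len(ids), len(presence.station_ids)), dtype=np.int8)
        for k, m in enumerate(ids):
            prof[k] = presence.presence[midx[m]]
            f = fit_by_id.get(m)
            if f is not None and f.estimable and f.converged:
                coeff[k] = (f.beta0, f.beta1)
                ok[k] = True
        return FeatureSet(
            motu_ids=ids, station_ids=list(presence.station_ids),
            coeff_features=coeff, profile_features=prof, coeff_ok=ok,
            labels=np.array(labels) if labels is not None else None,
        )

    train_ids: list[str] = []
    train_labels: list[str] = []
    predict_ids: list[str] = []
    for a in assignments:
        if not a.assigned or a.motu_id not in midx:
            continue
        if n_present[midx[a.motu_id]] < min_stations:
            continue
        if a.clade_category == TARGET_CATEGORY:
            predict_ids.append(a.motu_id)
        else:
            label = lifestyle_of(a.clade_category)
            if label is not None:
                train_ids.append(a.motu_id)
                train_labels.append(label)
    for cls in (LIFESTYLE_PLANKTONIC, LIFESTYLE_BENTHIC):
        if train_labels.count(cls) == 0:
            raise ValueError(f"cannot train: no {cls!r} MOTUs pass the filter")
    return collect(train_ids, train_labels), collect(predict_ids, None)


def _features_of(fs: FeatureSet, model_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and usable-row mask for one of the two models."""
    if model_id == "coeff":
        return fs.coeff_features, fs.coeff_ok
    if model_id == "profile":
        return fs.profile_features, np.ones(len(fs), dtype=bool)
    raise ValueError(f"unknown model id {model_id!r}")


def train_model(
    features: np.ndarray,
    labels: Sequence[str],
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit a random forest; deterministic given the seed.

    Requires at least two examples of each class.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


def evaluate(
    features: np.ndarray,
    labels: Sequence[str],
    model_id: str,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    n_splits: int = 5,
    n_repeats: int = 10,
    positive_class: str = LIFESTYLE_BENTHIC,
) -> ModelReport:
    """Stratified k-fold cross-validation repeated ``n_repeats`` times.

    Reports mean accuracy and mean F1 with the minority (benthic) class as
    the positive class by default.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_splits:
        raise ValueError(
            f"stratification error: smallest class ({counts.min()}) < "
            f"{n_splits} folds"
        )
    cv = RepeatedStratifiedKFold(
        n_splits=n_splits, n_repeats=n_repeats, random_state=seed
    )
    accs, f1s = [], []
    for k, (tr, te) in enumerate(cv.split(X, y)):
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + k + 1, n_jobs=1
        )
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        accs.append(accuracy_score(y[te], pred))
        f1s.append(f1_score(y[te], pred, pos_label=positive_class, zero_division=0))
    return ModelReport(
        model_id=model_id,
        accuracy=float(np.mean(accs)),
        f1=float(np.mean(f1s)),
        positive_class=positive_class,
        scheme=f"stratified {n_splits}-fold CV x {n_repeats} repeats",
        seed=seed,
    )


@dataclass
class ConsensusResult:
    calls: list[LifestyleCall]
    #: agreement among MOTUs where both models produced a vote
    agreement_rate: float
    #: agreement with the full prediction set as denominator
    agreement_rate_all: float

    @property
    def putative_planktonic_ids(self) -> list[str]:
        return [c.motu_id for c in self.calls if c.consensus == CONSENSUS_PLANKTONIC]


def predict_consensus(
    model_coeff: RandomForestClassifier,
    model_profile: RandomForestClassifier,
    prediction_set: FeatureSet,
) -> ConsensusResult:
    """Vote both models over the Globothalamea prediction set.

    MOTUs lacking coefficient features get no coeff vote and are
    unresolved. The consensus set is by construction a subset of each
    model's planktonic-predicted set.
    """
    n = len(prediction_set)
    coeff_votes: list[str | None] = [None] * n
    ok = prediction_set.coeff_ok
    if ok.any():
        preds = model_coeff.predict(prediction_set.coeff_features[ok])
        for k, v in zip(np.flatnonzero(ok), preds):
            coeff_votes[k] = str(v)
    profile_votes = [str(v) for v in model_profile.predict(prediction_set.profile_features)]
    calls = []
    n_agree = 0
    n_both = 0
    for k, m in enumerate(prediction_set.motu_ids):
        pc, pp = coeff_votes[k], profile_votes[k]
        if pc is not None:
            n_both += 1
            if pc == pp:
                n_agree += 1
        if pc == pp == LIFESTYLE_PLANKTONIC:
            consensus = CONSENSUS_PLANKTONIC
        elif pc == pp == LIFESTYLE_BENTHIC:
            consensus = CONSENSUS_BENTHIC
        else:
            consensus = CONSENSUS_UNRESOLVED
        calls.append(
            LifestyleCall(motu_id=m, pred_coeff=pc, pred_profile=pp, consensus=consensus)
        )
    return ConsensusResult(
        calls=calls,
        agreement_rate=n_agree / n_both if n_both else float("nan"),
        agreement_rate_all=n_agree / n if n else float("nan"),
    )


def classify_lifestyles(
    assignments: Sequence[Assignment],
    presence: StationPresence,
    fits: Sequence[LogisticFit],
    min_stations: int = DEFAULT_MIN_STATIONS,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    evaluate_models: bool = True,
) -> tuple[ConsensusResult, list[ModelReport], FeatureSet, FeatureSet]:
    """End-to-end classify stage: build sets, train, evaluate, vote."""
    training, prediction = build_training(assignments, presence, fits, min_stations)
    reports = []
    models = {}
    for model_id in ("coeff", "profile"):
        X, ok = _features_of(training, model_id)
        y = training.labels[ok]
        models[model_id] = train_model(X[ok], y, n_trees=n_trees, seed=seed)
        if evaluate_models:
            reports.append(
                evaluate(X[ok], y, model_id, n_trees=n_trees, seed=seed)
            )
    consensus = predict_consensus(models["coeff"], models["profile"], prediction)
    return consensus, reports, training, prediction
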