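"""Station-level presence/absence and per-MOTU logistic distance-decay fits.

Each MOTU's probability of occurrence is modeled against the station's
distance to coast with a binomial GLM, logit P(present) = beta0 + beta1 * d
(distance in raw km, so beta1 is the change in log-odds per km). A
two-sided Wald test on beta1 at alpha = 0.05 calls the trend increasing,
decreasing, or constant. Complete separation or non-convergence triggers a
ridge-penalized refit (lambda = 1e-4) so rare MOTUs with clustered
occurrences are flagged rather than dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from .types import Assignment, FormatError, OccurrenceTable, SampleRecord

TREND_INCREASING = "increasing"
TREND_DECREASING = "decreasing"
TREND_CONSTANT = "constant"

RIDGE_LAMBDA = 1e-4
#: |log-odds| beyond this the ML fit is treated as separated/diverged
_SEPARATION_LIMIT = 30.0


@dataclass
class StationPresence:
    """MOTU x station presence with the distance covariate."""

    motu_ids: list[str]
    station_ids: list[str]
    presence: np.ndarray  # binary, motus x stations
    station_distance: np.ndarray  # km, aligned to station_ids

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=np.int8)
        assert set(np.unique(self.presence)) <= {0, 1}
        assert self.presence.shape == (len(self.motu_ids), len(self.station_ids))

    @property
    def n_stations_present(self) -> np.ndarray:
        return self.presence.sum(axis=1)

    def row(self, motu_id: str) -> np.ndarray:
        return self.presence[self.motu_ids.index(motu_id)]


def station_presence(
    occurrence: OccurrenceTable, metadata: Sequence[SampleRecord]
) -> StationPresence:
    """Collapse samples to stations: present iff summed reads >= 1.

    Stations are ordered by sorted id so the result is invariant to sample
    order; a station's samples must agree on distance_to_coast.
    """
    meta = {r.sample_id: r for r in metadata}
    missing = [s for s in occurrence.sample_ids if s not in meta]
    if missing:
        raise FormatError(f"samples without metadata: {missing}")
    station_ids = sorted({meta[s].station_id for s in occurrence.sample_ids})
    st_index = {s: i for i, s in enumerate(station_ids)}
    dist = np.full(len(station_ids), np.nan)
    for s in occurrence.sample_ids:
        rec = meta[s]
        i = st_index[rec.station_id]
        if np.isnan(dist[i]):
            dist[i] = rec.distance_to_coast
        elif dist[i] != rec.distance_to_coast:
            raise FormatError(
                f"station {rec.station_id!r}: conflicting distances "
                f"{dist[i]} vs {rec.distance_to_coast}"
            )
    agg = np.zeros((len(occurrence.motu_ids), len(station_ids)), dtype=np.int64)
    for j, s in enumerate(occurrence.sample_ids):
        agg[:, st_index[meta[s].station_id]] += occurrence.counts[:, j]
    return StationPresence(
        motu_ids=list(occurrence.motu_ids),
        station_ids=station_ids,
        presence=(agg >= 1).astype(np.int8),
        station_distance=dist,
    )


@dataclass(frozen=True)
class LogisticFit:
    """Per-MOTU logistic occurrence fit against distance to coast."""

    motu_id: str
    beta0: float
    beta1: float
    se_beta1: float
    converged: bool
    estimable: bool
    penalized: bool
    trend: str | None

    def predict(self, distance_km) -> np.ndarray:
        """Fitted occurrence probability at the given distance(s)."""
        return expit(self.beta0 + self.beta1 * np.asarray(distance_km, dtype=float))


def _ridge_logistic(
    y: np.ndarray, d: np.ndarray, lam: float = RIDGE_LAMBDA, maxiter: int = 200
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson logistic fit with an L2 penalty on both coefficients.

    Standard errors come from the inverse penalized Hessian. Used when the
    unpenalized ML fit separates or fails to converge.
    """
    X = np.column_stack([np.ones_like(d), d])
    beta = np.zeros(2)
    converged = False
    for _ in range(maxiter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu) - lam * beta
        H = (X * w[:, None]).T @ X + lam * np.eye(2)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            converged = True
            break
    eta = X @ beta
    mu = expit(eta)
    w = mu * (1 - mu)
    H = (X * w[:, None]).T @ X + lam * np.eye(2)
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se, converged


def _wald_trend(beta1: float, se: float, alpha: float) -> str:
    if not np.isfinite(se) or se <= 0:
        return TREND_CONSTANT
    z = beta1 / se
    p = 2 * norm.sf(abs(z))
    if p < alpha:
        return TREND_INCREASING if beta1 > 0 else TREND_DECREASING
    return TREND_CONSTANT


def fit_logistic(
    presence_row: np.ndarray,
    distances: np.ndarray,
    motu_id: str = "motu",
    alpha: float = 0.05,
) -> LogisticFit:
    """Maximum-likelihood fit of logit P(present) = beta0 + beta1 * d.

    All-present / all-absent rows return a degenerate, non-estimable fit
    (fitted probability ~1 or ~0 everywhere, trend "constant") rather than
    raising. Separation or non-convergence triggers the ridge refit.
    """
    y = np.asarray(presence_row, dtype=float)
    d = np.asarray(distances, dtype=float)
    if len(y) != len(d) or len(y) < 2:
        raise ValueError("need presence and distance vectors of equal length >= 2")
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    if y.min() == y.max():
        # degenerate: no variation to regress on
        b0 = _SEPARATION_LIMIT if y.max() == 1 else -_SEPARATION_LIMIT
        return LogisticFit(
            motu_id=motu_id, beta0=b0, beta1=0.0, se_beta1=np.nan,
            converged=True, estimable=False, penalized=False,
            trend=TREND_CONSTANT,
        )
    X = sm.add_constant(d)
    beta = se = None
    penalized = False
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            ok = (
                res.converged
                and np.all(np.isfinite(res.params))
                and np.all(np.abs(res.params[0:1]) < _SEPARATION_LIMIT)
                and abs(res.params[1] * (np.max(d) - np.min(d))) < 2 * _SEPARATION_LIMIT
                and np.all(np.isfinite(res.bse))
            )
            if ok:
                beta, se, converged = res.params, res.bse, True
        except Exception:
            pass
    if beta is None:
        beta, se, converged = _ridge_logistic(y, d)
        penalized = True
    trend = _wald_trend(beta[1], se[1], alpha) if converged else None
    return LogisticFit(
        motu_id=motu_id, beta0=float(beta[0]), beta1=float(beta[1]),
        se_beta1=float(se[1]), converged=converged, estimable=True,
        penalized=penalized, trend=trend,
    )


def fit_all(
    presence: StationPresence, alpha: float = 0.05, log_distance: bool = False
) -> list[LogisticFit]:
    """Fit every MOTU row; ``log_distance`` switches the covariate to
    log(km)."""
    d = presence.station_distance
    if log_distance:
        d = np.log(d)
    return [
        fit_logistic(presence.presence[i], d, motu_id=m, alpha=alpha)
        for i, m in enumerate(presence.motu_ids)
    ]


def trend_by_category(
    fits: Sequence[LogisticFit], assignments: Sequence[Assignment]
) -> pd.DataFrame:
    """Contingency counts of occurrence trend per clade category
    (non-estimable and non-converged fits excluded)."""
    cat = {a.motu_id: a.clade_category for a in assignments if a.assigned}
    rows: dict[tuple[str, str], int] = {}
    for f in fits:
        if not f.estimable or not f.converged or f.trend is None:
            continue
        if f.motu_id not in cat:
            continue
        key = (cat[f.motu_id], f.trend)
        rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [(c, t, n) for (c, t), n in sorted(rows.items())],
        columns=["category", "trend", "n_motus"],
    )
    return df


def _per_sample_proportions(
    occurrence: OccurrenceTable, assignments: Sequence[Assignment]
) -> tuple[pd.DataFrame, dict[str, str]]:
    cat = {a.motu_id: a.clade_category for a in assignments if a.assigned}
    keep = [i for i, m in enumerate(occurrence.motu_ids) if m in cat]
    cats = sorted({cat[occurrence.motu_ids[i]] for i in keep})
    counts = occurrence.counts[keep]
    labels = [cat[occurrence.motu_ids[i]] for i in keep]
    per_cat = np.zeros((len(cats), counts.shape[1]))
    for row, lab in zip(counts, labels):
        per_cat[cats.index(lab)] += row
    totals = per_cat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(totals > 0, per_cat / np.where(totals > 0, totals, 1), np.nan)
    df = pd.DataFrame(props.T, index=occurrence.sample_ids, columns=cats)
    return df, cat


def proportions_by_fraction(
    occurrence: OccurrenceTable,
    assignments: Sequence[Assignment],
    metadata: Sequence[SampleRecord],
) -> pd.DataFrame:
    """Tidy per-sample category read proportions with the sample's size
    fraction; proportions sum to 1 per sample with nonzero assigned reads."""
    props, _ = _per_sample_proportions(occurrence, assignments)
    meta = {r.sample_id: r for r in metadata}
    rows = []
    for sample, row in props.iterrows():
        frac = meta[sample].size_fraction if sample in meta else ""
        for cat, p in row.items():
            rows.append(
                {"sample_id": sample, "size_fraction": frac, "category": cat,
                 "proportion": p}
            )
    return pd.DataFrame(rows, columns=["sample_id", "size_fraction", "category", "proportion"])


DEFAULT_BIN_EDGES = [0.0, 50.0, 100.0, 250.0, 500.0, 1000.0, 2000.0]


def proportions_by_distance(
    occurrence: OccurrenceTable,
    assignments: Sequence[Assignment],
    metadata: Sequence[SampleRecord],
    bin_edges: Sequence[float] = tuple(DEFAULT_BIN_EDGES),
) -> pd.DataFrame:
    """Mean per-sample category proportions in half-open distance bins
    [edge_i, edge_{i+1}); samples beyond the last edge fall into an overflow
    bin with a warning. Empty bins are reported with n_samples 0 and NaN
    means."""
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing, length >= 2")
    props, _ = _per_sample_proportions(occurrence, assignments)
    meta = {r.sample_id: r for r in metadata}
    n_bins = len(edges) - 1
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(n_bins)]
    overflow_label = f"[{edges[-1]:g},inf)"
    assign_bin: dict[str, str] = {}
    overflowed = False
    for sample in props.index:
        d = meta[sample].distance_to_coast
        k = int(np.searchsorted(edges, d, side="right")) - 1
        if d < edges[0]:
            k = 0
        if k >= n_bins:
            assign_bin[sample] = overflow_label
            overflowed = True
        else:
            assign_bin[sample] = labels[k]
    if overflowed:
        warnings.warn(
            "samples beyond the last bin edge assigned to an overflow bin",
            stacklevel=2,
        )
        labels = labels + [overflow_label]
    rows = []
    for lab in labels:
        members = [s for s in props.index if assign_bin[s] == lab]
        sub = props.loc[members]
        for cat in props.columns:
            vals = sub[cat].dropna()
            rows.append(
                {
                    "distance_bin": lab,
                    "category": cat,
                    "n_samples": len(vals),
                    "mean_proportion": float(vals.mean()) if len(vals) else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["distance_bin", "category", "n_samples", "mean_proportion"])
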