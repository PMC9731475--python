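"""Kernel-mix expected abundance and threshold-rule likelihood classification.

The seasonal mean abundance of a hazard species is modelled as a sum of
Gaussian peaks (migratory build-ups) and sigmoid-difference "bumps"
(populations that are stable over part of the year and absent otherwise).
Fitting the mix to observed (seasonality, abundance) pairs yields the
*expected abundance* curve.

Collision likelihood on a day is then a binary label — low or elevated —
obtained from a single-attribute threshold rule.  The rule is extracted from
a logistic regression fitted on class-balanced data (strikes are rare, so
the minority class is oversampled by nearest-neighbour interpolation): the
attribute with the largest standardised coefficient is selected and the
threshold is the raw attribute value at which the predicted strike
probability crosses one half.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from ._rng import substream
from .seasonal import SeasonalitySpec

__all__ = [
    "GaussianKernel",
    "SigmoidBump",
    "KernelMix",
    "ThresholdRule",
    "eval_gaussian",
    "eval_bump",
    "eval_mix",
    "fit_mix",
    "oversample_minority",
    "fit_threshold_rule",
    "classify_day",
]


@dataclass(frozen=True)
class GaussianKernel:
    """Bell curve a*exp(-(x-b)^2 / (2 c^2)): peak height a, centre b, width c."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("peak height a must be >= 0")
        if self.c <= 0:
            raise ValueError("width c must be > 0")


@dataclass(frozen=True)
class SigmoidBump:
    """Difference of two logistics: a plateau of height a, centre b,
    half-width c, edge steepness k (smaller k = sharper edges)."""

    a: float
    b: float
    c: float
    k: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("bump height a must be >= 0")
        if self.c <= 0 or self.k <= 0:
            raise ValueError("half-width c and steepness k must be > 0")


@dataclass
class KernelMix:
    """m Gaussian components + n sigmoid bumps; evaluation is their sum."""

    gaussians: list[GaussianKernel] = field(default_factory=list)
    bumps: list[SigmoidBump] = field(default_factory=list)
    seasonality: SeasonalitySpec | None = None

    def __call__(self, x) -> np.ndarray | float:
        return eval_mix(self, x)

    # -- YAML round-trip (species kernel configuration schema) --------------
    def to_yaml(self, path: str | Path, species: str | None = None) -> None:
        doc = {
            "species": species,
            "day0": self.seasonality.marker_date.isoformat() if self.seasonality else None,
            "mode": self.seasonality.mode if self.seasonality else None,
            "gaussians": [asdict(g) for g in self.gaussians],
            "sigmoids": [asdict(s) for s in self.bumps],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KernelMix":
        import datetime as dt

        doc = yaml.safe_load(Path(path).read_text())
        spec = None
        if doc.get("day0"):
            spec = SeasonalitySpec(dt.date.fromisoformat(doc["day0"]), doc.get("mode") or "angular")
        return cls(
            gaussians=[GaussianKernel(**g) for g in doc.get("gaussians", [])],
            bumps=[SigmoidBump(**s) for s in doc.get("sigmoids", [])],
            seasonality=spec,
        )


def eval_gaussian(g: GaussianKernel, x) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    val = g.a * np.exp(-((x - g.b) ** 2) / (2.0 * g.c**2))
    return val if val.ndim else float(val)


def eval_bump(s: SigmoidBump, x) -> np.ndarray | float:
    # expit is overflow-safe for large |x - b| / k
    x = np.asarray(x, dtype=float)
    val = s.a * (expit((x - s.b + s.c) / s.k) - expit((x - s.b - s.c) / s.k))
    return val if val.ndim else float(val)


def eval_mix(mix: KernelMix, x) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    total = np.zeros_like(x)
    for g in mix.gaussians:
        total = total + eval_gaussian(g, x)
    for s in mix.bumps:
        total = total + eval_bump(s, x)
    return total if total.ndim else float(total)


# ---------------------------------------------------------------------------
# Kernel-mix least squares
# ---------------------------------------------------------------------------


def _pack(mix_params: np.ndarray, m: int, n: int):
    gs = [GaussianKernel(*mix_params[3 * i : 3 * i + 3]) for i in range(m)]
    off = 3 * m
    bs = [SigmoidBump(*mix_params[off + 4 * i : off + 4 * i + 4]) for i in range(n)]
    return gs, bs


def _residuals(params: np.ndarray, m: int, n: int, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    total = np.zeros_like(x)
    for i in range(m):
        a, b, c = params[3 * i : 3 * i + 3]
        total += a * np.exp(-((x - b) ** 2) / (2.0 * c**2))
    off = 3 * m
    for i in range(n):
        a, b, c, k = params[off + 4 * i : off + 4 * i + 4]
        total += a * (expit((x - b + c) / k) - expit((x - b - c) / k))
    return total - y


def fit_mix(
    points: Sequence[tuple[float, float]] | np.ndarray,
    m: int = 1,
    n: int = 0,
    restarts: int = 32,
    seed: int = 0,
    seasonality: SeasonalitySpec | None = None,
) -> tuple[KernelMix, dict]:
    """Least-squares fit of an (m Gaussians, n bumps) mix to (x, y) points.

    Multi-start: ``restarts`` random initialisations drawn from the data's
    x-range and y-scale, refined with bounded trust-region least squares
    (a >= 0, c > 0, k > 0).  Returns the best mix and diagnostics including
    the SSE of every start, so the best-of-restarts contract is checkable.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("no data points to fit")
    if m + n < 1:
        raise ValueError("need at least one kernel component")
    n_params = 3 * m + 4 * n
    if len(pts) < 3 * n_params:
        raise ValueError(f"need at least {3 * n_params} points to fit {n_params} parameters, got {len(pts)}")

    x, y = pts[:, 0], pts[:, 1]
    rng = substream(seed, "fit_mix")
    x_lo, x_hi = float(x.min()), float(x.max())
    span = max(x_hi - x_lo, 1e-6)
    y_scale = max(float(np.abs(y).max()), 1e-6)

    lo = np.concatenate([np.tile([0.0, x_lo - span, 1e-6], m), np.tile([0.0, x_lo - span, 1e-6, 1e-6], n)])
    hi = np.concatenate(
        [np.tile([10 * y_scale, x_hi + span, 10 * span], m), np.tile([10 * y_scale, x_hi + span, 10 * span, span], n)]
    )

    best = None
    tried_sse: list[float] = []
    for _ in range(max(1, restarts)):
        p0 = np.concatenate(
            [
                np.concatenate(
                    [[rng.uniform(0.1, 2.0) * y_scale, rng.uniform(x_lo, x_hi), rng.uniform(0.05, 0.5) * span]]
                )
                for _ in range(m)
            ]
            + [
                np.concatenate(
                    [
                        [
                            rng.uniform(0.1, 2.0) * y_scale,
                            rng.uniform(x_lo, x_hi),
                            rng.uniform(0.05, 0.5) * span,
                            rng.uniform(0.01, 0.2) * span,
                        ]
                    ]
                )
                for _ in range(n)
            ]
        ) if (m or n) else np.array([])
        try:
            res = least_squares(_residuals, p0, args=(m, n, x, y), bounds=(lo, hi), method="trf")
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        tried_sse.append(sse)
        if best is None or sse < best[1]:
            best = (res.x, sse)

    if best is None:
        raise RuntimeError(f"no least-squares start converged ({restarts} tried)")
    gs, bs = _pack(best[0], m, n)
    mix = KernelMix(gs, bs, seasonality)
    return mix, {"sse": best[1], "tried_sse": tried_sse, "n_points": len(pts)}


# ---------------------------------------------------------------------------
# Minority oversampling (nearest-neighbour interpolation)
# ---------------------------------------------------------------------------


def oversample_minority(
    features: np.ndarray, labels: np.ndarray, seed: int = 0, k_neighbors: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a binary problem by synthesising minority points.

    Each synthetic point lies on the segment between a random minority point
    and one of its k nearest minority neighbours.  The majority class is left
    untouched.  A single minority point cannot be interpolated, so it is
    duplicated (with a warning).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim == 1:
        X = X[:, None]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need binary labels, got classes {classes}")
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    if n_needed == 0:
        return X, y

    rng = substream(seed, "oversample")
    X_min = X[y == minority]
    if len(X_min) == 1:
        warnings.warn("single minority point: oversampling falls back to duplication")
        synth = np.repeat(X_min, n_needed, axis=0)
    else:
        k = min(k_neighbors, len(X_min) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        _, nbr = nn.kneighbors(X_min)  # column 0 is the point itself
        base = rng.integers(0, len(X_min), n_needed)
        pick = nbr[base, rng.integers(1, k + 1, n_needed)]
        gap = rng.uniform(0.0, 1.0, (n_needed, 1))
        synth = X_min[base] + gap * (X_min[pick] - X_min[base])

    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# Threshold-rule extraction
# ---------------------------------------------------------------------------


@dataclass
class ThresholdRule:
    """Single-attribute likelihood rule: elevated iff the attribute is
    strictly beyond ``threshold`` in ``direction``; the boundary value itself
    is low (the low branch is the closed interval).

    A rule may carry a seasonality split: days are first divided at
    ``split_at`` on the seasonality score and dispatched to one of two
    branch rules (the hunting-mode pattern of the Nankeen Kestrel).
    """

    attribute: str
    threshold: float
    direction: str = "above"  # elevated when above / below
    accuracy: float | None = None
    f_score: float | None = None
    split_attribute: str | None = None
    split_at: float | None = None
    low_branch: "ThresholdRule | None" = None
    high_branch: "ThresholdRule | None" = None

    def to_json(self, path: str | Path) -> None:
        def enc(r: "ThresholdRule | None"):
            if r is None:
                return None
            d = {k: v for k, v in asdict(r).items() if k not in ("low_branch", "high_branch")}
            d["low_branch"] = enc(r.low_branch)
            d["high_branch"] = enc(r.high_branch)
            return d

        Path(path).write_text(json.dumps(enc(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdRule":
        def dec(d):
            if d is None:
                return None
            lo, hi = dec(d.pop("low_branch", None)), dec(d.pop("high_branch", None))
            return cls(**d, low_branch=lo, high_branch=hi)

        return dec(json.loads(Path(path).read_text()))


_DEFAULT_ATTRS = ("seasonality", "abundance", "expected_abundance")


def _cv_scores(X: np.ndarray, y: np.ndarray, seed: int, folds: int = 5) -> tuple[float, float]:
    """Stratified K-fold accuracy / F-score; oversampling inside training folds only."""
    n_splits = min(folds, int(np.bincount(y.astype(int)).min()))
    if n_splits < 2:
        return float("nan"), float("nan")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**31))
    accs, f1s = [], []
    for i, (tr, te) in enumerate(skf.split(X, y)):
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xb, yb = oversample_minority((X[tr] - mu) / sd, y[tr], seed=seed + i)
        clf = LogisticRegression(max_iter=1000).fit(Xb, yb)
        pred = clf.predict((X[te] - mu) / sd)
        accs.append(float(np.mean(pred == y[te])))
        f1s.append(float(f1_score(y[te], pred)))
    return float(np.mean(accs)), float(np.mean(f1s))


def fit_threshold_rule(
    table: pd.DataFrame,
    attributes: Sequence[str] = _DEFAULT_ATTRS,
    seed: int = 0,
    label_col: str = "strike",
) -> ThresholdRule:
    """Extract a single-attribute threshold rule from a species-day table.

    A logistic regression is fitted on standardised candidate attributes
    after minority oversampling; the attribute with the largest absolute
    standardised coefficient is selected, and the threshold is the raw-scale
    value of that attribute where the predicted probability crosses 0.5 with
    the other attributes held at their means.  Accuracy and F-score are
    reported from stratified 5-fold cross-validation (oversampling applied
    inside training folds only, so no synthetic point leaks into a test fold).
    """
    y = table[label_col].to_numpy(bool).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("degenerate labels: need both strike and non-strike days")
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("need at least 2 days in each class")

    attrs = [a for a in attributes if a in table.columns]
    keep = []
    for a in attrs:
        if np.std(table[a].to_numpy(float)) == 0:
            warnings.warn(f"attribute {a!r} has zero variance and is excluded")
        else:
            keep.append(a)
    if not keep:
        raise ValueError("no candidate attribute with non-zero variance")

    X = table[keep].to_numpy(float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    Z = (X - mu) / sd

    Zb, yb = oversample_minority(Z, y, seed=seed)
    clf = LogisticRegression(max_iter=1000).fit(Zb, yb)
    coefs = clf.coef_[0]
    j = int(np.argmax(np.abs(coefs)))

    # p = 0.5 where intercept + coef_j * z_j + sum_others coef_i * mean_i = 0;
    # standardised means are 0, so z* = -intercept / coef_j.
    z_star = -float(clf.intercept_[0]) / float(coefs[j])
    threshold = float(mu[j] + sd[j] * z_star)
    direction = "above" if coefs[j] > 0 else "below"

    acc, f1 = _cv_scores(X, y, seed)
    return ThresholdRule(keep[j], threshold, direction, accuracy=acc, f_score=f1)


def classify_day(rule: ThresholdRule, row) -> str:
    """Classify one species-day as "low" or "elevated" under a threshold rule.

    The boundary value is low: elevated requires being *strictly* beyond the
    threshold.  Rules with a seasonality split dispatch to a branch first
    (the split boundary itself goes to the low branch).
    """
    if rule.split_attribute is not None:
        s = _get(row, rule.split_attribute)
        branch = rule.low_branch if s <= rule.split_at else rule.high_branch
        if branch is None:
            raise ValueError("split rule is missing a branch")
        return classify_day(branch, row)
    value = _get(row, rule.attribute)
    if rule.direction == "above":
        return "elevated" if value > rule.threshold else "low"
    return "elevated" if value < rule.threshold else "low"


def _get(row, attr: str) -> float:
    try:
        return float(row[attr])
    except (KeyError, IndexError, TypeError) as exc:
        raise KeyError(f"row is missing attribute {attr!r}") from exc
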