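"""Sex-group inference from Xhet values.

Two modes: an unsupervised 1-D two-means threshold (no labels needed;
Xhet distributions are strongly bimodal in mixed-sex cohorts) and a
supervised one-feature logistic regression against external labels.
Labels are deliberately "xx-like"/"xy-like" rather than female/male: the
statistic measures a genotype pattern, not reported sex, and samples near
the cutoff are flagged ambiguous instead of being forced into a cluster
(e.g. XX samples with long runs of X homozygosity, or aneuploidies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

LABEL_XX = "xx-like"
LABEL_XY = "xy-like"
LABEL_AMBIGUOUS = "ambiguous"
LABEL_UNDEFINED = "undefined"


@dataclass(frozen=True)
class SexCall:
    sample_id: str
    xhet: Optional[float]
    label: str
    method: str  # "threshold" | "logistic"
    score: Optional[float]  # signed distance to cutoff, or fitted probability
    threshold_used: Optional[float]


class NoSeparationError(ValueError):
    pass


def unsupervised_threshold(xhet_values: Sequence[float]) -> float:
    """Deterministic 1-D 2-means cutoff between the two Xhet clusters.

    Centers are initialized at the min and max value, points assigned to
    the nearer center, centers moved to cluster means, repeated to a fixed
    point.  The cutoff is the midpoint of the two final cluster means.
    All-identical input has no separation and raises.
    """
    vals = np.asarray([v for v in xhet_values if v is not None], dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 defined Xhet values")
    if np.ptp(vals) == 0:
        raise NoSeparationError("no separation: all Xhet values identical")
    lo, hi = float(vals.min()), float(vals.max())
    for _ in range(100):
        # ties (equidistant points) go to the lower cluster
        assign_hi = np.abs(vals - hi) < np.abs(vals - lo)
        new_lo = float(vals[~assign_hi].mean())
        new_hi = float(vals[assign_hi].mean())
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    return (lo + hi) / 2.0


def classify(
    xhet_by_sample: dict[str, Optional[float]],
    cutoff: float,
    margin: Optional[float] = None,
) -> list[SexCall]:
    """Threshold classification with an ambiguity band around the cutoff.

    xhet below the cutoff is xy-like, at or above is xx-like; values within
    ``margin`` of the cutoff (default 10% of the cutoff) are forced to
    ambiguous.  Undefined Xhet stays undefined — never silently clustered.
    """
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must be in (0,1), got {cutoff}")
    if margin is None:
        margin = 0.1 * cutoff
    calls = []
    for sid in sorted(xhet_by_sample):
        x = xhet_by_sample[sid]
        if x is None:
            calls.append(SexCall(sid, None, LABEL_UNDEFINED, "threshold", None, cutoff))
            continue
        label = LABEL_XY if x < cutoff else LABEL_XX
        if abs(x - cutoff) < margin:
            label = LABEL_AMBIGUOUS
        calls.append(SexCall(sid, x, label, "threshold", x - cutoff, cutoff))
    return calls


@dataclass(frozen=True)
class LogisticFit:
    intercept: float
    slope: float
    separated: bool
    boundary: float  # xhet value where fitted probability = 0.5

    def predict_proba(self, x: float) -> float:
        z = self.intercept + self.slope * x
        return 1.0 / (1.0 + math.exp(-z))


def _irls(x: np.ndarray, y: np.ndarray, ridge: float, max_iter: int = 200,
          tol: float = 1e-10) -> tuple[np.ndarray, bool]:
    """One-feature logistic IRLS with an optional ridge penalty.

    Returns (beta, converged).  Non-convergence with exploding |beta| is the
    signature of complete separation in the unpenalized fit.
    """
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        z = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        w = p * (1 - p)
        grad = X.T @ (y - p) - ridge * beta
        hess = (X * w[:, None]).T @ X + ridge * np.eye(2)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if np.abs(step).max() < tol:
            return beta, True
        if np.abs(beta).max() > 1e6:
            return beta, False
    return beta, False


def fit_logistic(
    xhet_values: Sequence[float],
    labels: Sequence[int],
    ridge: float = 1e-3,
) -> LogisticFit:
    """Fit P(xx-like | xhet) by IRLS, with complete-separation handling.

    ``labels`` are 1 for the xx-like class, 0 for xy-like; both classes
    must be present.  When the classes are perfectly separated the
    unpenalized maximum-likelihood estimate does not exist (coefficients
    diverge); this is detected and a ridge-stabilized fit is reported with
    ``separated=True`` instead of returning diverged coefficients.
    """
    x = np.asarray(xhet_values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xhet values and labels must be equal-length 1-D")
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")

    beta, converged = _irls(x, y, ridge=0.0)
    separated = not converged
    if separated:
        beta, _ = _irls(x, y, ridge=ridge)
    intercept, slope = float(beta[0]), float(beta[1])
    boundary = -intercept / slope if slope != 0 else math.nan
    return LogisticFit(intercept=intercept, slope=slope, separated=separated,
                       boundary=boundary)


def classify_logistic(
    xhet_by_sample: dict[str, Optional[float]],
    fit: LogisticFit,
    margin_p: float = 0.05,
) -> list[SexCall]:
    """Classify by fitted probability; within margin_p of 0.5 is ambiguous."""
    calls = []
    for sid in sorted(xhet_by_sample):
        x = xhet_by_sample[sid]
        if x is None:
            calls.append(SexCall(sid, None, LABEL_UNDEFINED, "logistic", None,
                                 fit.boundary))
            continue
        p = fit.predict_proba(x)
        label = LABEL_XX if p >= 0.5 else LABEL_XY
        if abs(p - 0.5) < margin_p:
            label = LABEL_AMBIGUOUS
        calls.append(SexCall(sid, x, label, "logistic", p, fit.boundary))
    return calls


def write_sexcalls_tsv(calls: Sequence[SexCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\txhet\tlabel\tmethod\tscore\tthreshold\n")
        for c in calls:
            x = "" if c.xhet is None else f"{c.xhet:.6f}"
            s = "" if c.score is None else f"{c.score:.6f}"
            t = "" if c.threshold_used is None else f"{c.threshold_used:.6f}"
            fh.write(f"{c.sample_id}\t{x}\t{c.label}\t{c.method}\t{s}\t{t}\n")
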