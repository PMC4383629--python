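"""Confusion-matrix construction and the full pocket-evaluation metric suite.

A recognized pocket is scored against the optimal pocket over the receptor
boundary atom set B: each boundary atom is classified positive/negative by
both the reference and the prediction, giving TP/FP/TN/FN counts.  From the
counts come the primary rates (TPR/FPR/P/SP/AC), two entropy-based measures
(normalized mutual information and the G-statistic likelihood ratio, both
insensitive to the pocket/non-pocket class imbalance), and eleven secondary
metrics (ROC-based, precision-based, and ordinal-association).

Conventions: entropies use base-2 logs (bits); the likelihood ratio uses
natural logs (G-statistic, chi-square comparable); 0*log(0) = 0 throughout.
Degenerate denominators yield 0 and are recorded in ``MetricSet.flags``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "OperatingCurve",
    "confusion_from_sets",
    "primary_metrics",
    "nmi",
    "likelihood_ratio",
    "secondary_metrics",
    "all_metrics",
    "operating_points",
    "random_baseline",
]


class ContainmentError(ValueError):
    """Pocket sets are not subsets of the boundary set."""


@dataclass(frozen=True)
class ConfusionCounts:
    """TP / FP / TN / FN counts over the boundary atom set."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be non-negative")
        if self.N < 1:
            raise ValueError("total count must be >= 1")

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def scaled(self, k: int) -> "ConfusionCounts":
        return ConfusionCounts(self.TP * k, self.FP * k, self.TN * k, self.FN * k)


_METRIC_FIELDS = (
    "TPR", "FPR", "P", "SP", "AC", "S", "R",
    "NMI", "LR",
    "BA", "G2", "ED", "YI", "F", "G1", "PSI", "NPV",
    "gamma", "tau_b", "tau_c",
)


@dataclass(frozen=True)
class MetricSet:
    """Evaluation metrics; fields are None until the producing stage fills them.

    ``flags`` records degenerate-denominator fallbacks (metric name -> reason).
    """

    TPR: float | None = None
    FPR: float | None = None
    P: float | None = None
    SP: float | None = None
    AC: float | None = None
    S: float | None = None
    R: float | None = None
    NMI: float | None = None
    LR: float | None = None
    BA: float | None = None
    G2: float | None = None
    ED: float | None = None
    YI: float | None = None
    F: float | None = None
    G1: float | None = None
    PSI: float | None = None
    NPV: float | None = None
    gamma: float | None = None
    tau_b: float | None = None
    tau_c: float | None = None
    flags: tuple[str, ...] = ()

    def merged(self, other: "MetricSet") -> "MetricSet":
        updates = {
            f: getattr(other, f)
            for f in _METRIC_FIELDS
            if getattr(other, f) is not None
        }
        updates["flags"] = tuple(dict.fromkeys(self.flags + other.flags))
        return replace(self, **updates)

    def as_dict(self) -> dict[str, float | None]:
        return {f: getattr(self, f) for f in _METRIC_FIELDS}


def confusion_from_sets(
    optimal: Iterable[int],
    recognized: Iterable[int],
    boundary: Iterable[int],
) -> ConfusionCounts:
    """Counts of boundary atoms cross-classified by reference and prediction."""
    opt, rec, b = set(optimal), set(recognized), set(boundary)
    if not opt <= b:
        raise ContainmentError("optimal pocket is not a subset of the boundary set")
    if not rec <= b:
        raise ContainmentError("recognized pocket is not a subset of the boundary set")
    tp = len(opt & rec)
    fp = len(rec - opt)
    fn = len(opt - rec)
    tn = len(b) - tp - fp - fn
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(f"{name}: zero denominator, reported as 0")
        return 0.0
    return num / den


def primary_metrics(c: ConfusionCounts) -> MetricSet:
    """TPR (= S = R), FPR, precision, specificity, accuracy."""
    flags: list[str] = []
    tpr = _safe_div(c.TP, c.TP + c.FN, "TPR", flags)
    fpr = _safe_div(c.FP, c.TN + c.FP, "FPR", flags)
    p = _safe_div(c.TP, c.TP + c.FP, "P", flags)
    sp = _safe_div(c.TN, c.TN + c.FP, "SP", flags)
    ac = c.TP + c.TN
    return MetricSet(
        TPR=tpr, FPR=fpr, P=p, SP=sp, AC=ac / c.N, S=tpr, R=tpr, flags=tuple(flags)
    )


def _entropy2(ps: Sequence[float]) -> float:
    return -sum(p * math.log2(p) for p in ps if p > 0)


def nmi(c: ConfusionCounts) -> float:
    """Normalized mutual information (H(x) - H(x|y)) / H(x), base-2 entropies.

    x is the predicted label margin, y the true label margin; H(x) = 0 gives
    NMI = 0 by convention.
    """
    n = float(c.N)
    # predicted margins
    px = [(c.TP + c.FP) / n, (c.TN + c.FN) / n]
    hx = _entropy2(px)
    if hx == 0:
        return 0.0
    # condition on the true label
    h_cond = 0.0
    for pos_cell, neg_cell in (((c.TP, c.FN)), ((c.FP, c.TN))):
        py = (pos_cell + neg_cell) / n
        if py == 0:
            continue
        h_cond += py * _entropy2([pos_cell / (pos_cell + neg_cell),
                                  neg_cell / (pos_cell + neg_cell)])
    return (hx - h_cond) / hx


def likelihood_ratio(c: ConfusionCounts) -> float:
    """G-statistic: 2 * sum O * ln(O / E), expected counts from the margins."""
    n = float(c.N)
    obs = np.array([[c.TP, c.FN], [c.FP, c.TN]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / n
    total = 0.0
    for o, e in zip(obs.ravel(), exp.ravel()):
        if o > 0:
            total += o * math.log(o / e)
    return 2.0 * total


def secondary_metrics(c: ConfusionCounts) -> MetricSet:
    """The eleven ROC-, precision- and ordinal-association-based metrics."""
    flags: list[str] = []
    prim = primary_metrics(c)
    s, sp, p = prim.S, prim.SP, prim.P
    flags.extend(prim.flags)
    npv = _safe_div(c.TN, c.TN + c.FN, "NPV", flags)
    concord = c.TP * c.TN - c.FP * c.FN
    gamma = _safe_div(concord, c.TP * c.TN + c.FP * c.FN, "gamma", flags)
    tau_b_den = math.sqrt(
        float(c.TP + c.FN) * (c.TN + c.FP) * (c.TP + c.FP) * (c.TN + c.FN)
    )
    tau_b = _safe_div(concord, tau_b_den, "tau_b", flags)
    tau_c = 4.0 * concord / c.N**2
    return MetricSet(
        BA=(s + sp) / 2.0,
        G2=math.sqrt(s * sp),
        ED=math.sqrt((s - 1.0) ** 2 + (sp - 1.0) ** 2),
        YI=s + sp - 1.0,
        F=_safe_div(2.0 * s * p, s + p, "F", flags),
        G1=math.sqrt(s * p),
        PSI=npv + p - 1.0,
        NPV=npv,
        gamma=gamma,
        tau_b=tau_b,
        tau_c=tau_c,
        flags=tuple(flags),
    )


def all_metrics(c: ConfusionCounts) -> MetricSet:
    """Primary + entropy-based + secondary metrics in one set."""
    out = primary_metrics(c).merged(secondary_metrics(c))
    return replace(out, NMI=nmi(c), LR=likelihood_ratio(c))


class OperatingCurve(NamedTuple):
    """Per-run operating points plus an empirical (trapezoidal) area.

    ``empirical`` is always True: the area is a trapezoid sum over the sorted
    points, not a fitted (binormal) curve.
    """

    points: np.ndarray  # (n_runs, 2)
    area: float
    empirical: bool = True


def operating_points(
    runs: Sequence[ConfusionCounts],
    space: Literal["roc", "pr"] = "roc",
) -> OperatingCurve:
    """(FPR, TPR) or (R, P) operating points for a batch of evaluations."""
    if not runs:
        raise ValueError("need at least one run")
    pts = []
    for c in runs:
        m = primary_metrics(c)
        pts.append((m.FPR, m.TPR) if space == "roc" else (m.R, m.P))
    arr = np.array(pts, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    area = float(np.trapezoid(arr[order, 1], arr[order, 0])) if len(arr) > 1 else 0.0
    return OperatingCurve(points=arr, area=area)


def random_baseline(
    boundary: Iterable[int], n: int, seed: int | None = None
) -> set[int]:
    """Uniform sample (without replacement) of n boundary atoms, seeded."""
    pool = sorted(set(boundary))
    if not 0 <= n <= len(pool):
        raise ValueError(f"n must be in [0, {len(pool)}], got {n}")
    rng = np.random.default_rng(seed)
    return set(int(i) for i in rng.choice(pool, size=n, replace=False))
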