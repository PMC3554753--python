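"""Grain-filling kinetics and expression-dynamics analysis.

The grain-weight time course is fitted with the three-parameter logistic

    Y(t) = K / (1 + a * exp(-b * t))

(K = asymptotic grain weight in mg, t in days after flowering), and the
filling rate is its derivative

    V(t) = K * a * b * exp(-b * t) / (1 + a * exp(-b * t))**2

with maximum ``K * b / 4`` at ``t = ln(a) / b``.  Expression profiles are
filtered (strictly above 10 TPM in at least one stage), log2(TPM + 1)
transformed, hierarchically clustered on a correlation distance, and
correlated (Pearson) with the filling rate and with their predicted
targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import curve_fit

DEFAULT_TPM_THRESHOLD = 10.0
DEFAULT_K_CLUSTERS = 10


class FitError(RuntimeError):
    """Raised when the logistic fit fails or violates model invariants."""


def logistic_weight(t, K, a, b):
    """Logistic grain weight (mg) at time ``t`` (DAF)."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + a * np.exp(-b * t))


@dataclass
class GrainFillingModel:
    K: float  # mg
    a: float  # dimensionless
    b: float  # per day
    covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.K <= 0 or self.a <= 0 or self.b <= 0:
            raise FitError(
                f"logistic parameters must be positive (K={self.K}, a={self.a}, b={self.b})"
            )

    def weight(self, t):
        return logistic_weight(t, self.K, self.a, self.b)

    def rate(self, t):
        """Filling rate V(t) = dY/dt, mg/day."""
        t = np.asarray(t, dtype=float)
        e = self.a * np.exp(-self.b * t)
        return self.K * self.b * e / (1.0 + e) ** 2

    @property
    def t_max_rate(self) -> float:
        """Time of maximum filling rate, ln(a)/b."""
        return float(np.log(self.a) / self.b)

    @property
    def max_rate(self) -> float:
        return self.K * self.b / 4.0


def filling_rate(model: GrainFillingModel, t) -> np.ndarray | float:
    """Filling rate of a fitted model at time(s) ``t``."""
    return model.rate(t)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # K0 slightly above the largest observed weight; a0, b0 from the
    # log-linearised model log((K0 - Y)/Y) = ln(a) - b t
    K0 = 1.05 * float(np.max(y))
    frac = np.clip((K0 - y) / np.clip(y, 1e-9, None), 1e-9, None)
    z = np.log(frac)
    slope, intercept = np.polyfit(t, z, 1)
    b0 = max(-float(slope), 1e-3)
    a0 = max(float(np.exp(intercept)), 1e-6)
    return K0, a0, b0


def fit_logistic(weights: Sequence[tuple[float, float]]) -> GrainFillingModel:
    """Nonlinear least-squares fit of the logistic grain-weight model.

    Deterministic given the data: the initial guess comes from a documented
    log-linearisation, and optimisation is bounded to positive parameters.
    """
    data = np.asarray(sorted(weights), dtype=float)
    if data.shape[0] < 4:
        raise FitError("need at least 4 time points")
    t, y = data[:, 0], data[:, 1]
    if np.any(y <= 0):
        raise FitError("grain weights must be positive")
    p0 = _initial_guess(t, y)
    try:
        popt, pcov = curve_fit(
            logistic_weight, t, y, p0=p0,
            bounds=(np.zeros(3), np.full(3, np.inf)), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"logistic fit did not converge: {exc}") from exc
    K, a, b = map(float, popt)
    # a or b collapsing to the boundary means the data carry no growth signal
    if b < 1e-6 or a < 1e-6:
        raise FitError(
            f"degenerate fit (K={K:.4g}, a={a:.4g}, b={b:.4g}); "
            "input is not an increasing sigmoid"
        )
    return GrainFillingModel(K, a, b, covariance=pcov)


def filter_expressed(
    profiles: pd.DataFrame, threshold: float = DEFAULT_TPM_THRESHOLD
) -> pd.DataFrame:
    """Keep profiles whose maximum stage TPM is strictly above ``threshold``."""
    return profiles.loc[profiles.max(axis=1) > threshold]


def log2_transform(profiles: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM + 1); the pseudocount keeps zero-TPM stages finite."""
    return np.log2(profiles.astype(float) + 1.0)


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance with degenerate-row handling.

    Two constant rows are at distance 0 when identical, else 1; a constant
    vs non-constant pair is at distance 1 (correlation treated as 0).
    """
    n = X.shape[0]
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] == 0 and norms[j] == 0:
                d = 0.0 if np.allclose(X[i], X[j]) else 1.0
            elif norms[i] == 0 or norms[j] == 0:
                d = 1.0
            else:
                r = float(centered[i] @ centered[j] / (norms[i] * norms[j]))
                d = 1.0 - max(-1.0, min(1.0, r))
            out[k] = d
            k += 1
    return out


@dataclass
class ClusterResult:
    labels: pd.Series  # profile id -> 1-based cluster label
    means: pd.DataFrame  # cluster label x stage, log2 scale
    rate_pcc: pd.Series | None = None  # cluster label -> PCC vs filling rate

    def partition(self) -> frozenset[frozenset]:
        """Label-free view of the clustering, for permutation comparisons."""
        groups: dict[int, set] = {}
        for pid, lab in self.labels.items():
            groups.setdefault(int(lab), set()).add(pid)
        return frozenset(frozenset(g) for g in groups.values())


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int = DEFAULT_K_CLUSTERS,
    model: GrainFillingModel | None = None,
    stage_days: Sequence[float] | None = None,
) -> ClusterResult:
    """Average-linkage hierarchical clustering on 1 - Pearson distance.

    Profiles are log2(TPM + 1)-transformed first.  Rows are processed in
    lexicographic id order so the result does not depend on input order;
    cluster labels are renumbered by first occurrence.  When a fitted model
    and stage days are given, each cluster mean profile is correlated with
    the filling rate at those days.
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the {len(profiles)} profiles")
    ordered = profiles.sort_index()
    X = log2_transform(ordered).to_numpy()
    if len(ordered) == 1:
        raw = np.ones(1, dtype=int)
    else:
        Z = linkage(_correlation_distance(X), method="average")
        raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels.append(relabel[lab])
    label_series = pd.Series(labels, index=ordered.index, name="cluster")
    logX = log2_transform(ordered)
    means = logX.groupby(label_series).mean()
    rate_pcc = None
    if model is not None and stage_days is not None:
        v = model.rate(np.asarray(stage_days, dtype=float))
        rate_pcc = pd.Series(
            {lab: pearson(means.loc[lab].to_numpy(), v) for lab in means.index},
            name="rate_pcc",
        )
    return ClusterResult(label_series, means, rate_pcc)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def correlate_with_rate(
    profile: Sequence[float] | pd.Series,
    model: GrainFillingModel,
    stage_days: Sequence[float],
) -> float:
    """PCC between a stage-expression vector and V at the stage days."""
    v = model.rate(np.asarray(stage_days, dtype=float))
    return pearson(np.asarray(profile, dtype=float), v)


@dataclass(frozen=True)
class CorrelationReport:
    mirna_id: str
    target_id: str
    pcc: float
    sign_class: str  # "negative" | "positive" | "not_classifiable"


def mirna_target_correlation(
    mirna_matrix: pd.DataFrame,
    gene_matrix: pd.DataFrame,
    pairs: Iterable[tuple[str, str]],
) -> list[CorrelationReport]:
    """Per-pair Pearson correlation over the five stages.

    Degenerate (constant) vectors are reported as ``not_classifiable``
    rather than raising.
    """
    reports = []
    for mirna_id, target_id in pairs:
        r = pearson(
            mirna_matrix.loc[mirna_id].to_numpy(),
            gene_matrix.loc[target_id].to_numpy(),
        )
        if np.isnan(r):
            cls = "not_classifiable"
        else:
            cls = "negative" if r < 0 else "positive"
        reports.append(CorrelationReport(mirna_id, target_id, r, cls))
    return reports


def correlation_summary(reports: Iterable[CorrelationReport]) -> Mapping[str, int]:
    """Counts per sign class."""
    out = {"negative": 0, "positive": 0, "not_classifiable": 0}
    for r in reports:
        out[r.sign_class] += 1
    return out
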