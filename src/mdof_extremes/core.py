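"""Merged-maxima conditional exceedance estimation for MDOF panels.

The method treats a panel of regional rate series as one multidegree-of-
freedom (MDOF) system.  Local maxima of every component are interleaved,
in time order, into a single merged vector R_1..R_N, each maximum carrying
its source component's failure limit eta_j.  A scaling parameter
0 < lambda <= 1 lowers all limits simultaneously, and the conditional
exceedance rate

    p_k(lambda) = Prob{ R_j > eta_j*lambda |
                        R_{j-1} <= eta_{j-1}*lambda, ...,
                        R_{j-k+1} <= eta_{j-k+1}*lambda }

is estimated by direct counting.  Under stationarity the nonexceedance
probability of the whole system over the record is approximated as
P_k(lambda) ~= exp(-N * p_k(lambda)), with convergence in the
conditioning depth k.  Conditioning on the k-1 preceding maxima removes
cascades of intercorrelated local exceedances so that only the first
failure in each cluster is counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .panel import ComponentSeries, Panel

__all__ = [
    "MaximaSequence",
    "MergedVector",
    "ExceedanceCurve",
    "MixtureSpec",
    "KConvergence",
    "extract_local_maxima",
    "resolve_maxima_mode",
    "merge_causes",
    "assemble_merged_vector",
    "default_lambda_grid",
    "estimate_pk",
    "nonexceedance_probability",
    "system_failure_probability",
    "check_k_convergence",
    "mean_upcrossing_rate",
    "upcrossing_nonexceedance",
    "mixture_longterm",
]

#: component series shorter than this default to "all_samples" extraction
SHORT_SERIES_LENGTH = 50


@dataclass(frozen=True)
class MaximaSequence:
    """Time-ordered local maxima of one component, with its limit eta."""

    component_id: str
    times: np.ndarray
    values: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.size != values.size:
            raise ValueError("times and values differ in length")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("maxima times must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("maxima must be nonnegative")
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class MergedVector:
    """All components' local maxima merged into one nondecreasing-time
    vector, with the unified limit vector eta_1..eta_N."""

    times: np.ndarray
    values: np.ndarray
    limits: np.ndarray
    sources: tuple[str, ...]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        limits = np.asarray(self.limits, dtype=np.float64)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "limits", limits)
        object.__setattr__(self, "sources", tuple(self.sources))
        n = times.size
        if not (values.size == n and limits.size == n and len(self.sources) == n):
            raise ValueError("merged vector fields differ in length")
        if n == 0:
            raise ValueError("merged vector is empty")
        if np.any(np.diff(times) < 0):
            raise ValueError("merged times must be nondecreasing")
        if np.any(limits <= 0):
            raise ValueError("limits must be positive")

    @property
    def N(self) -> int:
        return int(self.times.size)

    @property
    def scaled(self) -> np.ndarray:
        """Nondimensional maxima R_j / eta_j."""
        return self.values / self.limits

    @property
    def n_years(self) -> int:
        """Number of distinct observation years covered by the record."""
        return int(np.unique(self.times).size)


@dataclass(frozen=True)
class ExceedanceCurve:
    """p_k(lambda) over a lambda grid, with the counts behind it.

    ``n_cond[i]`` is the number of merged-vector indices where the
    conditioning event holds at ``lambdas[i]``; ``n_exc[i]`` of those also
    exceed their scaled limit.  ``supported`` marks grid points with a
    nonzero conditioning count (p is reported as 0 elsewhere).  Mixture
    curves carry no counts (``n_cond``/``n_exc`` set to -1).
    """

    k: int
    lambdas: np.ndarray
    p: np.ndarray
    n_cond: np.ndarray
    n_exc: np.ndarray
    N: int
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lambdas", np.asarray(self.lambdas, dtype=np.float64))
        object.__setattr__(self, "p", np.asarray(self.p, dtype=np.float64))
        object.__setattr__(self, "n_cond", np.asarray(self.n_cond, dtype=np.int64))
        object.__setattr__(self, "n_exc", np.asarray(self.n_exc, dtype=np.int64))
        if self.ci_lo is not None:
            object.__setattr__(self, "ci_lo", np.asarray(self.ci_lo, dtype=np.float64))
        if self.ci_hi is not None:
            object.__setattr__(self, "ci_hi", np.asarray(self.ci_hi, dtype=np.float64))
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p values must lie in [0, 1]")
        if self.k < 1:
            raise ValueError("conditioning level k must be >= 1")

    @property
    def supported(self) -> np.ndarray:
        return self.n_cond > 0

    @property
    def has_counts(self) -> bool:
        return bool(np.all(self.n_cond >= 0))

    def interp_p(self, lam: float) -> float:
        """Linear interpolation of p on the grid (for reporting only)."""
        return float(np.interp(lam, self.lambdas, self.p))


@dataclass(frozen=True)
class MixtureSpec:
    """Environmental-state mixture: weights q_m over per-state curves."""

    weights: np.ndarray
    curves: tuple[ExceedanceCurve, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "curves", tuple(self.curves))
        if w.size != len(self.curves) or w.size == 0:
            raise ValueError("one weight per curve is required")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
        ref = self.curves[0]
        for c in self.curves[1:]:
            if c.k != ref.k:
                raise ValueError("all mixture curves must share the same k")
            if c.lambdas.size != ref.lambdas.size or not np.array_equal(
                c.lambdas, ref.lambdas
            ):
                raise ValueError("all mixture curves must share the lambda grid")


# ---------------------------------------------------------------------------
# maxima extraction and merging


def resolve_maxima_mode(mode: str, series_length: int) -> str:
    """Resolve the "auto" extraction mode: short annual series keep every
    sample, long records keep interior local maxima only."""
    if mode == "auto":
        return "all_samples" if series_length < SHORT_SERIES_LENGTH else "interior"
    if mode not in ("interior", "all_samples"):
        raise ValueError(f"unknown maxima mode {mode!r}")
    return mode


def extract_local_maxima(series: ComponentSeries, mode: str = "interior") -> MaximaSequence:
    """Extract the time-ordered local maxima of one component.

    ``"interior"`` keeps samples strictly greater than both neighbours;
    a plateau of equal values counts once, at its first sample, when it
    exceeds both flanking samples.  Endpoints are never interior maxima.
    ``"all_samples"`` keeps every sample — appropriate for short annual
    series where discarding non-peak years would leave too little data.
    """
    mode = resolve_maxima_mode(mode, len(series))
    v = series.values
    t = series.times
    if mode == "all_samples":
        idx = np.arange(v.size)
    else:
        idx_list: list[int] = []
        n = v.size
        i = 0
        while i < n:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            # run of equal values spans [i, j]
            if i > 0 and j < n - 1 and v[i] > v[i - 1] and v[i] > v[j + 1]:
                idx_list.append(i)
            i = j + 1
        idx = np.asarray(idx_list, dtype=np.int64)
    return MaximaSequence(
        component_id=series.component_id,
        times=t[idx],
        values=v[idx],
        threshold=series.threshold,
    )


def merge_causes(cardio: Panel, cancer: Panel, cancer_scale: float = 4.0) -> Panel:
    """Combine two cause panels into one bivariate-maximum panel.

    Per country and year the combined value is
    ``max(x_cardio, cancer_scale * x_cancer)`` — scaling the secondary
    cause up by the factor by which its failure limit is lowered (the
    default fourfold factor matches cancer's limit to the CVD one).  The
    output keeps the cardio threshold.  Years present in only one panel
    are dropped for that country; countries present in only one panel are
    dropped.
    """
    if not cancer_scale > 0:
        raise ValueError("cancer_scale must be positive")
    cancer_by_id = {c.component_id: c for c in cancer.components}
    merged: list[ComponentSeries] = []
    for comp in cardio.components:
        other = cancer_by_id.get(comp.component_id)
        if other is None:
            continue
        common, ia, ib = np.intersect1d(comp.times, other.times, return_indices=True)
        if common.size == 0:
            continue
        values = np.maximum(comp.values[ia], cancer_scale * other.values[ib])
        merged.append(
            ComponentSeries(
                component_id=comp.component_id,
                times=common,
                values=values,
                threshold=comp.threshold,
            )
        )
    if not merged:
        raise ValueError("the two panels share no components with overlapping years")
    meta = dict(cardio.metadata)
    meta["merged_with"] = dict(cancer.metadata).get("source", "secondary cause")
    meta["cancer_scale"] = float(cancer_scale)
    return Panel(components=tuple(merged), metadata=meta)


def assemble_merged_vector(maxima: Sequence[MaximaSequence]) -> MergedVector:
    """Interleave all components' maxima into one nondecreasing-time vector.

    Ties at equal times are broken by the components' input order (stable),
    so N = sum of the per-component counts and the final time is the
    latest time over all components.
    """
    seqs = [m for m in maxima if len(m) > 0]
    if not seqs:
        raise ValueError("all maxima sequences are empty")
    times = np.concatenate([m.times for m in seqs])
    values = np.concatenate([m.values for m in seqs])
    limits = np.concatenate([np.full(len(m), m.threshold) for m in seqs])
    sources = [m.component_id for m in seqs for _ in range(len(m))]
    order = np.argsort(times, kind="stable")
    return MergedVector(
        times=times[order],
        values=values[order],
        limits=limits[order],
        sources=tuple(sources[i] for i in order),
    )


# ---------------------------------------------------------------------------
# conditional exceedance rates


def default_lambda_grid(merged: MergedVector, size: int = 200, start: float | None = None) -> np.ndarray:
    """Evenly spaced lambda grid from the median of R_j/eta_j up to 1.

    The lower end keeps conditioning counts well populated; the upper end
    is the design limit lambda = 1.
    """
    if start is None:
        start = float(np.quantile(merged.scaled, 0.5))
        start = min(max(start, 1e-6), 0.99)
    if size < 2:
        raise ValueError("grid size must be >= 2")
    return np.linspace(start, 1.0, size)


def estimate_pk(merged: MergedVector, lambdas: np.ndarray, k: int) -> ExceedanceCurve:
    """Estimate the conditional exceedance rate p_k on a lambda grid.

    For each lambda the conditioning event at index j (1-based, j >= k)
    is that the k-1 preceding maxima stayed at or below their scaled
    limits; p is the fraction of conditioning indices whose own maximum
    strictly exceeds its scaled limit.  Exceedance is strict (">"),
    conditioning is non-strict ("<="): a value exactly at eta_j*lambda
    counts as nonexceedance.  Grid points with an empty conditioning set
    get p = 0 and are flagged unsupported.
    """
    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=np.float64))
    if lambdas.size == 0:
        raise ValueError("lambda grid is empty")
    if np.any(lambdas <= 0):
        raise ValueError("lambda values must be positive")
    if np.any(lambdas > 1):
        warnings.warn(
            "lambda values above 1 probe beyond the design limit", stacklevel=2
        )
    N = merged.N
    if not 1 <= k <= N:
        raise ValueError(f"need 1 <= k <= N (k={k}, N={N})")
    ratio = merged.scaled
    p = np.zeros(lambdas.size)
    n_cond = np.zeros(lambdas.size, dtype=np.int64)
    n_exc = np.zeros(lambdas.size, dtype=np.int64)
    w = k - 1
    for i, lam in enumerate(lambdas):
        below = ratio <= lam
        if w == 0:
            nc = N
            ne = int(np.count_nonzero(~below))
        else:
            # window sums of `below`: S[m] = sum(below[m : m + w])
            cs = np.concatenate(([0], np.cumsum(below)))
            window = cs[w:] - cs[:-w]
            cond = window[: N - w] == w  # conditioning for j0 = w .. N-1
            nc = int(np.count_nonzero(cond))
            ne = int(np.count_nonzero(cond & ~below[w:]))
        n_cond[i] = nc
        n_exc[i] = ne
        p[i] = ne / nc if nc > 0 else 0.0
    return ExceedanceCurve(k=k, lambdas=lambdas, p=p, n_cond=n_cond, n_exc=n_exc, N=N)


def nonexceedance_probability(curve: ExceedanceCurve) -> np.ndarray:
    """P_k(lambda) ~= exp(-N * p_k(lambda)) over the curve's grid."""
    return np.exp(-curve.N * curve.p)


def system_failure_probability(curve: ExceedanceCurve) -> float:
    """System failure probability 1 - P_k(1).

    Requires lambda = 1 on the grid (the design limit)."""
    at_one = np.isclose(curve.lambdas, 1.0)
    if not at_one.any():
        raise ValueError("the curve's grid does not include lambda = 1")
    p1 = float(curve.p[at_one][-1])
    return float(1.0 - np.exp(-curve.N * p1))


@dataclass(frozen=True)
class KConvergence:
    """Result of the conditioning-depth convergence scan."""

    k_star: int
    converged: bool
    discrepancy: dict[int, float]  # k -> max relative |p_k - p_{k-1}|


def check_k_convergence(
    curves: Sequence[ExceedanceCurve],
    tol: float = 0.05,
    floor: float | None = None,
) -> KConvergence:
    """Find the smallest conditioning depth at which p_k has stabilized.

    Consecutive curves are compared pointwise:
    ``max_lambda |p_k - p_{k-1}| / max(p_k, floor) <= tol`` declares
    convergence at k.  The floor (default 1/N) keeps deep-tail points
    with near-zero rates from dominating the relative comparison.  If no
    level qualifies the largest supplied k is returned, flagged
    unconverged.
    """
    curves = sorted(curves, key=lambda c: c.k)
    if len(curves) < 2:
        raise ValueError("need at least two curves to assess convergence")
    ref = curves[0]
    for c in curves[1:]:
        if c.lambdas.size != ref.lambdas.size or not np.allclose(c.lambdas, ref.lambdas):
            raise ValueError("curves must share the same lambda grid")
    if floor is None:
        floor = 1.0 / ref.N
    discrepancy: dict[int, float] = {}
    k_star = curves[-1].k
    converged = False
    for prev, cur in zip(curves[:-1], curves[1:]):
        mask = (prev.n_cond > 0) & (cur.n_cond > 0)
        if not mask.any():
            discrepancy[cur.k] = np.inf
            continue
        denom = np.maximum(cur.p[mask], floor)
        d = float(np.max(np.abs(cur.p[mask] - prev.p[mask]) / denom))
        discrepancy[cur.k] = d
        if not converged and d <= tol:
            k_star = cur.k
            converged = True
    return KConvergence(k_star=k_star, converged=converged, discrepancy=discrepancy)


# ---------------------------------------------------------------------------
# up-crossing cross-check and nonstationary mixture


def mean_upcrossing_rate(values: np.ndarray, level: float, duration: float) -> float:
    """Mean up-crossing rate nu+(level): transitions from <= level to
    > level between consecutive samples, per unit time."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least two samples")
    if not duration > 0:
        raise ValueError("duration must be positive")
    crossings = np.count_nonzero((values[:-1] <= level) & (values[1:] > level))
    return crossings / duration


def upcrossing_nonexceedance(rate: float, duration: float) -> float:
    """P(level) ~= exp(-nu+ * T), the k = 1 continuous-time analogue."""
    return float(np.exp(-rate * duration))


def mixture_longterm(mix: MixtureSpec) -> ExceedanceCurve:
    """Long-term p_k as the probability-weighted sum of per-state curves.

    Counts are not meaningful after mixing and are set to -1."""
    ref = mix.curves[0]
    p = np.zeros_like(ref.p)
    for q, c in zip(mix.weights, mix.curves):
        p = p + q * c.p
    sentinel = np.full(ref.lambdas.size, -1, dtype=np.int64)
    return ExceedanceCurve(
        k=ref.k,
        lambdas=ref.lambdas.copy(),
        p=p,
        n_cond=sentinel,
        n_exc=sentinel.copy(),
        N=ref.N,
    )
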