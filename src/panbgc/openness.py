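"""Pangenome-openness metrics for gene cluster families.

Three accumulation metrics are computed over random orderings of the
family's members:

* ``gene_repertoire`` — cumulative count of distinct ortholog groups after
  sampling x BGCs (does the total gene repertoire keep growing?);
* ``composition`` — cumulative count of distinct OG presence-sets (do new
  members deploy novel combinations of known genes, regardless of gene
  order and copy number?);
* ``novel_gene`` — rate at which never-before-seen OGs appear; by default
  this counts distinct OGs at first appearance (coinciding with the
  repertoire curve), with an alternative mode counting every gene copy of
  a first-seen OG.

Mean curves are fitted to Heaps' law, y = k * x^gamma, by three methods
(log–log OLS, weighted log–log emphasizing later points, and bounded
non-linear least squares), the fit with the highest linear-scale R^2 is
kept, and gamma is binned into closed (< 0.3), intermediate (0.3–0.6) or
open (> 0.6). Families need at least three members; smaller families are
refused because gamma cannot be estimated reliably.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .exceptions import TooFewMembersError
from .pangenome import PresenceAbsenceMatrix, build_presence_absence

METRICS = ("gene_repertoire", "composition", "novel_gene")

CLOSED = "closed"
INTERMEDIATE = "intermediate"
OPEN = "open"

#: gamma thresholds for openness categories (strict < 0.3 closed, > 0.6 open)
CLOSED_BELOW = 0.3
OPEN_ABOVE = 0.6


@dataclass
class AccumulationCurve:
    """Per-permutation and mean cumulative counts for one metric."""

    metric: str
    x: np.ndarray  # 1..n
    per_permutation_y: np.ndarray  # shape (P, n)
    n_permutations: int
    seed: int
    exhaustive: bool

    @property
    def mean_y(self) -> np.ndarray:
        return self.per_permutation_y.mean(axis=0)


@dataclass
class FitConfig:
    """Knobs of the Heaps'-law fit.

    ``weight_rule`` maps the x vector to regression weights for the
    weighted method (default: w_i = x_i, so later sampling points count
    more). ``gamma_bounds`` constrain the non-linear fit; exponents above 2
    are already pathological for accumulation data.
    """

    weight_rule: Union[str, Callable[[np.ndarray], np.ndarray]] = "x"
    nls_max_iterations: int = 200
    nls_tolerance: float = 1e-10
    gamma_bounds: tuple[float, float] = (0.0, 2.0)
    k_lower_bound: float = 1e-9

    def __post_init__(self) -> None:
        lo, hi = self.gamma_bounds
        if not lo < hi:
            raise ValueError("gamma_bounds must be well-ordered")
        if self.nls_tolerance <= 0:
            raise ValueError("nls_tolerance must be positive")
        if self.k_lower_bound <= 0:
            raise ValueError("k_lower_bound must be positive")

    def weights(self, x: np.ndarray) -> np.ndarray:
        if callable(self.weight_rule):
            w = np.asarray(self.weight_rule(x), dtype=float)
        elif self.weight_rule == "x":
            w = x.astype(float)
        elif self.weight_rule == "x2":
            w = x.astype(float) ** 2
        elif self.weight_rule == "sqrt":
            w = np.sqrt(x.astype(float))
        else:
            raise ValueError(f"unknown weight rule {self.weight_rule!r}")
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        return w


@dataclass
class HeapsFit:
    """Fitted parameters of y = k * x^gamma for one method."""

    k: float
    gamma: float
    r2: float
    method: str
    converged: bool = True

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.k * np.asarray(x, dtype=float) ** self.gamma


@dataclass
class MetricOpenness:
    """Best fit and category for one metric."""

    metric: str
    best: HeapsFit
    fits: dict[str, HeapsFit]
    category: str
    curve: AccumulationCurve
    per_permutation_gamma: Optional[dict] = None


@dataclass
class OpennessResult:
    """Per-metric openness of one family plus provenance."""

    gcf_id: str
    n_bgcs: int
    n_permutations: int
    seed: int
    metrics: dict[str, MetricOpenness] = field(default_factory=dict)


@dataclass
class RankTestResult:
    """Tie-corrected Kruskal–Wallis statistic with chi-squared p-value."""

    H: float
    p: float
    group_sizes: list[int]


# ---------------------------------------------------------------------------
# Accumulation curves


def _curve_row(
    order: Sequence[int],
    presence_rows: list[frozenset],
    count_rows: list[dict],
    metric: str,
    novel_mode: str,
    composition_multiset: bool,
    multiset_rows: list[tuple],
) -> list[int]:
    y = []
    if metric == "gene_repertoire" or (metric == "novel_gene" and novel_mode == "og"):
        seen: set = set()
        for i in order:
            seen |= presence_rows[i]
            y.append(len(seen))
    elif metric == "novel_gene":  # copy-counting variant
        seen = set()
        total = 0
        for i in order:
            fresh = presence_rows[i] - seen
            total += sum(count_rows[i][og] for og in fresh)
            seen |= presence_rows[i]
            y.append(total)
    elif metric == "composition":
        combos: set = set()
        for i in order:
            key = multiset_rows[i] if composition_multiset else presence_rows[i]
            combos.add(key)
            y.append(len(combos))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return y


def accumulation_curve(
    matrix: PresenceAbsenceMatrix,
    metric: str,
    n_permutations: int = 30,
    seed: int = 0,
    novel_mode: str = "og",
    composition_multiset: bool = False,
) -> AccumulationCurve:
    """Compute one accumulation curve over member-sampling permutations.

    When n! <= ``n_permutations`` the full permutation set is enumerated
    once each (``exhaustive=True``), removing Monte-Carlo noise for the
    small families that dominate real data; otherwise that many uniform
    random orders are drawn from ``numpy.random.default_rng(seed)``.

    ``novel_mode`` selects between counting distinct OGs at first
    appearance (``"og"``, the default) and counting every gene copy
    belonging to a first-seen OG (``"copies"``). ``composition_multiset``
    makes the combination metric distinguish copy numbers.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if novel_mode not in ("og", "copies"):
        raise ValueError("novel_mode must be 'og' or 'copies'")
    n = matrix.n_bgcs
    if n < 3:
        raise TooFewMembersError(n)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    presence_rows = matrix.presence_sets()
    count_rows = [
        {og: int(c) for og, c in zip(matrix.og_ids, matrix.counts[i]) if c > 0}
        for i in range(n)
    ]
    multiset_rows = [
        tuple(sorted(count_rows[i].items())) for i in range(n)
    ]

    exhaustive = math.factorial(n) <= n_permutations
    if exhaustive:
        orders = list(iter_permutations(range(n)))
    else:
        rng = np.random.default_rng(seed)
        orders = [tuple(rng.permutation(n)) for _ in range(n_permutations)]

    rows = [
        _curve_row(
            order,
            presence_rows,
            count_rows,
            metric,
            novel_mode,
            composition_multiset,
            multiset_rows,
        )
        for order in orders
    ]
    return AccumulationCurve(
        metric=metric,
        x=np.arange(1, n + 1),
        per_permutation_y=np.asarray(rows, dtype=float),
        n_permutations=len(orders),
        seed=seed,
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# Heaps' law fitting


def _linear_r2(x: np.ndarray, y: np.ndarray, k: float, gamma: float) -> float:
    pred = k * x.astype(float) ** gamma
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        # zero-variance curve: a perfect constant fit scores 1, anything else 0
        return 1.0 if sse <= 1e-12 * max(1.0, float(np.sum(y**2))) else 0.0
    return 1.0 - sse / sst


def _loglog_estimate(
    x: np.ndarray, y: np.ndarray, w: Optional[np.ndarray] = None
) -> tuple[float, float]:
    lx, ly = np.log(x.astype(float)), np.log(y.astype(float))
    if w is None:
        slope, intercept = np.polyfit(lx, ly, 1)
    else:
        # np.polyfit weights multiply residuals, so sqrt(w) yields the
        # weighted least squares solution for sum w_i * resid_i^2
        slope, intercept = np.polyfit(lx, ly, 1, w=np.sqrt(w))
    return float(np.exp(intercept)), float(slope)


def fit_heaps(
    y: Sequence[float],
    method: str,
    config: Optional[FitConfig] = None,
    x: Optional[Sequence[float]] = None,
) -> HeapsFit:
    """Fit y = k * x^gamma to curve values at x = 1..n by one method.

    ``loglog`` is ordinary least squares of log y on log x; ``weighted``
    the same regression with increasing weights (default w_i = x_i);
    ``nls`` bounded non-linear least squares on the original scale,
    initialized from the log–log estimate. All methods report R^2 on the
    linear scale so their fits are comparable.
    """
    config = config or FitConfig()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise TooFewMembersError(n)
    if (y <= 0).any():
        raise ValueError("all curve values must be positive for a Heaps fit")
    x = np.arange(1, n + 1, dtype=float) if x is None else np.asarray(x, dtype=float)
    if len(x) != n or (x <= 0).any():
        raise ValueError("x must be positive and match y in length")

    converged = True
    if method == "loglog":
        k, gamma = _loglog_estimate(x, y)
    elif method == "weighted":
        k, gamma = _loglog_estimate(x, y, config.weights(x))
    elif method == "nls":
        k0, g0 = _loglog_estimate(x, y)
        glo, ghi = config.gamma_bounds
        k0 = max(k0, config.k_lower_bound)
        g0 = min(max(g0, glo), ghi)
        result = optimize.least_squares(
            lambda p: p[0] * x ** p[1] - y,
            x0=[k0, g0],
            bounds=([config.k_lower_bound, glo], [np.inf, ghi]),
            xtol=config.nls_tolerance,
            ftol=config.nls_tolerance,
            gtol=config.nls_tolerance,
            max_nfev=config.nls_max_iterations,
        )
        k, gamma = float(result.x[0]), float(result.x[1])
        if not result.success:
            converged = False
            warnings.warn(
                f"non-linear Heaps fit did not converge: {result.message}",
                RuntimeWarning,
                stacklevel=2,
            )
    else:
        raise ValueError("method must be loglog, weighted or nls")

    return HeapsFit(
        k=max(k, config.k_lower_bound),
        gamma=gamma,
        r2=_linear_r2(x, y, max(k, config.k_lower_bound), gamma),
        method=method,
        converged=converged,
    )


_METHOD_PRIORITY = {"loglog": 0, "weighted": 1, "nls": 2}


def select_best_fit(fits: Sequence[HeapsFit]) -> HeapsFit:
    """Keep the fit with the highest linear-scale R^2; exact ties go to
    loglog, then weighted, then nls."""
    if not fits:
        raise ValueError("no fits supplied")
    return max(fits, key=lambda f: (f.r2, -_METHOD_PRIORITY[f.method]))


def categorize_openness(gamma: float) -> str:
    """Bin a Heaps exponent: closed (< 0.3), intermediate (0.3–0.6
    inclusive on both ends), open (> 0.6)."""
    if not math.isfinite(gamma):
        raise ValueError("gamma must be finite")
    if gamma < CLOSED_BELOW:
        return CLOSED
    if gamma > OPEN_ABOVE:
        return OPEN
    return INTERMEDIATE


# ---------------------------------------------------------------------------
# Family-level driver


def analyze_openness(
    source: Union[PresenceAbsenceMatrix, "object"],
    n_permutations: int = 30,
    seed: int = 0,
    config: Optional[FitConfig] = None,
    metrics: Sequence[str] = METRICS,
    novel_mode: str = "og",
    composition_multiset: bool = False,
    fit_per_permutation: bool = False,
    gcf_id: str = "",
) -> OpennessResult:
    """Run the full openness analysis for one family.

    ``source`` may be a presence–absence matrix or a GCF with total
    ortholog assignment. For each requested metric the accumulation curve
    is built, its mean fitted by all three methods, the best fit selected
    by linear-scale R^2 and categorized. ``fit_per_permutation`` adds the
    median and spread of per-permutation gamma values for diagnostics.
    """
    if isinstance(source, PresenceAbsenceMatrix):
        matrix = source
    else:
        matrix = build_presence_absence(source)
        gcf_id = gcf_id or source.gcf_id
    config = config or FitConfig()
    if matrix.n_bgcs < 3:
        raise TooFewMembersError(matrix.n_bgcs)

    result = OpennessResult(
        gcf_id=gcf_id,
        n_bgcs=matrix.n_bgcs,
        n_permutations=n_permutations,
        seed=seed,
    )
    for metric in metrics:
        curve = accumulation_curve(
            matrix,
            metric,
            n_permutations=n_permutations,
            seed=seed,
            novel_mode=novel_mode,
            composition_multiset=composition_multiset,
        )
        fits = {
            m: fit_heaps(curve.mean_y, m, config, x=curve.x)
            for m in ("loglog", "weighted", "nls")
        }
        best = select_best_fit(list(fits.values()))
        per_perm = None
        if fit_per_permutation:
            gammas = [
                fit_heaps(row, best.method, config, x=curve.x).gamma
                for row in curve.per_permutation_y
            ]
            per_perm = {
                "gamma_median": float(np.median(gammas)),
                "gamma_iqr": float(
                    np.percentile(gammas, 75) - np.percentile(gammas, 25)
                ),
                "gamma_values": [float(g) for g in gammas],
            }
        result.metrics[metric] = MetricOpenness(
            metric=metric,
            best=best,
            fits=fits,
            category=categorize_openness(best.gamma),
            curve=curve,
            per_permutation_gamma=per_perm,
        )
    return result


# ---------------------------------------------------------------------------
# Kruskal–Wallis comparison of gamma distributions


def compare_gamma_distributions(groups: Sequence[Sequence[float]]) -> RankTestResult:
    """Tie-corrected Kruskal–Wallis rank-sum test across >= 2 groups of
    gamma values, with the chi-squared upper-tail p at (groups - 1)
    degrees of freedom.

    Computed from the rank formula directly so that fully tied data (all
    values identical) yields H = 0 rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes):
        raise ValueError("every group must contain at least one value")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    if n_total < 3:
        raise ValueError("need at least three values in total")

    ranks = stats.rankdata(pooled)
    h = 0.0
    offset = 0
    for size in sizes:
        r_sum = ranks[offset : offset + size].sum()
        h += r_sum**2 / size
        offset += size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    denom = 1.0 - tie_term / (n_total**3 - n_total)
    if denom == 0.0:
        # every value identical: no rank information, H is 0 by convention
        return RankTestResult(H=0.0, p=1.0, group_sizes=sizes)
    h /= denom
    h = max(h, 0.0)
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return RankTestResult(H=float(h), p=p, group_sizes=sizes)
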