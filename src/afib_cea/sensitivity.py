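"""One-way (tornado) and probabilistic sensitivity analyses.

One-way analysis re-runs the cohort model with a single parameter set to
its lower and upper plausible bound and records the reference-vs-comparator
ICER swing.  The probabilistic analysis is second-order Monte Carlo:
parameter uncertainty only, with probabilities and utilities drawn from
beta distributions and costs from log-normal distributions fitted by the
method of moments to the published base value and range (the range is read
as a 95% interval, so sd = (high - low) / 3.92).  Outputs include the
cost-effectiveness acceptability curve (CEAC) and the incremental
cost-effectiveness plane scatter with a coverage ellipse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cea
from .engine import run_strategy, run_all_strategies
from .parameters import (
    ModelInputs,
    ParameterRange,
    Strategy,
    canonical_strategy,
    get_parameter,
    parameter_kind,
    ranged_parameter_ids,
    set_parameter,
    validate,
)

# a published (low, high) range is read as a central 95% interval
RANGE_Z = 3.92


class DistributionError(ValueError):
    """Raised when a range cannot be matched by the requested family."""


@dataclass
class TornadoEntry:
    """One bar of the tornado diagram."""

    parameter: str
    low: float
    high: float
    icer_at_low: float | str
    icer_at_high: float | str
    base_icer: float | str
    swing: float
    degenerate: bool = False


def _pair_icer(inputs: ModelInputs, reference: Strategy, comparator: Strategy):
    ref = run_strategy(inputs, reference)
    comp = run_strategy(inputs, comparator)
    return cea.icer(ref, comp)


def one_way_sensitivity(inputs: ModelInputs,
                        parameters: Sequence[str] | None = None,
                        reference="rivaroxaban",
                        comparator="warfarin") -> list[TornadoEntry]:
    """Tornado analysis over the given parameter identifiers.

    ``parameters`` defaults to every identifier with a non-degenerate
    range.  Each parameter is set to its low and high bound in turn (all
    others at base) and the reference-vs-comparator ICER recorded; entries
    come back sorted by decreasing swing.  A dominance flag at either bound
    marks maximal influence (infinite swing).
    """
    reference = canonical_strategy(reference)
    comparator = canonical_strategy(comparator)
    if reference == comparator:
        raise ValueError("reference and comparator must differ")
    if parameters is None:
        parameters = ranged_parameter_ids(inputs)
    for pid in parameters:
        if pid not in inputs.ranges:
            raise KeyError(f"parameter {pid!r} has no range; ranged parameters: "
                           f"{ranged_parameter_ids(inputs)}")

    base_icer = _pair_icer(inputs, reference, comparator)

    entries = []
    for pid in parameters:
        rng = inputs.ranges[pid]
        if rng.degenerate:
            entries.append(TornadoEntry(pid, rng.low, rng.high, base_icer,
                                        base_icer, base_icer, 0.0,
                                        degenerate=True))
            continue
        vals = []
        for bound in (rng.low, rng.high):
            probe = inputs.copy()
            set_parameter(probe, pid, bound)
            vals.append(_pair_icer(probe, reference, comparator))
        lo, hi = vals
        if isinstance(lo, str) or isinstance(hi, str):
            swing = math.inf
        else:
            swing = abs(hi - lo)
        entries.append(TornadoEntry(pid, rng.low, rng.high, lo, hi,
                                    base_icer, swing))

    entries.sort(key=lambda e: -e.swing)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter,
        "low_bound": e.low,
        "high_bound": e.high,
        "icer_at_low": e.icer_at_low,
        "icer_at_high": e.icer_at_high,
        "base_icer": e.base_icer,
        "swing": e.swing,
    } for e in entries])


# ---------------------------------------------------------------------------
# PSA distributions
# ---------------------------------------------------------------------------

@dataclass
class PSADistribution:
    """A fitted second-order distribution for one parameter.

    ``family`` is ``"beta"``, ``"lognormal"`` or ``"fixed"``; ``params``
    holds (alpha, beta) or (mu, sigma) respectively.
    """

    family: str
    mean: float
    sd: float
    params: tuple[float, ...]
    parameter: str | None = None

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "fixed":
            return (np.full(size, self.mean) if size is not None else self.mean)
        if self.family == "beta":
            a, b = self.params
            return rng.beta(a, b, size=size)
        mu, sigma = self.params
        return rng.lognormal(mean=mu, sigma=sigma, size=size)


def fit_psa_distribution(prange: ParameterRange, family: str,
                         parameter: str | None = None) -> PSADistribution:
    """Method-of-moments fit with mean = base and sd = range width / 3.92.

    Beta: alpha = m(m(1-m)/v - 1), beta = (1-m)(m(1-m)/v - 1).
    Log-normal: sigma^2 = ln(1 + v/m^2), mu = ln m - sigma^2 / 2.
    A degenerate range yields the ``fixed`` family.
    """
    if not (prange.low <= prange.base <= prange.high):
        raise DistributionError(f"invalid range ({prange.low}, {prange.base}, "
                                f"{prange.high})")
    m = prange.base
    sd = prange.width / RANGE_Z
    if sd == 0 or family == "fixed":
        return PSADistribution("fixed", m, 0.0, (), parameter)
    v = sd * sd
    if family == "beta":
        if not (0.0 < m < 1.0):
            raise DistributionError(f"beta mean must be in (0,1), got {m}")
        if v >= m * (1.0 - m):
            raise DistributionError(
                f"variance infeasible for beta (v={v:.6g} >= m(1-m)={m*(1-m):.6g})")
        nu = m * (1.0 - m) / v - 1.0
        return PSADistribution("beta", m, sd, (m * nu, (1.0 - m) * nu), parameter)
    if family == "lognormal":
        if m <= 0:
            raise DistributionError("lognormal mean must be positive")
        sigma2 = math.log(1.0 + v / (m * m))
        mu = math.log(m) - sigma2 / 2.0
        return PSADistribution("lognormal", m, sd, (mu, math.sqrt(sigma2)), parameter)
    raise DistributionError(f"unknown distribution family {family!r}")


_KIND_FAMILY = {"probability": "beta", "utility": "beta", "cost": "lognormal"}


def default_family(pid: str) -> str:
    """beta for probabilities and utilities, lognormal for costs."""
    return _KIND_FAMILY[parameter_kind(pid)]


def fit_all_distributions(inputs: ModelInputs) -> dict[str, PSADistribution]:
    """Fitted distribution for every parameter (fixed when unranged)."""
    out = {}
    for pid, rng in inputs.ranges.items():
        family = "fixed" if rng.degenerate else default_family(pid)
        out[pid] = fit_psa_distribution(rng, family, parameter=pid)
    return out


# ---------------------------------------------------------------------------
# PSA sampling and runs
# ---------------------------------------------------------------------------

_MAX_REPAIR_ATTEMPTS = 100


def sample_psa(inputs: ModelInputs, n_draws: int, seed: int) -> list[ModelInputs]:
    """Draw ``n_draws`` complete parameter sets for second-order Monte Carlo.

    Every non-fixed parameter is drawn independently from its fitted
    distribution; severity splits are renormalized to sum to 1 after
    drawing.  A draw that still fails validation (for example inverted
    state utilities from overlapping ranges) is redrawn, up to 100 attempts
    per draw.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    dists = fit_all_distributions(inputs)
    active = [(pid, d) for pid, d in dists.items() if d.family != "fixed"]

    samples = []
    for _ in range(n_draws):
        for attempt in range(_MAX_REPAIR_ATTEMPTS):
            draw = inputs.copy()
            for pid, dist in active:
                set_parameter(draw, pid, float(dist.sample(rng)))
            draw.is_split.normalize()
            draw.ich_split.normalize()
            if validate(draw).ok:
                samples.append(draw)
                break
        else:
            raise RuntimeError(
                f"could not draw a valid parameter set in {_MAX_REPAIR_ATTEMPTS} attempts")
    return samples


@dataclass
class PSAOutcomes:
    """Per-draw strategy outcomes from the second-order Monte Carlo run."""

    strategies: list[str]
    costs: np.ndarray   # (n_draws, n_strategies)
    qalys: np.ndarray   # (n_draws, n_strategies)
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def column(self, strategy: str) -> int:
        return self.strategies.index(str(canonical_strategy(strategy)))

    def to_frame(self) -> pd.DataFrame:
        data = {"draw": np.arange(self.n_draws)}
        for j, s in enumerate(self.strategies):
            data[f"cost_{s}"] = self.costs[:, j]
            data[f"qaly_{s}"] = self.qalys[:, j]
        return pd.DataFrame(data)


def run_psa(samples: Sequence[ModelInputs], config=None,
            seed: int | None = None) -> PSAOutcomes:
    """Run the deterministic cohort engine once per sampled parameter set
    per strategy (second-order uncertainty only; no patient-level noise)."""
    if not samples:
        raise ValueError("samples must be nonempty")
    strategies = [s.value for s in Strategy]
    n = len(samples)
    costs = np.empty((n, len(strategies)))
    qalys = np.empty((n, len(strategies)))
    for i, draw in enumerate(samples):
        if config is not None:
            draw = draw.copy()
            draw.run = config
        for j, s in enumerate(strategies):
            o = run_strategy(draw, s)
            costs[i, j] = o.total_cost
            qalys[i, j] = o.total_qaly
    return PSAOutcomes(strategies=strategies, costs=costs, qalys=qalys, seed=seed)


# ---------------------------------------------------------------------------
# CEAC and ICE scatter
# ---------------------------------------------------------------------------

@dataclass
class CEACCurve:
    """Probability each strategy is optimal (max NMB) along a WTP grid."""

    wtp_grid: np.ndarray               # (G,)
    probabilities: np.ndarray          # (G, n_strategies)
    strategies: list[str]

    def probability(self, strategy: str) -> np.ndarray:
        return self.probabilities[:, self.strategies.index(str(canonical_strategy(strategy)))]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities, columns=self.strategies)
        df.insert(0, "wtp", self.wtp_grid)
        return df


def ceac(psa: PSAOutcomes, wtp_grid) -> CEACCurve:
    """Acceptability: the fraction of draws in which each strategy attains
    the maximal net monetary benefit, ties split equally."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be nonempty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("wtp_grid must be ascending")
    n, k = psa.costs.shape
    probs = np.empty((grid.size, k))
    for g, lam in enumerate(grid):
        nmb = lam * psa.qalys - psa.costs
        best = nmb.max(axis=1, keepdims=True)
        winners = (nmb == best)
        weights = winners / winners.sum(axis=1, keepdims=True)
        probs[g] = weights.mean(axis=0)
    return CEACCurve(wtp_grid=grid, probabilities=probs,
                     strategies=list(psa.strategies))


@dataclass
class ICEScatter:
    """Incremental cost-effectiveness plane cloud with a coverage ellipse.

    The ellipse is the mean-centered Mahalanobis contour of the per-draw
    (ΔQALY, Δcost) sample at the chi-square(2) quantile of ``coverage``.
    """

    delta_qaly: np.ndarray
    delta_cost: np.ndarray
    coverage: float
    center: np.ndarray          # (2,)
    cov: np.ndarray             # (2, 2)
    chi2_quantile: float

    def ellipse_axes(self) -> tuple[np.ndarray, np.ndarray, float]:
        """(semi-axis lengths, eigenvectors, angle in degrees of the major
        axis); zero-length axes for a degenerate (all-identical) cloud."""
        evals, evecs = np.linalg.eigh(self.cov)
        evals = np.clip(evals, 0.0, None)
        semi = np.sqrt(evals * self.chi2_quantile)
        order = np.argsort(semi)[::-1]
        semi, evecs = semi[order], evecs[:, order]
        angle = math.degrees(math.atan2(evecs[1, 0], evecs[0, 0]))
        return semi, evecs, angle

    @property
    def ellipse_area(self) -> float:
        semi, _, _ = self.ellipse_axes()
        return math.pi * semi[0] * semi[1]

    def fraction_inside(self) -> float:
        """Empirical fraction of draws inside the ellipse (Mahalanobis
        distance squared <= the chi-square quantile)."""
        pts = np.column_stack([self.delta_qaly, self.delta_cost]) - self.center
        try:
            inv = np.linalg.inv(self.cov)
        except np.linalg.LinAlgError:
            return float(np.mean(np.all(pts == 0, axis=1)))
        d2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
        return float(np.mean(d2 <= self.chi2_quantile))


def ice_scatter(psa: PSAOutcomes, reference="rivaroxaban",
                comparator="warfarin", coverage: float = 0.95) -> "ICEScatter":
    """Per-draw incremental (ΔQALY, Δcost) pairs plus the coverage ellipse."""
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must be in (0, 1)")
    if psa.n_draws < 3:
        raise ValueError("need at least 3 draws to estimate the covariance")
    jr = psa.column(reference)
    jc = psa.column(comparator)
    dq = psa.qalys[:, jr] - psa.qalys[:, jc]
    dc = psa.costs[:, jr] - psa.costs[:, jc]
    pts = np.column_stack([dq, dc])
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    q = float(stats.chi2.ppf(coverage, df=2))
    return ICEScatter(delta_qaly=dq, delta_cost=dc, coverage=coverage,
                      center=center, cov=cov, chi2_quantile=q)
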