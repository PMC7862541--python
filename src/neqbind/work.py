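"""Work integration and bidirectional free-energy estimators.

A fast alchemical transition driven by linearly switching a coupling
parameter lambda from one end state to the other dissipates work; the
work values from an ensemble of such transitions, in both directions,
determine the equilibrium free energy difference through the Crooks
fluctuation theorem.  This module turns per-transition dH/dlambda series
into work values and work sets into free-energy estimates:

* :func:`estimate_cft_ml` — the maximum-likelihood (Bennett acceptance
  ratio) estimator from bidirectional work samples, the primary method;
* :func:`estimate_jarzynski` — exponential averaging of one direction;
* :func:`estimate_cgi` — Crooks Gaussian intersection.

Sign convention: reverse works are stored exactly as measured along the
1->0 transition, i.e. *not* pre-negated.  Estimators negate them
internally where the theory requires the work along 0->1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .constants import beta as _beta

__all__ = [
    "DhdlSeries",
    "WorkSet",
    "FreeEnergyEstimate",
    "NonOverlappingWorkError",
    "integrate_work",
    "estimate_cft_ml",
    "estimate_jarzynski",
    "estimate_cgi",
    "bootstrap_stderr",
]

Direction = Literal["forward", "reverse"]


class NonOverlappingWorkError(RuntimeError):
    """The forward and reverse work distributions do not overlap enough
    for a numerically meaningful maximum-likelihood solution."""


@dataclass(frozen=True)
class DhdlSeries:
    """One alchemical transition: dH/dlambda sampled along lambda.

    ``lambda_values`` follow the file order of the transition:
    0 -> 1 for forward series and 1 -> 0 for reverse series.  The work
    reported by :func:`integrate_work` is always the work along the
    series' own path.
    """

    lambda_values: np.ndarray
    dhdl_values: np.ndarray
    direction: Direction = "forward"

    def __post_init__(self):
        lam = np.asarray(self.lambda_values, dtype=float)
        dhdl = np.asarray(self.dhdl_values, dtype=float)
        object.__setattr__(self, "lambda_values", lam)
        object.__setattr__(self, "dhdl_values", dhdl)
        if lam.ndim != 1 or dhdl.ndim != 1 or lam.size != dhdl.size:
            raise ValueError("lambda and dH/dlambda must be 1-D of equal length")
        if lam.size < 2:
            raise ValueError("a dH/dlambda series needs at least 2 points")
        if not (np.isfinite(lam).all() and np.isfinite(dhdl).all()):
            raise ValueError("non-finite value in dH/dlambda series")
        diffs = np.diff(lam)
        if self.direction == "forward":
            if np.any(diffs < 0):
                raise ValueError("forward series must have non-decreasing lambda")
            if not (abs(lam[0]) < 1e-6 and abs(lam[-1] - 1.0) < 1e-6):
                raise ValueError("forward series must run lambda from 0 to 1")
        elif self.direction == "reverse":
            if np.any(diffs > 0):
                raise ValueError("reverse series must have non-increasing lambda")
            if not (abs(lam[0] - 1.0) < 1e-6 and abs(lam[-1]) < 1e-6):
                raise ValueError("reverse series must run lambda from 1 to 0")
        else:
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class WorkSet:
    """Bidirectional non-equilibrium work samples at one temperature.

    ``reverse_works`` are measured along the 1->0 transition (raw engine
    output, not negated).
    """

    forward_works: np.ndarray
    reverse_works: np.ndarray
    temperature: float = 300.15

    def __post_init__(self):
        fwd = np.atleast_1d(np.asarray(self.forward_works, dtype=float))
        rev = np.atleast_1d(np.asarray(self.reverse_works, dtype=float))
        object.__setattr__(self, "forward_works", fwd)
        object.__setattr__(self, "reverse_works", rev)
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name, arr in (("forward", fwd), ("reverse", rev)):
            if arr.size and not np.isfinite(arr).all():
                bad = np.flatnonzero(~np.isfinite(arr))
                raise ValueError(
                    f"non-finite {name} work value(s) at index {bad.tolist()}"
                )

    @property
    def n_forward(self) -> int:
        return int(self.forward_works.size)

    @property
    def n_reverse(self) -> int:
        return int(self.reverse_works.size)


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A free-energy difference with uncertainty and provenance."""

    dg: float
    stderr: float
    method: str
    n_forward: int = 0
    n_reverse: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")


def integrate_work(series: DhdlSeries) -> float:
    """Trapezoidal work integral of dH/dlambda along the series' path.

    Forward series give the work along 0->1; reverse series give the
    work along 1->0 (no sign flip is applied — the lambda path of a
    reverse series already runs downhill).
    """
    return float(np.trapezoid(series.dhdl_values, series.lambda_values))


def _bar_residual(dg: float, wf: np.ndarray, wr_neg: np.ndarray, beta: float) -> float:
    """Bennett self-consistency function; strictly increasing in dg.

    Root at the maximum-likelihood free energy.  ``wr_neg`` holds the
    negated reverse works (i.e. works expressed along 0->1).
    """
    nf, nr = wf.size, wr_neg.size
    log_ratio = np.log(nf / nr)
    # 1/(1 + (nf/nr) exp(beta(Wf - dg)))   via stable sigmoid
    xf = log_ratio + beta * (wf - dg)
    xr = -log_ratio - beta * (wr_neg - dg)
    with np.errstate(over="ignore"):
        sf = 1.0 / (1.0 + np.exp(xf))
        sr = 1.0 / (1.0 + np.exp(xr))
    return float(sf.sum() - sr.sum())


def _bar_analytic_variance(
    dg: float, wf: np.ndarray, wr_neg: np.ndarray, beta: float
) -> float:
    """Asymptotic variance of the Bennett/ML estimate (Fermi-overlap form)."""
    nf, nr = wf.size, wr_neg.size
    n = nf + nr
    m = np.log(nf / nr) / beta
    xf = beta * (m + wf - dg)
    xr = beta * (m + wr_neg - dg)
    x = np.concatenate([xf, xr])
    # f(1-f) for the logistic f equals 1/(2 + 2 cosh x)
    mean_ff = float(np.mean(1.0 / (2.0 + 2.0 * np.cosh(np.clip(x, -500, 500)))))
    if mean_ff <= 0:
        return np.inf
    var = (1.0 / mean_ff - (n / nf + n / nr)) / (beta**2 * n)
    return max(var, 0.0)


def estimate_cft_ml(works: WorkSet) -> FreeEnergyEstimate:
    """Maximum-likelihood free energy from bidirectional works (BAR).

    Solves the Bennett acceptance-ratio self-consistency equation,
    which maximizes the Crooks-theorem likelihood of the observed
    forward and reverse work samples, including the sample-count offset
    M = ln(n_f/n_r)/beta.  The root is bracketed by the pooled work
    range (geometrically expanded up to 10x) and polished to
    |residual| < 1e-10; the returned uncertainty is the standard
    asymptotic ML variance.

    Raises :class:`NonOverlappingWorkError` when no bracket contains
    the root — the signature of non-overlapping work distributions.
    """
    if works.n_forward < 1 or works.n_reverse < 1:
        raise ValueError("CFT-ML needs at least one work sample per direction")
    b = _beta(works.temperature)
    wf = works.forward_works
    wr_neg = -works.reverse_works
    pooled = np.concatenate([wf, wr_neg])
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi - lo < 1e-12:
        lo, hi = lo - 1.0, hi + 1.0
    width = hi - lo
    for expand in range(5):
        if _bar_residual(lo, wf, wr_neg, b) * _bar_residual(hi, wf, wr_neg, b) <= 0:
            break
        pad = width * (2.0**expand)
        lo, hi = lo - pad, hi + pad
        if hi - lo > 10.0 * width * 2 + width:
            break
    else:
        pass
    if _bar_residual(lo, wf, wr_neg, b) * _bar_residual(hi, wf, wr_neg, b) > 0:
        raise NonOverlappingWorkError(
            "no root in expanded work bracket "
            f"[{lo:.3f}, {hi:.3f}] kJ/mol: forward and reverse work "
            "distributions do not overlap; the estimate would be an "
            "extrapolation"
        )
    dg = brentq(_bar_residual, lo, hi, args=(wf, wr_neg, b), xtol=1e-12, rtol=1e-15)
    # polish against the stated residual tolerance
    res = _bar_residual(dg, wf, wr_neg, b)
    if abs(res) > 1e-10:
        dg = brentq(
            _bar_residual, dg - 1e-6, dg + 1e-6, args=(wf, wr_neg, b), xtol=1e-14
        )
    # overlap diagnostic: mean Fermi product f(1-f) vanishes when no
    # sample sits in the crossover region, making the root meaningless
    n = wf.size + wr_neg.size
    m = np.log(wf.size / wr_neg.size) / b
    x = b * (m + np.concatenate([wf, wr_neg]) - dg)
    overlap = float(np.mean(1.0 / (2.0 + 2.0 * np.cosh(np.clip(x, -500, 500)))))
    if overlap < 1e-10:
        raise NonOverlappingWorkError(
            "forward and reverse work distributions do not overlap "
            f"(mean Fermi overlap {overlap:.2e} at dG = {dg:.2f} kJ/mol); "
            "the maximum-likelihood estimate is unreliable"
        )
    var = _bar_analytic_variance(dg, wf, wr_neg, b)
    return FreeEnergyEstimate(
        dg=float(dg),
        stderr=float(np.sqrt(var)),
        method="cft-ml",
        n_forward=works.n_forward,
        n_reverse=works.n_reverse,
    )


def estimate_jarzynski(
    works: Sequence[float] | np.ndarray,
    temperature: float = 300.15,
    direction: Direction = "forward",
    n_boot: int = 200,
    seed: int = 0,
) -> FreeEnergyEstimate:
    """Unidirectional exponential-average (Jarzynski) estimate.

    dG = -kT ln <exp(-beta W)> computed with log-sum-exp.  For reverse
    works (measured along 1->0) the estimate of the 0->1 free energy is
    +kT ln <exp(-beta W_rev)> applied to the measured values, i.e. the
    negated estimate of the reverse transition.  Uncertainty is a
    bootstrap standard error (biased low for strongly dissipative
    work distributions, as is inherent to the estimator).
    """
    w = np.atleast_1d(np.asarray(works, dtype=float))
    if w.size == 0:
        raise ValueError("Jarzynski estimator needs at least one work sample")
    if not np.isfinite(w).all():
        raise ValueError("non-finite work value")
    b = _beta(temperature)

    def _jar(sample: np.ndarray) -> float:
        dg_path = -(logsumexp(-b * sample) - np.log(sample.size)) / b
        return dg_path if direction == "forward" else -dg_path

    dg = _jar(w)
    rng = np.random.default_rng(seed)
    if w.size > 1 and n_boot >= 2:
        boots = np.array(
            [_jar(rng.choice(w, size=w.size, replace=True)) for _ in range(n_boot)]
        )
        stderr = float(np.std(boots, ddof=1))
    else:
        stderr = 0.0
    return FreeEnergyEstimate(
        dg=float(dg),
        stderr=stderr,
        method="jarzynski",
        n_forward=w.size if direction == "forward" else 0,
        n_reverse=w.size if direction == "reverse" else 0,
    )


def _cgi_point(wf: np.ndarray, wr_neg: np.ndarray) -> float:
    """Gaussian-intersection point estimate from the two work samples."""
    mf, mr = float(np.mean(wf)), float(np.mean(wr_neg))
    vf, vr = float(np.var(wf, ddof=1)), float(np.var(wr_neg, ddof=1))
    if vf <= 0 or vr <= 0:
        raise ValueError("CGI requires non-zero work variance in both directions")
    if abs(vf - vr) < 1e-12 * max(vf, vr):
        return 0.5 * (mf + mr)
    # equate the two normal log-densities: quadratic in x
    a = 1.0 / vf - 1.0 / vr
    bq = -2.0 * (mf / vf - mr / vr)
    c = mf**2 / vf - mr**2 / vr + np.log(vf / vr)
    disc = bq**2 - 4 * a * c
    if disc < 0:
        raise RuntimeError("Gaussian intersection has no real solution")
    roots = ((-bq + np.sqrt(disc)) / (2 * a), (-bq - np.sqrt(disc)) / (2 * a))
    lo, hi = min(mf, mr), max(mf, mr)
    between = [r for r in roots if lo <= r <= hi]
    if between:
        return float(between[0])
    # pathological overlap: fall back to the root nearest the midpoint
    mid = 0.5 * (mf + mr)
    return float(min(roots, key=lambda r: abs(r - mid)))


def estimate_cgi(works: WorkSet, n_boot: int = 200, seed: int = 0) -> FreeEnergyEstimate:
    """Crooks Gaussian intersection estimate.

    Fits a normal distribution to the forward works and to the negated
    reverse works; under the Crooks theorem with Gaussian work
    distributions the two densities cross exactly at dG.  The root
    between the two means is selected; the equal-variance case has the
    analytic solution at the midpoint of the means.  Uncertainty is a
    bootstrap standard error over both directions.
    """
    if works.n_forward < 2 or works.n_reverse < 2:
        raise ValueError("CGI needs at least two work samples per direction")
    wf = works.forward_works
    wr_neg = -works.reverse_works
    dg = _cgi_point(wf, wr_neg)
    stderr = (
        bootstrap_stderr("cgi", works, n_boot=n_boot, seed=seed) if n_boot >= 2 else 0.0
    )
    return FreeEnergyEstimate(
        dg=float(dg),
        stderr=stderr,
        method="cgi",
        n_forward=works.n_forward,
        n_reverse=works.n_reverse,
    )


_ESTIMATORS = {
    "cft-ml": estimate_cft_ml,
    "cgi": estimate_cgi,
}


def estimate(works: WorkSet, method: str = "cft-ml") -> FreeEnergyEstimate:
    """Dispatch a bidirectional estimate by method tag."""
    if method == "jarzynski":
        return estimate_jarzynski(
            works.forward_works, temperature=works.temperature, direction="forward"
        )
    try:
        return _ESTIMATORS[method](works)
    except KeyError:
        raise ValueError(f"unknown estimator {method!r}") from None


def bootstrap_stderr(
    estimator: str, works: WorkSet, n_boot: int = 200, seed: int = 0
) -> float:
    """Bootstrap standard error of an estimator over a work set.

    Resamples with replacement within each direction independently;
    deterministic for a given seed.  Estimator failures on a resample
    are re-raised with the resample index attached.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if estimator not in ("cft-ml", "cgi", "jarzynski"):
        raise ValueError(f"unknown estimator {estimator!r}")
    rng = np.random.default_rng(seed)
    wf, wr = works.forward_works, works.reverse_works
    values = np.empty(n_boot)
    for i in range(n_boot):
        bf = rng.choice(wf, size=wf.size, replace=True)
        br = rng.choice(wr, size=wr.size, replace=True)
        resampled = dataclasses.replace(works, forward_works=bf, reverse_works=br)
        try:
            if estimator == "cft-ml":
                values[i] = estimate_cft_ml(resampled).dg
            elif estimator == "cgi":
                values[i] = _cgi_point(bf, -br)
            elif estimator == "jarzynski":
                values[i] = estimate_jarzynski(
                    bf, temperature=works.temperature, n_boot=0, seed=0
                ).dg
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
        except (NonOverlappingWorkError, RuntimeError, ValueError) as exc:
            raise RuntimeError(f"estimator failed on bootstrap resample {i}") from exc
    return float(np.std(values, ddof=1))
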