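"""Univariate normal mixtures: EM fitting, bimodality LRT, class threshold.

A bimodal CpG O/E distribution — a mixture of a low-mean (historically
methylated) and a high-mean (unmethylated) normal component — is the
population-level signature of gene-body DNA methylation. This module fits
one- and two-component normal mixtures by maximum likelihood, tests
bimodality with the statistic G² = 2(ln L₂ − ln L₁) referred to a
chi-square distribution with 2 degrees of freedom, and solves for the
abscissa x* where the two weighted component densities intersect, which
is then used as the low/high classification threshold.

The 2-d.f. chi-square reference is the classical procedure for this
analysis; it ignores the boundary non-regularity of mixture LRTs and is
kept as-is (see the methods note for the caveat).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-6  # O/E units squared; prevents component collapse on ties


@dataclass(frozen=True)
class MixtureFit:
    """A fitted k-component univariate normal mixture.

    Components are sorted by ascending mean; ``weights`` sum to 1.
    ``loglik`` is the maximized log-likelihood of the raw values.
    """

    k: int
    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    loglik: float
    n: int
    converged: bool
    n_iter: int

    def __post_init__(self):
        assert len(self.weights) == len(self.means) == len(self.sds) == self.k
        assert abs(sum(self.weights) - 1.0) < 1e-12
        assert all(s > 0 for s in self.sds)
        assert all(
            self.means[i] <= self.means[i + 1] for i in range(self.k - 1)
        ), "components must be sorted by mean"


@dataclass(frozen=True)
class BimodalityTest:
    """Likelihood-ratio test of two components against one.

    g2 = 2(lnL2 - lnL1) clipped at zero; p is the chi-square(df=2)
    upper-tail probability at g2.
    """

    g2: float
    df: int
    p: float


@dataclass(frozen=True)
class ClassThreshold:
    """Density-intersection classification threshold x*.

    For method "intersection", w1*phi(x*; mu1, sd1) = w2*phi(x*; mu2, sd2)
    and mu1 < x* < mu2. If no intersection lies strictly between the
    means, the midpoint is returned with method "midpoint-fallback".
    """

    x_star: float
    method: str


def _clean(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    finite = np.isfinite(x)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("dropping %d non-finite values before mixture fit", n_dropped)
    return x[finite]


def _loglik_one(x: np.ndarray, mu: float, sd: float) -> float:
    return float(np.sum(stats.norm.logpdf(x, mu, sd)))


def _mixture_loglik(x, w, mu, sd) -> float:
    comp = np.log(w)[:, None] + stats.norm.logpdf(x[None, :], np.asarray(mu)[:, None], np.asarray(sd)[:, None])
    m = comp.max(axis=0)
    return float(np.sum(m + np.log(np.exp(comp - m).sum(axis=0))))


def _em_two(
    x: np.ndarray,
    w0: np.ndarray,
    mu0: np.ndarray,
    sd0: np.ndarray,
    tol: float,
    max_iter: int,
    equal_var: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int]:
    """EM for a two-component normal mixture from one initialization.

    With ``equal_var`` the components share one pooled variance (the
    classical common-variance mixture, which is what the 2-d.f. LRT
    assumes: the two-component model adds exactly a weight and a second
    mean over the single normal). The observed-data log-likelihood is
    checked to be non-decreasing at every iteration (a guaranteed
    property of EM; a violation beyond numerical slack indicates a
    defect and raises).
    """
    w, mu, var = w0.copy(), mu0.copy(), np.maximum(sd0**2, _VAR_FLOOR)
    ll = _mixture_loglik(x, w, mu, np.sqrt(var))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: responsibilities via log-sum-exp
        logp = np.log(w)[:, None] + stats.norm.logpdf(
            x[None, :], mu[:, None], np.sqrt(var)[:, None]
        )
        m = logp.max(axis=0)
        log_total = m + np.log(np.exp(logp - m).sum(axis=0))
        r = np.exp(logp - log_total[None, :])
        # M-step
        nk = r.sum(axis=1)
        w = nk / x.size
        mu = (r @ x) / nk
        if equal_var:
            pooled = float(
                (r * (x[None, :] - mu[:, None]) ** 2).sum() / x.size
            )
            var = np.maximum(np.full(2, pooled), _VAR_FLOOR)
        else:
            var = np.maximum((r @ x**2) / nk - mu**2, _VAR_FLOOR)
        ll_new = _mixture_loglik(x, w, mu, np.sqrt(var))
        if ll_new < ll - 1e-8 * max(1.0, abs(ll)):
            raise RuntimeError(
                f"EM log-likelihood decreased ({ll:.6f} -> {ll_new:.6f})"
            )
        rel = abs(ll_new - ll) / max(1.0, abs(ll))
        ll = ll_new
        if rel < tol:
            converged = True
            break
    return w, mu, np.sqrt(var), ll, converged, it


def fit_mixture(
    values,
    k: int = 2,
    seed: int = 0,
    restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 1000,
    equal_var: bool = True,
) -> MixtureFit:
    """Maximum-likelihood fit of a k-component (k = 1 or 2) normal mixture.

    k=1 is the closed-form MLE (sample mean, MLE standard deviation).
    k=2 runs EM from a quantile-split initialization plus ``restarts - 1``
    perturbed restarts and returns the best converged fit, components
    sorted by ascending mean. Non-finite values are dropped first.

    By default the two components share one variance — the model under
    which the bimodality LRT has its stated 2 degrees of freedom (the
    richer model adds only a mixing weight and a second mean); set
    ``equal_var=False`` for per-component variances.
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    x = _clean(values)
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} finite values for k={k}, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: degenerate (zero) variance")

    if k == 1:
        mu = float(x.mean())
        sd = float(math.sqrt(max(x.var(), _VAR_FLOOR)))  # MLE (ddof=0)
        return MixtureFit(
            k=1,
            weights=(1.0,),
            means=(mu,),
            sds=(sd,),
            loglik=_loglik_one(x, mu, sd),
            n=int(x.size),
            converged=True,
            n_iter=0,
        )

    rng = np.random.default_rng(seed)
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # heavy ties at the median
        lo, hi = np.sort(x)[: x.size // 2], np.sort(x)[x.size // 2 :]
    base_mu = np.array([lo.mean(), hi.mean()])
    base_sd = np.array(
        [max(lo.std(), math.sqrt(_VAR_FLOOR)), max(hi.std(), math.sqrt(_VAR_FLOOR))]
    )
    base_w = np.array([lo.size, hi.size], dtype=float) / x.size
    sx = x.std()

    best = None
    for r in range(max(1, restarts)):
        mu0 = base_mu if r == 0 else base_mu + rng.normal(0.0, 0.25 * sx, size=2)
        sd0 = np.full(2, sx) if equal_var else base_sd
        w, mu, sd, ll, conv, it = _em_two(
            x, base_w, mu0, sd0, tol, max_iter, equal_var=equal_var
        )
        cand = (conv, ll, w, mu, sd, it)
        if best is None:
            best = cand
        else:
            # prefer converged fits; among equals, higher log-likelihood
            if (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
    conv, ll, w, mu, sd, it = best
    # nestedness guard: the k=1 MLE is a point of the k=2 parameter space
    # (equal means/sds); if EM early-stopped below it on unimodal data,
    # return that degenerate representation so lnL2 >= lnL1 always holds
    mu1, sd1 = float(x.mean()), float(math.sqrt(max(x.var(), _VAR_FLOOR)))
    ll1 = _loglik_one(x, mu1, sd1)
    if ll < ll1:
        w = np.array([0.5, 0.5])
        mu = np.array([mu1, mu1])
        sd = np.array([sd1, sd1])
        ll, conv = ll1, True
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    w = w / w.sum()
    return MixtureFit(
        k=2,
        weights=tuple(float(v) for v in w),
        means=tuple(float(v) for v in mu),
        sds=tuple(float(v) for v in sd),
        loglik=ll,
        n=int(x.size),
        converged=bool(conv),
        n_iter=int(it),
    )


def lrt_bimodality(fit1: MixtureFit, fit2: MixtureFit) -> BimodalityTest:
    """G² likelihood-ratio test of bimodality (two components vs one).

    g2 = 2(lnL2 - lnL1), clipped at zero (the one-component model is
    nested, so a negative difference can only be numerical); the p-value
    is the chi-square upper tail with 2 degrees of freedom.
    """
    if fit1.k != 1 or fit2.k != 2:
        raise ValueError("expected fit1 with k=1 and fit2 with k=2")
    if fit1.n != fit2.n:
        raise ValueError(f"sample-size mismatch: {fit1.n} vs {fit2.n}")
    g2 = max(0.0, 2.0 * (fit2.loglik - fit1.loglik))
    return BimodalityTest(g2=g2, df=2, p=float(stats.chi2.sf(g2, df=2)))


def intersection_threshold(fit2: MixtureFit) -> ClassThreshold:
    """Intersection of the two weighted normal densities, between the means.

    Solves w1*phi(x; mu1, sd1) = w2*phi(x; mu2, sd2). Equal SDs give the
    closed form x* = (mu1+mu2)/2 + sd^2 ln(w1/w2)/(mu2-mu1); otherwise
    the equation is a quadratic in x and the root inside (mu1, mu2) is
    selected. If no root lies in that open interval the midpoint is
    returned with method "midpoint-fallback".
    """
    if fit2.k != 2:
        raise ValueError("intersection threshold requires a two-component fit")
    (w1, w2), (m1, m2), (s1, s2) = fit2.weights, fit2.means, fit2.sds
    if m1 == m2:
        raise ValueError("equal component means: no separating threshold")

    if abs(s1 - s2) < 1e-12:
        x = (m1 + m2) / 2.0 + s1**2 * math.log(w1 / w2) / (m2 - m1)
        if m1 < x < m2:
            return ClassThreshold(x_star=float(x), method="intersection")
        logger.warning(
            "density intersection %.6g outside (%.6g, %.6g); using midpoint", x, m1, m2
        )
        return ClassThreshold(x_star=(m1 + m2) / 2.0, method="midpoint-fallback")

    # ln w1 - ln s1 - (x-m1)^2/(2 s1^2) = ln w2 - ln s2 - (x-m2)^2/(2 s2^2)
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m2 / s2**2)
    c = (
        m2**2 / s2**2
        - m1**2 / s1**2
        + 2.0 * math.log((w1 * s2) / (w2 * s1))
    )
    disc = b * b - 4.0 * a * c
    roots = []
    if disc >= 0:
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [x for x in roots if m1 < x < m2]
    if inside:
        # at most one intersection lies strictly between the means
        return ClassThreshold(x_star=float(inside[0]), method="intersection")
    logger.warning(
        "no density intersection in (%.6g, %.6g); using midpoint", m1, m2
    )
    return ClassThreshold(x_star=(m1 + m2) / 2.0, method="midpoint-fallback")


def sample_mixture(
    n: int,
    weights,
    means,
    sds,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw n values from a finite normal mixture (for simulation studies)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = np.asarray(weights, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    comp = rng.choice(weights.size, size=n, p=weights / weights.sum())
    return rng.normal(means[comp], sds[comp])
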