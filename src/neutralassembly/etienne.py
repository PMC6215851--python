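"""Community-level neutrality under Hubbell's neutral theory.

The central object is the Etienne sampling formula, the exact probability of
observing a species-abundance distribution ``D = (n_1, ..., n_S)`` in a
dispersal-limited local community of ``J`` individuals assembled from an
infinite metacommunity with fundamental biodiversity number ``theta`` and
immigration parameter ``I`` (equivalently immigration probability
``m = I / (I + J - 1)``):

    P(D | theta, m, J) = J! / (prod_i n_i * prod_j phi_j!)
                         * theta^S / (I)_J
                         * sum_{A=S}^{J} K(D, A) * I^A / (theta)_A

where ``(x)_n`` is the rising factorial, ``A`` counts immigrant ancestors,
and ``K(D, A)`` aggregates, over all ways of assigning ``a_i`` ancestors to
species ``i`` with ``sum a_i = A``, products of unsigned Stirling numbers of
the first kind:

    K(D, A) = sum_{a_1..a_S, sum=A} prod_i  s(n_i, a_i) * (a_i - 1)! / (n_i - 1)!

Everything is computed in log space: the Stirling triangle via its additive
recurrence, ``K(D, .)`` by sequentially convolving per-species log-weight
vectors with log-sum-exp, and the rising factorials as log-gamma
differences.  This keeps the likelihood finite for read depths in the
thousands, where the raw terms overflow any fixed-precision float.

The module also provides maximum-likelihood estimation of ``(theta, m)``,
the sequential-construction (urn) simulator, and the exact neutrality test:
simulate communities at the fitted parameters, compare the observed sample's
log-likelihood ``log L0`` with the mean simulated log-likelihood ``log L1``
through the deviation ``q = 2 |log L1 - log L0|``, and score it against a
chi-squared distribution with one degree of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import chi2

from .otu_io import CommunitySAD

__all__ = [
    "StirlingLedger",
    "log_stirling_first",
    "EtienneLikelihood",
    "etienne_log_likelihood",
    "EtienneParams",
    "EtienneFit",
    "EtienneModel",
    "fit_etienne_mle",
    "simulate_etienne_sample",
    "deviation_statistic",
    "ExactTestResult",
    "exact_neutrality_test",
    "m_from_I",
    "I_from_m",
]


# ---------------------------------------------------------------------------
# Unsigned Stirling numbers of the first kind, log scale
# ---------------------------------------------------------------------------

# Row n (index n) holds log s(n, a) for a = 1..n.  Grown lazily and shared
# process-wide: the triangle depends only on n, never on the data.
_LOG_STIRLING_ROWS: list[np.ndarray] = [np.empty(0), np.zeros(1)]


def _extend_stirling(n_max: int) -> None:
    rows = _LOG_STIRLING_ROWS
    while len(rows) <= n_max:
        n = len(rows) - 1  # highest row built so far
        prev = rows[n]
        out = np.empty(n + 1)
        logn = math.log(n)
        # s(n+1, a) = n * s(n, a) + s(n, a-1)
        out[0] = logn + prev[0]
        if n > 1:
            out[1:n] = np.logaddexp(logn + prev[1:], prev[:-1])
        out[n] = 0.0
        rows.append(out)


class StirlingLedger:
    """Log-scale triangle of unsigned Stirling numbers of the first kind."""

    def __init__(self, n_max: int):
        if n_max < 1:
            raise ValueError("n_max must be at least 1")
        self.n_max = int(n_max)
        _extend_stirling(self.n_max)

    def row(self, n: int) -> np.ndarray:
        """``log s(n, a)`` for a = 1..n (read-only view)."""
        if not 1 <= n <= self.n_max:
            raise ValueError(f"row {n} outside ledger range 1..{self.n_max}")
        return _LOG_STIRLING_ROWS[n]

    def log(self, n: int, a: int) -> float:
        """``log s(n, a)``; -inf outside the triangle's support."""
        if not 1 <= a <= n:
            return -math.inf
        return float(self.row(n)[a - 1])


def log_stirling_first(n_max: int) -> StirlingLedger:
    """Return a ledger of ``log s(n, a)`` for all ``1 <= a <= n <= n_max``.

    Built by the recurrence ``s(n+1, a) = n s(n, a) + s(n, a-1)`` in log
    space; rows are cached process-wide so repeated calls are cheap.
    """
    return StirlingLedger(n_max)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _log_conv(la: np.ndarray, lb: np.ndarray) -> np.ndarray:
    """Log-space polynomial convolution via log-sum-exp accumulation."""
    if la.size < lb.size:
        la, lb = lb, la
    out = np.full(la.size + lb.size - 1, -np.inf)
    for k in range(lb.size):
        seg = out[k : k + la.size]
        np.logaddexp(seg, la + lb[k], out=seg)
    return out


class EtienneLikelihood:
    """Per-community precomputation for fast ``(theta, I)`` evaluation.

    The ancestry kernel ``log K(D, A)`` and the combinatorial constant depend
    only on the SAD, so a single instance supports many likelihood
    evaluations (the MLE probes hundreds of parameter points).
    """

    def __init__(self, sad: CommunitySAD):
        ab = sad.abundances
        self.J = sad.J
        self.S = sad.S
        self.log_const = (
            gammaln(self.J + 1)
            - float(np.log(ab).sum())
            - float(sum(gammaln(c + 1) for c in sad.phi.values()))
        )
        self.log_k = self._log_k_vector(ab)
        self.A = np.arange(self.S, self.J + 1, dtype=float)
        self._k = np.arange(self.J, dtype=float)

    def _log_poch_I(self, I: float) -> float:
        """log (I)_J, stable for arbitrarily large I.

        gammaln(I + J) - gammaln(I) cancels catastrophically once
        I >> J / eps; the explicit sum log (I)_J = J log I + sum log1p(k/I)
        stays accurate there.
        """
        if I < 1e6:
            return float(gammaln(I + self.J) - gammaln(I))
        return self.J * math.log(I) + float(np.log1p(self._k / I).sum())

    def _log_poch_theta(self, theta: float) -> np.ndarray:
        """log (theta)_A for A = S..J, stable for arbitrarily large theta
        (same cancellation hazard as :meth:`_log_poch_I`)."""
        if theta < 1e6:
            return gammaln(theta + self.A) - gammaln(theta)
        csum = np.cumsum(np.log1p(self._k / theta))
        return self.A * math.log(theta) + csum[self.S - 1 : self.J]

    @staticmethod
    def _log_k_vector(abundances: np.ndarray) -> np.ndarray:
        """``log K(D, A)`` for A = S..J (index 0 is A = S).

        Species with a single read contribute the weight vector [1] and only
        shift the ancestor count, so they are skipped; ascending order keeps
        the running convolution short for as long as possible.
        """
        ledger = log_stirling_first(int(abundances.max()))
        log_k = np.zeros(1)
        for n in sorted(int(n) for n in abundances if n > 1):
            a = np.arange(1, n + 1)
            w = ledger.row(n) + gammaln(a) - gammaln(n)
            log_k = _log_conv(log_k, w)
        return log_k

    def __call__(self, theta: float, I: float) -> float:
        """``log P(D | theta, I, J)``; raises on a non-positive parameter."""
        if not (np.isfinite(theta) and np.isfinite(I) and theta > 0 and I > 0):
            raise ValueError(f"theta and I must be positive and finite, got {theta}, {I}")
        log_theta = math.log(theta)
        log_i = math.log(I)
        terms = self.log_k + self.A * log_i - self._log_poch_theta(theta)
        return float(
            self.log_const + self.S * log_theta - self._log_poch_I(I) + logsumexp(terms)
        )


def etienne_log_likelihood(sad: CommunitySAD, theta: float, I: float) -> float:
    """Etienne sampling-formula log-probability of one SAD.

    For repeated evaluations on the same SAD construct an
    :class:`EtienneLikelihood` once and call it.
    """
    return EtienneLikelihood(sad)(theta, I)


# ---------------------------------------------------------------------------
# Parameters and MLE
# ---------------------------------------------------------------------------


def m_from_I(I: float, J: int) -> float:
    """Immigration probability from the immigration parameter."""
    return I / (I + J - 1)


def I_from_m(m: float, J: int) -> float:
    """Immigration parameter from the immigration probability."""
    if not 0 < m < 1:
        raise ValueError("m must lie strictly between 0 and 1")
    return m * (J - 1) / (1 - m)


@dataclass(frozen=True)
class EtienneParams:
    """Neutral-model parameters of one local community.

    ``theta`` is the fundamental biodiversity number, ``I`` the number of
    potential immigrants competing for each vacancy, ``m = I/(I+J-1)`` the
    per-death immigration probability, ``J`` the community size.
    """

    theta: float
    I: float
    m: float
    J: int

    def __post_init__(self):
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise ValueError("theta must be positive and finite")
        if not (np.isfinite(self.I) and self.I > 0):
            raise ValueError("I must be positive and finite")
        if self.J < 1:
            raise ValueError("J must be at least 1")
        if self.J > 1:
            implied = m_from_I(self.I, self.J)
            if abs(implied - self.m) > 1e-12 * max(self.m, implied):
                raise ValueError(
                    f"inconsistent parameters: m={self.m} but I/(I+J-1)={implied}"
                )

    @classmethod
    def from_I(cls, theta: float, I: float, J: int) -> "EtienneParams":
        return cls(theta=theta, I=I, m=m_from_I(I, J) if J > 1 else 1.0, J=J)

    @classmethod
    def from_m(cls, theta: float, m: float, J: int) -> "EtienneParams":
        return cls(theta=theta, I=I_from_m(m, J), m=m, J=J)


@dataclass(frozen=True)
class EtienneFit:
    """Maximum-likelihood fit of the neutral model to one community."""

    params: EtienneParams
    log_likelihood: float
    converged: bool
    n_starts: int


class EtienneModel:
    """Maximum-likelihood estimator of ``(theta, m)`` for one SAD.

    The likelihood is maximized over ``(log theta, logit m)`` by Nelder-Mead
    from a grid of starts; the surface is notoriously flat in ``m`` near 1,
    so multiple starts guard against ridge traps.  Follows the scikit-learn
    estimator protocol: constructor holds hyper-parameters, :meth:`fit`
    stores results in trailing-underscore attributes.

    Attributes (after ``fit``)
    --------------------------
    theta_, m_, I_ : float
        Parameter estimates (``I_ = m_ (J-1) / (1 - m_)``).
    log_likelihood_ : float
        Maximized log-likelihood ``log P(D | theta_, m_, J)``.
    converged_ : bool
        False for boundary communities (S == 1 or S == J) or if no start
        terminated successfully.
    """

    def __init__(
        self,
        theta_starts=(5.0, 20.0, 80.0, 320.0),
        m_starts=(0.1, 0.5, 0.9, 0.999),
        tol: float = 1e-6,
        max_iter: int = 500,
    ):
        self.theta_starts = theta_starts
        self.m_starts = m_starts
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {
            "theta_starts": self.theta_starts,
            "m_starts": self.m_starts,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params) -> "EtienneModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, sad: CommunitySAD, y=None) -> "EtienneModel":
        lik = EtienneLikelihood(sad)
        J, S = lik.J, lik.S
        boundary = S == 1 or S == J
        if boundary:
            warnings.warn(
                f"community with S={S}, J={J} lies on the parameter boundary; "
                "reporting the best boundary estimate (converged_=False)",
                stacklevel=2,
            )

        def neg(x):
            log_t, logit_m = x
            if abs(log_t) > 35 or logit_m > 35 or logit_m < -35:
                return np.inf
            theta = math.exp(log_t)
            m = float(expit(logit_m))
            if not 0 < m < 1:
                return np.inf
            return -lik(theta, I_from_m(m, J))

        best = None
        n_starts = 0
        any_success = False
        for t0 in self.theta_starts:
            for m0 in self.m_starts:
                n_starts += 1
                x0 = np.array([math.log(t0), math.log(m0 / (1 - m0))])
                res = optimize.minimize(
                    neg,
                    x0,
                    method="Nelder-Mead",
                    options={
                        "fatol": self.tol,
                        "xatol": 1e-4,
                        "maxiter": self.max_iter,
                    },
                )
                any_success = any_success or bool(res.success)
                if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                    best = res
        if best is None:  # pragma: no cover - defensive
            raise RuntimeError("all optimizer starts failed")

        log_t, logit_m = best.x
        self.theta_ = math.exp(float(np.clip(log_t, -35, 35)))
        self.m_ = float(expit(np.clip(logit_m, -35, 35)))
        self.I_ = I_from_m(self.m_, J)
        self.log_likelihood_ = -float(best.fun)
        self.converged_ = bool(any_success) and not boundary
        self.n_starts_ = n_starts
        self.J_ = J
        self.S_ = S
        self._likelihood = lik
        return self

    def score(self, sad: CommunitySAD | None = None) -> float:
        """Log-likelihood at the fitted parameters (of a new SAD, if given)."""
        if sad is None:
            return self.log_likelihood_
        return EtienneLikelihood(sad)(self.theta_, self.I_)

    def to_fit(self) -> EtienneFit:
        return EtienneFit(
            params=EtienneParams.from_m(self.theta_, self.m_, self.J_),
            log_likelihood=self.log_likelihood_,
            converged=self.converged_,
            n_starts=self.n_starts_,
        )


def fit_etienne_mle(sad: CommunitySAD, **model_params) -> EtienneFit:
    """Fit ``(theta, m)`` to one SAD by maximum likelihood."""
    return EtienneModel(**model_params).fit(sad).to_fit()


# ---------------------------------------------------------------------------
# Simulation and the exact test
# ---------------------------------------------------------------------------


def simulate_etienne_sample(
    theta: float, I: float, J: int, seed=None, rng: np.random.Generator | None = None
) -> CommunitySAD:
    """Draw one neutral community by Etienne's sequential construction.

    Individual ``j`` (j = 1..J) descends from a new immigrant ancestor with
    probability ``I / (I + j - 1)``, otherwise copies a uniformly chosen
    earlier individual; ancestor ``a`` founds a new species with probability
    ``theta / (theta + a - 1)``, otherwise copies an earlier ancestor's
    species.
    """
    if not (np.isfinite(theta) and theta > 0 and np.isfinite(I) and I > 0):
        raise ValueError("theta and I must be positive and finite")
    if J < 1:
        raise ValueError("J must be at least 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    J = int(J)

    u_new = rng.random(J)
    u_pick = rng.random(J)
    ancestor = np.empty(J, dtype=np.int64)
    n_anc = 0
    for j in range(J):
        if u_new[j] * (I + j) < I:
            ancestor[j] = n_anc
            n_anc += 1
        else:
            ancestor[j] = ancestor[int(u_pick[j] * j)]

    u_new = rng.random(n_anc)
    u_pick = rng.random(n_anc)
    species = np.empty(n_anc, dtype=np.int64)
    n_sp = 0
    for a in range(n_anc):
        if u_new[a] * (theta + a) < theta:
            species[a] = n_sp
            n_sp += 1
        else:
            species[a] = species[int(u_pick[a] * a)]

    counts = np.bincount(species[ancestor], minlength=n_sp)
    return CommunitySAD.from_counts(counts)


def deviation_statistic(
    log_l0: float, log_l1: float, two_sided: bool = False
) -> tuple[float, float]:
    """Deviation ``q = -2 [log L0 - log L1]`` and its chi-squared(1) upper
    tail probability.

    ``log L0`` is the observed sample's log-likelihood, ``log L1`` the
    neutral-model reference (mean over simulated communities).  The
    statistic is signed: ``q`` is large and positive when the observed
    sample is much less likely than typical neutral replicates — the
    direction that indicates non-neutral structure — and the test rejects
    only on that side.  A negative ``q`` (observed sample more likely than
    its neutral replicates, common because ``log L0`` is a maximized
    likelihood) sits in the lower tail, where the upper-tail probability is
    1: such communities are never rejected.

    With ``two_sided=True`` the tail is evaluated at ``|q|``, flagging also
    communities *more* compressible than their neutral replicates; that
    variant is anti-conservative on neutral data because the maximization
    bonus in ``log L0`` counts against the community.
    """
    if not (np.isfinite(log_l0) and np.isfinite(log_l1)):
        raise ValueError("log-likelihoods must be finite")
    q = 2.0 * (log_l1 - log_l0)
    if two_sided:
        p = float(chi2.sf(abs(q), df=1))
    else:
        p = float(chi2.sf(q, df=1)) if q > 0 else 1.0
    return q, p


@dataclass
class ExactTestResult:
    """Outcome of the exact neutrality test on one community."""

    log_l0: float
    log_l1: float
    q: float
    p: float
    n_sim: int
    seed: object
    fit: EtienneFit
    sim_log_likelihoods: np.ndarray
    log_l1_arithmetic: float  # log of the arithmetic mean of the likelihoods

    def passes(self, alpha: float = 0.05) -> bool:
        """True when the community is judged neutral (p > alpha)."""
        return self.p > alpha


def exact_neutrality_test(
    sad: CommunitySAD,
    n_sim: int = 100,
    seed=None,
    mean: str = "log",
    two_sided: bool = False,
    model: EtienneModel | None = None,
) -> ExactTestResult:
    """Exact test of community neutrality.

    Fits ``(theta, m)`` to the observed SAD (``log L0`` is the maximized
    log-likelihood), simulates ``n_sim`` communities at the fitted
    parameters and community size, evaluates each simulated SAD's
    log-likelihood at those same parameters, and compares their mean
    (``log L1``) with ``log L0`` through the chi-squared deviation.

    ``mean="log"`` (default) averages the log-likelihoods — the log
    geometric-mean likelihood; ``mean="likelihood"`` averages the
    likelihoods themselves.  Both means are recorded in the result.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be at least 2")
    if mean not in ("log", "likelihood"):
        raise ValueError("mean must be 'log' or 'likelihood'")
    if sad.S < 2:
        raise ValueError("the exact test needs a community with at least 2 species")

    fitted = (model or EtienneModel()).fit(sad)
    log_l0 = fitted.log_likelihood_
    theta, I, J = fitted.theta_, fitted.I_, fitted.J_

    child_seeds = np.random.SeedSequence(seed).spawn(n_sim)
    sim_ll = np.empty(n_sim)
    for k in range(n_sim):
        sim = simulate_etienne_sample(theta, I, J, rng=np.random.default_rng(child_seeds[k]))
        sim_ll[k] = EtienneLikelihood(sim)(theta, I)

    log_l1_log = float(sim_ll.mean())
    log_l1_arith = float(logsumexp(sim_ll) - math.log(n_sim))
    log_l1 = log_l1_log if mean == "log" else log_l1_arith
    q, p = deviation_statistic(log_l0, log_l1, two_sided=two_sided)
    return ExactTestResult(
        log_l0=log_l0,
        log_l1=log_l1,
        q=q,
        p=p,
        n_sim=n_sim,
        seed=seed,
        fit=fitted.to_fit(),
        sim_log_likelihoods=sim_ll,
        log_l1_arithmetic=log_l1_arith,
    )
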