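"""Species-level neutrality under Sloan's continuous neutral model.

Sloan's model tracks one species in a saturated local ("destination")
community of ``N_T`` individuals coupled to a source community where the
species has relative abundance ``p_i``.  Each death is replaced by an
immigrant with probability ``m`` or by local reproduction with probability
``1 - m``, giving the birth/death/immigration transition probabilities

    Pr(N_i + 1 | N_i) = (N_T - N_i)/N_T * [ m p_i + (1-m) N_i/(N_T-1) ]
    Pr(N_i - 1 | N_i) = N_i/N_T * [ m (1-p_i) + (1-m) (N_T-N_i)/(N_T-1) ]

with the stay probability as their complement.  At stationarity the relative
abundance ``x = N_i / N_T`` is approximately

    x ~ Beta( N_T m p_i,  N_T m (1 - p_i) ).

Operationally (following the occurrence-frequency formulation), a species
counts as *detected* in a sample when its relative abundance exceeds a
threshold ``d``; the model-predicted occurrence frequency is then
``F_i(m) = 1 - BetaCDF(d; N_T m p_i, N_T m (1-p_i))``.  The migration
parameter is fitted by least squares of the observed occurrence frequencies
``x_i`` on ``F_i(m)``, goodness of fit is summarized by R², and each species
is classified as neutral / above / below according to whether ``x_i`` falls
inside a 95% binomial interval around its predicted frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betainc
from statsmodels.stats.proportion import proportion_confint

from .otu_io import GroupMap, OTUTable

__all__ = [
    "SloanParams",
    "species_trajectory",
    "transition_probabilities",
    "stationary_distribution",
    "simulate_sloan_dynamics",
    "beta_shapes",
    "beta_density",
    "predicted_occurrence",
    "OccurrenceStats",
    "occurrence_stats",
    "SpeciesOccurrence",
    "SloanFit",
    "SloanNeutralModel",
    "fit_sloan",
    "fit_sloan_from_table",
    "SloanResampleSummary",
    "resampled_sloan_analysis",
    "compare_neutral_percentages",
]


@dataclass
class SloanParams:
    """Parameters of the local-community model.

    ``N_T``: community size (operationally the mean reads per sample);
    ``m``: per-death immigration probability; ``p``: source-community
    relative abundances (sum to 1); ``delta``: species-independent death
    rate — it only sets the physical time per simulation step (one expected
    death per ``1/delta``) and is irrelevant at stationarity.
    """

    N_T: int
    m: float
    p: np.ndarray
    delta: float = 1.0

    def __post_init__(self):
        if self.N_T < 2:
            raise ValueError("N_T must be at least 2")
        if not 0 < self.m < 1:
            raise ValueError("m must lie strictly between 0 and 1")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        p = np.asarray(self.p, dtype=float)
        if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("p must be a probability vector summing to 1")
        self.p = p


def species_trajectory(
    params: SloanParams, species_index: int, n_steps: int, seed=None, **kwargs
) -> np.ndarray:
    """Trajectory of one species of a parameterized community (thin wrapper
    over :func:`simulate_sloan_dynamics`)."""
    return simulate_sloan_dynamics(
        params.N_T, params.m, float(params.p[species_index]), n_steps, seed=seed, **kwargs
    )


def transition_probabilities(N_i, N_T, m, p_i):
    """One-death transition probabilities (P_up, P_stay, P_down).

    Accepts scalars or arrays (broadcast).  P_stay is computed as the
    complement of P_up + P_down, so the three always sum to one exactly.
    """
    N_i = np.asarray(N_i, dtype=float)
    if np.any(N_i < 0) or np.any(N_i > N_T):
        raise ValueError("N_i must lie in [0, N_T]")
    if N_T < 2:
        raise ValueError("N_T must be at least 2")
    if not (0 <= np.min(m) and np.max(m) <= 1 and 0 <= np.min(p_i) and np.max(p_i) <= 1):
        raise ValueError("m and p_i must lie in [0, 1]")
    p_up = (N_T - N_i) / N_T * (m * p_i + (1 - m) * N_i / (N_T - 1))
    p_down = N_i / N_T * (m * (1 - p_i) + (1 - m) * (N_T - N_i) / (N_T - 1))
    p_stay = 1.0 - p_up - p_down
    return p_up, p_stay, p_down


def stationary_distribution(N_T: int, m: float, p_i: float) -> np.ndarray:
    """Exact stationary distribution of the birth-death chain on 0..N_T.

    Computed by detailed balance in log space; the beta law is this chain's
    diffusion (large ``N_T``) approximation.
    """
    states = np.arange(N_T + 1)
    p_up, _, p_down = transition_probabilities(states, N_T, m, p_i)
    with np.errstate(divide="ignore"):
        log_ratio = np.log(p_up[:-1]) - np.log(p_down[1:])
    log_pi = np.concatenate(([0.0], np.cumsum(log_ratio)))
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    return pi / pi.sum()


def simulate_sloan_dynamics(
    N_T: int,
    m: float,
    p_i: float,
    n_steps: int,
    seed=None,
    n0: int | None = None,
    burn_in: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate the species' abundance trajectory (one step per expected
    death); returns ``n_steps`` post-burn-in states."""
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    states = np.arange(N_T + 1)
    p_up, _, p_down = transition_probabilities(states, N_T, m, p_i)
    up = p_up.tolist()
    up_down = (p_up + p_down).tolist()
    s = int(round(p_i * N_T)) if n0 is None else int(n0)
    if not 0 <= s <= N_T:
        raise ValueError("n0 must lie in [0, N_T]")
    u = rng.random(burn_in + n_steps)
    traj = np.empty(n_steps, dtype=np.int64)
    for t in range(burn_in + n_steps):
        ut = u[t]
        if ut < up[s]:
            s += 1
        elif ut < up_down[s]:
            s -= 1
        if t >= burn_in:
            traj[t - burn_in] = s
    return traj


def beta_shapes(N_T: float, m: float, p_i) -> tuple:
    """Shape parameters (alpha, beta) of the stationary beta law."""
    p_i = np.asarray(p_i, dtype=float)
    return N_T * m * p_i, N_T * m * (1.0 - p_i)


def beta_density(x, N_T: float, m: float, p_i: float):
    """Stationary density of relative abundance, Beta(N_T m p, N_T m (1-p))."""
    a, b = beta_shapes(N_T, m, p_i)
    if not (a > 0 and b > 0):
        raise ValueError(f"beta shape parameters must be positive, got ({a}, {b})")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(x >= 1):
        raise ValueError("x must lie strictly in (0, 1)")
    return stats.beta.pdf(x, a, b)


def predicted_occurrence(p, N_T: float, m: float, detection_threshold: float):
    """Model-predicted occurrence frequency ``1 - BetaCDF(d)`` per species.

    Degenerate sources are handled exactly: ``p_i = 0`` gives a point mass at
    zero abundance (never detected); ``p_i = 1`` a point mass at one
    (always detected for ``d < 1``).
    """
    p = np.asarray(p, dtype=float)
    a, b = beta_shapes(N_T, m, p)
    out = np.empty_like(p)
    interior = (p > 0) & (p < 1)
    if np.any(interior):
        out[interior] = 1.0 - betainc(a[interior], b[interior], detection_threshold)
    out[p <= 0] = 0.0
    out[p >= 1] = 1.0 if detection_threshold < 1 else 0.0
    return out


@dataclass
class OccurrenceStats:
    """Source/destination summary feeding the Sloan fit.

    ``p``: mean relative abundance of each taxon across source samples;
    ``x``: fraction of destination samples where the taxon's relative
    abundance exceeds the detection threshold; ``N_T``: rounded mean reads
    per destination sample.
    """

    p: np.ndarray
    x: np.ndarray
    N_T: int
    taxon_ids: list[str]
    n_dest_samples: int
    detection_threshold: float


def occurrence_stats(
    table: OTUTable,
    source_samples,
    dest_samples,
    detection_threshold: float | None = None,
) -> OccurrenceStats:
    """Compute per-taxon source abundance and destination occurrence.

    Taxa absent from both sample sets are dropped.  The default detection
    threshold is one read at the average destination depth, ``1 / N_T``.
    """
    source_samples = list(source_samples)
    dest_samples = list(dest_samples)
    if not source_samples or not dest_samples:
        raise ValueError("source and destination sample sets must be non-empty")
    src = table.counts[table.sample_indices(source_samples)]
    dst = table.counts[table.sample_indices(dest_samples)]
    src_depth = src.sum(axis=1)
    dst_depth = dst.sum(axis=1)
    if np.any(src_depth == 0) or np.any(dst_depth == 0):
        raise ValueError("all selected samples must contain at least one read")
    N_T = int(round(dst_depth.mean()))
    d = 1.0 / N_T if detection_threshold is None else float(detection_threshold)
    if not 0 <= d < 1:
        raise ValueError("detection_threshold must lie in [0, 1)")
    p = (src / src_depth[:, None]).mean(axis=0)
    x = ((dst / dst_depth[:, None]) > d).mean(axis=0)
    keep = (src.sum(axis=0) > 0) | (dst.sum(axis=0) > 0)
    return OccurrenceStats(
        p=p[keep],
        x=x[keep],
        N_T=N_T,
        taxon_ids=[t for t, k in zip(table.taxon_ids, keep) if k],
        n_dest_samples=len(dest_samples),
        detection_threshold=d,
    )


@dataclass
class SpeciesOccurrence:
    """Per-species outcome of the Sloan neutrality classification."""

    taxon_id: str
    p_i: float
    x_i: float
    predicted_freq: float
    ci_low: float
    ci_high: float
    classification: str  # neutral | above | below


@dataclass
class SloanFit:
    """Fitted Sloan model for one source -> destination design."""

    N_T: int
    m_hat: float
    r_squared: float
    detection_threshold: float
    species: list
    pct_neutral: float
    pct_above: float
    pct_below: float
    n_species_total: int
    converged: bool = True

    @property
    def pct_non_neutral(self) -> float:
        return self.pct_above + self.pct_below

    def species_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": [s.taxon_id for s in self.species],
                "p_i": [s.p_i for s in self.species],
                "x_i": [s.x_i for s in self.species],
                "predicted": [s.predicted_freq for s in self.species],
                "ci_low": [s.ci_low for s in self.species],
                "ci_high": [s.ci_high for s in self.species],
                "classification": [s.classification for s in self.species],
            }
        )


class SloanNeutralModel:
    """Least-squares estimator of the migration probability ``m``.

    Fits observed occurrence frequencies ``x_i`` to the model prediction
    ``F_i(m) = 1 - BetaCDF(d; N_T m p_i, N_T m (1-p_i))`` by bounded 1-D
    minimization of the mean squared residual, and classifies each species
    against a binomial 95% interval around ``F_i(m_hat)`` ("wilson" score
    interval by default, "exact" for Clopper-Pearson).

    Attributes after ``fit``: ``m_``, ``r_squared_``, ``N_T_``,
    ``detection_threshold_``, ``n_dest_samples_``, ``converged_``.
    """

    def __init__(self, interval: str = "wilson", ci_level: float = 0.95, tol: float = 1e-6):
        if interval not in ("wilson", "exact"):
            raise ValueError("interval must be 'wilson' or 'exact'")
        self.interval = interval
        self.ci_level = ci_level
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {"interval": self.interval, "ci_level": self.ci_level, "tol": self.tol}

    def set_params(self, **params) -> "SloanNeutralModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, p, x, *, N_T: int, n_dest_samples: int, detection_threshold: float | None = None):
        p = np.asarray(p, dtype=float)
        x = np.asarray(x, dtype=float)
        if p.shape != x.shape or p.ndim != 1:
            raise ValueError("p and x must be aligned 1-D vectors")
        if p.size < 2:
            raise ValueError("at least two taxa are required to fit m")
        d = 1.0 / N_T if detection_threshold is None else float(detection_threshold)

        def sse(m):
            return float(np.mean((x - predicted_occurrence(p, N_T, m, d)) ** 2))

        res = optimize.minimize_scalar(
            sse, bounds=(1e-6, 1 - 1e-6), method="bounded", options={"xatol": self.tol}
        )
        self.m_ = float(res.x)
        self.converged_ = bool(res.success)
        if not self.converged_:
            warnings.warn("Sloan migration fit did not converge", stacklevel=2)
        fitted = predicted_occurrence(p, N_T, self.m_, d)
        ss_res = float(np.sum((x - fitted) ** 2))
        ss_tot = float(np.sum((x - x.mean()) ** 2))
        if ss_tot == 0.0:
            warnings.warn(
                "observed occurrence frequencies are all equal; R^2 is undefined",
                stacklevel=2,
            )
            self.r_squared_ = float("nan")
        else:
            self.r_squared_ = 1.0 - ss_res / ss_tot
        self.N_T_ = int(N_T)
        self.n_dest_samples_ = int(n_dest_samples)
        self.detection_threshold_ = d
        return self

    def predict(self, p) -> np.ndarray:
        """Predicted occurrence frequencies at the fitted ``m``."""
        return predicted_occurrence(p, self.N_T_, self.m_, self.detection_threshold_)

    def prediction_interval(self, p) -> tuple:
        """Binomial interval around the predicted occurrence frequency,
        for the configured confidence level and ``n_dest_samples_`` draws."""
        pred = self.predict(p)
        method = "wilson" if self.interval == "wilson" else "beta"
        low, high = proportion_confint(
            pred * self.n_dest_samples_,
            self.n_dest_samples_,
            alpha=1 - self.ci_level,
            method=method,
        )
        # guard float round-off at the 0/1 edges: the interval must contain
        # its own centre
        low = np.minimum(np.asarray(low, dtype=float), pred)
        high = np.maximum(np.asarray(high, dtype=float), pred)
        return low, high

    def classify(self, p, x, taxon_ids=None) -> list:
        """Per-species neutral/above/below classification (total and
        exclusive by construction)."""
        p = np.asarray(p, dtype=float)
        x = np.asarray(x, dtype=float)
        pred = self.predict(p)
        low, high = self.prediction_interval(p)
        if taxon_ids is None:
            taxon_ids = [f"taxon_{i}" for i in range(p.size)]
        out = []
        for i in range(p.size):
            if x[i] > high[i]:
                cls = "above"
            elif x[i] < low[i]:
                cls = "below"
            else:
                cls = "neutral"
            out.append(
                SpeciesOccurrence(
                    taxon_id=str(taxon_ids[i]),
                    p_i=float(p[i]),
                    x_i=float(x[i]),
                    predicted_freq=float(pred[i]),
                    ci_low=float(low[i]),
                    ci_high=float(high[i]),
                    classification=cls,
                )
            )
        return out


def fit_sloan(
    p,
    x,
    N_T: int,
    n_dest_samples: int,
    detection_threshold: float | None = None,
    taxon_ids=None,
    interval: str = "wilson",
) -> SloanFit:
    """Fit Sloan's model and classify every species; returns the full
    per-design summary (m, R², classifications, percentages)."""
    model = SloanNeutralModel(interval=interval).fit(
        p, x, N_T=N_T, n_dest_samples=n_dest_samples, detection_threshold=detection_threshold
    )
    species = model.classify(p, x, taxon_ids=taxon_ids)
    n = len(species)
    counts = {"neutral": 0, "above": 0, "below": 0}
    for s in species:
        counts[s.classification] += 1
    return SloanFit(
        N_T=model.N_T_,
        m_hat=model.m_,
        r_squared=model.r_squared_,
        detection_threshold=model.detection_threshold_,
        species=species,
        pct_neutral=100.0 * counts["neutral"] / n,
        pct_above=100.0 * counts["above"] / n,
        pct_below=100.0 * counts["below"] / n,
        n_species_total=n,
        converged=model.converged_,
    )


def fit_sloan_from_table(
    table: OTUTable,
    source_samples,
    dest_samples,
    detection_threshold: float | None = None,
    interval: str = "wilson",
) -> SloanFit:
    """Convenience: occurrence statistics + Sloan fit in one call."""
    st = occurrence_stats(table, source_samples, dest_samples, detection_threshold)
    return fit_sloan(
        st.p,
        st.x,
        N_T=st.N_T,
        n_dest_samples=st.n_dest_samples,
        detection_threshold=st.detection_threshold,
        taxon_ids=st.taxon_ids,
        interval=interval,
    )


_REPEAT_COLUMNS = ["N", "m", "R2", "total", "pct_neutral", "pct_non_neutral"]


@dataclass
class SloanResampleSummary:
    """Balanced-resampling summary of a source -> destination design."""

    source: str
    destination: str
    n_per_group: int
    n_repeats: int
    seed: object
    per_repeat: pd.DataFrame
    with_replacement: bool = False

    @property
    def mean(self) -> pd.Series:
        return self.per_repeat[_REPEAT_COLUMNS].mean()

    @property
    def sd(self) -> pd.Series:
        if len(self.per_repeat) < 2:
            return pd.Series(0.0, index=_REPEAT_COLUMNS)
        return self.per_repeat[_REPEAT_COLUMNS].std(ddof=1)


def resampled_sloan_analysis(
    table: OTUTable,
    groups: GroupMap,
    source_label: str,
    dest_label: str,
    n_per_group: int = 50,
    n_repeats: int = 30,
    seed: int = 0,
    detection_threshold: float | None = None,
    interval: str = "wilson",
) -> SloanResampleSummary:
    """Sloan analysis with balanced resampling of samples.

    Each repeat draws ``n_per_group`` source and destination samples and
    runs the full occurrence/fit/classification; means and SDs over repeats
    are the design's final result.  A same-group design (source == dest)
    uses a single draw as both source and destination.  Groups smaller than
    ``n_per_group`` are resampled with replacement (flagged).  Per-repeat
    seeds are ``seed + repeat`` so any repeat is individually reproducible.
    """
    groups.validate_against(table)
    src_pool = np.array(groups.samples(source_label))
    dst_pool = np.array(groups.samples(dest_label))
    replace = len(src_pool) < n_per_group or len(dst_pool) < n_per_group
    if replace:
        warnings.warn(
            "group smaller than n_per_group; resampling with replacement",
            stacklevel=2,
        )
    rows = []
    for r in range(n_repeats):
        rng = np.random.default_rng(seed + r)
        src = rng.choice(src_pool, size=n_per_group, replace=replace)
        if source_label == dest_label:
            dst = src
        else:
            dst = rng.choice(dst_pool, size=n_per_group, replace=replace)
        fit = fit_sloan_from_table(
            table, src, dst, detection_threshold=detection_threshold, interval=interval
        )
        rows.append(
            {
                "repeat": r,
                "N": fit.N_T,
                "m": fit.m_hat,
                "R2": fit.r_squared,
                "total": fit.n_species_total,
                "pct_neutral": fit.pct_neutral,
                "pct_non_neutral": fit.pct_non_neutral,
            }
        )
    return SloanResampleSummary(
        source=source_label,
        destination=dest_label,
        n_per_group=n_per_group,
        n_repeats=n_repeats,
        seed=seed,
        per_repeat=pd.DataFrame(rows),
        with_replacement=replace,
    )


def compare_neutral_percentages(
    a: SloanResampleSummary, b: SloanResampleSummary
) -> tuple[float, float]:
    """Unpaired t-test on per-repeat neutral percentages of two designs."""
    res = stats.ttest_ind(a.per_repeat["pct_neutral"], b.per_repeat["pct_neutral"])
    return float(res.statistic), float(res.pvalue)
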