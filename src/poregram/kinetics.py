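"""Dwell-time mixture inference and capture-rate estimation.

Dwell times of idealized levels are modelled as k-component exponential
mixtures, left-truncated at the recording dead time d: each component
density is ``(1/mu) * exp(-(x - d)/mu)`` on ``(d, inf)``. Maximum-likelihood
fits use EM with quantile-spread multistart; the log-likelihood is checked
to be non-decreasing at every iteration. This is a deliberate
simplification of full missed-event interval-likelihood (MIL) fitting:
dwells here come from already-idealized levels, so no hidden-Markov
missed-event correction is applied.

The capture rate k (events s^-1 uM^-1) is the event count divided by total
open-pore time and analyte concentration, reflecting a Poisson capture
process whose clock runs only while the pore is unoccupied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

DEFAULT_DEAD_TIME_MS = 0.2  # 10 samples at 50 kHz
SLOW_THRESHOLD_MS = 10.0  # dwell above this counts as the long-lived population


@dataclass
class DwellSample:
    """Positive dwell times (ms) with their left-censoring bound and context."""

    dwells_ms: np.ndarray
    dead_time_ms: float = 0.0
    context: str = ""

    def __post_init__(self) -> None:
        self.dwells_ms = np.asarray(self.dwells_ms, dtype=float)
        if self.dead_time_ms < 0:
            raise ValueError("dead_time_ms must be >= 0")
        self.dwells_ms = self.dwells_ms[self.dwells_ms > self.dead_time_ms]


@dataclass
class MixtureFit:
    k: int
    weights: np.ndarray
    means_ms: np.ndarray  # sorted ascending
    loglik: float
    bic: float
    aic: float
    n: int
    dead_time_ms: float
    ci_means: list | None = None  # bootstrap percentile CIs, per component
    ci_weights: list | None = None
    warnings: list = field(default_factory=list)


def _em_fit(
    x: np.ndarray, k: int, d: float, mu0: np.ndarray, tol: float = 1e-8, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray, float]:
    """EM for a left-truncated exponential mixture from one initialization."""
    y = x - d  # truncated exponential is memoryless: shift to the origin
    w = np.full(k, 1.0 / k)
    mu = mu0.copy()
    prev = -np.inf
    for _ in range(max_iter):
        # E-step: responsibilities under shifted-exponential components
        logp = np.log(w)[None, :] - np.log(mu)[None, :] - y[:, None] / mu[None, :]
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        if ll + 1e-12 < prev:
            raise AssertionError("EM log-likelihood decreased")
        if ll - prev < tol:
            prev = ll
            break
        prev = ll
        r = np.exp(logp - lse[:, None])
        # M-step
        nk = r.sum(axis=0)
        w = nk / y.size
        mu = (r * y[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        mu = np.maximum(mu, 1e-9)
    order = np.argsort(mu)
    return w[order], mu[order], prev


def fit_exp_mixture(
    sample: DwellSample,
    k: int,
    n_starts: int = 5,
    n_boot: int = 0,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """Maximum-likelihood k-component exponential mixture with left truncation.

    Multistart EM (quantile-spread initializations); the best log-likelihood
    wins and means are returned sorted ascending. For ``k=1`` this equals
    the closed form ``mu = mean(x) - dead_time``. Optional bootstrap
    percentile confidence intervals (``n_boot`` resamples, seeded).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = sample.dwells_ms
    if x.size < 5 * k:
        raise ValueError(f"need at least {5 * k} dwells for k={k}, got {x.size}")
    d = sample.dead_time_ms
    y = x - d
    if np.all(y <= 0):
        raise ValueError("all dwells at or below the dead time")

    best = None
    qs = np.linspace(0.1, 0.9, k) if k > 1 else np.array([0.5])
    base = np.maximum(np.quantile(y, qs), 1e-6)
    for s in range(n_starts):
        spread = 3.0 ** (s - n_starts // 2)
        mu0 = base * spread if k > 1 else np.array([y.mean() * spread])
        try:
            w, mu, ll = _em_fit(y + d, k, d, mu0, tol, max_iter)
        except (AssertionError, FloatingPointError):
            continue
        if best is None or ll > best[2]:
            best = (w, mu, ll)
    if best is None:
        raise RuntimeError("all EM starts failed")
    w, mu, ll = best
    p = 2 * k - 1
    fit = MixtureFit(
        k=k,
        weights=w,
        means_ms=mu,
        loglik=ll,
        bic=-2 * ll + p * np.log(x.size),
        aic=-2 * ll + 2 * p,
        n=int(x.size),
        dead_time_ms=d,
    )
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        bm, bw = [], []
        for _ in range(n_boot):
            xb = rng.choice(x, size=x.size, replace=True)
            try:
                wb, mub, _ = _em_fit(xb, k, d, mu.copy(), tol, max_iter)
            except AssertionError:
                continue
            bm.append(mub)
            bw.append(wb)
        bm, bw = np.array(bm), np.array(bw)
        fit.ci_means = [tuple(np.percentile(bm[:, j], [2.5, 97.5])) for j in range(k)]
        fit.ci_weights = [tuple(np.percentile(bw[:, j], [2.5, 97.5])) for j in range(k)]
    return fit


def select_k(sample: DwellSample, k_max: int = 3, seed: int = 0) -> int:
    """Smallest k whose BIC is within 2 of the best over 1..k_max.

    Underpowered samples (too few dwells to fit the larger models) trigger a
    warning and fall back to the largest fittable k.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    n = sample.dwells_ms.size
    feasible = min(k_max, max(n // 5, 1))
    if feasible < k_max:
        warnings.warn(
            f"only {n} dwells: model selection limited to k <= {feasible} (low power)",
            stacklevel=2,
        )
    bics = {}
    for k in range(1, feasible + 1):
        try:
            bics[k] = fit_exp_mixture(sample, k, seed=seed).bic
        except (ValueError, RuntimeError):
            break
    if not bics:
        return 1
    best = min(bics.values())
    return min(k for k, b in bics.items() if b <= best + 2.0)


def slow_fraction(
    events, threshold_ms: float = SLOW_THRESHOLD_MS
) -> dict:
    """Fraction of long-lived A3/B3 dwells among final vs preceding features.

    ``events`` are parsed :class:`~poregram.grammar.TranslocationEvent`
    objects; the terminal level of the last feature of each complete event
    is "final", terminal levels of earlier features are "preceding". Returns
    per-context fractions with 95% binomial (Wilson) confidence intervals.
    """
    from statsmodels.stats.proportion import proportion_confint

    final, preceding = [], []
    for ev in events:
        feats = [f for f in ev.features if not f.truncated]
        for i, feat in enumerate(feats):
            term = [seg for lab, seg in feat.levels if lab in ("A3", "B3")]
            if not term:
                continue
            (final if i == len(feats) - 1 else preceding).append(term[0].dwell_ms)
    if not final:
        raise ValueError("no final features present")
    out = {}
    for name, dw in (("final", final), ("preceding", preceding)):
        dw = np.asarray(dw)
        nslow = int((dw > threshold_ms).sum())
        frac = nslow / dw.size if dw.size else float("nan")
        ci = (
            proportion_confint(nslow, dw.size, alpha=0.05, method="wilson")
            if dw.size
            else (float("nan"), float("nan"))
        )
        out[name] = dict(fraction=frac, n=int(dw.size), n_slow=nslow, ci=tuple(ci))
    return out


def capture_rate(
    n_events: int, open_time_s: float, analyte_conc_uM: float
) -> dict:
    """Capture rate k = events / (open time x concentration), with 95% CI.

    The Poisson-exact (Garwood) interval covers the zero-event case, which
    returns rate 0 with a finite upper bound.
    """
    if analyte_conc_uM <= 0:
        raise ValueError("analyte concentration must be > 0")
    if open_time_s <= 0:
        raise ValueError("open-pore time must be > 0")
    denom = open_time_s * analyte_conc_uM
    lo = 0.0 if n_events == 0 else _st.chi2.ppf(0.025, 2 * n_events) / 2 / denom
    hi = _st.chi2.ppf(0.975, 2 * (n_events + 1)) / 2 / denom
    return dict(rate_per_s_per_uM=n_events / denom, n_events=n_events,
                open_time_s=open_time_s, ci=(float(lo), float(hi)))


def open_time_from_idealization(ideal, n_samples: int) -> float:
    """Open-pore seconds of a trace given its event windows."""
    occupied = sum(w.end_idx - w.start_idx for w in ideal.event_windows)
    return (n_samples - occupied) / ideal.sample_rate
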