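"""Parametric richness estimation and the shared-singleton null model.

The abundance model is a mixed Poisson whose rate distribution is a
two-component exponential mixture.  Integrating the Poisson against an
exponential of mean ``mu`` gives a geometric marginal,

    g(k; mu) = (1 / (1 + mu)) * (mu / (1 + mu))**k,    k = 0, 1, 2, ...

so observed OTU counts follow the two-component geometric mixture
``P(k) = w g(k; mu1) + (1 - w) g(k; mu2)``.  Parameters are fitted by
maximizing the zero-truncated multinomial likelihood of the frequency counts
f(1), ..., f(tau) with counts above the truncation point tau pooled into one
tail category.  Total richness is estimated as

    S_hat = D_tau / (1 - P(0)) + (number of OTUs observed more than tau times)

and the expected-singleton pool (species not yet seen at least twice under a
complete census) as ``N_pool = S_hat - (D - f1)``.

The null model for singleton sharing across R replicate samples draws, with
replacement, n tokens from a pool of N species in each replicate; a species
is detected in one replicate with probability ``p = 1 - (1 - 1/N)**n`` and
the expected number of species detected in exactly k of R replicates is
``N * C(R, k) * p**k * (1 - p)**(R - k)``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import comb

from .otu_io import CountTable

__all__ = [
    "FrequencyCounts",
    "RichnessFit",
    "SharedPrediction",
    "frequency_counts",
    "fit_mixed_poisson",
    "expected_singleton_pool",
    "predict_shared",
    "compare_observed_predicted",
]


@dataclass
class FrequencyCounts:
    """f(k) = number of OTUs observed exactly k times; D = richness; N = reads."""
    f: dict[int, int]
    D: int
    N: int

    def __post_init__(self):
        if sum(self.f.values()) != self.D:
            raise ValueError("sum of f(k) must equal D")
        if sum(k * v for k, v in self.f.items()) != self.N:
            raise ValueError("sum of k*f(k) must equal N")

    @property
    def f1(self) -> int:
        return self.f.get(1, 0)

    @property
    def kmax(self) -> int:
        return max(self.f) if self.f else 0


def frequency_counts(source: CountTable | Sequence[int], sample: str | None = None) -> FrequencyCounts:
    """Frequency counts from a table column or a raw per-OTU count vector."""
    if isinstance(source, CountTable):
        counts = source.column(sample).to_numpy()
    else:
        counts = np.asarray(source, dtype=np.int64)
    counts = counts[counts > 0]
    ks, fs = np.unique(counts, return_counts=True)
    return FrequencyCounts({int(k): int(v) for k, v in zip(ks, fs)},
                           D=int(len(counts)), N=int(counts.sum()))


# -- geometric mixture -------------------------------------------------------

def _log_geom(k: np.ndarray, mu: float) -> np.ndarray:
    r = mu / (1.0 + mu)
    return k * math.log(r) - math.log1p(mu)


def mixture_pmf(k, w: float, mu1: float, mu2: float) -> np.ndarray:
    """P(X = k) under the two-component geometric mixture."""
    k = np.asarray(k, dtype=np.float64)
    la = math.log(w) + _log_geom(k, mu1) if w > 0 else np.full_like(k, -np.inf)
    lb = math.log1p(-w) + _log_geom(k, mu2) if w < 1 else np.full_like(k, -np.inf)
    return np.exp(np.logaddexp(la, lb))


def _tail_prob(tau: int, w: float, mu1: float, mu2: float) -> float:
    """P(X > tau) = w r1^(tau+1) + (1-w) r2^(tau+1)."""
    r1, r2 = mu1 / (1 + mu1), mu2 / (1 + mu2)
    return w * r1 ** (tau + 1) + (1 - w) * r2 ** (tau + 1)


@dataclass
class RichnessFit:
    w: float
    mu1: float
    mu2: float
    S_hat: float
    D: int
    N: int
    f1_observed: int
    tau: int
    n_above_tau: int
    loglik: float
    gof_chi2: float
    gof_p: float
    se_S: float = math.nan
    single_component: bool = False
    freq: FrequencyCounts | None = field(default=None, repr=False)

    @property
    def p0(self) -> float:
        return self.w / (1 + self.mu1) + (1 - self.w) / (1 + self.mu2)

    @property
    def n_pool(self) -> float:
        return expected_singleton_pool(self)


def _nll(theta: np.ndarray, ks: np.ndarray, fs: np.ndarray, n_tail: int, tau: int) -> float:
    w = 1.0 / (1.0 + math.exp(-theta[0]))
    mu1, mu2 = math.exp(theta[1]), math.exp(theta[2])
    lw, l1w = math.log(w), math.log1p(-w)
    log_pk = np.logaddexp(lw + _log_geom(ks, mu1), l1w + _log_geom(ks, mu2))
    p0 = w / (1 + mu1) + (1 - w) / (1 + mu2)
    log_trunc = math.log1p(-p0)
    nll = -float((fs * (log_pk - log_trunc)).sum())
    if n_tail:
        pt = _tail_prob(tau, w, mu1, mu2)
        if pt <= 0:
            return 1e300
        nll -= n_tail * (math.log(pt) - log_trunc)
    return nll


def _starting_points(freq: FrequencyCounts) -> list[np.ndarray]:
    mean_k = max(freq.N / freq.D, 1.05)
    starts = []
    for w0 in (0.3, 0.5, 0.7, 0.9):
        for lo, hi in ((0.2, 2 * mean_k), (0.5, 5 * mean_k)):
            starts.append(np.array([math.log(w0 / (1 - w0)),
                                    math.log(lo), math.log(hi)]))
    starts.append(np.array([0.0, math.log(mean_k / 2), math.log(mean_k * 4)]))
    starts.append(np.array([1.4, math.log(0.3), math.log(mean_k)]))
    return starts[:10]


def _fit_single_geometric(ks, fs, n_tail, tau) -> tuple[float, float]:
    """Zero-truncated single geometric: 1-D likelihood maximization."""
    def nll(log_mu):
        mu = math.exp(log_mu[0])
        log_pk = _log_geom(ks, mu)
        log_trunc = math.log1p(-1.0 / (1 + mu))
        val = -float((fs * (log_pk - log_trunc)).sum())
        if n_tail:
            r = mu / (1 + mu)
            val -= n_tail * ((tau + 1) * math.log(r) - log_trunc)
        return val
    res = optimize.minimize(nll, x0=[0.0], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
    return math.exp(res.x[0]), -res.fun


def _gof(ks, fs, n_tail, tau, w, mu1, mu2, n_params) -> tuple[float, float]:
    """Chi-square on binned observed vs expected zero-truncated frequencies."""
    p0 = w / (1 + mu1) + (1 - w) / (1 + mu2)
    probs = mixture_pmf(ks, w, mu1, mu2) / (1 - p0)
    tail = _tail_prob(tau, w, mu1, mu2) / (1 - p0)
    obs = np.append(fs.astype(float), n_tail)
    exp_ = np.append(probs, tail) * obs.sum()
    # pool sparse bins from the right until every expected count is >= 5
    o, e = list(obs), list(exp_)
    i = len(o) - 1
    while i > 0:
        if e[i] < 5:
            e[i - 1] += e[i]
            o[i - 1] += o[i]
            del e[i], o[i]
        i -= 1
    o, e = np.asarray(o), np.asarray(e)
    chi2 = float(((o - e) ** 2 / e).sum())
    df = len(o) - 1 - n_params
    p = float(stats.chi2.sf(chi2, df)) if df >= 1 else math.nan
    return chi2, p


def _fit_at_tau(freq: FrequencyCounts, tau: int) -> RichnessFit:
    ks_all = np.array(sorted(freq.f))
    inside = ks_all[ks_all <= tau]
    if len(inside) < 3:
        raise ValueError(f"need frequency counts on >= 3 distinct k <= tau (tau={tau})")
    ks = inside.astype(np.float64)
    fs = np.array([freq.f[int(k)] for k in inside], dtype=np.float64)
    n_tail = int(sum(freq.f[int(k)] for k in ks_all[ks_all > tau]))
    d_tau = int(fs.sum())

    best = None
    for x0 in _starting_points(freq):
        try:
            res = optimize.minimize(_nll, x0, args=(ks, fs, n_tail, tau),
                                    method="L-BFGS-B",
                                    options={"maxiter": 500, "ftol": 1e-12})
        except (OverflowError, FloatingPointError):
            continue
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None:
        raise RuntimeError("mixed-Poisson fit failed to converge from all starts")

    w = 1.0 / (1.0 + math.exp(-best.x[0]))
    mu1, mu2 = math.exp(best.x[1]), math.exp(best.x[2])
    if mu1 > mu2:
        mu1, mu2, w = mu2, mu1, 1.0 - w
    single = False
    if w < 1e-3 or w > 1 - 1e-3 or abs(math.log(mu2 / mu1)) < 1e-4:
        mu, ll = _fit_single_geometric(ks, fs, n_tail, tau)
        warnings.warn("mixture degenerate; fell back to a single geometric")
        w, mu1, mu2, single = 1.0, mu, mu, True
        loglik = ll
        n_params = 1
    else:
        loglik = -best.fun
        n_params = 3

    p0 = w / (1 + mu1) + (1 - w) / (1 + mu2)
    s_hat = d_tau / (1 - p0) + n_tail
    chi2, p = _gof(ks, fs, n_tail, tau, w, mu1, mu2, n_params)
    fit = RichnessFit(w=w, mu1=mu1, mu2=mu2, S_hat=float(s_hat), D=freq.D,
                      N=freq.N, f1_observed=freq.f1, tau=tau,
                      n_above_tau=n_tail, loglik=loglik, gof_chi2=chi2,
                      gof_p=p, single_component=single, freq=freq)
    if not single:
        fit.se_S = _se_s_hat(best.x, ks, fs, n_tail, tau, d_tau)
    return fit


def _se_s_hat(theta, ks, fs, n_tail, tau, d_tau) -> float:
    """Delta-method standard error of S_hat from the observed information."""
    try:
        h = 1e-4
        hess = np.zeros((3, 3))
        for i in range(3):
            for j in range(i, 3):
                ei, ej = np.eye(3)[i] * h, np.eye(3)[j] * h
                hess[i, j] = hess[j, i] = (
                    _nll(theta + ei + ej, ks, fs, n_tail, tau)
                    - _nll(theta + ei - ej, ks, fs, n_tail, tau)
                    - _nll(theta - ei + ej, ks, fs, n_tail, tau)
                    + _nll(theta - ei - ej, ks, fs, n_tail, tau)) / (4 * h * h)
        cov = np.linalg.inv(hess)

        def s_of(th):
            w = 1.0 / (1.0 + math.exp(-th[0]))
            mu1, mu2 = math.exp(th[1]), math.exp(th[2])
            p0 = w / (1 + mu1) + (1 - w) / (1 + mu2)
            return d_tau / (1 - p0) + n_tail

        grad = np.array([(s_of(theta + np.eye(3)[i] * h)
                          - s_of(theta - np.eye(3)[i] * h)) / (2 * h)
                         for i in range(3)])
        var = float(grad @ cov @ grad)
        return math.sqrt(var) if var > 0 else math.nan
    except (np.linalg.LinAlgError, ValueError, OverflowError):
        return math.nan


TAU_GRID = (10, 25, 50, 100)


def fit_mixed_poisson(freq: FrequencyCounts, truncation: int | str = "auto",
                      gof_alpha: float = 0.05) -> RichnessFit:
    """Fit the two-exponential mixed-Poisson model to frequency counts.

    ``truncation="auto"`` scans tau over {10, 25, 50, 100, kmax} and keeps the
    highest tau whose goodness-of-fit p-value is acceptable (falling back to
    the best-fitting tau when none is).
    """
    if truncation != "auto":
        return _fit_at_tau(freq, int(truncation))
    taus = sorted({t for t in TAU_GRID if t < freq.kmax} | {freq.kmax})
    fits = []
    for tau in taus:
        try:
            fits.append(_fit_at_tau(freq, tau))
        except (ValueError, RuntimeError):
            continue
    if not fits:
        raise RuntimeError("no truncation point admitted a fit")
    acceptable = [f for f in fits if not math.isnan(f.gof_p) and f.gof_p >= gof_alpha]
    if acceptable:
        return max(acceptable, key=lambda f: f.tau)
    return max(fits, key=lambda f: (0 if math.isnan(f.gof_p) else f.gof_p))


def expected_singleton_pool(fit: RichnessFit, definition: str = "not_seen_twice") -> float:
    """Expected-singleton pool for the sharing null model.

    Default: species not yet observed at least twice under a complete census,
    ``N_pool = S_hat - (D - f1)`` (undetected species plus observed
    singletons).  The alternative ``"model_f1"`` returns the model's expected
    number of species with count exactly 1, ``S_hat * P(X = 1)``.
    """
    if fit.S_hat < fit.D:
        raise ValueError("invalid fit: S_hat < D")
    if definition == "not_seen_twice":
        return fit.S_hat - (fit.D - fit.f1_observed)
    if definition == "model_f1":
        return fit.S_hat * float(mixture_pmf(1, fit.w, fit.mu1, fit.mu2))
    raise ValueError(f"unknown definition {definition!r}")


# -- sharing null model ------------------------------------------------------

@dataclass
class SharedPrediction:
    """Closed-form (and optionally Monte Carlo) shared-singleton prediction."""
    N: int
    n: int
    R: int
    p: float
    expected_exactly: dict[int, float]     # k -> E[species in exactly k of R]
    percentages: dict[str, float]          # shared_by_k / unshared, in %
    convention: str
    mc_summary: dict[str, tuple[float, float]] | None = None
    mc_reps: int = 0
    seed: int | None = None


def _class_percentages(p: float, R: int, convention: str) -> dict[str, float]:
    out = {}
    if convention == "subset":
        for x in range(2, R + 1):
            out[f"shared_by_{x}"] = 100.0 * p ** x / (1 - (1 - p) ** x)
        out["unshared"] = 100.0 * (1 - p) ** (R - 1)
    elif convention == "global":
        denom = 1 - (1 - p) ** R
        for x in range(2, R + 1):
            out[f"shared_by_{x}"] = 100.0 * p ** x / denom
        out["unshared"] = 100.0 * p * (1 - p) ** (R - 1) / denom
    else:
        raise ValueError("convention must be 'subset' or 'global'")
    return out


def predict_shared(N: int, n: int, R: int = 4, convention: str = "subset",
                   mc_reps: int = 0, seed: int | None = None,
                   replacement: bool = True) -> SharedPrediction:
    """Null prediction of singleton sharing across R replicate draws.

    Each replicate draws n tokens from a pool of N species; with
    ``replacement=True`` (the default semantics) the per-replicate detection
    probability is ``p = 1 - (1 - 1/N)**n``; ``replacement=False`` draws n
    distinct species (hypergeometric), ``p = n/N``.
    """
    if N < 1 or n < 1 or R < 2:
        raise ValueError("need N >= 1, n >= 1, R >= 2")
    if not replacement and n > N:
        raise ValueError("cannot draw more distinct species than the pool holds")
    p = 1.0 - (1.0 - 1.0 / N) ** n if replacement else n / N
    expected = {k: N * float(comb(R, k)) * p ** k * (1 - p) ** (R - k)
                for k in range(0, R + 1)}
    pct = _class_percentages(p, R, convention)
    pred = SharedPrediction(N=N, n=n, R=R, p=p, expected_exactly=expected,
                            percentages=pct, convention=convention,
                            mc_reps=mc_reps, seed=seed)
    if mc_reps:
        pred.mc_summary = _monte_carlo(N, n, R, convention, mc_reps, seed, replacement)
    return pred


def _monte_carlo(N, n, R, convention, reps, seed, replacement) -> dict[str, tuple[float, float]]:
    rng = np.random.default_rng(seed)
    acc: dict[str, list[float]] = {}
    sample_cols = list(range(R))
    for _ in range(reps):
        if replacement:
            draws = rng.integers(0, N, size=(R, n))
            pres = np.zeros((N, R), dtype=bool)
            for r in range(R):
                pres[np.unique(draws[r]), r] = True
        else:
            pres = np.zeros((N, R), dtype=bool)
            for r in range(R):
                pres[rng.choice(N, size=n, replace=False), r] = True
        pres = pres[pres.any(axis=1)]
        vals: dict[str, float] = {}
        for x in range(2, R + 1):
            pcts = []
            for combo in itertools.combinations(sample_cols, x):
                num = pres[:, combo].all(axis=1).sum()
                den = pres.shape[0] if convention == "global" \
                    else pres[:, combo].any(axis=1).sum()
                pcts.append(100.0 * num / den if den else 0.0)
            vals[f"shared_by_{x}"] = float(np.mean(pcts))
        un = []
        for r in range(R):
            only = pres[:, r] & ~np.delete(pres, r, axis=1).any(axis=1)
            den = pres.shape[0] if convention == "global" else pres[:, r].sum()
            un.append(100.0 * only.sum() / den if den else 0.0)
        vals["unshared"] = float(np.mean(un))
        for key, v in vals.items():
            acc.setdefault(key, []).append(v)
    return {key: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
            for key, v in acc.items()}


@dataclass
class ClassComparison:
    t: float | None
    p: float | None
    observed_mean: float
    predicted_mean: float
    skipped: bool = False


def compare_observed_predicted(observed: Mapping[str, Sequence[float]],
                               predicted: Mapping[str, Sequence[float]]) -> dict[str, ClassComparison]:
    """Two-sample Student t-test per occupancy class (observed vs predicted).

    Classes with fewer than two data points on either side are reported
    without a test, mirroring error-bar-less single data points.
    """
    out = {}
    for key in observed:
        if key not in predicted:
            continue
        obs, pred = list(observed[key]), list(predicted[key])
        if len(obs) < 2 or len(pred) < 2:
            warnings.warn(f"class {key!r}: single data point, test skipped")
            out[key] = ClassComparison(None, None, float(np.mean(obs)),
                                       float(np.mean(pred)), skipped=True)
            continue
        t, p = stats.ttest_ind(obs, pred)
        out[key] = ClassComparison(float(t), float(p), float(np.mean(obs)),
                                   float(np.mean(pred)))
    return out
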