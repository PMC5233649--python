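"""Gaussian-process modelling of temporal expression and the SNR filter.

Each transcript's time course (log-scale expression over a dense sampling of
developmental time) is modelled as a GP with a Matérn ν=5/2 covariance plus
a constant-bias component for the expression level and independent Gaussian
observation noise:

    k(r) = σf² (1 + √5 r/τ + 5 r²/(3 τ²)) exp(−√5 r/τ) + σm²,   r = |t − t′|,

with hyperparameters σf² (signal variance), τ (timescale, hours), σn²
(noise variance) and σm² (level variance, a nuisance absorbing the mean
expression level), fitted by maximizing the log marginal likelihood

    L = −½ yᵀ(K + σn²I)⁻¹ y − ½ log|K + σn²I| − (n/2) log 2π

with multi-start L-BFGS-B over log-parameters and analytic gradients.

The signal-to-noise ratio SNR = log(σf²/σn²) (natural log) summarizes
whether a transcript's temporal dynamics dominate its sampling noise;
transcripts are screened by requiring SNR above a threshold rather than by
absolute expression level, so consistently expressed but low-abundance
transcripts are retained.

With a 10 h timescale a 66 h span holds only a handful of effectively
independent signal fluctuations, so σf² (and hence the SNR) is estimated
with an irreducible spread of roughly half a log unit; the filter threshold
should be read with that granularity in mind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .filters import FilterReport

SQRT5 = math.sqrt(5.0)

# hyperparameter bounds: variances span the useful dynamic range of
# log-expression data; timescale from a fraction of the sampling interval to
# twice the 66 h span; the level variance is unconstrained nuisance
VAR_BOUNDS = (1e-6, 1e4)
TAU_BOUNDS = (0.25, 132.0)
LEVEL_BOUNDS = (1e-8, 1e6)

def matern52(t1, t2, sigma_f2: float, tau: float):
    """Matérn ν=5/2 covariance between times `t1` and `t2` (hours)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if sigma_f2 < 0:
        raise ValueError("sigma_f2 must be >= 0")
    r = np.abs(np.asarray(t1, dtype=float) - np.asarray(t2, dtype=float))
    s = SQRT5 * r / tau
    return sigma_f2 * (1.0 + s + s * s / 3.0) * np.exp(-s)


def matern52_gram(times: np.ndarray, sigma_f2: float, tau: float) -> np.ndarray:
    r = np.abs(times[:, None] - times[None, :])
    s = SQRT5 * r / tau
    return sigma_f2 * (1.0 + s + s * s / 3.0) * np.exp(-s)


def log2p1(x):
    """Default fitting transform: log2(RPKM + 1)."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)


@dataclass
class GPResults:
    """Fitted hyperparameters and posterior summaries for one transcript.

    sigma_f2 and sigma_n2 are in squared log-expression units, tau in hours,
    snr = log(sigma_f2) − log(sigma_n2) (dimensionless, natural log), log
    marginal likelihood in nats (at the ML optimum). Posterior vectors are
    evaluated on the prediction grid (the observation grid by default); the
    95% band is predictive, i.e. includes the noise variance.
    """

    transcript_id: str
    sigma_f2: float
    tau: float
    sigma_n2: float
    sigma_level2: float
    log_marginal_likelihood: float
    times: np.ndarray
    y: np.ndarray
    converged: bool = True
    message: str = ""
    posterior_mean: np.ndarray = field(default=None, repr=False)
    posterior_lower95: np.ndarray = field(default=None, repr=False)
    posterior_upper95: np.ndarray = field(default=None, repr=False)

    @property
    def snr(self) -> float:
        return math.log(self.sigma_f2) - math.log(self.sigma_n2)

    @property
    def params(self) -> dict:
        return {"sigma_f2": self.sigma_f2, "tau": self.tau, "sigma_n2": self.sigma_n2,
                "sigma_level2": self.sigma_level2}

    def predict(self, pred_times: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and variance of the latent profile at `pred_times`."""
        return gp_posterior(self.times, self.y, self.sigma_f2, self.tau,
                            self.sigma_n2, np.asarray(pred_times, dtype=float),
                            sigma_level2=self.sigma_level2)

    def summary(self) -> str:
        lines = [
            f"GP fit for {self.transcript_id} (Matern-5/2 + level, n={len(self.times)})",
            f"  sigma_f2 (signal var) : {self.sigma_f2:12.6g}",
            f"  tau (timescale, h)    : {self.tau:12.6g}",
            f"  sigma_n2 (noise var)  : {self.sigma_n2:12.6g}",
            f"  sigma_level2 (level)  : {self.sigma_level2:12.6g}",
            f"  SNR = log(sf2/sn2)    : {self.snr:12.4f}",
            f"  log marginal lik.     : {self.log_marginal_likelihood:12.4f}",
            f"  converged             : {self.converged}",
        ]
        return "\n".join(lines)


def _kernel_parts(r: np.ndarray, tau: float):
    s = SQRT5 * r / tau
    E = np.exp(-s)
    M = (1.0 + s + s * s / 3.0) * E
    dM_dlogtau = (s * s / 3.0) * (1.0 + s) * E
    return M, dM_dlogtau


def _nll_and_grad(theta: np.ndarray, y: np.ndarray, r: np.ndarray):
    """Negative log marginal likelihood and gradient wrt log-hyperparameters.

    theta = (log σf², log τ, log σn², log σm²).
    """
    log_sf2, log_tau, log_sn2, log_sm2 = theta
    sf2, tau, sn2, sm2 = (math.exp(v) for v in theta)
    n = len(y)
    M, dM = _kernel_parts(r, tau)
    K = sf2 * M + sm2
    K[np.diag_indices_from(K)] += sn2
    try:
        c, low = cho_factor(K, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros(4)
    alpha = cho_solve((c, low), y, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    nll = 0.5 * float(y @ alpha) + 0.5 * logdet + 0.5 * n * math.log(2 * math.pi)
    Kinv = cho_solve((c, low), np.eye(n), check_finite=False)
    A = np.outer(alpha, alpha) - Kinv  # dL/dK = ½ A
    g = np.array([
        0.5 * np.sum(A * (sf2 * M)),
        0.5 * np.sum(A * (sf2 * dM)),
        0.5 * sn2 * np.trace(A),
        0.5 * sm2 * np.sum(A),
    ])
    return nll, -g


def gp_log_marginal_likelihood(times, y, sigma_f2, tau, sigma_n2,
                               sigma_level2: float = 0.0) -> float:
    """Log marginal likelihood of the Matérn-5/2 (+level) GP at fixed hyperparameters."""
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.abs(times[:, None] - times[None, :])
    n = len(y)
    M, _ = _kernel_parts(r, tau)
    K = sigma_f2 * M + sigma_level2
    K[np.diag_indices_from(K)] += sigma_n2
    c, low = cho_factor(K, lower=True, check_finite=False)
    alpha = cho_solve((c, low), y, check_finite=False)
    return -(0.5 * float(y @ alpha) + np.sum(np.log(np.diag(c)))
             + 0.5 * n * math.log(2 * math.pi))


def gp_posterior(times, y, sigma_f2, tau, sigma_n2, pred_times,
                 sigma_level2: float = 0.0):
    """Posterior mean and variance of the latent profile (signal + level)."""
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    pred_times = np.asarray(pred_times, dtype=float)
    K = matern52_gram(times, sigma_f2, tau) + sigma_level2
    K[np.diag_indices_from(K)] += sigma_n2 + 1e-12
    c, low = cho_factor(K, lower=True, check_finite=False)
    Ks = matern52(pred_times[:, None], times[None, :], sigma_f2, tau) + sigma_level2
    alpha = cho_solve((c, low), y, check_finite=False)
    mean = Ks @ alpha
    v = cho_solve((c, low), Ks.T, check_finite=False)
    var = (sigma_f2 + sigma_level2) - np.einsum("ij,ji->i", Ks, v)
    return mean, np.maximum(var, 0.0)


class GPTimeSeriesModel:
    """Per-transcript GP model of a log-expression time course.

    Parameters
    ----------
    times : hours, strictly increasing.
    values : expression (RPKM scale) at each time, non-negative.
    transform : callable mapping raw values to the fitting scale, or None to
        fit `values` as-is. Default log2(x+1).
    transcript_id : label carried into results.
    """

    def __init__(self, times, values, transform=log2p1, transcript_id: str = ""):
        self.times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if self.times.ndim != 1 or values.shape != self.times.shape:
            raise ValueError("times and values must be 1-D of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite expression values")
        if len(self.times) < 8:
            raise ValueError("need at least 8 observations to fit a GP")
        self.values = values
        self.transformed = np.asarray(
            transform(values) if transform is not None else values, dtype=float)
        self.transcript_id = transcript_id

    @classmethod
    def from_dataframe(cls, row: pd.Series, sample_times: pd.Series, **kw):
        """Build from one row of an expression matrix and its sample-sheet times."""
        order = np.argsort(np.asarray(sample_times, dtype=float))
        return cls(np.asarray(sample_times, dtype=float)[order], row.values[order],
                   transcript_id=str(row.name), **kw)

    def fit(self, restarts: int = 5, seed: int = 0,
            fixed_params: Optional[dict] = None) -> GPResults:
        """Maximize the marginal likelihood by multi-start bounded L-BFGS-B.

        The first start is data-driven (sample variance split between signal
        and noise, timescale at a tenth of the span, level at the squared
        mean); the remaining starts are log-uniform draws within the bounds
        from a generator seeded by `seed`. With `fixed_params` no optimization
        is done and posterior summaries are computed at the given
        (sigma_f2, tau, sigma_n2[, sigma_level2]).
        """
        t = self.times
        y = self.transformed
        if fixed_params is not None:
            p = dict(fixed_params)
            p.setdefault("sigma_level2", 0.0)
            return self._results(p["sigma_f2"], p["tau"], p["sigma_n2"],
                                 p["sigma_level2"], y, True, "fixed")
        var = float(np.var(y))
        if var < 1e-12:
            # flat series: no information about signal or noise
            return self._results(VAR_BOUNDS[0], TAU_BOUNDS[0], VAR_BOUNDS[0],
                                 max(float(np.mean(y)) ** 2, LEVEL_BOUNDS[0]),
                                 y, True, "constant series")

        r = np.abs(t[:, None] - t[None, :])
        span = float(t[-1] - t[0])
        bounds = [tuple(np.log(VAR_BOUNDS)), tuple(np.log(TAU_BOUNDS)),
                  tuple(np.log(VAR_BOUNDS)), tuple(np.log(LEVEL_BOUNDS))]
        starts = [np.log([0.9 * var, max(span / 10.0, TAU_BOUNDS[0]),
                          max(0.1 * var, 1e-4),
                          max(float(np.mean(y)) ** 2, LEVEL_BOUNDS[0])])]
        rng = np.random.default_rng(seed)
        for _ in range(max(restarts - 1, 0)):
            starts.append(np.array([
                rng.uniform(np.log(1e-3), np.log(1e2)),
                rng.uniform(*np.log(TAU_BOUNDS)),
                rng.uniform(np.log(1e-3), np.log(1e2)),
                rng.uniform(np.log(1e-6), np.log(1e2)),
            ]))
        best = None
        n_fail = 0
        for x0 in starts:
            try:
                opt = minimize(_nll_and_grad, x0, args=(y, r), jac=True,
                               method="L-BFGS-B", bounds=bounds,
                               options={"maxiter": 300})
            except Exception:
                n_fail += 1
                continue
            if not np.isfinite(opt.fun):
                n_fail += 1
                continue
            if best is None or opt.fun < best.fun:
                best = opt
        if best is None:
            return self._results(float("nan"), float("nan"), float("nan"),
                                 float("nan"), y, False,
                                 f"all {len(starts)} starts failed")
        sf2, tau, sn2, sm2 = np.exp(best.x)
        return self._results(float(sf2), float(tau), float(sn2), float(sm2), y,
                             True, f"{n_fail} starts failed" if n_fail else "")

    def _results(self, sf2, tau, sn2, sm2, y, converged, message) -> GPResults:
        if converged and np.isfinite(sf2):
            lml = gp_log_marginal_likelihood(self.times, y, sf2, tau, sn2, sm2)
            mean, var = gp_posterior(self.times, y, sf2, tau, sn2, self.times,
                                     sigma_level2=sm2)
            half = 1.96 * np.sqrt(var + sn2)
            lo, hi = mean - half, mean + half
        else:
            lml = float("nan")
            mean = lo = hi = np.full_like(self.times, np.nan)
        return GPResults(
            transcript_id=self.transcript_id, sigma_f2=sf2, tau=tau,
            sigma_n2=sn2, sigma_level2=sm2, log_marginal_likelihood=lml,
            times=self.times, y=y, converged=converged, message=message,
            posterior_mean=mean, posterior_lower95=lo, posterior_upper95=hi,
        )


def fit_transcripts(expr: pd.DataFrame, times: Sequence[float], restarts: int = 5,
                    seed: int = 0, transform=log2p1) -> dict[str, GPResults]:
    """Fit a GP per row of `expr` (transcripts × samples, RPKM scale).

    Per-transcript optimizer seeds are derived from `seed` and the row
    position so results do not depend on fitting order.
    """
    times = np.asarray(times, dtype=float)
    fits: dict[str, GPResults] = {}
    for i, (tid, row) in enumerate(expr.iterrows()):
        model = GPTimeSeriesModel(times, row.values, transform=transform,
                                  transcript_id=str(tid))
        fits[str(tid)] = model.fit(restarts=restarts, seed=(seed * 1000003 + i) % (2 ** 31))
    return fits


def fits_to_frame(fits: dict[str, GPResults]) -> pd.DataFrame:
    rows = []
    for tid, f in fits.items():
        rows.append({"transcript_id": tid, "sigma_f2": f.sigma_f2, "tau": f.tau,
                     "sigma_n2": f.sigma_n2,
                     "snr": f.snr if f.converged else float("nan"),
                     "lml": f.log_marginal_likelihood, "converged": f.converged})
    return pd.DataFrame(rows).set_index("transcript_id")


def smoothed_profiles(fits: dict[str, GPResults]) -> pd.DataFrame:
    """GP posterior means (log scale) on the observation grid, one row per fit."""
    rows = {tid: f.posterior_mean for tid, f in fits.items() if f.converged}
    any_fit = next(iter(fits.values()))
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"t{i}" for i in range(len(any_fit.times))])


def consecutive_expression_filter(counts: pd.DataFrame, min_run: int = 5) -> FilterReport:
    """Keep transcripts expressed (count > 0) in at least `min_run` consecutive samples.

    Columns must be ordered by time.
    """
    rep = FilterReport(step="consecutive_expression")
    arr = counts.values > 0
    for tid, row in zip(counts.index, arr):
        run = best = 0
        for v in row:
            run = run + 1 if v else 0
            best = max(best, run)
        if best >= min_run:
            rep.ids_kept.append(str(tid))
        else:
            rep.ids_removed.append(str(tid))
            rep.reasons[str(tid)] = f"max_run_{best}"
    return rep


def snr_filter(fits: dict[str, GPResults], threshold: float = 0.6) -> FilterReport:
    """Keep transcripts with SNR strictly above `threshold`; failed fits are removed."""
    rep = FilterReport(step="snr")
    for tid, f in fits.items():
        if not f.converged or not np.isfinite(f.sigma_f2):
            rep.ids_removed.append(tid)
            rep.reasons[tid] = "fit_failure"
        elif f.snr > threshold:
            rep.ids_kept.append(tid)
        else:
            rep.ids_removed.append(tid)
            rep.reasons[tid] = f"snr_{f.snr:.3f}"
    return rep
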