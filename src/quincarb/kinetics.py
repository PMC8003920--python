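"""Time-dependent (covalent) cholinesterase inhibition kinetics.

A carbamate QC inhibits the enzyme E through a reversible Michaelis-type
complex that decays into the covalently carbamylated enzyme EC::

    E + QC  <=[Ka]=>  E.QC  --k_max-->  EC + Q

At a fixed inhibitor concentration the loss of activity is pseudo
first-order with observed rate

    k_obs([QC]) = k_max * [QC] / (Ka + [QC]),

so residual activity follows v_i(t) = v_0 * exp(-k_obs t).  The overall
second-order inhibition (carbamylation) rate constant is k_i = k_max / Ka;
when [QC] << Ka the saturation curve degenerates to the line
k_obs = k_i * [QC] and only k_i is identifiable.

This module simulates such assays, estimates k_obs per concentration from
ln(v_0/v_i) vs t regressions, discriminates the linear and saturating
concentration dependence with an extra-sum-of-squares F-test, and tabulates
BChE/AChE selectivity ratios.

Units: concentrations in mol/L, times in minutes, k_obs and k_max in 1/min,
k_i in L mol^-1 min^-1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SchemeParams",
    "AssaySeriesDesign",
    "ActivitySeries",
    "KobsEstimate",
    "CarbamylationFit",
    "SelectivityRecord",
    "InsufficientDataError",
    "FitFailureError",
    "kobs_true",
    "simulate_activity",
    "fit_kobs",
    "fit_concentration_dependence",
    "selectivity_table",
]

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few usable data points for the requested estimate."""


class FitFailureError(RuntimeError):
    """The regression produced physically inadmissible estimates."""


@dataclass(frozen=True)
class SchemeParams:
    """True kinetic constants of the carbamylation scheme.

    k_max: maximal first-order carbamylation rate (1/min).
    K_a: dissociation constant of the enzyme-inhibitor complex (mol/L).
    k_decarb: decarbamylation (reactivation) rate (1/min); 0 by default
        because decarbamylation is much slower than the assay timescale.
    """

    k_max: float
    K_a: float
    k_decarb: float = 0.0

    def __post_init__(self):
        if not (self.k_max > 0):
            raise ValueError("k_max must be positive")
        if not (self.K_a > 0):
            raise ValueError("K_a must be positive")
        if self.k_decarb < 0:
            raise ValueError("k_decarb must be non-negative")

    @property
    def k_i(self) -> float:
        """Overall second-order inhibition rate constant k_max/K_a."""
        return self.k_max / self.K_a


@dataclass(frozen=True)
class AssaySeriesDesign:
    """Concentration x incubation-time grid of a time-dependent assay."""

    inhibitor_concentrations: Tuple[float, ...]
    incubation_times: Tuple[float, ...]
    replicates: int = 1

    def __post_init__(self):
        conc = tuple(float(c) for c in self.inhibitor_concentrations)
        times = tuple(float(t) for t in self.incubation_times)
        if any(c <= 0 for c in conc):
            raise ValueError("inhibitor concentrations must be positive")
        if len(set(conc)) != len(conc):
            raise ValueError("inhibitor concentrations must be distinct")
        if any(t < 0 for t in times):
            raise ValueError("incubation times must be non-negative")
        if tuple(sorted(times)) != times:
            raise ValueError("incubation times must be sorted")
        if 0.0 not in times:
            raise ValueError("incubation times must include 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "inhibitor_concentrations", conc)
        object.__setattr__(self, "incubation_times", times)


@dataclass
class ActivitySeries:
    """Residual velocities over incubation time at one inhibitor concentration."""

    compound_id: str
    enzyme: str
    qc_conc: float  # mol/L; 0 marks an inhibitor-free control series
    times: np.ndarray  # min
    velocities: np.ndarray  # arbitrary rate units
    v0: float  # uninhibited control velocity

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.times.shape != self.velocities.shape:
            raise ValueError("times and velocities must have equal length")
        if not (self.v0 > 0):
            raise ValueError("control velocity v0 must be positive")


@dataclass(frozen=True)
class KobsEstimate:
    """Pseudo-first-order rate estimate at one inhibitor concentration."""

    k_obs: float  # 1/min
    se: float  # standard error, 1/min (nan when df = 0)
    r_squared: float  # uncentered R^2 of the through-origin regression
    n_points: int  # usable (v_i > 0) points
    n_dropped: int = 0  # points discarded for v_i <= 0


@dataclass(frozen=True)
class CarbamylationFit:
    """Concentration dependence of k_obs: linear or saturating."""

    mode: str  # "linear" | "saturation"
    k_i: float  # L mol^-1 min^-1
    k_i_ci: Tuple[float, float]
    k_max: float | None = None  # 1/min, saturation mode only
    k_max_ci: Tuple[float, float] | None = None
    K_a: float | None = None  # mol/L, saturation mode only
    K_a_ci: Tuple[float, float] | None = None
    f_statistic: float = float("nan")
    p_value: float = float("nan")
    n_concentrations: int = 0


@dataclass(frozen=True)
class SelectivityRecord:
    compound_id: str
    k_i_ache: float
    k_i_bche: float

    @property
    def ratio(self) -> float:
        """BChE/AChE selectivity; ~1 means a dual inhibitor."""
        return self.k_i_bche / self.k_i_ache


def kobs_true(params: SchemeParams, qc_conc: float) -> float:
    """Saturating k_obs([QC]) = k_max [QC] / (Ka + [QC])."""
    return params.k_max * qc_conc / (params.K_a + qc_conc)


def _residual_activity(params: SchemeParams, qc_conc: float, t: np.ndarray) -> np.ndarray:
    """Fraction of active enzyme at incubation time t.

    With decarbamylation the active fraction obeys the two-state linear ODE
    a' = -k_c a + k_d (1 - a); its solution relaxes to the equilibrium
    fraction k_d/(k_c + k_d) instead of zero.
    """
    kc = kobs_true(params, qc_conc)
    kd = params.k_decarb
    if kd == 0.0:
        return np.exp(-kc * t)
    s = kc + kd
    return kd / s + (kc / s) * np.exp(-s * t)


def simulate_activity(
    params: SchemeParams,
    design: AssaySeriesDesign,
    v0: float,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator | None = None,
    compound_id: str = "sim",
    enzyme: str = "AChE",
    include_control: bool = False,
) -> List[ActivitySeries]:
    """Simulate one time-dependent inhibition experiment.

    Velocities are v0 * a(t) * eps with multiplicative log-normal noise eps
    of coefficient of variation ``noise_cv`` (assay noise scales with the
    signal).  Deterministic under a fixed seed.  ``include_control`` appends
    an inhibitor-free series ([QC] = 0, no decay).
    """
    if not (v0 > 0):
        raise ValueError("v0 must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))  # log-sd giving the target CV
    times = np.tile(np.asarray(design.incubation_times), design.replicates)
    out: List[ActivitySeries] = []
    concentrations = list(design.inhibitor_concentrations)
    if include_control:
        concentrations.append(0.0)
    for conc in concentrations:
        frac = _residual_activity(params, conc, times) if conc > 0 else np.ones_like(times)
        v = v0 * frac
        if noise_cv > 0:
            # mean-1 log-normal: exp(N(-sigma^2/2, sigma^2))
            v = v * rng.lognormal(-0.5 * sigma**2, sigma, size=v.shape)
        out.append(
            ActivitySeries(
                compound_id=compound_id,
                enzyme=enzyme,
                qc_conc=conc,
                times=times.copy(),
                velocities=v,
                v0=v0,
            )
        )
    return out


def fit_kobs(series: ActivitySeries, through_origin: bool = True) -> KobsEstimate:
    """Estimate k_obs from ln(v0/v_i) = k_obs * t by least squares.

    The regression is forced through the origin by default (the model has no
    intercept); ``through_origin=False`` adds an intercept for diagnostics.
    Points with v_i <= 0 cannot be log-transformed and are dropped (counted
    in ``n_dropped``).
    """
    t = series.times
    v = series.velocities
    usable = v > 0
    n_dropped = int(np.sum(~usable))
    t, v = t[usable], v[usable]
    y = np.log(series.v0 / v)
    informative = t > 0
    if int(np.sum(informative)) < 1:
        raise InsufficientDataError(
            "need at least one usable point at t > 0 to estimate k_obs"
        )
    if through_origin:
        sxx = float(np.sum(t * t))
        slope = float(np.sum(t * y)) / sxx
        resid = y - slope * t
        df = len(t) - 1
        ss_tot = float(np.sum(y * y))  # uncentered: model passes through 0
    else:
        slope, intercept = np.polyfit(t, y, 1)
        resid = y - (slope * t + intercept)
        sxx = float(np.sum((t - t.mean()) ** 2))
        df = len(t) - 2
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    se = float(np.sqrt(ss_res / df / sxx)) if df > 0 else float("nan")
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return KobsEstimate(
        k_obs=float(slope), se=se, r_squared=min(r2, 1.0),
        n_points=len(t), n_dropped=n_dropped,
    )


def _linear_fit(conc: np.ndarray, kobs: np.ndarray, w: np.ndarray):
    """Weighted through-origin slope of k_obs on [QC] and its residual SS."""
    sxx = float(np.sum(w * conc * conc))
    slope = float(np.sum(w * conc * kobs)) / sxx
    ss = float(np.sum(w * (kobs - slope * conc) ** 2))
    se = float(np.sqrt(ss / (len(conc) - 1) / sxx)) if len(conc) > 1 else float("nan")
    return slope, ss, se


def _saturation_model(conc, log_kmax, log_ka):
    kmax, ka = np.exp(log_kmax), np.exp(log_ka)
    return kmax * conc / (ka + conc)


def fit_concentration_dependence(
    kobs_by_conc: Sequence[Tuple[float, KobsEstimate | float]],
    alpha: float = 0.05,
    ka_guard: float = 5.0,
    weighted: bool = False,
) -> CarbamylationFit:
    """Fit k_obs vs [QC] and select the linear or saturation description.

    Both the through-origin line k_obs = k_i [QC] and the rectangular
    hyperbola k_obs = k_max [QC]/(Ka + [QC]) are fitted; the saturation
    model is adopted only when the extra-sum-of-squares F-test rejects the
    line at level ``alpha``, the nonlinear fit converged, and the fitted Ka
    lies below ``ka_guard`` times the largest tested concentration (an
    identifiability guard: a Ka far beyond the tested range is
    indistinguishable from a line).  In saturation mode k_i = k_max/Ka with
    a first-order-propagated confidence interval; otherwise k_i is the
    slope.  Estimates must come out positive, else :class:`FitFailureError`.
    """
    pairs = [(float(c), e.k_obs if isinstance(e, KobsEstimate) else float(e),
              e.se if isinstance(e, KobsEstimate) else float("nan"))
             for c, e in kobs_by_conc]
    pairs.sort()
    conc = np.array([p[0] for p in pairs])
    kobs = np.array([p[1] for p in pairs])
    ses = np.array([p[2] for p in pairs])
    n = len(conc)
    if len(np.unique(conc)) < 3:
        raise InsufficientDataError("need >= 3 distinct concentrations")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if weighted:
        if np.any(~np.isfinite(ses)) or np.any(ses <= 0):
            raise ValueError("weighted fit requires finite positive k_obs SEs")
        w = 1.0 / ses**2
    else:
        w = np.ones(n)

    slope, ss_lin, se_lin = _linear_fit(conc, kobs, w)

    sat = None
    if n >= 4:
        kmax0 = 1.2 * float(kobs.max())
        # interpolate the concentration reaching half the largest k_obs
        half = 0.5 * float(kobs.max())
        ka0 = float(np.interp(half, kobs, conc))
        ka0 = max(ka0, float(conc.min()) * 1e-2)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    _saturation_model, conc, kobs,
                    p0=[np.log(kmax0), np.log(ka0)],
                    sigma=None if not weighted else ses,
                    absolute_sigma=False,
                    method="lm", xtol=1e-10, ftol=1e-10, maxfev=500 * 3,
                )
            kmax, ka = float(np.exp(popt[0])), float(np.exp(popt[1]))
            resid = kobs - _saturation_model(conc, *popt)
            ss_sat = float(np.sum(w * resid**2))
            if np.all(np.isfinite(pcov)):
                sat = (kmax, ka, ss_sat, popt, pcov)
        except (RuntimeError, ValueError):
            logger.warning("saturation fit did not converge; falling back to linear")
            sat = None

    f_stat, p_value = float("nan"), float("nan")
    use_sat = False
    if sat is not None:
        kmax, ka, ss_sat, popt, pcov = sat
        df_sat = n - 2
        if df_sat > 0 and ss_lin >= ss_sat:
            if ss_sat == 0.0:
                f_stat, p_value = float("inf"), 0.0
            else:
                f_stat = (ss_lin - ss_sat) / 1.0 / (ss_sat / df_sat)
                p_value = float(stats.f.sf(f_stat, 1, df_sat))
            use_sat = p_value < alpha and ka < ka_guard * float(conc.max())

    tcrit = lambda df: float(stats.t.ppf(0.975, df)) if df > 0 else float("nan")
    if use_sat:
        kmax, ka, ss_sat, popt, pcov = sat
        if not (kmax > 0 and ka > 0):
            raise FitFailureError("negative saturation parameter estimates")
        df = n - 2
        # delta method: var(log x) -> var(x) = x^2 var(log x)
        var_logk, var_loga = pcov[0, 0], pcov[1, 1]
        cov_la = pcov[0, 1]
        se_kmax = kmax * float(np.sqrt(max(var_logk, 0.0)))
        se_ka = ka * float(np.sqrt(max(var_loga, 0.0)))
        k_i = kmax / ka
        # log k_i = log k_max - log Ka, so the propagation is exact in logs
        var_logki = var_logk + var_loga - 2 * cov_la
        se_ki = k_i * float(np.sqrt(max(var_logki, 0.0)))
        tc = tcrit(df)
        return CarbamylationFit(
            mode="saturation",
            k_i=k_i, k_i_ci=(k_i - tc * se_ki, k_i + tc * se_ki),
            k_max=kmax, k_max_ci=(kmax - tc * se_kmax, kmax + tc * se_kmax),
            K_a=ka, K_a_ci=(ka - tc * se_ka, ka + tc * se_ka),
            f_statistic=f_stat, p_value=p_value, n_concentrations=n,
        )
    if not (slope > 0):
        raise FitFailureError("non-positive linear k_i estimate")
    tc = tcrit(n - 1)
    return CarbamylationFit(
        mode="linear",
        k_i=slope, k_i_ci=(slope - tc * se_lin, slope + tc * se_lin),
        f_statistic=f_stat, p_value=p_value, n_concentrations=n,
    )


def selectivity_table(
    fits_ache: Mapping[str, CarbamylationFit],
    fits_bche: Mapping[str, CarbamylationFit],
) -> List[SelectivityRecord]:
    """Per-compound BChE/AChE selectivity ratios over shared compounds."""
    shared = [c for c in fits_ache if c in fits_bche]
    if not shared:
        raise ValueError("no compounds shared between the two fit maps")
    return [
        SelectivityRecord(
            compound_id=c,
            k_i_ache=fits_ache[c].k_i,
            k_i_bche=fits_bche[c].k_i,
        )
        for c in shared
    ]
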