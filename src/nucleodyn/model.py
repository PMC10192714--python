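"""Diffusion + two-binding-population FCS autocorrelation model.

The autocorrelation of a fluorescence trace recorded in a confocal spot is
modelled as free 3D diffusion of the labelled protein through a Gaussian
observation volume plus exchange with two populations of immobile chromatin
sites with distinct residence times:

    G(tau) = [f_diff / (2^{3/2} N)] * (1 + tau/tau_D)^-1 * (1 + tau/(omega^2 tau_D))^-1/2
             + f_short * exp(-tau/tau_short) + f_long * exp(-tau/tau_long)

where ``N`` is the mean number of fluorescent molecules in the observation
volume, ``tau_D`` the characteristic diffusion time, ``omega`` the
axial/radial waist ratio, and ``tau_short``/``tau_long`` the residence times
on short- and long-lived sites.  The reciprocal of a residence time is the
dissociation rate ``k_off``.

Conventions
-----------
* ``f_diff + f_short + f_long = 1``.  The 1/(2^{3/2} N) prefactor multiplies
  only the diffusive term, so ``f_short``/``f_long`` are the *amplitudes* of
  the exponential terms, not occupancies.
* For species of equal brightness the share of the total zero-lag amplitude
  contributed by each term estimates the population occupancy; fits report
  these shares as :attr:`FitResult.population_fractions`.
* The short/long label-swap degeneracy is resolved by requiring
  ``tau_short < tau_long`` (fits are relabelled after optimisation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np

from .errors import InputError, NonIdentifiableError, ParameterError

__all__ = [
    "GAMMA_3D",
    "FCSParams",
    "ACFCurve",
    "FitResult",
    "eval_acf_model",
    "koff_from_residence",
    "fit_acf",
]

#: Geometric factor of the 3D Gaussian observation volume, 2^{-3/2}.
GAMMA_3D = 2.0 ** -1.5

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class FCSParams:
    """Parameter set of the diffusion + two-binding-population model.

    All times are in seconds.  ``f_diff``, ``f_short`` and ``f_long`` must
    lie in [0, 1] and sum to one; ``tau_short < tau_long``.
    """

    n_molecules: float
    f_diff: float
    tau_diff: float
    omega: float
    f_short: float
    tau_short: float
    f_long: float
    tau_long: float

    def __post_init__(self) -> None:
        for name in ("n_molecules", "tau_diff", "tau_short", "tau_long"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ParameterError(f"{name} must be finite and > 0, got {value!r}")
        if not (np.isfinite(self.omega) and self.omega > 1):
            raise ParameterError(f"omega must be > 1, got {self.omega!r}")
        for name in ("f_diff", "f_short", "f_long"):
            value = getattr(self, name)
            if not (np.isfinite(value) and -_FRACTION_TOL <= value <= 1 + _FRACTION_TOL):
                raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")
        total = self.f_diff + self.f_short + self.f_long
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ParameterError(f"f_diff + f_short + f_long must equal 1, got {total!r}")
        if not self.tau_short < self.tau_long:
            raise ParameterError(
                f"tau_short ({self.tau_short}) must be < tau_long ({self.tau_long})"
            )

    @property
    def amplitudes(self) -> tuple[float, float, float]:
        """Zero-lag amplitudes (A_diff, A_short, A_long) of the three terms."""
        return (self.f_diff * GAMMA_3D / self.n_molecules, self.f_short, self.f_long)

    @property
    def population_fractions(self) -> tuple[float, float, float]:
        """Amplitude shares of the three components.

        For equal-brightness species these estimate the occupancies
        (free, short-bound, long-bound).
        """
        a = self.amplitudes
        total = sum(a)
        if total <= 0:
            raise ParameterError("total amplitude is zero; fractions undefined")
        return (a[0] / total, a[1] / total, a[2] / total)

    @property
    def g0(self) -> float:
        """Closed-form zero-lag value f_diff/(2^{3/2} N) + f_short + f_long."""
        return sum(self.amplitudes)


@dataclass
class ACFCurve:
    """An autocorrelation curve: lag times (s), amplitudes and optional SEM."""

    lags: np.ndarray
    g: np.ndarray
    sem: np.ndarray | None = None
    bin_width: float | None = None  # sampling interval of the source trace, if known

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.ndim != 1 or self.lags.shape != self.g.shape:
            raise InputError("lags and g must be 1-D arrays of equal length")
        if self.lags.size and not np.all(np.diff(self.lags) > 0):
            raise InputError("lags must be strictly increasing")
        if self.lags.size and self.lags[0] < 0:
            raise InputError("lags must be non-negative")
        if not np.all(np.isfinite(self.g)):
            raise InputError("g must be finite")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.g.shape:
                raise InputError("sem must match g in shape")
            if np.any(self.sem < 0) or not np.all(np.isfinite(self.sem)):
                raise InputError("sem must be finite and non-negative")

    def __len__(self) -> int:
        return self.lags.size


@dataclass
class FitResult:
    """Outcome of fitting :func:`eval_acf_model` to an :class:`ACFCurve`."""

    params: FCSParams
    param_errors: Mapping[str, float]
    residual_norm: float
    converged: bool
    n_evaluations: int
    koff_short: float = field(init=False)
    koff_long: float = field(init=False)

    def __post_init__(self) -> None:
        self.koff_short = koff_from_residence(self.params.tau_short)
        self.koff_long = koff_from_residence(self.params.tau_long)
        if self.residual_norm < 0:
            raise ParameterError("residual_norm must be >= 0")

    @property
    def population_fractions(self) -> tuple[float, float, float]:
        """Amplitude-share estimates of (free, short-bound, long-bound) occupancies."""
        return self.params.population_fractions


def koff_from_residence(tau: float) -> float:
    """Dissociation rate (s^-1) from a residence time (s): k_off = 1/tau."""
    if not (np.isfinite(tau) and tau > 0):
        raise ParameterError(f"residence time must be finite and > 0, got {tau!r}")
    return 1.0 / tau


def _eval_amplitude_form(
    lags: np.ndarray,
    a_diff: float,
    f_short: float,
    f_long: float,
    tau_diff: float,
    tau_short: float,
    tau_long: float,
    omega: float,
) -> np.ndarray:
    diff = a_diff / ((1.0 + lags / tau_diff) * np.sqrt(1.0 + lags / (omega**2 * tau_diff)))
    return diff + f_short * np.exp(-lags / tau_short) + f_long * np.exp(-lags / tau_long)


def eval_acf_model(params: FCSParams, lags: Sequence[float] | np.ndarray) -> np.ndarray:
    """Evaluate the model ACF at the given lag times (s).

    Returns G(tau) elementwise; lags must be finite and >= 0.
    """
    lags = np.asarray(lags, dtype=float)
    if not np.all(np.isfinite(lags)):
        raise InputError("lags must be finite")
    if np.any(lags < 0):
        raise InputError("lags must be non-negative")
    a_diff, f_short, f_long = params.amplitudes
    return _eval_amplitude_form(
        lags, a_diff, f_short, f_long, params.tau_diff, params.tau_short, params.tau_long, params.omega
    )


_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "a_diff": (0.0, np.inf),
    "f_short": (0.0, 1.0),
    "f_long": (0.0, 1.0),
    "tau_diff": (1e-7, 10.0),
    "tau_short": (1e-4, 100.0),
    "tau_long": (1e-3, 1000.0),
    "omega": (1.001, 100.0),
}

# Names accepted in `fixed`/`bounds`, mapped to internal amplitude-form names.
_NAME_MAP = {
    "n_molecules": "a_diff",
    "a_diff": "a_diff",
    "f_diff": "a_diff",
    "f_short": "f_short",
    "f_long": "f_long",
    "tau_diff": "tau_diff",
    "tau_short": "tau_short",
    "tau_long": "tau_long",
    "omega": "omega",
}


def _auto_init(lags: np.ndarray, g: np.ndarray) -> dict[str, float]:
    g0 = float(np.median(g[: max(3, g.size // 50)]))
    g0 = max(g0, 1e-6)
    half = 0.5 * g0
    below = np.nonzero(g <= half)[0]
    tau_diff = float(lags[below[0]]) if below.size else float(lags[min(len(lags) - 1, len(lags) // 2)])
    tau_diff = float(np.clip(tau_diff, 1e-6, 1.0))
    return {
        "a_diff": 0.5 * g0,
        "f_short": 0.3 * g0,
        "f_long": 0.2 * g0,
        "tau_diff": tau_diff,
        "tau_short": 0.01,
        "tau_long": 1.0,
    }


def _params_to_internal(params: FCSParams) -> dict[str, float]:
    a_diff, f_short, f_long = params.amplitudes
    return {
        "a_diff": a_diff,
        "f_short": f_short,
        "f_long": f_long,
        "tau_diff": params.tau_diff,
        "tau_short": params.tau_short,
        "tau_long": params.tau_long,
    }


def fit_acf(
    curve: ACFCurve,
    init: FCSParams | str = "auto",
    fixed: Sequence[str] | None = ("omega",),
    bounds: Mapping[str, tuple[float, float]] | None = None,
    omega: float = 5.0,
    lag_min_s: float | None = None,
    n_starts: int = 5,
) -> FitResult:
    """Weighted least-squares fit of the diffusion + two-binding model.

    Parameters
    ----------
    curve
        The measured ACF.  If ``curve.sem`` is present, residuals are
        weighted by 1/sem; otherwise the fit is unweighted.
    init
        ``"auto"`` (heuristic initialisation plus ``n_starts`` multi-starts
        jittered +/-50%) or an explicit :class:`FCSParams` starting point.
    fixed
        Parameter names held fixed (default: ``omega``, which is poorly
        separable from ``tau_diff`` on noisy curves).
    bounds
        Optional per-parameter ``(lo, hi)`` overrides.
    omega
        Value of the waist ratio used when ``omega`` is fixed and no
        explicit ``init`` is given.
    lag_min_s
        Smallest lag admitted to the fit.  Defaults to three sampling
        intervals when ``curve.bin_width`` is known (shot-noise/afterpulse
        guard), else no trimming.
    """
    if len(curve) < 10:
        raise InputError("need at least 10 lags to fit the model")
    lags = curve.lags
    g = curve.g
    sem = curve.sem
    if lag_min_s is None and curve.bin_width is not None:
        lag_min_s = 3.0 * curve.bin_width
    if lag_min_s is not None:
        keep = lags >= lag_min_s
        lags, g = lags[keep], g[keep]
        sem = sem[keep] if sem is not None else None
    else:
        keep = lags > 0
        lags, g = lags[keep], g[keep]
        sem = sem[keep] if sem is not None else None
    if lags.size < 10:
        raise InputError("fewer than 10 lags remain after the lag window cut")
    if lags[-1] / lags[0] < 1e3:
        raise InputError("lags must span at least 3 decades")
    if not np.any(g != 0):
        raise NonIdentifiableError("ACF is identically zero; no signal to fit")

    if sem is not None:
        positive = sem[sem > 0]
        floor = positive.min() if positive.size else 1.0
        weights = 1.0 / np.where(sem > 0, sem, floor)
    else:
        weights = np.ones_like(g)

    eff_bounds = dict(_DEFAULT_BOUNDS)
    if bounds:
        for name, interval in bounds.items():
            key = _NAME_MAP.get(name)
            if key is None:
                raise InputError(f"unknown parameter name in bounds: {name!r}")
            lo, hi = interval
            if not lo < hi:
                raise InputError(f"infeasible bounds for {name!r}: {interval!r}")
            eff_bounds[key] = (lo, hi)

    fixed_set = {(_NAME_MAP.get(name) or name) for name in (fixed or ())}
    unknown = fixed_set - set(_DEFAULT_BOUNDS)
    if unknown:
        raise InputError(f"unknown parameter names in fixed: {sorted(unknown)}")

    if isinstance(init, FCSParams):
        base = _params_to_internal(init)
        omega_value = init.omega
        starts = [base]
    elif init == "auto":
        base = _auto_init(lags, g)
        omega_value = omega
        rng = np.random.default_rng(171432)  # fixed: fitting is deterministic
        starts = [base]
        # The half-decay lag overestimates tau_diff badly when the bound
        # amplitudes hold the curve up, so seed additional starts down a
        # tau_diff ladder with matching faster binding guesses.
        for scale in (0.1, 0.01):
            td = max(base["tau_diff"] * scale, lags[0])
            starts.append({**base, "tau_diff": td, "tau_short": max(10 * td, 1e-3)})
        for _ in range(max(0, n_starts - 1)):
            starts.append(
                {k: v * float(rng.uniform(0.5, 1.5)) for k, v in base.items()}
            )
    else:
        raise InputError(f"init must be 'auto' or FCSParams, got {init!r}")

    fit_names = ["a_diff", "f_short", "f_long", "tau_diff", "tau_short", "tau_long"]

    def _is_ordered(out: lmfit.minimizer.MinimizerResult) -> bool:
        # reaction-dominant arrangement: diffusion is the fastest timescale
        taus = sorted([out.params["tau_short"].value, out.params["tau_long"].value])
        return out.params["tau_diff"].value < taus[0]

    def _prefer(a, b) -> bool:
        """Tie-break between local optima: a physically ordered solution beats a
        label-swapped one unless its residual is materially (>5%) worse."""
        oa, ob = _is_ordered(a), _is_ordered(b)
        if oa != ob:
            return a.chisqr < 1.05 * b.chisqr if oa else a.chisqr < b.chisqr / 1.05
        return a.chisqr < b.chisqr

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = _eval_amplitude_form(
            lags,
            p["a_diff"].value,
            p["f_short"].value,
            p["f_long"].value,
            p["tau_diff"].value,
            p["tau_short"].value,
            p["tau_long"].value,
            p["omega"].value,
        )
        return (model - g) * weights

    best = None
    for start in starts:
        pars = lmfit.Parameters()
        for name in ("a_diff", "tau_diff", "tau_short", "tau_long"):
            lo, hi = eff_bounds[name]
            value = float(np.clip(start[name], lo if np.isfinite(lo) else None, hi if np.isfinite(hi) else None))
            pars.add(name, value=value, min=lo, max=hi, vary=name not in fixed_set)
        # f_short + f_long < 1 is enforced structurally: f_long is the fraction
        # f_long_frac of the amplitude budget left by f_short.
        fs0 = float(np.clip(start["f_short"], *eff_bounds["f_short"]))
        fs0 = min(fs0, 1.0 - 1e-6)
        fl0 = float(np.clip(start["f_long"], *eff_bounds["f_long"]))
        frac0 = float(np.clip(fl0 / max(1.0 - fs0, 1e-9), 1e-9, 1.0 - 1e-6))
        pars.add("f_short", value=fs0, min=eff_bounds["f_short"][0],
                 max=min(eff_bounds["f_short"][1], 1.0 - 1e-9),
                 vary="f_short" not in fixed_set)
        pars.add("f_long_frac", value=frac0, min=0.0, max=1.0 - 1e-9,
                 vary="f_long" not in fixed_set)
        pars.add("f_long", expr="f_long_frac * (1 - f_short)")
        lo, hi = eff_bounds["omega"]
        pars.add("omega", value=float(np.clip(omega_value, lo, hi)), min=lo, max=hi,
                 vary="omega" not in fixed_set)
        if not (lo <= pars["omega"].value <= hi):
            raise InputError("omega init violates bounds")
        try:
            with np.errstate(invalid="ignore"):
                out = lmfit.minimize(residual, pars, method="least_squares",
                                     ftol=1e-14, xtol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or _prefer(out, best):
            best = out
    if best is None:
        raise NonIdentifiableError("all optimisation starts failed")

    p = best.params
    vals = {name: p[name].value for name in fit_names + ["omega"]}
    errs = {name: (p[name].stderr if p[name].stderr is not None else math.nan)
            for name in fit_names + ["omega"]}

    # Resolve the label-swap degeneracy: short must be the faster component.
    if vals["tau_short"] > vals["tau_long"]:
        vals["tau_short"], vals["tau_long"] = vals["tau_long"], vals["tau_short"]
        vals["f_short"], vals["f_long"] = vals["f_long"], vals["f_short"]
        errs["tau_short"], errs["tau_long"] = errs["tau_long"], errs["tau_short"]
        errs["f_short"], errs["f_long"] = errs["f_long"], errs["f_short"]
    if vals["tau_short"] == vals["tau_long"]:
        vals["tau_long"] *= 1.0 + 1e-9  # keep the strict ordering invariant

    f_short, f_long = vals["f_short"], vals["f_long"]
    # When the curve's amplitude exceeds what the sum-to-one convention can
    # represent, the optimizer parks at the boundary and the diffusive
    # fraction collapses; amplitude shares (population_fractions) stay valid
    # even then, so the fit is returned rather than rejected.
    f_diff = max(1.0 - f_short - f_long, 1e-9)
    n_molecules = f_diff * GAMMA_3D / vals["a_diff"] if vals["a_diff"] > 0 else np.inf
    if not np.isfinite(n_molecules) or n_molecules <= 0:
        raise NonIdentifiableError("diffusive amplitude is zero; N is unidentified")

    params_out = FCSParams(
        n_molecules=n_molecules,
        f_diff=f_diff,
        tau_diff=vals["tau_diff"],
        omega=vals["omega"],
        f_short=f_short,
        tau_short=vals["tau_short"],
        f_long=f_long,
        tau_long=vals["tau_long"],
    )
    # First-order error propagation for the derived parameters (correlations ignored).
    err_f_diff = math.hypot(errs["f_short"], errs["f_long"])
    rel_a = errs["a_diff"] / vals["a_diff"] if vals["a_diff"] > 0 else math.nan
    rel_f = err_f_diff / f_diff if f_diff > 0 else math.nan
    err_n = abs(n_molecules) * math.hypot(rel_a, rel_f)
    param_errors = {
        "n_molecules": err_n,
        "f_diff": err_f_diff,
        "tau_diff": errs["tau_diff"],
        "omega": errs["omega"],
        "f_short": errs["f_short"],
        "tau_short": errs["tau_short"],
        "f_long": errs["f_long"],
        "tau_long": errs["tau_long"],
    }
    return FitResult(
        params=params_out,
        param_errors=param_errors,
        residual_norm=float(best.chisqr),
        converged=bool(best.success),
        n_evaluations=int(best.nfev),
    )
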