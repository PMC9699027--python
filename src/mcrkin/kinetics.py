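"""Sequential two-step first-order degradation kinetics.

The model is the consecutive reaction A --k1--> B --k2--> C with first-order
steps: here A is the active ingredient (API), B the degradation intermediate
and C the final product.  Closed forms (c0 = initial API fraction)::

    cA(t) = c0 exp(-k1 t)
    cB(t) = c0 k1/(k2-k1) (exp(-k1 t) - exp(-k2 t))      (k1 != k2)
          = c0 k1 t exp(-k1 t)                            (confluent, k1 = k2)
    cC(t) = c0 - cA(t) - cB(t)

Rate constants are in month^-1; times in months.  Fitting is plain least
squares on all three concentration profiles jointly, with a log-spaced
multi-start to avoid the k1<->k2 exchange ambiguity of the intermediate
profile, refined by ``scipy.optimize.least_squares``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

__all__ = [
    "TwoStepKineticModel",
    "KineticFit",
    "SequentialKinetics",
    "two_step_profile",
    "fit_rate_constants",
    "fit_joint",
    "adjust_time_points",
]

COMPONENT_NAMES = ("API", "Inter", "Prod")
#: relative k1/k2 gap below which the confluent closed form is used
_CONFLUENT_RTOL = 1e-8


@dataclass(frozen=True)
class TwoStepKineticModel:
    """Rate constants of the sequential scheme, month^-1, with initial fraction c0."""

    k1: float
    k2: float
    c0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "c0"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("rate constants must be >= 0")
        if self.c0 <= 0:
            raise ValueError("c0 must be > 0")

    def profile(self, times) -> pd.DataFrame:
        return two_step_profile(times, self)


def _profile_array(times: np.ndarray, k1: float, k2: float, c0: float) -> np.ndarray:
    """(T, 3) array of (cAPI, cInter, cProd); exact mass conservation."""
    t = np.asarray(times, dtype=float)
    cA = c0 * np.exp(-k1 * t)
    if abs(k1 - k2) < _CONFLUENT_RTOL * max(k1, k2, 1e-300):
        cB = c0 * k1 * t * np.exp(-k1 * t)
    else:
        cB = c0 * k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    cB = np.clip(cB, 0.0, c0)
    return np.column_stack([cA, cB, c0 - cA - cB])


def two_step_profile(times, model: TwoStepKineticModel) -> pd.DataFrame:
    """Concentration table (cAPI, cInter, cProd) at the given times (months).

    All three concentrations lie in [0, c0] and sum to c0 exactly.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if (t < 0).any():
        raise ValueError("times must be >= 0")
    arr = _profile_array(t, model.k1, model.k2, model.c0)
    return pd.DataFrame(arr, columns=["cAPI", "cInter", "cProd"], index=t)


@dataclass
class KineticFit:
    """Results of a kinetic least-squares fit.

    ``k2`` holds the single second-stage constant for one-dataset fits; joint
    fits populate ``k21`` (tablets) and ``k22`` (substances) instead.
    ``cov`` is the Gauss-Newton covariance approximation
    sigma^2 (J^T J)^-1 of the free parameters, in the order of ``param_names``.
    """

    k1: float
    k2: float | None = None
    k21: float | None = None
    k22: float | None = None
    rss: float = np.nan
    rss_split: float | None = None
    shared_k1: bool = False
    adjusted_times: np.ndarray | None = None
    cov: np.ndarray | None = None
    param_names: tuple[str, ...] = ("k1", "k2")
    n_obs: int = 0
    converged: bool = True

    @property
    def params(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in self.param_names], dtype=float)

    @property
    def bse(self) -> np.ndarray:
        """Approximate standard errors of the fitted constants."""
        if self.cov is None:
            return np.full(len(self.param_names), np.nan)
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    def summary(self) -> str:
        lines = ["Sequential two-step first-order kinetic fit",
                 "=" * 44]
        for name, val, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:>4s}  {val: .5f}  (se {se:.2g})  month^-1")
        lines.append(f"rss   {self.rss:.6g}   n_obs {self.n_obs}")
        if self.rss_split is not None:
            lines.append(f"rss (fully split k1) {self.rss_split:.6g}")
        if self.adjusted_times is not None:
            lines.append(f"time points adjusted ({len(self.adjusted_times)} samples)")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Constants table (name, value_month^-1, scope) mirroring a report row."""
        if self.k21 is not None:
            rows = [("k1", self.k1, "both" if self.shared_k1 else "tablets"),
                    ("k21", self.k21, "tablets"),
                    ("k22", self.k22, "substances")]
        else:
            rows = [("k1", self.k1, "both"), ("k2", self.k2, "both")]
        return pd.DataFrame(rows, columns=["name", "value_month^-1", "scope"])

    def plot(self, times=None, concentrations=None, ax=None, scope_k2: str | None = None):
        """Plot fitted profiles (and observed concentrations if given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        k2 = self.k2 if self.k2 is not None else (
            self.k21 if scope_k2 == "tablets" else self.k22)
        tmax = 120.0 if times is None else float(np.max(times))
        grid = np.linspace(0, tmax, 200)
        prof = _profile_array(grid, self.k1, k2, 1.0)
        for j, name in enumerate(COMPONENT_NAMES):
            ax.plot(grid, prof[:, j], label=name)
        if concentrations is not None and times is not None:
            C = np.asarray(concentrations)
            for j in range(C.shape[1]):
                ax.plot(np.asarray(times), C[:, j], "o", ms=3)
        ax.set_xlabel("age, months")
        ax.set_ylabel("fraction")
        ax.legend()
        return ax


def _check_conc(C: np.ndarray, c0: float) -> np.ndarray:
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if not np.all(np.isfinite(C)):
        raise ValueError("concentrations contain non-finite values")
    if C.shape[1] != 3:
        raise ValueError("expected three concentration columns (API, Inter, Prod)")
    if C.max() > c0 * (1 + 0.5):
        raise ValueError("concentrations exceed c0 well beyond tolerance")
    return C


def _residuals(params, C, t, c0):
    k1, k2 = params
    return (_profile_array(t, max(k1, 0.0), max(k2, 0.0), c0) - C).ravel()


def _grid_starts(n: int = 8) -> np.ndarray:
    ks = np.logspace(-4, 0, n)
    g = np.array([(a, b) for a in ks for b in ks])
    return g


def _refine(fun, x0, bounds):
    return least_squares(fun, x0, bounds=bounds, xtol=1e-12, ftol=1e-12, gtol=1e-12)


def _cov_from(res, n_obs: int) -> np.ndarray | None:
    dof = n_obs - len(res.x)
    if dof <= 0:
        return None
    rss = 2 * res.cost
    J = res.jac
    try:
        return rss / dof * np.linalg.pinv(J.T @ J)
    except np.linalg.LinAlgError:
        return None


def fit_rate_constants(
    C, times, c0: float = 1.0, n_grid: int = 8, n_refine: int = 3
) -> KineticFit:
    """Least-squares estimate of (k1, k2) from observed concentration profiles.

    Minimises the squared deviation of all three components jointly from the
    closed-form profiles.  An ``n_grid`` x ``n_grid`` log-spaced grid over
    k in [1e-4, 1] month^-1 seeds ``n_refine`` local refinements; fitting the
    API decay together with the intermediate disambiguates the (k1, k2)
    exchange symmetry of the intermediate profile alone.
    """
    t = np.asarray(times, dtype=float)
    C = _check_conc(C, c0)
    if len(t) != len(C):
        raise ValueError("times and concentration rows differ in length")
    if len(np.unique(t)) < 3:
        raise ValueError("need >= 3 distinct time points")
    fun = lambda p: _residuals(p, C, t, c0)
    grid = _grid_starts(n_grid)
    rss_grid = np.array([float(fun(p) @ fun(p)) for p in grid])
    best = None
    for idx in np.argsort(rss_grid)[:n_refine]:
        res = _refine(fun, grid[idx], ([0, 0], [np.inf, np.inf]))
        if best is None or res.cost < best.cost:
            best = res
    k1, k2 = best.x
    return KineticFit(
        k1=float(k1), k2=float(k2), rss=float(2 * best.cost),
        cov=_cov_from(best, C.size), param_names=("k1", "k2"),
        n_obs=C.size, converged=bool(best.success),
    )


def fit_joint(
    C_tab, t_tab, C_sub, t_sub, share_k1: bool = True, c0: float = 1.0
) -> KineticFit:
    """Joint fit of tablet and substance profiles.

    With ``share_k1`` the first-stage constant is common and the second-stage
    constants are dataset-specific: parameters (k1, k21, k22) minimise the
    pooled residual.  Without it the two datasets are fitted independently.
    The fully split residual sum is reported in either case so the shared-k1
    hypothesis can be compared against it (nested models: rss_shared >=
    rss_split always).
    """
    t_tab = np.asarray(t_tab, dtype=float)
    t_sub = np.asarray(t_sub, dtype=float)
    C_tab = _check_conc(C_tab, c0)
    C_sub = _check_conc(C_sub, c0)
    if len(C_tab) == 0 or len(C_sub) == 0:
        raise ValueError("both datasets must be non-empty")
    fit_t = fit_rate_constants(C_tab, t_tab, c0=c0)
    fit_s = fit_rate_constants(C_sub, t_sub, c0=c0)
    rss_split = fit_t.rss + fit_s.rss
    n_obs = C_tab.size + C_sub.size
    if not share_k1:
        return KineticFit(
            k1=fit_t.k1, k21=fit_t.k2, k22=fit_s.k2, rss=rss_split,
            rss_split=rss_split, shared_k1=False,
            param_names=("k1", "k21", "k22"), n_obs=n_obs,
        )

    def fun(p):
        k1, k21, k22 = p
        return np.concatenate([
            _residuals((k1, k21), C_tab, t_tab, c0),
            _residuals((k1, k22), C_sub, t_sub, c0),
        ])

    starts = [
        np.array([0.5 * (fit_t.k1 + fit_s.k1), fit_t.k2, fit_s.k2]),
        np.array([fit_t.k1, fit_t.k2, fit_s.k2]),
        np.array([fit_s.k1, fit_t.k2, fit_s.k2]),
    ]
    best = None
    for x0 in starts:
        res = _refine(fun, np.clip(x0, 1e-8, None), ([0] * 3, [np.inf] * 3))
        if best is None or res.cost < best.cost:
            best = res
    k1, k21, k22 = (float(v) for v in best.x)
    return KineticFit(
        k1=k1, k21=k21, k22=k22, rss=float(2 * best.cost), rss_split=rss_split,
        shared_k1=True, cov=_cov_from(best, n_obs),
        param_names=("k1", "k21", "k22"), n_obs=n_obs,
        converged=bool(best.success),
    )


def adjust_time_points(
    C,
    nominal_times,
    bound_months: float = 6.0,
    model_init: TwoStepKineticModel | None = None,
    penalty_weight: float | None = None,
    c0: float = 1.0,
    max_outer: int = 100,
) -> tuple[np.ndarray, KineticFit]:
    """Fit rate constants while refining uncertain nominal sample ages.

    Alternates (i) a rate-constant fit at the current times with (ii) a
    bounded per-sample 1-D search of each time within ``bound_months`` of its
    nominal value, under a quadratic pull-back penalty
    ``penalty_weight * (t - t_nominal)^2`` (default weight: 1e-3 x the mean
    squared concentration), until the penalised rss changes by < 1e-10.

    With ``bound_months = 0`` this reduces exactly to
    :func:`fit_rate_constants` at the nominal times.
    """
    if bound_months < 0:
        raise ValueError("bound_months must be >= 0")
    t_nom = np.asarray(nominal_times, dtype=float)
    C = _check_conc(C, c0)
    if bound_months == 0:
        fit = fit_rate_constants(C, t_nom, c0=c0)
        fit.adjusted_times = t_nom.copy()
        return t_nom.copy(), fit
    lam = penalty_weight if penalty_weight is not None else 1e-3 * float(np.mean(C**2))
    t = t_nom.copy()
    prev_obj = np.inf
    fit = (fit_rate_constants(C, t, c0=c0) if model_init is None
           else KineticFit(k1=model_init.k1, k2=model_init.k2))
    converged = False
    for _ in range(max_outer):
        fit = fit_rate_constants(C, t, c0=c0)
        k1, k2 = fit.k1, fit.k2
        for i in range(len(t)):
            lo = max(t_nom[i] - bound_months, 0.0)
            hi = t_nom[i] + bound_months
            ci = C[i]

            def obj(ti, ci=ci, nom=t_nom[i]):
                r = _profile_array(np.array([ti]), k1, k2, c0)[0] - ci
                return float(r @ r) + lam * (ti - nom) ** 2

            res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-8})
            t[i] = res.x
        resid = (_profile_array(t, k1, k2, c0) - C).ravel()
        obj_val = float(resid @ resid) + lam * float(((t - t_nom) ** 2).sum())
        if abs(prev_obj - obj_val) < 1e-10:
            converged = True
            break
        prev_obj = obj_val
    fit = fit_rate_constants(C, t, c0=c0)
    fit.adjusted_times = t.copy()
    fit.converged = converged and fit.converged
    return t, fit


class SequentialKinetics:
    """Model object for the sequential two-step kinetic fit.

    Parameters
    ----------
    concentrations : array-like, shape (n, 3)
        Observed (API, Inter, Prod) fractions per sample.
    times : array-like, shape (n,)
        Nominal sample ages, months.
    c0 : float
        Initial API fraction (closure constant of the degradation subsystem).

    ``fit()`` returns a :class:`KineticFit`; ``fit(adjust_times=...)`` also
    refines uncertain ages.
    """

    def __init__(self, concentrations, times, c0: float = 1.0):
        self.C = _check_conc(concentrations, c0)
        self.times = np.asarray(times, dtype=float)
        self.c0 = c0

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "age_months",
                       c0: float = 1.0) -> "SequentialKinetics":
        cols = [c for c in df.columns if c != time_col]
        return cls(df[cols].to_numpy(), df[time_col].to_numpy(), c0=c0)

    def fit(self, adjust_times: float | None = None, **kwargs) -> KineticFit:
        if adjust_times is None:
            return fit_rate_constants(self.C, self.times, c0=self.c0, **kwargs)
        _, fit = adjust_time_points(
            self.C, self.times, bound_months=adjust_times, c0=self.c0, **kwargs
        )
        return fit
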