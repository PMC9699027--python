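"""Soft MCR-ALS: constrained alternating least squares for bilinear spectra.

The bilinear model is X = C S^T + E, with X (I samples x J wavenumbers),
C (I x N) component concentrations and S (J x N) pure spectra.  Alternating
least squares fixes one factor and solves for the other:

* C-step:  C_in = X (S_hat^T)^+, then constraints (fixed values, shared
  scalars, non-negativity, closure) produce C_hat.
* S-step:  unknown spectra are solved from the matrix deflated by the known
  part, S_2 = ((X - C_1 S_1^T)^T) (C_2^T)^+, with known spectra S_1 returned
  unchanged; non-negativity applied if requested.

Non-negativity is enforced by non-negative least squares (per sample row for
C, per wavelength for S), not by clipping, so each half-step remains an exact
constrained LS minimisation.  Closure rescales each sample's subset of
concentrations to a fixed sum (soft closure).  Pseudo-inverses use SVD with
a relative singular-value cutoff of 1e-10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "ComponentSystem",
    "ConstraintSpec",
    "ClosureSpec",
    "MCRALS",
    "MCRALSResults",
    "MCRDivergenceError",
    "c_step",
    "s_step",
    "apply_closure",
    "lack_of_fit",
    "minimize_spectral_admixture",
    "run_als",
]

_PINV_RCOND = 1e-10
_DIVERGENCE_TOL = 1e-10
#: iterations without best-LoF improvement before declaring a plateau
_STALL_LIMIT = 8
#: relative LoF excess over the best iterate that counts as true divergence
_DRIFT_LIMIT = 0.01


class MCRDivergenceError(RuntimeError):
    """Raised when ALS iterations repeatedly increase the lack of fit."""


@dataclass
class ComponentSystem:
    """Named component spectra with known/unknown flags.

    ``spectra`` is J x N; columns flagged known (S1) are held fixed in the
    S-step, the rest (S2) are estimated.  Unknown columns may hold an initial
    approximation (required before running ALS).
    """

    names: list[str]
    spectra: np.ndarray
    spectrum_known: np.ndarray

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.spectrum_known = np.asarray(self.spectrum_known, dtype=bool)
        n = len(self.names)
        if n < 1:
            raise ValueError("need at least one component")
        if self.spectra.shape[1] != n or len(self.spectrum_known) != n:
            raise ValueError("spectra columns / flags must match component count")
        known = self.spectra[:, self.spectrum_known]
        if known.size and np.nanmin(known) < -1e-12:
            raise ValueError("known spectra must be non-negative")

    @property
    def n_components(self) -> int:
        return len(self.names)

    @property
    def all_known(self) -> bool:
        return bool(self.spectrum_known.all())

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class ClosureSpec:
    """Closure constraint: the named components' concentrations sum to
    ``constant`` in every sample (mass balance of a closed system)."""

    components: tuple[str, ...]
    constant: float = 1.0

    def __post_init__(self) -> None:
        if self.constant <= 0:
            raise ValueError("closure constant must be > 0")


@dataclass
class ConstraintSpec:
    """Declarative constraint set for one MCR run.

    ``fixed_C`` maps a component name to a fixed concentration (scalar shared
    by all samples, or per-sample array).  ``free_scalar_C`` names components
    whose concentration is a single unknown scalar shared by all samples
    (the blister weighting factor); estimated by 1-D least squares holding
    the other columns fixed.
    """

    nonneg_C: bool = True
    nonneg_S: bool = True
    closure: ClosureSpec | None = None
    fixed_C: dict[str, float | np.ndarray] = field(default_factory=dict)
    free_scalar_C: tuple[str, ...] = ()

    def validate(self, names: list[str]) -> None:
        for n in self.fixed_C:
            if n not in names:
                raise ValueError(f"fixed_C component {n!r} not in system")
        for n in self.free_scalar_C:
            if n not in names:
                raise ValueError(f"free_scalar_C component {n!r} not in system")
        if set(self.fixed_C) & set(self.free_scalar_C):
            raise ValueError("fixed_C and free_scalar_C sets must be disjoint")
        if self.closure is not None:
            missing = set(self.closure.components) - set(names)
            if missing:
                raise ValueError(f"closure names {sorted(missing)} not in system")


def _pinv(A: np.ndarray) -> np.ndarray:
    return np.linalg.pinv(A, rcond=_PINV_RCOND)


def _nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A x - b||, x >= 0 for every row b of B; returns rows x.

    The unconstrained solution is computed for all rows at once; only rows
    with negative entries are re-solved with active-set NNLS.
    """
    X = (B @ _pinv(A).T)
    bad = np.flatnonzero((X < 0).any(axis=1))
    for i in bad:
        X[i], _ = nnls(A, B[i])
    return X


def _ls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return B @ _pinv(A).T


def apply_closure(
    C: np.ndarray, subset: np.ndarray, constant: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale each row's ``subset`` entries to sum to ``constant``.

    Rows whose subset sum is <= 1e-15 cannot be rescaled; they are left
    unchanged and flagged.  Returns (C_new, flagged_row_indices).
    """
    if constant <= 0:
        raise ValueError("closure constant must be > 0")
    C = np.array(C, dtype=float)
    sums = C[:, subset].sum(axis=1)
    ok = sums > 1e-15
    C[np.ix_(ok, subset)] *= (constant / sums[ok])[:, None]
    return C, np.flatnonzero(~ok)


def lack_of_fit(X: np.ndarray, C: np.ndarray, S: np.ndarray) -> float:
    """Relative lack of fit ||X - C S^T||_F / ||X||_F, as a fraction."""
    nX = np.linalg.norm(X)
    if nX == 0:
        raise ValueError("lack of fit undefined for an all-zero data matrix")
    return float(np.linalg.norm(X - C @ S.T) / nX)


def c_step(
    X: np.ndarray,
    S_hat: np.ndarray,
    constraints: ConstraintSpec,
    names: list[str] | None = None,
) -> np.ndarray:
    """One concentration step: least squares against S_hat, then constraints.

    Constraint order: fixed values substituted -> shared free scalars
    estimated -> non-negativity (per-row NNLS of the remaining free columns
    against the residual after the constrained contributions) -> closure.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    S = np.atleast_2d(np.asarray(S_hat, dtype=float))
    I, N = X.shape[0], S.shape[1]
    if names is None:
        names = [f"c{j}" for j in range(N)]
    constraints.validate(list(names))
    col_norms = np.linalg.norm(S, axis=0)
    if np.any(col_norms == 0):
        raise ValueError("S_hat contains an all-zero spectrum column")
    sv = np.linalg.svd(S, compute_uv=False)
    if sv[-1] < _PINV_RCOND * sv[0]:
        warnings.warn(
            "S_hat is rank-deficient beyond the pseudo-inverse tolerance; "
            "returning the minimum-norm solution", RuntimeWarning, stacklevel=2,
        )
    C = _ls_rows(S, X)

    fixed_idx = [names.index(n) for n in constraints.fixed_C]
    scalar_idx = [names.index(n) for n in constraints.free_scalar_C]
    free_idx = [j for j in range(N) if j not in fixed_idx and j not in scalar_idx]

    for n, v in constraints.fixed_C.items():
        C[:, names.index(n)] = np.asarray(v, dtype=float)

    if scalar_idx:
        # one scalar w multiplying the summed spectra of the scalar set,
        # fitted over all samples jointly with the other columns held fixed
        other = [j for j in range(N) if j not in scalar_idx]
        R = X - C[:, other] @ S[:, other].T
        s_eff = S[:, scalar_idx].sum(axis=1)
        w = float((R @ s_eff).sum()) / (I * float(s_eff @ s_eff))
        if constraints.nonneg_C:
            w = max(w, 0.0)
        C[:, scalar_idx] = w

    if free_idx:
        cons_idx = fixed_idx + scalar_idx
        B = X - C[:, cons_idx] @ S[:, cons_idx].T if cons_idx else X
        solver = _nnls_rows if constraints.nonneg_C else _ls_rows
        C[:, free_idx] = solver(S[:, free_idx], B)

    if constraints.closure is not None:
        subset = np.array([names.index(n) for n in constraints.closure.components])
        C, _ = apply_closure(C, subset, constraints.closure.constant)
    return C


def s_step(
    X: np.ndarray,
    C_hat: np.ndarray,
    system: ComponentSystem,
    constraints: ConstraintSpec,
) -> np.ndarray:
    """One spectral step: known spectra pass through, unknowns are solved
    from the deflated matrix X - C1 S1^T against the unknown columns C2."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = np.atleast_2d(np.asarray(C_hat, dtype=float))
    S = system.spectra.copy()
    known = system.spectrum_known
    if known.all():
        return S
    unk = ~known
    C2 = C[:, unk]
    zero_cols = np.flatnonzero(np.linalg.norm(C2, axis=0) == 0)
    if zero_cols.size:
        bad = [system.names[j] for j in np.flatnonzero(unk)[zero_cols]]
        raise ValueError(f"unidentifiable component(s) {bad}: zero concentration column")
    D = X - C[:, known] @ S[:, known].T if known.any() else X
    solver = _nnls_rows if constraints.nonneg_S else _ls_rows
    S[:, unk] = solver(C2, D.T)
    return S


@dataclass
class MCRALSResults:
    """Fitted MCR decomposition.

    ``C`` holds fractional concentrations / weighting factors (I x N),
    ``S`` the pure spectra (J x N); ``lof_trace`` is the lack of fit
    (fraction) after each accepted iteration.
    """

    C: np.ndarray
    S: np.ndarray
    names: list[str]
    lof_trace: list[float]
    iterations: int
    converged: bool
    residual_norm: float
    closure_degenerate_rows: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def lof(self) -> float:
        return self.lof_trace[-1]

    @property
    def lof_percent(self) -> float:
        return 100.0 * self.lof

    def concentrations(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, columns=self.names)

    def spectra(self, wavenumbers=None) -> pd.DataFrame:
        idx = None if wavenumbers is None else pd.Index(wavenumbers, name="wavenumber")
        return pd.DataFrame(self.S, columns=self.names, index=idx)

    def summary(self) -> str:
        lines = [
            "MCR-ALS decomposition",
            "=" * 42,
            f"components   {', '.join(self.names)}",
            f"samples      {self.C.shape[0]}",
            f"iterations   {self.iterations} ({'converged' if self.converged else 'max_iter'})",
            f"LoF          {self.lof_percent:.3f} %",
            f"residual     {self.residual_norm:.4g}",
        ]
        return "\n".join(lines)

    def plot_spectra(self, wavenumbers=None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(self.S.shape[0]) if wavenumbers is None else wavenumbers
        for j, name in enumerate(self.names):
            ax.plot(x, self.S[:, j], label=name)
        ax.set_xlabel("wavenumber, cm$^{-1}$")
        ax.set_ylabel("absorbance, a.u.")
        if wavenumbers is not None:
            ax.invert_xaxis()
        ax.legend()
        return ax


class MCRALS:
    """Soft MCR-ALS model for a spectral matrix.

    Parameters
    ----------
    X : ndarray (I, J)
        Spectral data matrix.
    system : ComponentSystem
        Component names, known spectra and initial approximations of the
        unknown spectra.
    constraints : ConstraintSpec
        Soft constraints applied at each step.

    ``fit()`` alternates C- and S-steps until the relative LoF change falls
    below ``tol``.  If every spectrum is known, the problem is solved in a
    single C-step.
    """

    def __init__(self, X, system: ComponentSystem, constraints: ConstraintSpec):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[1] != system.spectra.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[1]} wavenumbers but system spectra have "
                f"{system.spectra.shape[0]}"
            )
        constraints.validate(system.names)
        self.system = system
        self.constraints = constraints

    def fit(self, tol: float = 1e-8, max_iter: int = 500) -> MCRALSResults:
        X, cs, names = self.X, self.constraints, self.system.names
        S = self.system.spectra.copy()
        if np.isnan(S).any():
            raise ValueError("unknown spectra need initial values before fitting")

        if self.system.all_known:
            C = c_step(X, S, cs, names)
            lof = lack_of_fit(X, C, S)
            return self._results(C, S, [lof], 1, True)

        lof_trace: list[float] = []
        best = None
        prev = None
        strikes = 0  # consecutive iterate-to-iterate LoF increases
        stall = 0    # consecutive iterations without improving the best LoF
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            C = c_step(X, S, cs, names)
            S_new = s_step(X, C, self._with_spectra(S), cs)
            lof = lack_of_fit(X, C, S_new)
            if prev is not None and lof > prev + _DIVERGENCE_TOL:
                strikes += 1
                if strikes >= 3:
                    # sustained increase: post-optimum drift of the soft
                    # (closure-rescaled) iteration stops at the best iterate;
                    # a run that has drifted well above its best diverged
                    if lof > best[0] * (1.0 + _DRIFT_LIMIT):
                        raise MCRDivergenceError(
                            f"LoF increased for {strikes} consecutive iterations "
                            f"(best {best[0]:.3e}, current {lof:.3e}) at iteration {it}"
                        )
                    converged = True
                    break
            else:
                strikes = 0
            if best is None or lof < best[0]:
                if best is not None and lof > best[0] - tol * best[0]:
                    stall += 1
                else:
                    stall = 0
                best = (lof, C, S_new)
                lof_trace.append(lof)
            else:
                stall += 1
            if lof < 1e-12:  # numerically exact fit
                converged = True
                break
            if prev is not None and abs(prev - lof) < tol * max(prev, 1e-300):
                converged = True
                break
            if stall >= _STALL_LIMIT:
                # limit-cycle plateau of the soft-closure iteration: the best
                # LoF has stopped improving at the convergence resolution
                converged = True
                break
            prev = lof
            S = S_new
        lof, C, S = best
        return self._results(C, S, lof_trace, it, converged)

    def _with_spectra(self, S: np.ndarray) -> ComponentSystem:
        return ComponentSystem(self.system.names, S, self.system.spectrum_known)

    def _results(self, C, S, trace, iterations, converged) -> MCRALSResults:
        flagged = np.array([], dtype=int)
        if self.constraints.closure is not None:
            subset = np.array(
                [self.system.names.index(n) for n in self.constraints.closure.components]
            )
            sums = C[:, subset].sum(axis=1)
            flagged = np.flatnonzero(sums <= 1e-15)
        return MCRALSResults(
            C=C, S=S, names=list(self.system.names), lof_trace=trace,
            iterations=iterations, converged=converged,
            residual_norm=float(np.linalg.norm(self.X - C @ S.T)),
            closure_degenerate_rows=flagged,
        )


def minimize_spectral_admixture(
    C: np.ndarray,
    S: np.ndarray,
    unknown: np.ndarray,
    passes: int = 3,
    support_frac: float = 0.05,
    max_gamma: float = 0.95,
    smooth_window: int = 15,
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve residual rotational ambiguity toward minimal-admixture spectra.

    A closure-constrained bilinear fit is invariant under replacing an
    unknown spectrum s_j by (s_j - g*s_m)/(1 - g) with the compensating
    concentration update c_m += g*c_j, c_j *= (1 - g): the reconstruction
    C S^T, the closure sums and (for g in [0, 1) and s_j - g*s_m >= 0) all
    non-negativity constraints are preserved exactly.  Among this continuum
    of equivalent solutions, this routine moves each unknown spectrum to the
    extreme point where it contains no removable multiple of any other
    component: g is the minimum of s_j/s_m over the support of s_m (points
    above ``support_frac`` of its maximum).  For component spectra that
    vanish somewhere on another component's support — the generic case for
    banded spectra — this extreme point is the true solution.

    With noisy spectral estimates the pointwise minimum chases the deepest
    noise dip and systematically under-corrects, so the ratio is evaluated
    on moving-average smoothed copies of the spectra (``smooth_window`` grid
    points; 1 disables smoothing).  Residual negatives after subtraction are
    clipped.

    Returns the updated (C, S); the input arrays are not modified.
    """
    C = np.array(C, dtype=float)
    S = np.array(S, dtype=float)
    unknown = np.asarray(unknown, dtype=bool)
    N = S.shape[1]
    w = max(1, min(int(smooth_window), S.shape[0]))
    kernel = np.ones(w) / w

    def _smooth(col: np.ndarray) -> np.ndarray:
        return np.convolve(col, kernel, mode="valid") if w > 1 else col

    for _ in range(passes):
        for j in range(N):
            if not unknown[j]:
                continue
            for m in range(N):
                if m == j:
                    continue
                sj = _smooth(S[:, j])
                sm = _smooth(S[:, m])
                support = sm > support_frac * sm.max()
                if not support.any():
                    continue
                g = float(np.min(sj[support] / sm[support]))
                g = min(max(g, 0.0), max_gamma)
                if g <= 0:
                    continue
                S[:, j] = np.clip((S[:, j] - g * S[:, m]) / (1.0 - g), 0.0, None)
                C[:, m] = C[:, m] + g * C[:, j]
                C[:, j] = (1.0 - g) * C[:, j]
    return C, S


def run_als(
    X,
    system: ComponentSystem,
    constraints: ConstraintSpec,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MCRALSResults:
    """Functional entry point: build :class:`MCRALS` and fit."""
    return MCRALS(X, system, constraints).fit(tol=tol, max_iter=max_iter)
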