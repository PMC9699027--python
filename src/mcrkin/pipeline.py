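"""Multi-step MCR + kinetics workflow for the tablet/substance aging study.

The workflow resolves a long-term degradation study in stages, each stage
passing its estimated spectra forward as the next stage's initialisation:

1. **Step 1 — substances.**  Three-component MCR (API spectrum known,
   intermediate and product unknown) with closure and non-negativity, then a
   kinetic fit in which uncertain substance production dates are refined
   within a bounded window.
2. **Step 2.1 — fresh tablets.**  Four-component MCR of un-aged tablets with
   three known spectra (PVC blister, MCC, API) and fixed prescription
   concentrations; estimates the composite excipient spectrum (*Rest*) and
   the blister weighting factor.
3. **Cleaning.**  The time-invariant part (PVC, MCC, Rest) is subtracted from
   every tablet spectrum and the remainder rescaled by the prescribed API
   fraction, leaving the degradation subsystem on a closure-1 scale.
4. **Step 2.2 — aged tablets.**  Three-component MCR of the cleaned tablets
   initialised with the Step-1 spectra; kinetic fit at the exact tablet ages.
5. **Step 3 — combined.**  One MCR on the stacked cleaned-tablet + substance
   matrix (shared spectra), then a joint kinetic fit with a shared first-stage
   constant and dataset-specific second-stage constants.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import (
    SpectralDataset,
    average_replicates,
    baseline_correct,
    interpolate_to_grid,
    read_spectra,
    select_range,
)
from .kinetics import KineticFit, adjust_time_points, fit_joint, fit_rate_constants
from .mcr import (
    MCRALS,
    ClosureSpec,
    ComponentSystem,
    ConstraintSpec,
    MCRALSResults,
    minimize_spectral_admixture,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TabletComposition",
    "StepResult",
    "PipelineReport",
    "step1_substances",
    "step2_fresh_tablets",
    "clean_tablet_spectra",
    "step2_tablets",
    "step3_combined",
    "run_pipeline",
]

DEGRADATION_COMPONENTS = ["API", "Inter", "Prod"]

#: moving-average window (grid points) for admixture-ratio estimation when
#: stripping removable admixture from estimated spectra
AMBIGUITY_SMOOTH_WINDOW = 15


@dataclass(frozen=True)
class TabletComposition:
    """Prescription masses (mg) and the derived relative concentrations.

    Fractions are the masses over the total, rounded to two decimals; the
    defaults give c_api + c_mcc + c_rest = 0.36 + 0.33 + 0.31 = 1.00.
    """

    mass_api: float = 100.0
    mass_mcc: float = 90.0
    mass_rest: float = 85.0

    @property
    def total(self) -> float:
        return self.mass_api + self.mass_mcc + self.mass_rest

    @property
    def c_api(self) -> float:
        return round(self.mass_api / self.total, 2)

    @property
    def c_mcc(self) -> float:
        return round(self.mass_mcc / self.total, 2)

    @property
    def c_rest(self) -> float:
        return round(self.mass_rest / self.total, 2)

    def __post_init__(self) -> None:
        if min(self.mass_api, self.mass_mcc, self.mass_rest) < 0:
            raise ValueError("masses must be >= 0")


@dataclass
class StepResult:
    """Outcome of one pipeline stage."""

    mcr: MCRALSResults
    kinetics: KineticFit | None = None
    spectra: dict[str, np.ndarray] = field(default_factory=dict)
    pvc_weight: float | None = None
    ages: np.ndarray | None = None

    @property
    def lof_percent(self) -> float:
        return self.mcr.lof_percent


def _project_out(x: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Deflate x by its projection onto s, clipped at zero."""
    return np.clip(x - (x @ s) / (s @ s) * s, 0.0, None)


def _init_unknown_spectra(
    ds: SpectralDataset, api_spectrum: np.ndarray, seed: int | None
) -> tuple[np.ndarray, np.ndarray]:
    """Data-driven initial spectra for (Inter, Prod).

    The product initialisation is the oldest sample's spectrum deflated by
    the API contribution; the intermediate uses the sample nearest the median
    age.  Degenerate (near-zero) deflations fall back to seeded non-negative
    random spectra.
    """
    ages = ds.ages()
    x_old = ds.absorbance[int(np.argmax(ages))]
    x_mid = ds.absorbance[int(np.argmin(np.abs(ages - np.median(ages))))]
    prod0 = _project_out(x_old, api_spectrum)
    inter0 = _project_out(x_mid, api_spectrum)
    rng = np.random.default_rng(seed)
    scale = float(np.linalg.norm(api_spectrum))
    for v in (inter0, prod0):
        if np.linalg.norm(v) < 1e-9 * scale:
            v[:] = rng.uniform(0.1, 1.0, size=v.shape) * scale / np.sqrt(len(v))
    return inter0, prod0


def _degradation_mcr(
    X: np.ndarray,
    api_spectrum: np.ndarray,
    inter_init: np.ndarray,
    prod_init: np.ndarray,
    tol: float,
    max_iter: int,
) -> MCRALSResults:
    system = ComponentSystem(
        DEGRADATION_COMPONENTS,
        np.column_stack([api_spectrum, inter_init, prod_init]),
        [True, False, False],
    )
    cs = ConstraintSpec(
        nonneg_C=True, nonneg_S=True,
        closure=ClosureSpec(tuple(DEGRADATION_COMPONENTS), 1.0),
    )
    res = MCRALS(X, system, cs).fit(tol=tol, max_iter=max_iter)
    # pick the minimal-admixture member of the equivalent-solution continuum
    # (rotational ambiguity left by the soft constraints); fit-preserving
    res.C, res.S = minimize_spectral_admixture(
        res.C, res.S, ~system.spectrum_known,
        smooth_window=AMBIGUITY_SMOOTH_WINDOW,
    )
    res.residual_norm = float(np.linalg.norm(X - res.C @ res.S.T))
    return res


def step1_substances(
    sub_ds: SpectralDataset,
    api_spectrum: np.ndarray,
    time_bound_months: float = 6.0,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
) -> StepResult:
    """Resolve the substance series and fit kinetics with age refinement."""
    if not (sub_ds.samples["material_kind"] == "substance").all():
        raise ValueError("step 1 expects substance samples only")
    if sub_ds.n_samples < 4:
        raise ValueError("need >= 4 substance samples for an identifiable kinetic fit")
    api_spectrum = np.asarray(api_spectrum, dtype=float)
    inter0, prod0 = _init_unknown_spectra(sub_ds, api_spectrum, seed)
    mcr = _degradation_mcr(sub_ds.absorbance, api_spectrum, inter0, prod0, tol, max_iter)
    t_adj, fit = adjust_time_points(mcr.C, sub_ds.ages(), bound_months=time_bound_months)
    return StepResult(
        mcr=mcr, kinetics=fit,
        spectra={"Inter": mcr.S[:, 1], "Prod": mcr.S[:, 2]},
        ages=t_adj,
    )


def step2_fresh_tablets(
    fresh_ds: SpectralDataset,
    known_spectra: dict[str, np.ndarray],
    composition: TabletComposition | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> StepResult:
    """Estimate the composite excipient spectrum and the blister weight.

    Four-component MCR of un-aged tablets: PVC/MCC/API spectra known,
    MCC/Rest/API concentrations fixed at the prescription values, the PVC
    pseudo-concentration one shared free scalar, the Rest spectrum unknown.
    """
    comp = composition or TabletComposition()
    ages = fresh_ds.ages()
    if (ages != 0).any():
        raise ValueError("step 2.1 expects fresh (age 0) tablets only")
    if fresh_ds.n_samples < 2:
        raise ValueError("need >= 2 fresh tablets")
    if comp.c_rest <= 0:
        raise ValueError("unidentifiable Rest component: c_rest must be > 0")
    for key in ("PVC", "MCC", "API"):
        if key not in known_spectra:
            raise ValueError(f"missing known spectrum {key!r}")
    s_pvc = np.asarray(known_spectra["PVC"], dtype=float)
    s_mcc = np.asarray(known_spectra["MCC"], dtype=float)
    s_api = np.asarray(known_spectra["API"], dtype=float)

    # Rest initialisation: mean fresh spectrum minus the known contributions
    x_mean = fresh_ds.absorbance.mean(axis=0)
    r = x_mean - comp.c_api * s_api - comp.c_mcc * s_mcc
    w0 = max(float(r @ s_pvc) / float(s_pvc @ s_pvc), 0.0)
    rest0 = np.clip(r - w0 * s_pvc, 0.0, None) / comp.c_rest
    if np.linalg.norm(rest0) < 1e-12:
        rest0 = np.full_like(x_mean, float(np.mean(x_mean)))

    names = ["PVC", "MCC", "Rest", "API"]
    system = ComponentSystem(
        names, np.column_stack([s_pvc, s_mcc, rest0, s_api]),
        [True, True, False, True],
    )
    cs = ConstraintSpec(
        nonneg_C=True, nonneg_S=True, closure=None,
        fixed_C={"MCC": comp.c_mcc, "Rest": comp.c_rest, "API": comp.c_api},
        free_scalar_C=("PVC",),
    )
    mcr = MCRALS(fresh_ds.absorbance, system, cs).fit(tol=tol, max_iter=max_iter)

    # The blister weight and the Rest spectrum trade off exactly along
    # s_Rest -> s_Rest + d*s_PVC, w -> w - c_rest*d (the fit is invariant).
    # Strip the removable PVC multiple from Rest and credit it back to w.
    j_rest, j_pvc = names.index("Rest"), names.index("PVC")
    s_rest = mcr.S[:, j_rest]
    w = float(mcr.C[0, j_pvc])
    win = max(1, min(AMBIGUITY_SMOOTH_WINDOW, len(s_pvc)))
    kern = np.ones(win) / win
    rest_sm = np.convolve(s_rest, kern, mode="valid")
    pvc_sm = np.convolve(s_pvc, kern, mode="valid")
    support = pvc_sm > 0.05 * pvc_sm.max()
    d = float(np.min(rest_sm[support] / pvc_sm[support]))
    if d > 0:
        s_rest = np.clip(s_rest - d * s_pvc, 0.0, None)
        w = w + comp.c_rest * d
        mcr.S[:, j_rest] = s_rest
        mcr.C[:, j_pvc] = w
    return StepResult(
        mcr=mcr, spectra={"Rest": s_rest}, pvc_weight=w,
    )


def clean_tablet_spectra(
    tab_ds: SpectralDataset,
    fixed_spectra: dict[str, np.ndarray],
    fixed_concentrations: dict[str, float],
    api_fraction: float = 0.36,
    wavenumbers: np.ndarray | None = None,
) -> SpectralDataset:
    """Subtract the time-invariant contributions and rescale to closure 1.

    X_clean = (X_tab - C_fix S_fix^T) / api_fraction, with the fixed part
    spanning PVC, MCC and Rest.  Negative residual values (noise around zero)
    are retained, not clipped; their fraction is logged.
    """
    if api_fraction <= 0:
        raise ValueError("api_fraction must be > 0")
    if set(fixed_spectra) != set(fixed_concentrations):
        raise ValueError("fixed spectra and concentrations must name the same components")
    if wavenumbers is not None and not np.array_equal(
        np.asarray(wavenumbers, dtype=float), tab_ds.wavenumbers
    ):
        raise ValueError("fixed spectra are on a different wavenumber grid")
    J = tab_ds.n_wavenumbers
    S_fix, c_fix = [], []
    for name, s in fixed_spectra.items():
        s = np.asarray(s, dtype=float)
        if s.shape != (J,):
            raise ValueError(f"spectrum {name!r} has {s.shape[0]} points, grid has {J}")
        S_fix.append(s)
        c_fix.append(float(fixed_concentrations[name]))
    S_fix = np.column_stack(S_fix)
    c_fix = np.asarray(c_fix)
    X_clean = (tab_ds.absorbance - c_fix @ S_fix.T) / api_fraction
    neg = float(np.mean(X_clean < 0))
    logger.info("cleaned spectra: %.1f%% negative residual values retained", 100 * neg)
    return SpectralDataset(tab_ds.wavenumbers, X_clean, tab_ds.samples)


def step2_tablets(
    clean_ds: SpectralDataset,
    init_spectra: dict[str, np.ndarray],
    api_spectrum: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> StepResult:
    """Resolve the cleaned tablet series; kinetic fit at exact tablet ages."""
    for key in ("Inter", "Prod"):
        if key not in init_spectra:
            raise ValueError(f"missing initial spectrum {key!r} (from step 1)")
    mcr = _degradation_mcr(
        clean_ds.absorbance, np.asarray(api_spectrum, dtype=float),
        np.asarray(init_spectra["Inter"], dtype=float),
        np.asarray(init_spectra["Prod"], dtype=float),
        tol, max_iter,
    )
    fit = fit_rate_constants(mcr.C, clean_ds.ages())
    return StepResult(
        mcr=mcr, kinetics=fit,
        spectra={"Inter": mcr.S[:, 1], "Prod": mcr.S[:, 2]},
        ages=clean_ds.ages(),
    )


def step3_combined(
    clean_tab_ds: SpectralDataset,
    sub_ds: SpectralDataset,
    init_spectra: dict[str, np.ndarray],
    api_spectrum: np.ndarray,
    sub_times: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> StepResult:
    """Stacked MCR of cleaned tablets + substances, then the shared-k1 fit.

    Both matrices live on the closure-1 degradation scale, so they share one
    spectra matrix; the joint kinetic fit estimates a common first-stage
    constant with dataset-specific second-stage constants (and reports the
    fully split fit's residual for comparison).
    """
    if not np.array_equal(clean_tab_ds.wavenumbers, sub_ds.wavenumbers):
        raise ValueError("tablet and substance datasets are on different grids")
    for key in ("Inter", "Prod"):
        if key not in init_spectra:
            raise ValueError(f"missing initial spectrum {key!r} (from step 2)")
    X = np.vstack([clean_tab_ds.absorbance, sub_ds.absorbance])
    mcr = _degradation_mcr(
        X, np.asarray(api_spectrum, dtype=float),
        np.asarray(init_spectra["Inter"], dtype=float),
        np.asarray(init_spectra["Prod"], dtype=float),
        tol, max_iter,
    )
    n_tab = clean_tab_ds.n_samples
    t_sub = sub_ds.ages() if sub_times is None else np.asarray(sub_times, dtype=float)
    fit = fit_joint(mcr.C[:n_tab], clean_tab_ds.ages(), mcr.C[n_tab:], t_sub,
                    share_k1=True)
    return StepResult(
        mcr=mcr, kinetics=fit,
        spectra={"Inter": mcr.S[:, 1], "Prod": mcr.S[:, 2]},
    )


@dataclass
class PipelineReport:
    """Aggregated results of a full pipeline run."""

    steps: dict[str, StepResult]
    constants: pd.DataFrame          # name, value_month^-1, scope
    lof: pd.DataFrame                # step, lof_percent
    spectra_estimates: pd.DataFrame  # wavenumber x component (final estimates)
    provenance: dict

    _SCOPES = {"both", "tablets", "substances"}

    def __post_init__(self) -> None:
        bad = set(self.constants["scope"]) - self._SCOPES
        if bad:
            raise ValueError(f"invalid constant scopes: {sorted(bad)}")

    def summary(self) -> str:
        lines = ["Multi-step MCR + kinetics pipeline", "=" * 42]
        for _, row in self.lof.iterrows():
            lines.append(f"{row['step']:<14s} LoF = {row['lof_percent']:.2f} %")
        lines.append("-" * 42)
        for _, row in self.constants.iterrows():
            lines.append(
                f"{row['name']:<4s} = {row['value_month^-1']:.4f} month^-1  "
                f"({row['scope']})"
            )
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.constants.to_csv(out / "constants.csv", index=False, float_format="%.8g")
        self.lof.to_csv(out / "lof.csv", index=False, float_format="%.6g")
        self.spectra_estimates.to_csv(out / "spectra_estimates.csv", float_format="%.8g")
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2))

    @staticmethod
    def load_constants(out_dir: str | Path) -> pd.DataFrame:
        return pd.read_csv(Path(out_dir) / "constants.csv")


DEFAULT_CONFIG = {
    "seed": 0,
    "synthetic": {"substances": {}, "tablets": {}},
    "preprocess": {"range": [4000.0, 9000.0], "baseline": "offset"},
    "mcr": {"tol": 1e-8, "max_iter": 500},
    "kinetics": {"time_bound_months": 6.0},
}


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text()) or {}
    return _merge(DEFAULT_CONFIG, dict(config))


def _prepare(ds: SpectralDataset, pre: dict) -> SpectralDataset:
    # averaging first lowers the noise the baseline estimate sees
    lo, hi = pre["range"]
    ds = select_range(ds, lo, hi)
    ds = average_replicates(ds)
    return baseline_correct(ds, pre["baseline"])


def _gather_inputs(cfg: dict):
    """Return (tab_ds, sub_ds, known_spectra dict on the dataset grid)."""
    from .kinetics import TwoStepKineticModel
    from .simulate import simulate_substance_dataset, simulate_tablet_dataset

    if "inputs" in cfg:
        paths = cfg["inputs"]
        tab_ds = read_spectra(paths["tablets"])
        sub_ds = read_spectra(paths["substances"])
        pure = read_spectra(paths["pure_components"])
        known = {}
        for name in ("PVC", "MCC", "API"):
            row = pure.samples.index[pure.samples["sample_id"] == name]
            if len(row) == 0:
                raise ValueError(f"pure-component file lacks spectrum {name!r}")
            known[name] = (pure.wavenumbers, pure.absorbance[row[0]])
        return tab_ds, sub_ds, known

    rng = np.random.default_rng(cfg["seed"])
    sub_seed, tab_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 2))
    syn = cfg["synthetic"]
    sub_kw = dict(syn.get("substances", {}))
    tab_kw = dict(syn.get("tablets", {}))
    for kw in (sub_kw, tab_kw):
        if {"k1", "k2"} <= set(kw):
            kw["model"] = TwoStepKineticModel(kw.pop("k1"), kw.pop("k2"))
    sub_ds, _ = simulate_substance_dataset(seed=sub_seed, **sub_kw)
    tab_ds, tab_truth = simulate_tablet_dataset(seed=tab_seed, **tab_kw)
    names = list(tab_truth.names)
    known = {
        n: (tab_truth.wavenumbers, tab_truth.spectra[:, names.index(n)])
        for n in ("PVC", "MCC", "API")
    }
    return tab_ds, sub_ds, known


def run_pipeline(config) -> PipelineReport:
    """Execute preprocessing, Steps 1 / 2.1 / cleaning / 2.2 / 3 and report.

    ``config`` is a dict or a YAML file path; see ``DEFAULT_CONFIG`` for the
    recognised keys.  Synthetic mode (the default) generates the study from
    the generator defaults with seeds derived from ``config['seed']``; file
    mode (``inputs:`` with tablets/substances/pure_components paths) reads
    the delimited layout of :mod:`mcrkin.dataset`.
    """
    cfg = _load_config(config)
    pre, mcr_opts = cfg["preprocess"], cfg["mcr"]
    tab_raw, sub_raw, known_raw = _gather_inputs(cfg)
    tab_ds = _prepare(tab_raw, pre)
    sub_ds = _prepare(sub_raw, pre)
    if not np.array_equal(tab_ds.wavenumbers, sub_ds.wavenumbers):
        raise ValueError("tablet and substance datasets are on different grids")
    known = {}
    for name, (wn, s) in known_raw.items():
        if np.array_equal(np.asarray(wn, dtype=float), tab_ds.wavenumbers):
            known[name] = np.asarray(s, dtype=float)
        else:
            known[name] = interpolate_to_grid(wn, s, tab_ds.wavenumbers)[0]
    comp = TabletComposition()

    s1 = step1_substances(
        sub_ds, known["API"],
        time_bound_months=cfg["kinetics"]["time_bound_months"],
        seed=cfg["seed"], **mcr_opts,
    )
    fresh = tab_ds.subset(tab_ds.ages() == 0)
    s21 = step2_fresh_tablets(fresh, known, comp, **mcr_opts)
    clean_ds = clean_tablet_spectra(
        tab_ds,
        {"PVC": known["PVC"], "MCC": known["MCC"], "Rest": s21.spectra["Rest"]},
        {"PVC": s21.pvc_weight, "MCC": comp.c_mcc, "Rest": comp.c_rest},
        api_fraction=comp.c_api,
    )
    s22 = step2_tablets(clean_ds, s1.spectra, known["API"], **mcr_opts)
    s3 = step3_combined(
        clean_ds, sub_ds, s22.spectra, known["API"], sub_times=s1.ages, **mcr_opts
    )

    steps = {"step1": s1, "step2.1": s21, "step2.2": s22, "step3": s3}
    constants = s3.kinetics.to_frame()
    lof = pd.DataFrame(
        [(k, r.lof_percent) for k, r in steps.items()],
        columns=["step", "lof_percent"],
    )
    spectra = pd.DataFrame(
        {
            "API": known["API"],
            "Inter": s3.spectra["Inter"],
            "Prod": s3.spectra["Prod"],
            "Rest": s21.spectra["Rest"],
        },
        index=pd.Index(tab_ds.wavenumbers, name="wavenumber"),
    )
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    provenance = {
        "config_hash": cfg_hash, "seed": cfg["seed"], "mcrkin_version": __version__,
        "numpy_version": np.__version__,
    }
    return PipelineReport(
        steps=steps, constants=constants, lof=lof,
        spectra_estimates=spectra, provenance=provenance,
    )
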