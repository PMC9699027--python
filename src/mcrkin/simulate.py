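"""Synthetic NIR aging-study generator with known ground truth.

Emulates the statistical structure the pipeline assumes: bilinear spectra
from Gaussian-peak pure-component spectra, degradation-subsystem
concentrations driven by the sequential two-step first-order scheme, a
blister weighting factor for tablets, additive iid Gaussian noise plus a
per-spectrum constant baseline offset, replicate measurements, and uncertain
nominal ages for substance samples.

Two study presets mirror the long-term aging study the pipeline targets:
36 substance spectra over 0-120 months and 5 tablet batches at ages
{0, 9, 18, 76, 79} months; both fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SpectralDataset
from .kinetics import TwoStepKineticModel, _profile_array

__all__ = [
    "PeakSpec",
    "SimulationTruth",
    "default_grid",
    "make_component_spectra",
    "simulate_substance_dataset",
    "simulate_tablet_dataset",
    "SUBSTANCE_COMPONENTS",
    "TABLET_COMPONENTS",
    "DEFAULT_PEAKS",
]

#: Gaussian peaks per component: name -> [(center cm^-1, sigma cm^-1, amplitude)].
PeakSpec = dict[str, list[tuple[float, float, float]]]

SUBSTANCE_COMPONENTS = ("API", "Inter", "Prod")
TABLET_COMPONENTS = ("PVC", "MCC", "Rest", "API", "Inter", "Prod")

# Band positions chosen to overlap heavily in the combination region
# (4000-5500 cm^-1, as NIR components do) while staying distinguishable
# (pairwise cosine < 0.95).  The intermediate carries a hydroxyl-like band
# near 5000 cm^-1.  Widths keep every spectrum near zero at the 9000 cm^-1
# edge (weak second-overtone region), so a per-spectrum additive offset is
# removable by minimum-subtraction baseline correction.
DEFAULT_PEAKS: PeakSpec = {
    "API":   [(4350, 80, 1.0), (4680, 90, 0.8), (5950, 150, 0.5), (8400, 150, 0.25)],
    "Inter": [(5000, 90, 1.0), (4400, 100, 0.55), (6200, 160, 0.45), (6900, 200, 0.35)],
    "Prod":  [(4250, 90, 0.9), (5200, 120, 0.7), (7100, 250, 0.45), (4800, 100, 0.3)],
    "MCC":   [(4770, 110, 0.9), (5180, 130, 0.85), (6850, 220, 0.5)],
    "PVC":   [(4330, 70, 0.9), (5780, 120, 0.6), (8250, 180, 0.3)],
    "Rest":  [(4600, 120, 0.8), (5280, 80, 0.6), (4750, 80, 0.5), (8300, 170, 0.35)],
}

#: default tablet blister weighting factor
DEFAULT_PVC_WEIGHT = 0.4


def default_grid(lo: float = 4000.0, hi: float = 9000.0, step: float = 8.0) -> np.ndarray:
    """Wavenumber grid in cm^-1 (ascending).  8 cm^-1 spacing fully resolves
    the default Gaussian bands (narrowest sigma 70 cm^-1)."""
    return np.arange(lo, hi + 0.5 * step, step)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset, for recovery studies."""

    names: tuple[str, ...]
    spectra: np.ndarray            # J x N, column order = names
    concentrations: np.ndarray     # per-object (pre-replicate) I x N
    wavenumbers: np.ndarray
    model: TwoStepKineticModel
    true_ages: np.ndarray
    nominal_ages: np.ndarray
    pvc_weight: float | None = None
    noise_sd: float = 0.0          # absolute sd actually applied
    baseline_offset_sd: float = 0.0
    seed: int | None = None

    def spectra_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.spectra, columns=list(self.names),
            index=pd.Index(self.wavenumbers, name="wavenumber"),
        )

    def constants_frame(self) -> pd.DataFrame:
        rows = [("k1", self.model.k1), ("k2", self.model.k2)]
        if self.pvc_weight is not None:
            rows.append(("pvc_weight", self.pvc_weight))
        rows.append(("seed", self.seed if self.seed is not None else np.nan))
        return pd.DataFrame(rows, columns=["name", "value"])


def make_component_spectra(peaks: PeakSpec, grid: np.ndarray) -> np.ndarray:
    """Evaluate each component's Gaussian peak sum on the grid; J x N, >= 0."""
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 4000 - 1e-9 or grid.max() > 9000 + 1e-9:
        raise ValueError("grid must lie within 4000-9000 cm^-1")
    cols = []
    for name, plist in peaks.items():
        if not plist:
            raise ValueError(f"component {name!r} has an empty peak list")
        s = np.zeros_like(grid)
        for center, width, amp in plist:
            if width <= 0 or amp <= 0:
                raise ValueError(f"component {name!r}: widths and amplitudes must be > 0")
            s += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
        cols.append(s)
    return np.column_stack(cols)


def _noise(rng, X0: np.ndarray, noise: float, baseline_offset_sd: float):
    """Additive Gaussian noise (sd relative to mean signal) + per-row offset."""
    scale = float(np.mean(np.abs(X0)))
    sd = noise * scale
    off_sd = baseline_offset_sd * scale
    E = rng.normal(0.0, sd, size=X0.shape) if sd > 0 else np.zeros_like(X0)
    off = (rng.normal(0.0, off_sd, size=(X0.shape[0], 1))
           if off_sd > 0 else np.zeros((X0.shape[0], 1)))
    return X0 + E + off, sd, off_sd


def simulate_substance_dataset(
    n_samples: int = 36,
    age_range: tuple[float, float] = (0.0, 120.0),
    model: TwoStepKineticModel | None = None,
    noise: float = 0.01,
    time_jitter_months: float = 3.0,
    baseline_offset_sd: float = 0.005,
    replicates: int = 3,
    grid: np.ndarray | None = None,
    peaks: PeakSpec | None = None,
    seed: int | None = None,
) -> tuple[SpectralDataset, SimulationTruth]:
    """Simulate a pure-substance aging series (closed API/Inter/Prod system).

    True ages are spaced evenly over ``age_range``; concentrations follow the
    two-step profile exactly; X = C S^T plus noise and per-spectrum offsets.
    Nominal (metadata) ages are the true ages plus uniform jitter within
    +/- ``time_jitter_months`` (clipped at 0), emulating production dates
    known only to within a few months.
    """
    if n_samples < 4:
        raise ValueError("need n_samples >= 4 (kinetics unidentifiable below)")
    if noise < 0 or baseline_offset_sd < 0 or time_jitter_months < 0:
        raise ValueError("noise, offset and jitter levels must be >= 0")
    model = model or TwoStepKineticModel(0.023, 0.01)
    rng = np.random.default_rng(seed)
    wn = default_grid() if grid is None else np.asarray(grid, dtype=float)
    pk = peaks or {k: DEFAULT_PEAKS[k] for k in SUBSTANCE_COMPONENTS}
    names = tuple(pk)
    S = make_component_spectra(pk, wn)

    t_true = np.linspace(age_range[0], age_range[1], n_samples)
    C = _profile_array(t_true, model.k1, model.k2, model.c0)
    jit = (rng.uniform(-time_jitter_months, time_jitter_months, n_samples)
           if time_jitter_months > 0 else np.zeros(n_samples))
    t_nom = np.clip(t_true + jit, 0.0, None)

    X0 = np.repeat(C @ S.T, replicates, axis=0)
    X, sd, off_sd = _noise(rng, X0, noise, baseline_offset_sd)
    meta = pd.DataFrame({
        "sample_id": np.repeat([f"sub{i:02d}" for i in range(n_samples)], replicates),
        "material_kind": "substance",
        "age_months": np.repeat(t_nom, replicates),
        "batch": "S1",
        "replicate": np.tile(np.arange(replicates), n_samples),
    })
    ds = SpectralDataset(wn, X, meta)
    truth = SimulationTruth(
        names=names, spectra=S, concentrations=C, wavenumbers=wn, model=model,
        true_ages=t_true, nominal_ages=t_nom, noise_sd=sd,
        baseline_offset_sd=off_sd, seed=seed,
    )
    return ds, truth


def simulate_tablet_dataset(
    batches: int = 5,
    ages: tuple[float, ...] = (0.0, 9.0, 18.0, 76.0, 79.0),
    tablets_per_cell: int = 2,
    composition=None,
    model: TwoStepKineticModel | None = None,
    pvc_weight: float = DEFAULT_PVC_WEIGHT,
    noise: float = 0.01,
    baseline_offset_sd: float = 0.005,
    replicates: int = 3,
    grid: np.ndarray | None = None,
    peaks: PeakSpec | None = None,
    seed: int | None = None,
) -> tuple[SpectralDataset, SimulationTruth]:
    """Simulate blister-packed tablet spectra (6-component bilinear model).

    Each tablet's spectrum is
    ``pvc_weight*s_PVC + c_mcc*s_MCC + c_rest*s_Rest + c_api*(cA*s_API +
    cB*s_Inter + cC*s_Prod)`` with (cA, cB, cC) from the two-step profile at
    the tablet's exact age (tablet production dates are reliable, so no age
    jitter).  The degradation subsystem's concentrations therefore sum to
    the prescribed API fraction at every age.
    """
    from .pipeline import TabletComposition  # local import avoids a cycle

    ages = tuple(float(a) for a in ages)
    if 0.0 not in ages:
        raise ValueError("ages must include 0 (fresh tablets are required)")
    if noise < 0 or baseline_offset_sd < 0:
        raise ValueError("noise levels must be >= 0")
    comp = composition or TabletComposition()
    model = model or TwoStepKineticModel(0.028, 0.003)
    rng = np.random.default_rng(seed)
    wn = default_grid() if grid is None else np.asarray(grid, dtype=float)
    pk = peaks or {k: DEFAULT_PEAKS[k] for k in TABLET_COMPONENTS}
    names = tuple(pk)
    S = make_component_spectra(pk, wn)

    rows, meta_rows = [], []
    for b in range(batches):
        for age in ages:
            prof = _profile_array(np.array([age]), model.k1, model.k2, 1.0)[0]
            for i in range(tablets_per_cell):
                conc = {
                    "PVC": pvc_weight, "MCC": comp.c_mcc, "Rest": comp.c_rest,
                    "API": comp.c_api * prof[0], "Inter": comp.c_api * prof[1],
                    "Prod": comp.c_api * prof[2],
                }
                rows.append([conc[n] for n in names])
                meta_rows.append((f"tabB{b + 1}A{age:g}N{i}", f"B{b + 1}", age))
    C = np.array(rows)
    n_obj = len(rows)
    X0 = np.repeat(C @ S.T, replicates, axis=0)
    X, sd, off_sd = _noise(rng, X0, noise, baseline_offset_sd)
    meta = pd.DataFrame({
        "sample_id": np.repeat([m[0] for m in meta_rows], replicates),
        "material_kind": "tablet",
        "age_months": np.repeat([m[2] for m in meta_rows], replicates),
        "batch": np.repeat([m[1] for m in meta_rows], replicates),
        "replicate": np.tile(np.arange(replicates), n_obj),
    })
    ds = SpectralDataset(wn, X, meta)
    true_ages = np.array([m[2] for m in meta_rows], dtype=float)
    truth = SimulationTruth(
        names=names, spectra=S, concentrations=C, wavenumbers=wn, model=model,
        true_ages=true_ages, nominal_ages=true_ages.copy(),
        pvc_weight=pvc_weight, noise_sd=sd, baseline_offset_sd=off_sd, seed=seed,
    )
    return ds, truth
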