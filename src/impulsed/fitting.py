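"""Inverse problem: voxelwise two-compartment fits and mono-exponential ADCs.

``fit_impulsed`` performs bounded nonlinear least squares for
(d_mean, f_in, D_ex) with D_in held fixed, multi-started from a coarse grid;
``fit_adc`` fits ln(S/S0) = -b * ADC per sequence; ``fit_maps`` applies both
voxelwise inside a lesion mask and aggregates ROI summaries (cellularity is
computed per voxel and then averaged, not taken as a ratio of means).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .protocol import adc_name
from .signal_model import PARAM_BOUNDS, TissueParams, TwoCompartmentModel

__all__ = ["ADCFit", "FitResult", "ParameterMaps", "FitOptions",
           "fit_adc", "fit_impulsed", "fit_maps", "normalize_per_sequence"]

# multi-start grid over (d_mean, f_in, D_ex)
_GRID_D = (6.0, 10.0, 14.0, 18.0, 22.0, 26.0)
_GRID_F = (0.1, 0.3, 0.5, 0.7)
_GRID_DEX = (0.5, 1.5, 2.5)

# interior bounds: the physiological constraints are open intervals
_LO = np.array([PARAM_BOUNDS["d_mean"][0] + 1e-6, 1e-6,
                PARAM_BOUNDS["D_ex"][0] + 1e-6])
_HI = np.array([PARAM_BOUNDS["d_mean"][1] - 1e-6, 1.0 - 1e-6,
                PARAM_BOUNDS["D_ex"][1] - 1e-6])


@dataclass(frozen=True)
class ADCFit:
    """Mono-exponential ADC fit for one sequence."""

    adc: float  # um^2/ms
    s0: float
    r_squared: float
    sequence_label: str = ""
    flagged: bool = False


@dataclass(frozen=True)
class FitResult:
    """Best-of-restarts two-compartment fit for one voxel or ROI signal."""

    params: TissueParams
    residual_rms: float
    converged: bool
    n_restarts_used: int
    on_boundary: bool = False
    d_spread: float = 0.0  # relative spread of d_mean over near-optimal restarts
    identifiable: bool = True

    @property
    def cellularity(self) -> float:
        return self.params.cellularity


@dataclass
class FitOptions:
    n_refine: int = 6  # local refinements launched from the best grid starts
    xtol: float = 1e-8
    ftol: float = 1e-8
    max_nfev: int = 500
    spread_threshold: float = 0.2
    #: signal difference per shell below which two fits are indistinguishable
    indist_tol: float = 2e-3
    profile_d: bool = True  # run the d-profile identifiability diagnostic


def fit_adc(b_values, signals, sequence_label: str = "") -> ADCFit:
    """Least-squares line through (b, ln S); ADC = -slope in um^2/ms.

    ``b_values`` in s/mm^2, ``signals`` normalized so S(b=0) ~ 1. Negative
    slopes are clipped to zero and flagged. Requires >= 2 distinct b and all
    signals positive.
    """
    b = np.asarray(b_values, dtype=float)
    s = np.asarray(signals, dtype=float)
    if b.size < 2 or np.unique(b).size < 2:
        raise ValueError("need at least two distinct b-values")
    if np.any(s <= 0):
        raise ValueError("non-positive signal; voxel must be flagged upstream")
    y = np.log(s)
    slope, intercept = np.polyfit(b, y, 1)
    resid = y - (slope * b + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    adc = -slope * 1e3  # (1/(s/mm^2)) -> um^2/ms
    flagged = False
    if adc < 0:
        adc, flagged = 0.0, True
    return ADCFit(adc=float(adc), s0=float(np.exp(intercept)),
                  r_squared=float(r2), sequence_label=sequence_label,
                  flagged=flagged)


def normalize_per_sequence(signal_vector, shells):
    """Normalize a flattened acquisition vector by each sequence's b=0 entry.

    Returns (b>0 shell list, normalized signals, s0 per sequence label).
    """
    sig = np.asarray(signal_vector, dtype=float)
    if sig.size != len(shells):
        raise ValueError(f"signal vector length {sig.size} does not match "
                         f"{len(shells)} protocol shells")
    s0 = {}
    for (label, b), v in zip(shells, sig):
        if b == 0:
            s0[label] = v
    out_shells, out_sig = [], []
    for (label, b), v in zip(shells, sig):
        if b == 0:
            continue
        if label not in s0 or s0[label] <= 0:
            raise ValueError(f"missing or non-positive b=0 signal for {label}")
        out_shells.append((label, b))
        out_sig.append(v / s0[label])
    return out_shells, np.asarray(out_sig), s0


class _ShellPredictor:
    """Vectorized S/S0 predictor for a fixed shell list."""

    def __init__(self, model: TwoCompartmentModel, shells):
        self.model = model
        self.labels = sorted({lab for lab, _ in shells})
        self.b_ms = np.array([b for _, b in shells]) * 1e-3
        self.groups = {lab: np.array([i for i, (l, _) in enumerate(shells)
                                      if l == lab]) for lab in self.labels}

    def __call__(self, d_mean: float, f_in: float, D_ex: float) -> np.ndarray:
        s_in = np.empty_like(self.b_ms)
        for lab in self.labels:
            idx = self.groups[lab]
            s_in[idx] = np.exp(-self.b_ms[idx] *
                               float(self.model.intra_adc(lab, d_mean)))
        return f_in * s_in + (1.0 - f_in) * np.exp(-self.b_ms * D_ex)


def fit_impulsed(shells, signals, model: TwoCompartmentModel,
                 opts: FitOptions | None = None) -> FitResult:
    """Bounded multi-start least squares for (d_mean, f_in, D_ex).

    ``shells`` is a list of (sequence label, b) with b > 0 and ``signals`` the
    matching S/S0 values. Needs at least two distinct sequence families
    (distinct diffusion times) for identifiability.
    """
    opts = opts or FitOptions()
    sig = np.asarray(signals, dtype=float)
    if len({lab for lab, _ in shells}) < 2:
        raise ValueError("signals must cover >= 2 sequences for identifiability")
    predict = _ShellPredictor(model, shells)

    def residual(p):
        return predict(*p) - sig

    starts = [(d, f, dex) for d in _GRID_D for f in _GRID_F for dex in _GRID_DEX]
    grid_obj = np.array([float(np.sum(residual(p) ** 2)) for p in starts])
    order = np.argsort(grid_obj, kind="stable")
    solutions = []
    any_converged = False
    for k in order[:opts.n_refine]:
        res = least_squares(residual, np.asarray(starts[k]),
                            bounds=(_LO, _HI), xtol=opts.xtol, ftol=opts.ftol,
                            max_nfev=opts.max_nfev)
        solutions.append((float(np.sum(res.fun ** 2)), res.x))
        any_converged = any_converged or bool(res.success)
    if not solutions or not any_converged:
        k = int(order[0])
        x = np.clip(np.asarray(starts[k]), _LO, _HI)
        obj = float(np.sum(residual(x) ** 2))
        params = TissueParams(*x, D_in=model.D_in)
        return FitResult(params=params,
                         residual_rms=float(np.sqrt(obj / sig.size)),
                         converged=False, n_restarts_used=len(solutions))

    # best solution; ties broken toward smaller d_mean for determinism
    best_obj = min(o for o, _ in solutions)
    best = min((x for o, x in solutions if o <= best_obj * (1 + 1e-12) + 1e-300),
               key=lambda x: x[0])
    # identifiability: profile the objective over fixed diameters, refitting
    # (f_in, D_ex); diameters whose profile objective is indistinguishable
    # from the optimum (within the per-shell signal tolerance) span the
    # near-optimal d set
    d_near = [float(best[0])]
    if opts.profile_d:
        floor = sig.size * opts.indist_tol ** 2
        for d_fix in _GRID_D:
            res_p = least_squares(
                lambda q: predict(d_fix, q[0], q[1]) - sig,
                np.clip(best[1:], _LO[1:], _HI[1:]),
                bounds=(_LO[1:], _HI[1:]), xtol=opts.xtol, ftol=opts.ftol,
                max_nfev=opts.max_nfev)
            if float(np.sum(res_p.fun ** 2)) <= best_obj * 1.05 + floor:
                d_near.append(d_fix)
    d_vals = np.array(d_near)
    d_spread = float((d_vals.max() - d_vals.min()) / max(d_vals.mean(), 1e-12))
    on_boundary = bool(np.any(np.isclose(best, _LO, atol=1e-5)) or
                       np.any(np.isclose(best, _HI, atol=1e-5)))
    params = TissueParams(float(best[0]), float(best[1]), float(best[2]),
                          D_in=model.D_in)
    return FitResult(params=params,
                     residual_rms=float(np.sqrt(best_obj / sig.size)),
                     converged=True, n_restarts_used=len(solutions),
                     on_boundary=on_boundary, d_spread=d_spread,
                     identifiable=d_spread <= opts.spread_threshold)


@dataclass
class ParameterMaps:
    """Voxelwise parameter maps plus the ROI summary table."""

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    roi_summary: pd.DataFrame
    n_flagged: int = 0

    PARAM_NAMES = ("d_mean", "f_in", "D_ex", "cellularity")


def fit_maps(volume4d: np.ndarray, mask: np.ndarray,
             model: TwoCompartmentModel,
             opts: FitOptions | None = None,
             lesion_id: str = "lesion") -> ParameterMaps:
    """Voxelwise two-compartment + ADC fits inside ``mask``.

    ``volume4d`` is indexed (x, y, z, acquisition) in the protocol's flattened
    (sequence, b) order. Voxels with non-positive signals are flagged,
    excluded from the ROI summary, and left NaN in the maps.
    """
    vol = np.asarray(volume4d, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if vol.ndim != 4:
        raise ValueError("volume must be 4D (x, y, z, acquisition)")
    shells = model.protocol.shells()
    if vol.shape[-1] != len(shells):
        raise ValueError(f"expected {len(shells)} acquisitions, got {vol.shape[-1]}")
    if vol.shape[:3] != mask.shape:
        raise ValueError("mask grid does not match the volume")
    if not mask.any():
        raise ValueError("empty mask")

    seq_labels = [s.label for s in model.protocol.sequences]
    map_names = list(ParameterMaps.PARAM_NAMES) + [adc_name(l) for l in seq_labels]
    maps = {name: np.full(mask.shape, np.nan) for name in map_names}
    records: list[dict] = []
    n_flagged = 0
    for ijk in np.argwhere(mask):
        voxel = vol[tuple(ijk)]
        rec: dict = {}
        try:
            fit_shells, norm_sig, _ = normalize_per_sequence(voxel, shells)
            if np.any(norm_sig <= 0):
                raise ValueError("non-positive signal")
        except ValueError:
            n_flagged += 1
            continue
        fr = fit_impulsed(fit_shells, norm_sig, model, opts)
        rec["d_mean"] = fr.params.d_mean
        rec["f_in"] = fr.params.f_in
        rec["D_ex"] = fr.params.D_ex
        rec["cellularity"] = fr.cellularity
        adc_ok = True
        for label in seq_labels:
            bs = [b for l, b in fit_shells if l == label]
            ss = [s for (l, _), s in zip(fit_shells, norm_sig) if l == label]
            adc = fit_adc([0.0] + bs, [1.0] + list(ss), label)
            if adc.flagged:
                adc_ok = False
            rec[adc_name(label)] = adc.adc
        if not adc_ok:
            n_flagged += 1
            continue
        for name, val in rec.items():
            maps[name][tuple(ijk)] = val
        records.append(rec)

    if not records:
        raise ValueError("all masked voxels were flagged")
    df = pd.DataFrame(records)
    summary = pd.DataFrame({
        "lesion_id": lesion_id,
        "parameter": df.columns,
        "mean": df.mean().values,
        "sd": df.std(ddof=1).fillna(0.0).values if len(df) > 1
              else np.zeros(df.shape[1]),
        "n_voxels": len(df),
        "n_flagged": n_flagged,
    })
    return ParameterMaps(maps=maps, mask=mask, roi_summary=summary,
                         n_flagged=n_flagged)
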