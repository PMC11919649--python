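"""Diffusion-encoding gradient waveforms and acquisition protocols.

Builds discretized effective gradient time courses (sign-flipped after the
refocusing pulse) for pulsed (PGSE) and cosine oscillating (OGSE) gradient
spin-echo sequences, computes b-values numerically for arbitrary waveforms,
and assembles multi-sequence acquisition protocols from JSON configs.

Units: time in ms, gradient amplitude in mT/m, b-values in s/mm^2,
gyromagnetic ratio gamma in rad s^-1 T^-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "G_MAX_PER_AXIS",
    "GradientWaveform",
    "Sequence",
    "AcquisitionProtocol",
    "ProtocolError",
    "make_pgse",
    "make_ogse",
    "b_value",
    "scale_to_b",
    "effective_diffusion_time",
    "load_protocol",
    "default_protocol",
]

#: Proton gyromagnetic ratio (rad s^-1 T^-1).
GAMMA_PROTON = 2.675e8

#: Per-axis hardware gradient limit (mT/m).
G_MAX_PER_AXIS = 45.0

#: Diffusion gradients may be played on all three axes simultaneously, so the
#: effective amplitude limit along the diagonal is sqrt(3) times the per-axis
#: maximum.
G_MAX_EFFECTIVE = G_MAX_PER_AXIS * np.sqrt(3.0)


class ProtocolError(ValueError):
    """Raised for infeasible sequence timing or gradient demands."""


def adc_name(label: str) -> str:
    """Canonical ADC column name for a sequence label (ADC_DWI, ADC_17Hz...)."""
    return "ADC_" + label.removeprefix("OGSE_")


@dataclass(frozen=True)
class GradientWaveform:
    """Discretized effective diffusion gradient for one spin-echo sequence.

    ``g_eff`` holds cell-averaged amplitudes on a uniform grid of step ``dt``
    covering [0, TE]; the second encoding lobe carries the opposite sign to
    account for the refocusing pulse, so the zeroth moment vanishes exactly.
    """

    dt: float
    g_eff: np.ndarray
    family: str  # "pgse" | "ogse"
    delta: float
    Delta: float
    n_cycles: int
    f_nominal: float
    TE: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ProtocolError("dt must be positive")
        if self.family not in ("pgse", "ogse"):
            raise ProtocolError(f"unknown waveform family {self.family!r}")
        g = np.asarray(self.g_eff, dtype=float)
        object.__setattr__(self, "g_eff", g)
        if g.ndim != 1 or g.size * self.dt > self.TE * (1 + 1e-9):
            raise ProtocolError("waveform samples must fit inside [0, TE]")
        gmax = np.max(np.abs(g))
        if gmax > 0 and abs(np.sum(g) * self.dt) > 1e-9 * gmax * self.TE:
            raise ProtocolError("waveform violates the rephasing condition")

    @property
    def amplitude(self) -> float:
        """Peak gradient amplitude |g| (mT/m)."""
        return float(np.max(np.abs(self.g_eff)))

    @property
    def f_realized(self) -> float:
        """Oscillation frequency actually played out (Hz); 0 for PGSE."""
        if self.family == "pgse":
            return 0.0
        return self.n_cycles / self.delta * 1e3

    @property
    def times(self) -> np.ndarray:
        """Cell-center time coordinates (ms)."""
        return (np.arange(self.g_eff.size) + 0.5) * self.dt

    def q_of_t(self, gamma: float = GAMMA_PROTON) -> np.ndarray:
        """First gradient moment q(t) = gamma * int g dt at cell edges (rad/m).

        Returned on the edge grid ``0, dt, ..., N*dt`` (length N+1); exact
        for the ideal waveform because ``g_eff`` stores cell averages.
        """
        dt_s = self.dt * 1e-3
        g_si = self.g_eff * 1e-3  # T/m
        q = np.concatenate([[0.0], np.cumsum(g_si) * dt_s]) * gamma
        return q


def _cell_average_lobe(edges: np.ndarray, t_start: float, t_end: float,
                       antideriv) -> np.ndarray:
    """Average of a lobe waveform over each grid cell via its antiderivative.

    ``antideriv(t)`` must be the antiderivative of the lobe shape on
    [t_start, t_end]; outside that support the lobe is zero.
    """
    lo = np.clip(edges[:-1], t_start, t_end)
    hi = np.clip(edges[1:], t_start, t_end)
    dt = edges[1] - edges[0]
    return (antideriv(hi) - antideriv(lo)) / dt


def _build_grid(TE: float, dt: float) -> tuple[np.ndarray, float]:
    """Uniform edge grid covering [0, TE] exactly; dt is snapped down to fit."""
    n = int(np.ceil(TE / dt - 1e-12))
    if n < 2:
        raise ProtocolError("TE must span at least two samples")
    return np.linspace(0.0, TE, n + 1), TE / n


def make_pgse(G: float, delta: float, Delta: float, TE: float,
              dt: float | None = None) -> GradientWaveform:
    """Rectangular-lobe PGSE effective waveform.

    Lobes of amplitude +G and (effectively) -G, duration ``delta``, leading
    edges separated by ``Delta``, centered so the midpoint of the lobe pair
    sits at TE/2.
    """
    if dt is None:
        dt = delta / 256.0
    if delta <= 0 or Delta < delta:
        raise ProtocolError("need 0 < delta <= Delta")
    if delta + Delta > TE:
        raise ProtocolError(
            f"PGSE timing does not fit: delta+Delta={delta + Delta:.1f} ms > TE={TE:.1f} ms")
    if dt > delta / 50:
        raise ProtocolError("dt too coarse: require dt <= delta/50")
    t0 = (TE - Delta - delta) / 2.0
    edges, dt = _build_grid(TE, dt)

    def rect(a, b):
        # antiderivative of the unit rectangle on [a, b]
        return lambda t: np.clip(t, a, b) - a

    g = G * _cell_average_lobe(edges, t0, t0 + delta, rect(t0, t0 + delta))
    g -= G * _cell_average_lobe(edges, t0 + Delta, t0 + Delta + delta,
                                rect(t0 + Delta, t0 + Delta + delta))
    return GradientWaveform(dt=dt, g_eff=g, family="pgse", delta=delta,
                            Delta=Delta, n_cycles=0, f_nominal=0.0, TE=TE)


def make_ogse(G: float, delta: float, Delta: float, n_cycles: int, TE: float,
              dt: float | None = None, f_nominal: float = 0.0) -> GradientWaveform:
    """Cosine-modulated OGSE effective waveform.

    Each lobe is ``G * cos(2 pi f (t - t_lobe))`` with ``f = n_cycles/delta``;
    the second lobe is sign-flipped. Integer ``n_cycles`` guarantees zero net
    first moment per lobe.
    """
    if n_cycles < 1 or int(n_cycles) != n_cycles:
        raise ProtocolError("n_cycles must be a positive integer")
    n_cycles = int(n_cycles)
    if delta <= 0 or Delta < delta:
        raise ProtocolError("need 0 < delta <= Delta")
    if delta + Delta > TE:
        raise ProtocolError(
            f"OGSE timing does not fit: delta+Delta={delta + Delta:.1f} ms > TE={TE:.1f} ms")
    if dt is None:
        dt = delta / (n_cycles * 256.0)
    if dt > delta / (n_cycles * 100.0):
        raise ProtocolError("dt too coarse: require >= 100 samples per cycle")
    f_ms = n_cycles / delta  # cycles per ms
    w = 2.0 * np.pi * f_ms
    t0 = (TE - Delta - delta) / 2.0
    edges, dt = _build_grid(TE, dt)

    def cos_anti(t_lobe):
        return lambda t: np.sin(w * (np.clip(t, t_lobe, t_lobe + delta) - t_lobe)) / w

    g = G * _cell_average_lobe(edges, t0, t0 + delta, cos_anti(t0))
    g -= G * _cell_average_lobe(edges, t0 + Delta, t0 + Delta + delta,
                                cos_anti(t0 + Delta))
    return GradientWaveform(dt=dt, g_eff=g, family="ogse", delta=delta,
                            Delta=Delta, n_cycles=n_cycles,
                            f_nominal=f_nominal or f_ms * 1e3, TE=TE)


def b_value(w: GradientWaveform, gamma: float = GAMMA_PROTON) -> float:
    """Numerical b-value (s/mm^2): integral of q(t)^2 over [0, TE]."""
    q = w.q_of_t(gamma)  # rad/m at cell edges
    dt_s = w.dt * 1e-3
    b_si = np.trapezoid(q * q, dx=dt_s)  # s/m^2
    return float(b_si * 1e-6)


def scale_to_b(w: GradientWaveform, b_target: float,
               gamma: float = GAMMA_PROTON,
               g_max: float = G_MAX_EFFECTIVE,
               label: str = "") -> GradientWaveform:
    """Rescale gradient amplitude so the waveform realizes ``b_target``.

    b scales with G^2, so the amplitude factor is sqrt(b_target/b_current).
    Raises :class:`ProtocolError` if the required amplitude exceeds ``g_max``.
    """
    if b_target < 0:
        raise ProtocolError("b_target must be non-negative")
    if b_target == 0:
        return replace(w, g_eff=np.zeros_like(w.g_eff))
    b_cur = b_value(w, gamma)
    if b_cur <= 0:
        raise ProtocolError("cannot scale a zero waveform to a positive b")
    factor = np.sqrt(b_target / b_cur)
    g_req = w.amplitude * factor
    if g_req > g_max * (1 + 1e-9):
        seq = f" for sequence {label!r}" if label else ""
        raise ProtocolError(
            f"b={b_target:g} s/mm^2 requires G={g_req:.1f} mT/m > limit {g_max:.1f}{seq}")
    return replace(w, g_eff=w.g_eff * factor)


def effective_diffusion_time(w: GradientWaveform) -> float:
    """Effective diffusion time (ms): Delta - delta/3 for PGSE, 1/(4f) for OGSE."""
    if w.family == "pgse":
        return w.Delta - w.delta / 3.0
    return 250.0 / w.f_realized  # 1/(4f) in ms with f in Hz


@dataclass(frozen=True)
class Sequence:
    """One protocol entry: a unit-amplitude waveform template plus its b list."""

    label: str
    template: GradientWaveform
    b_values: tuple[float, ...]
    td_printed: float | None = None  # vendor-reported effective td, if any

    def waveforms(self, gamma: float = GAMMA_PROTON,
                  g_max: float = G_MAX_EFFECTIVE) -> list[GradientWaveform]:
        return [scale_to_b(self.template, b, gamma, g_max, self.label)
                for b in self.b_values]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Ordered collection of diffusion sequences sharing one gamma."""

    sequences: tuple[Sequence, ...]
    gamma: float = GAMMA_PROTON
    g_max: float = G_MAX_EFFECTIVE

    def __post_init__(self) -> None:
        for seq in self.sequences:
            bs = np.asarray(seq.b_values, dtype=float)
            if bs.size < 2 or bs[0] != 0 or np.any(np.diff(bs) <= 0):
                raise ProtocolError(
                    f"{seq.label}: b-values must start at 0 and strictly increase")
            # feasibility of the largest b under the gradient limit
            scale_to_b(seq.template, bs[-1], self.gamma, self.g_max, seq.label)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sequences)

    def __getitem__(self, label: str) -> Sequence:
        for s in self.sequences:
            if s.label == label:
                return s
        raise KeyError(label)

    def shells(self) -> list[tuple[str, float]]:
        """Flattened acquisition order: (sequence label, b) pairs."""
        return [(s.label, b) for s in self.sequences for b in s.b_values]


def _sequence_from_config(entry: dict) -> Sequence:
    family = entry["family"]
    kwargs = dict(delta=entry["delta_ms"], Delta=entry["Delta_ms"],
                  TE=entry["TE_ms"])
    if family == "pgse":
        w = make_pgse(G=1.0, **kwargs)
    elif family == "ogse":
        w = make_ogse(G=1.0, n_cycles=entry["n_cycles"],
                      f_nominal=entry.get("f_nominal_hz", 0.0), **kwargs)
    else:
        raise ProtocolError(f"unknown family {family!r}")
    return Sequence(label=entry["label"], template=w,
                    b_values=tuple(float(b) for b in entry["b_values_s_mm2"]),
                    td_printed=entry.get("td_printed_ms"))


def load_protocol(path: str | Path | dict,
                  gamma: float = GAMMA_PROTON,
                  g_max: float = G_MAX_EFFECTIVE) -> AcquisitionProtocol:
    """Load an acquisition protocol from a JSON file or pre-parsed dict."""
    if isinstance(path, dict):
        cfg = path
    else:
        cfg = json.loads(Path(path).read_text())
    gamma = cfg.get("gamma", gamma) if isinstance(cfg, dict) else gamma
    entries = cfg["sequences"] if isinstance(cfg, dict) else cfg
    seqs = tuple(_sequence_from_config(e) for e in entries)
    return AcquisitionProtocol(sequences=seqs, gamma=gamma, g_max=g_max)


def default_protocol(**kwargs) -> AcquisitionProtocol:
    """The packaged clinical protocol (DWI + PGSE + 17/33 Hz cosine OGSE)."""
    with resources.files("impulsed.data").joinpath("table1.json").open() as fh:
        cfg = json.load(fh)
    return load_protocol(cfg, **kwargs)
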