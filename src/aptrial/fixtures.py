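"""Synthetic AP traces and toy populations for fast, ODE-free testing.

:func:`synth_trace` builds an idealised piecewise-linear action potential —
resting potential, fast (or deliberately slowed) upstroke, plateau, linear
repolarisation — with optional injected features that trigger the abnormality
detectors by construction: a triangular EAD-like bump after the peak
(repolarisation abnormality) or a delayed/low upstroke (depolarisation
abnormality).  Traces are exact realisations of their spec, so detector and
biomarker behaviour can be asserted against brute-force scans; optional
seeded Gaussian jitter (<= a fraction of a mV) exercises noise tolerance.

:func:`toy_population` draws conductance tables in the sampling box, with an
optional planted sub-group (e.g. a low-g_Kr subset) for profiling-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .cell_engine import SCALING_ORDER, APTrace, IonicScaling
from .population import DEFAULT_BOUNDS, PopulationTable

__all__ = ["SynthTraceSpec", "synth_trace", "toy_population"]


@dataclass(frozen=True)
class SynthTraceSpec:
    """Geometry of one idealised AP trace.

    Voltage path: ``rmp`` until ``upstroke_time``; linear rise to ``v_peak``
    over ``upstroke_delay`` ms (default 1 ms, i.e. a fast upstroke); constant
    plateau until ``plateau_end``; linear repolarisation to ``final_v``
    (default ``rmp``) at ``repol_end``; constant until ``cycle_length``.
    ``ead`` = (amplitude mV, onset ms, width ms) adds a triangular bump
    centred at ``onset``.  ``noise_sd`` adds seeded Gaussian jitter.
    """

    rmp: float = -85.0
    v_peak: float = 20.0
    upstroke_time: float = 10.0
    plateau_end: float = 200.0
    repol_end: float = 300.0
    upstroke_delay: float = 1.0
    final_v: Optional[float] = None
    ead: Optional[Tuple[float, float, float]] = None
    noise_sd: float = 0.0
    dt: float = 0.05
    cycle_length: float = 1000.0
    stim_onset: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        times = (
            self.stim_onset, self.upstroke_time,
            self.upstroke_time + self.upstroke_delay,
            self.plateau_end, self.repol_end, self.cycle_length,
        )
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"inconsistent trace times: {times}")
        if self.upstroke_delay <= 0:
            raise ValueError("upstroke_delay must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def synth_trace(spec: SynthTraceSpec) -> APTrace:
    """Realise the spec exactly on a uniform grid (deterministic under seed)."""
    t = np.arange(0.0, spec.cycle_length + spec.dt / 2, spec.dt)
    if t[-1] > spec.cycle_length:
        t = t[:-1]
    final_v = spec.rmp if spec.final_v is None else spec.final_v
    knots_t = [
        0.0,
        spec.upstroke_time,
        spec.upstroke_time + spec.upstroke_delay,
        spec.plateau_end,
        spec.repol_end,
        spec.cycle_length,
    ]
    knots_v = [spec.rmp, spec.rmp, spec.v_peak, spec.v_peak, final_v, final_v]
    # deduplicate coincident knots while keeping the later value
    clean_t, clean_v = [knots_t[0]], [knots_v[0]]
    for ti, vi in zip(knots_t[1:], knots_v[1:]):
        if ti == clean_t[-1]:
            clean_v[-1] = vi
        else:
            clean_t.append(ti)
            clean_v.append(vi)
    v = np.interp(t, clean_t, clean_v)

    if spec.ead is not None:
        amplitude, onset, width = spec.ead
        if width <= 0:
            raise ValueError("ead width must be positive")
        if amplitude <= 0:
            raise ValueError("ead amplitude must be positive")
        # triangular excursion anchored at the voltage the trace has at
        # onset: the combined max follows the rising flank regardless of the
        # underlying repolarisation slope, guaranteeing a positive-derivative
        # window, and rejoins the trace where the falling flank crosses it
        v_onset = float(np.interp(onset, t, v))
        apex = onset + width / 2.0
        triangle = v_onset + amplitude - (2.0 * amplitude / width) * np.abs(t - apex)
        v = np.where(t >= onset, np.maximum(v, triangle), v)

    if spec.noise_sd > 0:
        # smooth jitter emulating solver/baseline error: Gaussian knots every
        # 100 ms, linearly interpolated.  Independent per-sample noise would
        # carry unbounded derivatives and trivially trip the EAD detector's
        # slope criterion; with 100 ms knots the jitter derivative stays well
        # below that 0.01 mV/ms tolerance for amplitudes up to ~0.5 mV.
        rng = np.random.default_rng(spec.seed)
        knot_t = np.arange(0.0, spec.cycle_length + 100.0, 100.0)
        knot_v = rng.normal(0.0, spec.noise_sd, size=knot_t.shape)
        v = v + np.interp(t, knot_t, knot_v)

    return APTrace(
        t=t, v=v, stim_onset=spec.stim_onset, cycle_length=spec.cycle_length,
        provenance={"model": "synthetic", "spec": repr(spec)},
    )


def toy_population(
    n: int,
    seed: int = 0,
    planted_structure: Optional[dict] = None,
    id_prefix: str = "t",
):
    """Random conductance table in [0, 2]^9, optionally with a planted group.

    ``planted_structure`` keys: ``fraction`` (share of labelled models,
    default 0.3), ``factor`` (scale factor to shift, default "g_Kr"),
    ``low``/``high`` (labelled subset's marginal bounds, default [0, 0.8]).
    Returns ``(PopulationTable, labels)`` where labels is a dict model_id ->
    bool (True for the planted subset); labels are all False without
    structure.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo = np.array([DEFAULT_BOUNDS[name][0] for name in SCALING_ORDER])
    hi = np.array([DEFAULT_BOUNDS[name][1] for name in SCALING_ORDER])
    samples = lo + rng.random((n, len(SCALING_ORDER))) * (hi - lo)

    labels = {}
    planted = np.zeros(n, dtype=bool)
    if planted_structure:
        fraction = float(planted_structure.get("fraction", 0.3))
        factor = planted_structure.get("factor", "g_Kr")
        low = float(planted_structure.get("low", 0.0))
        high = float(planted_structure.get("high", 0.8))
        if factor not in SCALING_ORDER:
            raise ValueError(f"unknown factor {factor!r}")
        if not (0.0 < fraction <= 1.0):
            raise ValueError("fraction must lie in (0, 1]")
        n_planted = max(1, int(round(fraction * n)))
        chosen = rng.choice(n, size=n_planted, replace=False)
        planted[chosen] = True
        col = SCALING_ORDER.index(factor)
        samples[chosen, col] = low + rng.random(n_planted) * (high - low)

    width = max(4, len(str(n)))
    models = []
    for i, row in enumerate(samples):
        model_id = f"{id_prefix}{i:0{width}d}"
        models.append((model_id, IonicScaling.from_array(row)))
        labels[model_id] = bool(planted[i])
    return PopulationTable(models), labels
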