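"""AP biomarker extraction and abnormality detection on single-beat traces.

Biomarkers follow the standard safety-pharmacology set: APD at 40/50/90 %
repolarisation, triangulation (APD90 - APD40), maximum upstroke velocity,
peak voltage and resting membrane potential.  APD is measured from the
instant of maximum upstroke velocity (configurable to stimulus onset) to the
first downward crossing of V_x = V_peak - (x/100)(V_peak - RMP), linearly
interpolated between samples.  Biomarkers whose crossing never occurs are
reported as NaN rather than raising.

Abnormality detectors implement the trial's two screening rules:

* repolarisation abnormality (RA): any positive dV/dt in the window starting
  150 ms after the AP peak (an EAD-like secondary depolarisation), or failure
  to repolarise below -40 mV by the end of the beat after an upstroke;
* depolarisation abnormality (DA): peak voltage below 0 mV, or 0 mV first
  reached more than 100 ms after stimulus onset.

The positive-derivative clause uses a small slope tolerance (default
0.01 mV/ms) so that solver/interpolation noise is not flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from .cell_engine import APTrace

__all__ = [
    "BIOMARKER_NAMES",
    "BiomarkerSet",
    "AbnormalityFlags",
    "PopulationSummary",
    "compute_biomarkers",
    "detect_ra",
    "detect_da",
    "detect_abnormalities",
    "summarize_population",
]

BIOMARKER_NAMES = ("apd40", "apd50", "apd90", "tri_90_40", "dvdt_max", "v_peak", "rmp")

#: RA/DA sub-criterion labels
RA_POSITIVE_DERIVATIVE = "positive-derivative"
RA_FAILED_REPOLARIZATION = "failed-repolarization"
DA_LOW_PEAK = "low-peak"
DA_SLOW_UPSTROKE = "slow-upstroke"

#: default detector parameters
SLOPE_TOL_MV_PER_MS = 0.01
RA_WINDOW_AFTER_PEAK_MS = 150.0
RA_REPOL_THRESHOLD_MV = -40.0
DA_PEAK_THRESHOLD_MV = 0.0
DA_UPSTROKE_LIMIT_MS = 100.0
#: minimum dV/dt_max (mV/ms) for an upstroke to count as having occurred
UPSTROKE_DVDT_MIN = 10.0


@dataclass(frozen=True)
class BiomarkerSet:
    """Per-beat biomarker values; undefined entries are NaN."""

    apd40: float
    apd50: float
    apd90: float
    tri_90_40: float
    dvdt_max: float
    v_peak: float
    rmp: float

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in BIOMARKER_NAMES}


@dataclass(frozen=True)
class AbnormalityFlags:
    ra: bool = False
    da: bool = False
    ra_reason: Optional[str] = None
    da_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ra != (self.ra_reason is not None):
            raise ValueError("ra_reason must be present iff ra is set")
        if self.da != (self.da_reason is not None):
            raise ValueError("da_reason must be present iff da is set")

    @property
    def abnormal(self) -> bool:
        return self.ra or self.da


def _onset_index(trace: APTrace) -> int:
    """Index of the last sample at or before stimulus onset."""
    idx = int(np.searchsorted(trace.t, trace.stim_onset, side="right") - 1)
    return max(idx, 0)


def compute_biomarkers(trace: APTrace, apd_reference: str = "dvdt_max") -> BiomarkerSet:
    """Extract the biomarker set from one uniformly sampled beat.

    apd_reference selects the APD start time: "dvdt_max" (default) or
    "stim_onset".
    """
    if apd_reference not in ("dvdt_max", "stim_onset"):
        raise ValueError("apd_reference must be 'dvdt_max' or 'stim_onset'")
    t, v = trace.t, trace.v
    dt = trace.dt
    i0 = _onset_index(trace)
    rmp = float(v[i0])
    post_v = v[i0:]
    i_peak = i0 + int(np.argmax(post_v))
    v_peak = float(v[i_peak])

    dvdt = np.diff(v) / dt  # forward difference, value at t[i]
    if i_peak > i0:
        up = dvdt[i0:i_peak]
        dvdt_max = float(np.max(up))
        # earliest sample within float tolerance of the max slope: on linear
        # upstrokes the slopes tie, and argmax alone would pick an arbitrary
        # ramp sample depending on rounding noise
        tol = max(1e-9 * abs(dvdt_max), 1e-12)
        k = int(np.nonzero(up >= dvdt_max - tol)[0][0])
        t_ref = float(t[i0 + k])
    else:
        dvdt_max = float(np.max(dvdt[i0:])) if i0 < dvdt.size else 0.0
        t_ref = float(t[i0])
    if apd_reference == "stim_onset":
        t_ref = float(trace.stim_onset)

    apds = {}
    for x in (40, 50, 90):
        thr = v_peak - (x / 100.0) * (v_peak - rmp)
        apds[x] = _apd_crossing(t, v, i_peak, thr, t_ref)

    tri = apds[90] - apds[40]
    return BiomarkerSet(
        apd40=apds[40], apd50=apds[50], apd90=apds[90], tri_90_40=tri,
        dvdt_max=dvdt_max, v_peak=v_peak, rmp=rmp,
    )


def _apd_crossing(t, v, i_peak, threshold, t_ref) -> float:
    """Time from t_ref to the first downward crossing of threshold after the
    peak, linearly interpolated; NaN if the trace never crosses."""
    seg = v[i_peak:]
    if seg.size < 2 or seg[0] < threshold:
        return math.nan
    below = seg[1:] < threshold
    at_or_above = seg[:-1] >= threshold
    hits = np.nonzero(below & at_or_above)[0]
    if hits.size == 0:
        return math.nan
    k = int(hits[0])  # crossing between samples i_peak+k and i_peak+k+1
    v0, v1 = seg[k], seg[k + 1]
    frac = (v0 - threshold) / (v0 - v1)
    t_cross = t[i_peak + k] + frac * (t[i_peak + k + 1] - t[i_peak + k])
    return float(t_cross - t_ref)


def detect_ra(
    trace: APTrace,
    slope_tol: float = SLOPE_TOL_MV_PER_MS,
    window_after_peak: float = RA_WINDOW_AFTER_PEAK_MS,
    repol_threshold: float = RA_REPOL_THRESHOLD_MV,
    upstroke_dvdt_min: float = UPSTROKE_DVDT_MIN,
):
    """Repolarisation-abnormality flag and triggering sub-criterion."""
    t, v = trace.t, trace.v
    dt = trace.dt
    i0 = _onset_index(trace)
    i_peak = i0 + int(np.argmax(v[i0:]))
    t_peak = t[i_peak]

    start = int(np.searchsorted(t, t_peak + window_after_peak, side="left"))
    if start < t.size - 1:
        dvdt = np.diff(v[start:]) / dt
        if np.any(dvdt > slope_tol):
            return True, RA_POSITIVE_DERIVATIVE

    dvdt_all = np.diff(v) / dt
    upstroke = dvdt_all[i0:].size > 0 and float(np.max(dvdt_all[i0:])) >= upstroke_dvdt_min
    if upstroke and v[-1] > repol_threshold:
        return True, RA_FAILED_REPOLARIZATION
    return False, None


def detect_da(
    trace: APTrace,
    peak_threshold: float = DA_PEAK_THRESHOLD_MV,
    upstroke_limit: float = DA_UPSTROKE_LIMIT_MS,
):
    """Depolarisation-abnormality flag and triggering sub-criterion."""
    t, v = trace.t, trace.v
    i0 = _onset_index(trace)
    seg = v[i0:]
    if float(np.max(seg)) < peak_threshold:
        return True, DA_LOW_PEAK
    # first upward crossing of the threshold, linearly interpolated
    above = np.nonzero(seg >= peak_threshold)[0]
    k = int(above[0])
    if k == 0:
        t_cross = t[i0]
    else:
        v0, v1 = seg[k - 1], seg[k]
        frac = (peak_threshold - v0) / (v1 - v0)
        t_cross = t[i0 + k - 1] + frac * (t[i0 + k] - t[i0 + k - 1])
    if t_cross - trace.stim_onset > upstroke_limit:
        return True, DA_SLOW_UPSTROKE
    return False, None


def detect_abnormalities(trace: APTrace, **kwargs) -> AbnormalityFlags:
    ra_kwargs = {k: v for k, v in kwargs.items()
                 if k in ("slope_tol", "window_after_peak", "repol_threshold",
                          "upstroke_dvdt_min")}
    da_kwargs = {k: v for k, v in kwargs.items()
                 if k in ("peak_threshold", "upstroke_limit")}
    ra, ra_reason = detect_ra(trace, **ra_kwargs)
    da, da_reason = detect_da(trace, **da_kwargs)
    return AbnormalityFlags(ra=ra, da=da, ra_reason=ra_reason, da_reason=da_reason)


@dataclass
class PopulationSummary:
    """Median/quartile summary of biomarkers across a population of models.

    ``pct_change`` is the percentage change of each median relative to a
    paired control summary (100 * (drug - control) / control); present only
    when a control summary was supplied.  ``delta_apd90`` is the population
    APD90 dispersion (max - min over models with a defined APD90).
    """

    n: int
    median: Dict[str, float]
    q1: Dict[str, float]
    q3: Dict[str, float]
    delta_apd90: float
    pct_change: Optional[Dict[str, float]] = None
    notes: Mapping[str, object] = field(default_factory=dict)


def summarize_population(
    biomarkers: Sequence[BiomarkerSet],
    control: Optional[PopulationSummary] = None,
) -> PopulationSummary:
    """Median and quartiles per biomarker over models where it is defined."""
    if len(biomarkers) == 0:
        raise ValueError("need at least one biomarker set")
    table = {name: np.array([getattr(b, name) for b in biomarkers])
             for name in BIOMARKER_NAMES}
    median, q1, q3 = {}, {}, {}
    for name, values in table.items():
        defined = values[np.isfinite(values)]
        if defined.size == 0:
            median[name] = q1[name] = q3[name] = math.nan
        else:
            median[name] = float(np.median(defined))
            q1[name] = float(np.percentile(defined, 25))
            q3[name] = float(np.percentile(defined, 75))
    apd90 = table["apd90"][np.isfinite(table["apd90"])]
    delta = float(apd90.max() - apd90.min()) if apd90.size else math.nan
    pct = None
    if control is not None:
        pct = {}
        for name in BIOMARKER_NAMES:
            ref = control.median.get(name, math.nan)
            cur = median[name]
            if ref is None or not np.isfinite(ref) or ref == 0 or not np.isfinite(cur):
                pct[name] = math.nan
            else:
                pct[name] = 100.0 * (cur - ref) / ref
    return PopulationSummary(
        n=len(biomarkers), median=median, q1=q1, q3=q3,
        delta_apd90=delta, pct_change=pct,
    )
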