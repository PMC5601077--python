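"""Independent brute-force oracles for biomarker and detector checks.

These deliberately re-state the screening rules as naive sample-by-sample
scans, independent of the vectorised implementations under test.
"""

from __future__ import annotations

import math

import numpy as np


def random_trace_spec(rng, seed):
    """Randomised synthetic-AP spec mixing normal traces with EAD bumps,
    failed repolarisation, low peaks and slow upstrokes."""
    from aptrial.fixtures import SynthTraceSpec

    kind = rng.integers(0, 5)
    kwargs = dict(
        rmp=float(rng.uniform(-92, -80)),
        v_peak=float(rng.uniform(15, 45)),
        upstroke_time=float(rng.uniform(5, 30)),
        dt=0.2,
        noise_sd=float(rng.uniform(0, 0.003)),
        seed=int(seed),
    )
    kwargs["plateau_end"] = kwargs["upstroke_time"] + float(rng.uniform(80, 260))
    kwargs["repol_end"] = kwargs["plateau_end"] + float(rng.uniform(50, 250))
    if kind == 1:  # EAD-like bump late in repolarisation
        onset = kwargs["upstroke_time"] + float(rng.uniform(170, 600))
        kwargs["ead"] = (float(rng.uniform(3, 15)), onset,
                         float(rng.uniform(10, 50)))
    elif kind == 2:  # failed repolarisation
        kwargs["final_v"] = float(rng.uniform(-39, -10))
    elif kind == 3:  # compromised upstroke amplitude
        kwargs["v_peak"] = float(rng.uniform(-20, -1))
    elif kind == 4:  # slow upstroke, clear of the 100 ms boundary
        kwargs["upstroke_time"] = float(rng.uniform(5, 15))
        kwargs["upstroke_delay"] = float(rng.uniform(115, 200))
        kwargs["plateau_end"] = (kwargs["upstroke_time"]
                                 + kwargs["upstroke_delay"]
                                 + float(rng.uniform(50, 150)))
        kwargs["repol_end"] = kwargs["plateau_end"] + float(rng.uniform(50, 200))
    return SynthTraceSpec(**kwargs)


def detector_oracle_comparison(n_traces, seed):
    """Compare both detectors against the scan oracles on n_traces randomised
    synthetic traces; returns (n_mismatches, n_flagged)."""
    from aptrial.biomarkers import detect_abnormalities
    from aptrial.fixtures import synth_trace

    rng = np.random.default_rng(seed)
    mismatches = 0
    flagged = 0
    for i in range(n_traces):
        trace = synth_trace(random_trace_spec(rng, i))
        flags = detect_abnormalities(trace)
        ra_ref, _ = ra_brute_force(trace.t, trace.v, trace.stim_onset)
        da_ref, _ = da_brute_force(trace.t, trace.v, trace.stim_onset)
        mismatches += (flags.ra != ra_ref) + (flags.da != da_ref)
        flagged += flags.ra or flags.da
    return mismatches, flagged


def apd_brute_force(t, v, stim_onset, x) -> float:
    """APD_x by exhaustive scan: threshold from V_peak/RMP, crossing found by
    walking every sample after the peak, start reference at max forward
    difference during the upstroke."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    dt = t[1] - t[0]
    i0 = 0
    while i0 + 1 < t.size and t[i0 + 1] <= stim_onset:
        i0 += 1
    rmp = v[i0]
    i_peak = i0
    for i in range(i0, v.size):
        if v[i] > v[i_peak]:
            i_peak = i
    v_peak = v[i_peak]
    best, k_best = (v[i0 + 1] - v[i0]) / dt, i0
    for i in range(i0 + 1, i_peak):
        slope = (v[i + 1] - v[i]) / dt
        # keep the earliest of numerically tied maxima (linear upstrokes
        # produce runs of equal slopes up to rounding noise)
        if slope > best + 1e-9 * max(1.0, abs(best)):
            best, k_best = slope, i
    t_ref = t[k_best]
    thr = v_peak - (x / 100.0) * (v_peak - rmp)
    for i in range(i_peak, v.size - 1):
        if v[i] >= thr and v[i + 1] < thr:
            frac = (v[i] - thr) / (v[i] - v[i + 1])
            return t[i] + frac * dt - t_ref
    return math.nan


def ra_brute_force(t, v, stim_onset, slope_tol=0.01, window=150.0,
                   repol_threshold=-40.0, upstroke_dvdt_min=10.0):
    """RA rule by scan: positive derivative after peak+window, or final
    voltage above the repolarisation threshold given an upstroke."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    dt = t[1] - t[0]
    i0 = 0
    while i0 + 1 < t.size and t[i0 + 1] <= stim_onset:
        i0 += 1
    i_peak = i0
    for i in range(i0, v.size):
        if v[i] > v[i_peak]:
            i_peak = i
    t_limit = t[i_peak] + window
    for i in range(v.size - 1):
        if t[i] >= t_limit and (v[i + 1] - v[i]) / dt > slope_tol:
            return True, "positive-derivative"
    max_slope = -math.inf
    for i in range(i0, v.size - 1):
        max_slope = max(max_slope, (v[i + 1] - v[i]) / dt)
    if max_slope >= upstroke_dvdt_min and v[-1] > repol_threshold:
        return True, "failed-repolarization"
    return False, None


def da_brute_force(t, v, stim_onset, peak_threshold=0.0, limit=100.0):
    """DA rule by scan: peak below threshold, or threshold first reached
    (interpolated) later than the limit after stimulus onset."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    i0 = 0
    while i0 + 1 < t.size and t[i0 + 1] <= stim_onset:
        i0 += 1
    vmax = max(v[i0:])
    if vmax < peak_threshold:
        return True, "low-peak"
    for i in range(i0, v.size):
        if v[i] >= peak_threshold:
            if i == i0:
                t_cross = t[i0]
            else:
                frac = (peak_threshold - v[i - 1]) / (v[i] - v[i - 1])
                t_cross = t[i - 1] + frac * (t[i] - t[i - 1])
            if t_cross - stim_onset > limit:
                return True, "slow-upstroke"
            return False, None
    return True, "low-peak"
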