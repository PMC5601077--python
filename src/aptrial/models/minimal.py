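"""Minimal 4-variable human ventricular AP model (fast surrogate).

The Bueno-Orovio--Cherry--Fenton phenomenological model with the epicardial
parameter set: state (u, v, w, s) where u is a dimensionless voltage and
v, w, s are gating variables for the three lumped transmembrane currents
(fast inward J_fi, slow outward J_so, slow inward J_si).  Voltage in mV is
recovered by the published linear rescaling V = 85.7 u - 84.

Scaling hooks: g_Na scales J_fi (Na+-like), g_CaL scales J_si (Ca2+-like),
g_Kr scales J_so (K+-like repolarising current).  The remaining six hooks
(g_NaL, g_to, g_Ks, g_K1, g_NCX, g_NaK) have no counterpart in the 4-variable
formulation and are inert.

This model exists so that every analysis stage (calibration, trials, scoring)
can be exercised in seconds; it is not a substitute for the baseline
biophysical model in production runs.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

N_STATES = 4

#: resting state: fully recovered gates
INITIAL_STATE = np.array([0.0, 1.0, 1.0, 0.0])

VOLTAGE_GAIN = 85.7
VOLTAGE_OFFSET = -84.0

# epicardial parameter set
U_O = 0.0
U_U = 1.55
THETA_V = 0.3
THETA_W = 0.13
THETA_VM = 0.006
THETA_O = 0.006
TAU_V1M = 60.0
TAU_V2M = 1150.0
TAU_VP = 1.4506
TAU_W1M = 60.0
TAU_W2M = 15.0
K_WM = 65.0
U_WM = 0.03
TAU_WP = 200.0
TAU_FI = 0.11
TAU_O1 = 400.0
TAU_O2 = 6.0
TAU_SO1 = 30.0181
TAU_SO2 = 0.9957
K_SO = 2.0458
U_SO = 0.65
TAU_S1 = 2.7342
TAU_S2 = 16.0
K_S = 2.0994
U_S = 0.9087
TAU_SI = 1.8875
TAU_WINF = 0.07
W_INF_STAR = 0.94

# toy stimulus: du/dt source of 0.5/ms for 1 ms reliably clears theta_v
STIM_AMPLITUDE = -0.5
STIM_DURATION = 1.0


@njit(cache=True)
def currents(y, scale):
    """Lumped currents (J_fi, J_so, J_si) at a fixed state.

    Each scaled current is exactly linear in its scale factor, which is the
    homogeneity property the engine relies on when composing pore block with
    population variability.
    """
    u = y[0]
    v = y[1]
    w = y[2]
    s = y[3]
    s_na = scale[0]
    s_kr = scale[3]
    s_cal = scale[8]

    hv = 1.0 if u >= THETA_V else 0.0
    hw = 1.0 if u >= THETA_W else 0.0

    tau_so = TAU_SO1 + (TAU_SO2 - TAU_SO1) \
        * (1.0 + math.tanh(K_SO * (u - U_SO))) / 2.0
    tau_o = TAU_O1 if u < THETA_O else TAU_O2

    jfi = -s_na * v * hv * (u - THETA_V) * (U_U - u) / TAU_FI
    jso = s_kr * ((u - U_O) * (1.0 - hw) / tau_o + hw / tau_so)
    jsi = -s_cal * hw * w * s / TAU_SI
    return jfi, jso, jsi


@njit(cache=True)
def rhs(t, y, scale, i_stim):
    u = y[0]
    v = y[1]
    w = y[2]
    s = y[3]

    hv = 1.0 if u >= THETA_V else 0.0
    hw = 1.0 if u >= THETA_W else 0.0
    ho = 1.0 if u >= THETA_O else 0.0
    hvm = 1.0 if u >= THETA_VM else 0.0

    jfi, jso, jsi = currents(y, scale)

    tau_vm = TAU_V1M if u < THETA_VM else TAU_V2M
    v_inf = 1.0 if u < THETA_VM else 0.0
    tau_wm = TAU_W1M + (TAU_W2M - TAU_W1M) \
        * (1.0 + math.tanh(K_WM * (u - U_WM))) / 2.0
    w_inf = (1.0 - ho) * (1.0 - u / TAU_WINF) + ho * W_INF_STAR
    tau_s = TAU_S1 if u < THETA_W else TAU_S2

    dy = np.empty(4)
    dy[0] = -(jfi + jso + jsi + i_stim)
    dy[1] = (1.0 - hv) * (v_inf - v) / tau_vm - hv * v / TAU_VP
    dy[2] = (1.0 - hw) * (w_inf - w) / tau_wm - hw * w / TAU_WP
    dy[3] = ((1.0 + math.tanh(K_S * (u - U_S))) / 2.0 - s) / tau_s
    return dy
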