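"""O'Hara-Rudy dynamic (ORd) human ventricular cell model, endocardial variant.

The ORd model is the baseline cell used for the virtual population.  The
right-hand side below is a line-by-line transcription of the published ORd
equation set (41 state variables: membrane potential, intracellular and
subspace ion concentrations, sarcoplasmic-reticulum Ca2+ stores, Markov-style
gating variables for INa/INaL/Ito/ICaL/IKr/IKs/IK1, ryanodine-receptor release
fluxes, and CaMKII activation), compiled with numba for speed.

Nine maximal conductances / fluxes are exposed as dimensionless scale factors
(order fixed by :data:`SCALING_ORDER` in :mod:`aptrial.cell_engine`):

    g_Na, g_NaL, g_to, g_Kr, g_Ks, g_K1, g_NCX, g_NaK, g_CaL

g_CaL scales the whole L-type complex (Ca2+, Na+ and K+ components); g_NCX
scales both the bulk and subspace Na+/Ca2+-exchanger terms.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

N_STATES = 41

#: state layout
# 0  v      mV
# 1  nai    mM          2  nass   mM
# 3  ki     mM          4  kss    mM
# 5  cai    mM          6  cass   mM
# 7  cansr  mM          8  cajsr  mM
# 9  m     10 hf    11 hs    12 j     13 hsp   14 jp
# 15 mL    16 hL    17 hLp
# 18 a     19 iF    20 iS    21 ap    22 iFp   23 iSp
# 24 d     25 ff    26 fs    27 fcaf  28 fcas  29 jca
# 30 nca   31 ffp   32 fcafp
# 33 xrf   34 xrs   35 xs1   36 xs2   37 xk1
# 38 Jrelnp 39 Jrelp 40 CaMKt

# Published 1 Hz endocardial steady state; the pre-drug 150-beat pacing run
# absorbs any residual transient, so limited precision here is harmless.
INITIAL_STATE = np.array([
    -87.84,       # v
    7.23,         # nai
    7.23,         # nass
    143.79,       # ki
    143.79,       # kss
    8.54e-5,      # cai
    8.43e-5,      # cass
    1.61,         # cansr
    1.56,         # cajsr
    0.0074621,    # m
    0.692591,     # hf
    0.692574,     # hs
    0.692477,     # j
    0.448501,     # hsp
    0.692413,     # jp
    0.000194015,  # mL
    0.496116,     # hL
    0.265885,     # hLp
    0.00101185,   # a
    0.999542,     # iF
    0.589579,     # iS
    0.000515567,  # ap
    0.999542,     # iFp
    0.641861,     # iSp
    2.43e-9,      # d
    1.0,          # ff
    0.910671,     # fs
    1.0,          # fcaf
    0.99982,      # fcas
    0.999977,     # jca
    0.00267171,   # nca
    1.0,          # ffp
    1.0,          # fcafp
    8.26608e-6,   # xrf
    0.453268,     # xrs
    0.270492,     # xs1
    0.0001963,    # xs2
    0.996801,     # xk1
    2.53943e-5,   # Jrelnp
    3.17262e-7,   # Jrelp
    0.0124065,    # CaMKt
])

# reference rectangular stimulus of the published code: -80 uA/uF for 0.5 ms
STIM_AMPLITUDE = -80.0
STIM_DURATION = 0.5


@njit(cache=True, fastmath=False)
def rhs(t, y, scale, i_stim):  # noqa: C901 - single flat function for numba
    """ORd-endo state derivative.

    Parameters
    ----------
    t : float
        Time within the beat (ms); the equations are autonomous, the argument
        exists for the ODE-solver signature.
    y : ndarray, shape (41,)
    scale : ndarray, shape (9,)
        Conductance scale factors in SCALING_ORDER.
    i_stim : float
        Stimulus current density (uA/uF), negative = depolarising.
    """
    dy = np.empty(N_STATES)

    v = y[0]
    nai = y[1]
    nass = y[2]
    ki = y[3]
    kss = y[4]
    cai = y[5]
    cass = y[6]
    cansr = y[7]
    cajsr = y[8]
    m = y[9]
    hf = y[10]
    hs = y[11]
    j = y[12]
    hsp = y[13]
    jp = y[14]
    mL = y[15]
    hL = y[16]
    hLp = y[17]
    a = y[18]
    iF = y[19]
    iS = y[20]
    ap = y[21]
    iFp = y[22]
    iSp = y[23]
    d = y[24]
    ff = y[25]
    fs = y[26]
    fcaf = y[27]
    fcas = y[28]
    jca = y[29]
    nca = y[30]
    ffp = y[31]
    fcafp = y[32]
    xrf = y[33]
    xrs = y[34]
    xs1 = y[35]
    xs2 = y[36]
    xk1 = y[37]
    Jrelnp = y[38]
    Jrelp = y[39]
    CaMKt = y[40]

    s_na = scale[0]
    s_nal = scale[1]
    s_to = scale[2]
    s_kr = scale[3]
    s_ks = scale[4]
    s_k1 = scale[5]
    s_ncx = scale[6]
    s_nak = scale[7]
    s_cal = scale[8]

    # extracellular concentrations and physical constants
    nao = 140.0
    cao = 1.8
    ko = 5.4
    R = 8314.0
    T = 310.0
    F = 96485.0

    # cell geometry
    L = 0.01
    rad = 0.0011
    vcell = 1000.0 * 3.14 * rad * rad * L
    Ageo = 2.0 * 3.14 * rad * rad + 2.0 * 3.14 * rad * L
    Acap = 2.0 * Ageo
    vmyo = 0.68 * vcell
    vnsr = 0.0552 * vcell
    vjsr = 0.0048 * vcell
    vss = 0.02 * vcell

    # CaMKII
    KmCaMK = 0.15
    aCaMK = 0.05
    bCaMK = 0.00068
    CaMKo = 0.05
    KmCaM = 0.0015
    CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + CaMKt
    dy[40] = aCaMK * CaMKb * (CaMKb + CaMKt) - bCaMK * CaMKt

    # reversal potentials
    ENa = (R * T / F) * math.log(nao / nai)
    EK = (R * T / F) * math.log(ko / ki)
    PKNa = 0.01833
    EKs = (R * T / F) * math.log((ko + PKNa * nao) / (ki + PKNa * nai))
    vffrt = v * F * F / (R * T)
    vfrt = v * F / (R * T)

    # INa (fast)
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77)
                + 8.552 * math.exp(-(v + 77.42) / 5.955))
    dy[9] = (mss - m) / tm
    hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285)
                 + 6.149 * math.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * math.exp((v + 5.730) / 56.66))
    Ahf = 0.99
    Ahs = 1.0 - Ahf
    dy[10] = (hss - hf) / thf
    dy[11] = (hss - hs) / ths
    h = Ahf * hf + Ahs * hs
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * math.exp((v + 0.9941) / 38.45))
    dy[12] = (jss - j) / tj
    hssp = 1.0 / (1.0 + math.exp((v + 89.1) / 6.086))
    thsp = 3.0 * ths
    dy[13] = (hssp - hsp) / thsp
    hp = Ahf * hf + Ahs * hsp
    tjp = 1.46 * tj
    dy[14] = (jss - jp) / tjp
    GNa = 75.0 * s_na
    fINap = 1.0 / (1.0 + KmCaMK / CaMKa)
    INa = GNa * (v - ENa) * m ** 3 * ((1.0 - fINap) * h * j + fINap * hp * jp)

    # INaL (late)
    mLss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    tmL = tm
    dy[15] = (mLss - mL) / tmL
    hLss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    thL = 200.0
    dy[16] = (hLss - hL) / thL
    hLssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    thLp = 3.0 * thL
    dy[17] = (hLssp - hLp) / thLp
    GNaL = 0.0075 * s_nal
    fINaLp = 1.0 / (1.0 + KmCaMK / CaMKa)
    INaL = GNaL * (v - ENa) * mL * ((1.0 - fINaLp) * hL + fINaLp * hLp)

    # Ito
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814)))
    dy[18] = (ass - a) / ta
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    # delta_epi = 1 for the endocardial cell
    tiF = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * math.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * math.exp((v + 114.1) / 8.079))
    dy[19] = (iss - iF) / tiF
    dy[20] = (iss - iS) / tiS
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    i_gate = AiF * iF + AiS * iS
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    dy[21] = (assp - ap) / ta
    dti_develop = 1.354 + 1.0e-4 / (math.exp((v - 167.4) / 15.89)
                                    + math.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    tiFp = dti_develop * dti_recover * tiF
    tiSp = dti_develop * dti_recover * tiS
    dy[22] = (iss - iFp) / tiFp
    dy[23] = (iss - iSp) / tiSp
    ip = AiF * iFp + AiS * iSp
    Gto = 0.02 * s_to
    fItop = 1.0 / (1.0 + KmCaMK / CaMKa)
    Ito = Gto * (v - EK) * ((1.0 - fItop) * a * i_gate + fItop * ap * ip)

    # ICaL / ICaNa / ICaK
    dss = 1.0 / (1.0 + math.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    dy[24] = (dss - d) / td
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * math.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * math.exp((v + 5.0) / 6.0))
    Aff = 0.6
    Afs = 1.0 - Aff
    dy[25] = (fss - ff) / tff
    dy[26] = (fss - fs) / tfs
    f = Aff * ff + Afs * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0)
                         + 0.04 * math.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * math.exp(-v / 3.0)
                           + 0.00012 * math.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    dy[27] = (fcass - fcaf) / tfcaf
    dy[28] = (fcass - fcas) / tfcas
    fca = Afcaf * fcaf + Afcas * fcas
    tjca = 75.0
    dy[29] = (fcass - jca) / tjca
    ktaup = 2.5
    tffp = ktaup * tff
    dy[31] = (fss - ffp) / tffp
    fp = Aff * ffp + Afs * fs
    tfcafp = ktaup * tfcaf
    dy[32] = (fcass - fcafp) / tfcafp
    fcap = Afcaf * fcafp + Afcas * fcas
    Kmn = 0.002
    k2n = 1000.0
    km2n = jca * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4.0)
    dy[30] = anca * k2n - nca * km2n
    PhiCaL = 4.0 * vffrt * (cass * math.exp(2.0 * vfrt) - 0.341 * cao) \
        / (math.exp(2.0 * vfrt) - 1.0)
    PhiCaNa = 1.0 * vffrt * (0.75 * nass * math.exp(vfrt) - 0.75 * nao) \
        / (math.exp(vfrt) - 1.0)
    PhiCaK = 1.0 * vffrt * (0.75 * kss * math.exp(vfrt) - 0.75 * ko) \
        / (math.exp(vfrt) - 1.0)
    PCa = 0.0001 * s_cal
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    fICaLp = 1.0 / (1.0 + KmCaMK / CaMKa)
    gate_np = d * (f * (1.0 - nca) + jca * fca * nca)
    gate_p = d * (fp * (1.0 - nca) + jca * fcap * nca)
    ICaL = (1.0 - fICaLp) * PCa * PhiCaL * gate_np \
        + fICaLp * PCap * PhiCaL * gate_p
    ICaNa = (1.0 - fICaLp) * PCaNa * PhiCaNa * gate_np \
        + fICaLp * PCaNap * PhiCaNa * gate_p
    ICaK = (1.0 - fICaLp) * PCaK * PhiCaK * gate_np \
        + fICaLp * PCaKp * PhiCaK * gate_p

    # IKr
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    dy[33] = (xrss - xrf) / txrf
    dy[34] = (xrss - xrs) / txrs
    xr = Axrf * xrf + Axrs * xrs
    rkr = 1.0 / (1.0 + math.exp((v + 55.0) / 75.0)) \
        / (1.0 + math.exp((v - 10.0) / 30.0))
    GKr = 0.046 * s_kr
    IKr = GKr * math.sqrt(ko / 5.4) * xr * rkr * (v - EK)

    # IKs
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80)
                          + 0.001292 * math.exp(-(v + 210.0) / 230.0))
    dy[35] = (xs1ss - xs1) / txs1
    xs2ss = xs1ss
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0)
                  + 0.0193 * math.exp(-(v + 66.54) / 31.0))
    dy[36] = (xs2ss - xs2) / txs2
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034 * s_ks
    IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)

    # IK1
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * ko + 144.59)
                                  / (1.5692 * ko + 3.8115)))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36)
                    + math.exp((v + 236.8) / 69.33))
    dy[37] = (xk1ss - xk1) / txk1
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * ko) / 9.493))
    GK1 = 0.1908 * s_k1
    IK1 = GK1 * math.sqrt(ko) * rk1 * xk1 * (v - EK)

    # INaCa (Na+/Ca2+ exchanger), bulk myoplasm component
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    qna = 0.5224
    qca = 0.1670
    hca = math.exp(qca * v * F / (R * T))
    hna = math.exp(qna * v * F / (R * T))
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
    h8 = nao / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + nao / kna1 * (1.0 + nao / kna2)
    h11 = nao * nao / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * cao * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    KmCaAct = 150.0e-6
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2.0)
    zna = 1.0
    zca = 2.0
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    Gncx = 0.0008 * s_ncx
    INaCa_i = 0.8 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # subspace component
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    k3pp_ss = h8 * wnaca
    k3_ss = k3p + k3pp_ss
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3_ss)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3_ss * (k7 + k6) + k8 * k6 * (k2 + k3_ss)
    x4 = k2 * k8 * (k4 + k5) + k3_ss * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cass) ** 2.0)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp_ss
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # INaK (Na+/K+ pump)
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p_ = 1899.0
    k3m = 79300.0
    k4p_ = 639.0
    k4m = 40.0
    Knai0 = 9.073
    Knao0 = 27.78
    delta = -0.1550
    Knai = Knai0 * math.exp(delta * v * F / (3.0 * R * T))
    Knao = Knao0 * math.exp((1.0 - delta) * v * F / (3.0 * R * T))
    Kki = 0.5
    Kko = 0.3582
    MgADP = 0.05
    MgATP = 9.8
    Kmgatp = 1.698e-7
    H = 1.0e-7
    eP = 4.2
    Khp = 1.698e-7
    Knap = 224.0
    Kxkur = 292.0
    P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3.0) \
        / ((1.0 + nai / Knai) ** 3.0 + (1.0 + ki / Kki) ** 2.0 - 1.0)
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (nao / Knao) ** 3.0) \
        / ((1.0 + nao / Knao) ** 3.0 + (1.0 + ko / Kko) ** 2.0 - 1.0)
    a3 = (k3p_ * (ko / Kko) ** 2.0) \
        / ((1.0 + nao / Knao) ** 3.0 + (1.0 + ko / Kko) ** 2.0 - 1.0)
    b3 = (k3m * P * H) / (1.0 + MgATP / Kmgatp)
    a4 = (k4p_ * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * ki * ki / (Kki * Kki)) \
        / ((1.0 + nai / Knai) ** 3.0 + (1.0 + ki / Kki) ** 2.0 - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    zk = 1.0
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    Pnak = 30.0 * s_nak
    INaK = Pnak * (zna * JnakNa + zk * JnakK)

    # background and minor currents
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    GKb = 0.003
    IKb = GKb * xkb * (v - EK)
    PNab = 3.75e-10
    INab = PNab * vffrt * (nai * math.exp(vfrt) - nao) / (math.exp(vfrt) - 1.0)
    PCab = 2.5e-8
    ICab = PCab * 4.0 * vffrt * (cai * math.exp(2.0 * vfrt) - 0.341 * cao) \
        / (math.exp(2.0 * vfrt) - 1.0)
    GpCa = 0.0005
    IpCa = GpCa * cai / (0.0005 + cai)

    # membrane potential
    dy[0] = -(INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
              + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + i_stim)

    # diffusion fluxes between subspace and bulk
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    # SR Ca2+ release (RyR)
    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8.0)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    dy[38] = (Jrel_inf - Jrelnp) / tau_rel
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8.0)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    dy[39] = (Jrel_infp - Jrelp) / tau_relp
    fJrelp = 1.0 / (1.0 + KmCaMK / CaMKa)
    Jrel = (1.0 - fJrelp) * Jrelnp + fJrelp * Jrelp

    # SR Ca2+ uptake (SERCA) and leak, NSR->JSR translocation
    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    fJupp = 1.0 / (1.0 + KmCaMK / CaMKa)
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fJupp) * Jupnp + fJupp * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # ionic concentration balances (stimulus carried by K+)
    dy[1] = -(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab) * Acap \
        / (F * vmyo) + JdiffNa * vss / vmyo
    dy[2] = -(ICaNa + 3.0 * INaCa_ss) * Acap / (F * vss) - JdiffNa
    dy[3] = -(Ito + IKr + IKs + IK1 + IKb + i_stim - 2.0 * INaK) * Acap \
        / (F * vmyo) + JdiffK * vss / vmyo
    dy[4] = -ICaK * Acap / (F * vss) - JdiffK

    cmdnmax = 0.05
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2.0
                  + trpnmax * kmtrpn / (kmtrpn + cai) ** 2.0)
    dy[5] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * Acap / (2.0 * F * vmyo)
                    - Jup * vnsr / vmyo + Jdiff * vss / vmyo)
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2.0
                   + BSLmax * KmBSL / (KmBSL + cass) ** 2.0)
    dy[6] = Bcass * (-(ICaL - 2.0 * INaCa_ss) * Acap / (2.0 * F * vss)
                     + Jrel * vjsr / vss - Jdiff)
    dy[7] = Jup - Jtr * vjsr / vnsr
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2.0)
    dy[8] = Bcajsr * (Jtr - Jrel)

    return dy
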