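"""O'Hara-Rudy (2011) human endocardial ventricular myocyte model.

The full ORd ODE system (41 state variables: membrane potential, intracellular
ion concentrations, Hodgkin-Huxley gates, CaMK signalling and SR release fluxes)
with per-channel maximal-conductance multipliers for the six channels subject to
pharmacological block (INaL, ICaL, IKr, IKs, IK1, Ito).  The multipliers carry
both the Dutta conductance rescaling and the drug inhibition factor.

Integration is adaptive-step: gating variables advance by Rush-Larsen
(exact exponential relaxation to their voltage-dependent steady state), the
remaining states by forward Euler, with the step size controlled by the local
rate of change of Vm.  The whole pacing loop is numba-compiled; a 2-second beat
costs a few milliseconds, so 1,000-beat pre-pacing is cheap enough to run in a
test suite.

State vector layout (index: name):
  0 v      1 nai    2 nass   3 ki     4 kss    5 cai    6 cass   7 cansr
  8 cajsr  9 CaMKt 10 m     11 hf    12 hs    13 j     14 hsp   15 jp
 16 mL    17 hL    18 hLp   19 a     20 iF    21 iS    22 ap    23 iFp
 24 iSp   25 d     26 ff    27 fs    28 fcaf  29 fcas  30 jca   31 ffp
 32 fcafp 33 nca   34 xrf   35 xrs   36 xs1   37 xs2   38 xk1   39 Jrelnp
 40 Jrelp

Channel multiplier layout (index into ``gmult``):
  0 INaL, 1 ICaL, 2 IKr, 3 IKs, 4 IK1, 5 Ito
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

N_STATES = 41

#: order of the six block-able channels in every multiplier array
CHANNELS = ("INaL", "ICaL", "IKr", "IKs", "IK1", "Ito")

# physical constants
_R = 8314.0  # J/kmol/K
_T = 310.0  # K
_F = 96485.0  # C/mol

# extracellular concentrations (mM)
_NAO = 140.0
_CAO = 1.8
_KO = 5.4

# cell geometry (endocardial); ORd uses pi = 3.14 literally
_L = 0.01
_RAD = 0.0011
_VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
_AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
_ACAP = 2.0 * _AGEO
_VMYO = 0.68 * _VCELL
_VNSR = 0.0552 * _VCELL
_VJSR = 0.0048 * _VCELL
_VSS = 0.02 * _VCELL


def initial_state() -> np.ndarray:
    """Published ORd endocardial initial conditions (pre-pacing)."""
    y = np.zeros(N_STATES)
    y[0] = -87.0  # v (mV)
    y[1] = 7.0  # nai
    y[2] = 7.0  # nass
    y[3] = 145.0  # ki
    y[4] = 145.0  # kss
    y[5] = 1.0e-4  # cai
    y[6] = 1.0e-4  # cass
    y[7] = 1.2  # cansr
    y[8] = 1.2  # cajsr
    y[9] = 0.0  # CaMKt
    # gates: activation gates 0, inactivation gates 1
    for i in (11, 12, 13, 14, 15, 17, 18, 20, 21, 23, 24, 26, 27, 28, 29, 30, 38):
        y[i] = 1.0
    return y


@njit(cache=True)
def _rhs(y, gmult, ist, dy, xinf, xtau, cur):
    """ORd right-hand side.

    Fills ``dy`` (forward-Euler derivatives for non-gate states), ``xinf`` and
    ``xtau`` (Rush-Larsen targets/time constants for gate states), and ``cur``
    with the six block-able currents (A/F) in CHANNELS order.  Returns the total
    ionic current (for diagnostics).  ``ist`` is the stimulus current (A/F).
    """
    v = y[0]
    nai = y[1]
    nass = y[2]
    ki = y[3]
    kss = y[4]
    cai = y[5]
    cass = y[6]
    cansr = y[7]
    cajsr = y[8]
    camkt = y[9]

    # CaMK
    CaMKb = 0.05 * (1.0 - camkt) / (1.0 + 0.0015 / cass)
    CaMKa = CaMKb + camkt
    dy[9] = 0.05 * CaMKb * (CaMKb + camkt) - 0.00068 * camkt

    # reversal potentials
    ENa = (_R * _T / _F) * math.log(_NAO / nai)
    EK = (_R * _T / _F) * math.log(_KO / ki)
    PKNa = 0.01833
    EKs = (_R * _T / _F) * math.log((_KO + PKNa * _NAO) / (ki + PKNa * nai))
    vfrt = v * _F / (_R * _T)

    # INa (fast)
    xinf[10] = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    xtau[10] = 1.0 / (
        6.765 * math.exp((v + 11.64) / 34.77) + 8.552 * math.exp(-(v + 77.42) / 5.955)
    )
    hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
    thf = 1.0 / (
        1.432e-5 * math.exp(-(v + 1.196) / 6.285)
        + 6.149 * math.exp((v + 0.5096) / 20.27)
    )
    ths = 1.0 / (
        0.009794 * math.exp(-(v + 17.95) / 28.05)
        + 0.3343 * math.exp((v + 5.730) / 56.66)
    )
    xinf[11] = hss
    xtau[11] = thf
    xinf[12] = hss
    xtau[12] = ths
    h = 0.99 * y[11] + 0.01 * y[12]
    tj = 2.038 + 1.0 / (
        0.02136 * math.exp(-(v + 100.6) / 8.281)
        + 0.3052 * math.exp((v + 0.9941) / 38.45)
    )
    xinf[13] = hss
    xtau[13] = tj
    hssp = 1.0 / (1.0 + math.exp((v + 89.1) / 6.086))
    xinf[14] = hssp
    xtau[14] = 3.0 * ths
    hp = 0.99 * y[11] + 0.01 * y[14]
    xinf[15] = hss
    xtau[15] = 1.46 * tj
    GNa = 75.0
    fINap = 1.0 / (1.0 + 0.15 / CaMKa)
    m = y[10]
    INa = (
        GNa
        * (v - ENa)
        * m * m * m
        * ((1.0 - fINap) * h * y[13] + fINap * hp * y[15])
    )

    # INaL
    xinf[16] = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    xtau[16] = xtau[10]
    xinf[17] = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    xtau[17] = 200.0
    xinf[18] = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    xtau[18] = 600.0
    GNaL = 0.0075 * gmult[0]
    fINaLp = fINap
    INaL = GNaL * (v - ENa) * y[16] * ((1.0 - fINaLp) * y[17] + fINaLp * y[18])

    # Ito (endocardial: delta_epi = 1)
    xinf[19] = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    xtau[19] = 1.0515 / (
        1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
        + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814))
    )
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    tiF = 4.562 + 1.0 / (
        0.3933 * math.exp(-(v + 100.0) / 100.0)
        + 0.08004 * math.exp((v + 50.0) / 16.59)
    )
    tiS = 23.62 + 1.0 / (
        0.001416 * math.exp(-(v + 96.52) / 59.05)
        + 1.780e-8 * math.exp((v + 114.1) / 8.079)
    )
    xinf[20] = iss
    xtau[20] = tiF
    xinf[21] = iss
    xtau[21] = tiS
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    i_gate = AiF * y[20] + AiS * y[21]
    xinf[22] = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    xtau[22] = xtau[19]
    dti_develop = 1.354 + 1.0e-4 / (
        math.exp((v - 167.4) / 15.89) + math.exp(-(v - 12.23) / 0.2154)
    )
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    xinf[23] = iss
    xtau[23] = dti_develop * dti_recover * tiF
    xinf[24] = iss
    xtau[24] = dti_develop * dti_recover * tiS
    ip = AiF * y[23] + AiS * y[24]
    Gto = 0.02 * gmult[5]
    fItop = fINap
    Ito = Gto * (v - EK) * ((1.0 - fItop) * y[19] * i_gate + fItop * y[22] * ip)

    # ICaL / ICaNa / ICaK
    xinf[25] = 1.0 / (1.0 + math.exp(-(v + 3.940) / 4.230))
    xtau[25] = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (
        0.0045 * math.exp(-(v + 20.0) / 10.0) + 0.0045 * math.exp((v + 20.0) / 10.0)
    )
    tfs = 1000.0 + 1.0 / (
        0.000035 * math.exp(-(v + 5.0) / 4.0) + 0.000035 * math.exp((v + 5.0) / 6.0)
    )
    xinf[26] = fss
    xtau[26] = tff
    xinf[27] = fss
    xtau[27] = tfs
    f = 0.6 * y[26] + 0.4 * y[27]
    fcass = fss
    tfcaf = 7.0 + 1.0 / (
        0.04 * math.exp(-(v - 4.0) / 7.0) + 0.04 * math.exp((v - 4.0) / 7.0)
    )
    tfcas = 100.0 + 1.0 / (
        0.00012 * math.exp(-v / 3.0) + 0.00012 * math.exp(v / 7.0)
    )
    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    xinf[28] = fcass
    xtau[28] = tfcaf
    xinf[29] = fcass
    xtau[29] = tfcas
    fca = Afcaf * y[28] + Afcas * y[29]
    xinf[30] = fcass
    xtau[30] = 75.0
    xinf[31] = fss
    xtau[31] = 2.5 * tff
    fp = 0.6 * y[31] + 0.4 * y[27]
    xinf[32] = fcass
    xtau[32] = 2.5 * tfcaf
    fcap = Afcaf * y[32] + Afcas * y[29]
    jca = y[30]
    # nca: linear ODE, integrated as exponential relaxation
    Kmn = 0.002
    k2n = 1000.0
    km2n = jca * 1.0
    tmp = 1.0 + Kmn / cass
    anca = 1.0 / (k2n / km2n + tmp * tmp * tmp * tmp)
    xinf[33] = anca * k2n / km2n
    xtau[33] = 1.0 / km2n
    nca = y[33]

    b1 = vfrt
    b2 = 2.0 * vfrt
    # g(x) = x / (exp(x) - 1), g(0) = 1
    if abs(b1) < 1.0e-7:
        g1 = 1.0 - 0.5 * b1
        g2 = 1.0 - 0.5 * b2
    else:
        g1 = b1 / math.expm1(b1)
        g2 = b2 / math.expm1(b2)
    eb1 = math.exp(b1)
    eb2 = math.exp(b2)
    PhiCaL = 2.0 * _F * (cass * eb2 - 0.341 * _CAO) * g2
    PhiCaNa = _F * (0.75 * nass * eb1 - 0.75 * _NAO) * g1
    PhiCaK = _F * (0.75 * kss * eb1 - 0.75 * _KO) * g1
    PCa = 0.0001 * gmult[1]
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    fICaLp = fINap
    d_gate = y[25]
    gate_np = f * (1.0 - nca) + jca * fca * nca
    gate_p = fp * (1.0 - nca) + jca * fcap * nca
    ICaL = (1.0 - fICaLp) * PCa * PhiCaL * d_gate * gate_np + fICaLp * PCap * PhiCaL * d_gate * gate_p
    ICaNa = (1.0 - fICaLp) * PCaNa * PhiCaNa * d_gate * gate_np + fICaLp * PCaNap * PhiCaNa * d_gate * gate_p
    ICaK = (1.0 - fICaLp) * PCaK * PhiCaK * d_gate * gate_np + fICaLp * PCaKp * PhiCaK * d_gate * gate_p

    # IKr
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    xinf[34] = xrss
    xtau[34] = 12.98 + 1.0 / (
        0.3652 * math.exp((v - 31.66) / 3.869)
        + 4.123e-5 * math.exp(-(v - 47.78) / 20.38)
    )
    xinf[35] = xrss
    xtau[35] = 1.865 + 1.0 / (
        0.06629 * math.exp((v - 34.70) / 7.355)
        + 1.128e-5 * math.exp(-(v - 29.74) / 25.94)
    )
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    xr = Axrf * y[34] + (1.0 - Axrf) * y[35]
    rkr = (
        1.0
        / (1.0 + math.exp((v + 55.0) / 75.0))
        / (1.0 + math.exp((v - 10.0) / 30.0))
    )
    GKr = 0.046 * gmult[2]
    IKr = GKr * math.sqrt(_KO / 5.4) * xr * rkr * (v - EK)

    # IKs
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    xinf[36] = xs1ss
    xtau[36] = 817.3 + 1.0 / (
        2.326e-4 * math.exp((v + 48.28) / 17.80)
        + 0.001292 * math.exp(-(v + 210.0) / 230.0)
    )
    xinf[37] = xs1ss
    xtau[37] = 1.0 / (
        0.01 * math.exp((v - 50.0) / 20.0) + 0.0193 * math.exp(-(v + 66.54) / 31.0)
    )
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034 * gmult[3]
    IKs = GKs * KsCa * y[36] * y[37] * (v - EKs)

    # IK1
    xinf[38] = 1.0 / (
        1.0 + math.exp(-(v + 2.5538 * _KO + 144.59) / (1.5692 * _KO + 3.8115))
    )
    xtau[38] = 122.2 / (
        math.exp(-(v + 127.2) / 20.36) + math.exp((v + 236.8) / 69.33)
    )
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * _KO) / 9.493))
    GK1 = 0.1908 * gmult[4]
    IK1 = GK1 * math.sqrt(_KO) * rk1 * y[38] * (v - EK)

    # INaCa (Na/Ca exchanger), myoplasmic and subspace components
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
    hca = math.exp(qca * vfrt)
    hna = math.exp(qna * vfrt)
    # myoplasmic
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + _NAO / kna3 * (1.0 + 1.0 / hna)
    h8 = _NAO / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + _NAO / kna1 * (1.0 + _NAO / kna2)
    h11 = _NAO * _NAO / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * _CAO * kcaon
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
    s = x1 + x2 + x3 + x4
    E1 = x1 / s
    E2 = x2 / s
    E3 = x3 / s
    E4 = x4 / s
    KmCaAct = 150.0e-6
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2.0)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    Gncx = 0.0008
    INaCa_i = 0.8 * Gncx * allo * (JncxNa + 2.0 * JncxCa)
    # subspace
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k1 = h12 * _CAO * kcaon
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    s = x1 + x2 + x3 + x4
    E1 = x1 / s
    E2 = x2 / s
    E3 = x3 / s
    E4 = x4 / s
    allo = 1.0 / (1.0 + (KmCaAct / cass) ** 2.0)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo * (JncxNa + 2.0 * JncxCa)

    # INaK (Na/K pump)
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3pk = 1899.0
    k3m = 79300.0
    k4pk = 639.0
    k4m = 40.0
    Knai = 9.073 * math.exp(-0.1550 * vfrt / 3.0)
    Knao = 27.78 * math.exp((1.0 - (-0.1550)) * vfrt / 3.0)
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
    na_i = nai / Knai
    na_o = _NAO / Knao
    k_i = ki / Kki
    k_o = _KO / Kko
    d_i = (1.0 + na_i) ** 3.0 + (1.0 + k_i) ** 2.0 - 1.0
    d_o = (1.0 + na_o) ** 3.0 + (1.0 + k_o) ** 2.0 - 1.0
    a1 = k1p * na_i ** 3.0 / d_i
    bb1 = k1m * MgADP
    a2 = k2p
    bb2 = k2m * na_o ** 3.0 / d_o
    a3 = k3pk * k_o ** 2.0 / d_o
    bb3 = (k3m * P * H) / (1.0 + MgATP / Kmgatp)
    a4 = (k4pk * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
    bb4 = k4m * k_i ** 2.0 / d_i
    x1 = a4 * a1 * a2 + bb2 * bb4 * bb3 + a2 * bb4 * bb3 + bb3 * a1 * a2
    x2 = bb2 * bb1 * bb4 + a1 * a2 * a3 + a3 * bb1 * bb4 + a2 * a3 * bb4
    x3 = a2 * a3 * a4 + bb3 * bb2 * bb1 + bb2 * bb1 * a4 + a3 * a4 * bb1
    x4 = bb4 * bb3 * bb2 + a3 * a4 * a1 + bb2 * a4 * a1 + bb3 * bb2 * a1
    s = x1 + x2 + x3 + x4
    E1 = x1 / s
    E2 = x2 / s
    E3 = x3 / s
    E4 = x4 / s
    JnakNa = 3.0 * (E1 * a3 - E2 * bb3)
    JnakK = 2.0 * (E4 * bb1 - E3 * a1)
    Pnak = 30.0
    INaK = Pnak * (JnakNa + JnakK)

    # background and pump currents
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    IKb = 0.003 * xkb * (v - EK)
    INab = 3.75e-10 * _F * (nai * eb1 - _NAO) * g1
    ICab = 2.5e-8 * 2.0 * _F * (cai * eb2 - 0.341 * _CAO) * g2
    IpCa = 0.0005 * cai / (0.0005 + cai)

    # diffusion fluxes
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    # SR calcium release (RyR), CaMK-split, relaxation form
    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8.0)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    xinf[39] = Jrel_inf
    xtau[39] = tau_rel
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8.0)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    xinf[40] = Jrel_infp
    xtau[40] = tau_relp
    fJrelp = fINap
    Jrel = (1.0 - fJrelp) * y[39] + fJrelp * y[40]

    # SERCA uptake, leak, NSR->JSR translocation
    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    fJupp = fINap
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fJupp) * Jupnp + fJupp * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # concentration ODEs
    dy[1] = (
        -(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab) * _ACAP / (_F * _VMYO)
        + JdiffNa * _VSS / _VMYO
    )
    dy[2] = -(ICaNa + 3.0 * INaCa_ss) * _ACAP / (_F * _VSS) - JdiffNa
    dy[3] = (
        -(Ito + IKr + IKs + IK1 + IKb + ist - 2.0 * INaK) * _ACAP / (_F * _VMYO)
        + JdiffK * _VSS / _VMYO
    )
    dy[4] = -ICaK * _ACAP / (_F * _VSS) - JdiffK
    cmdnmax = 0.05
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    Bcai = 1.0 / (
        1.0
        + cmdnmax * kmcmdn / ((kmcmdn + cai) * (kmcmdn + cai))
        + trpnmax * kmtrpn / ((kmtrpn + cai) * (kmtrpn + cai))
    )
    dy[5] = Bcai * (
        -(IpCa + ICab - 2.0 * INaCa_i) * _ACAP / (2.0 * _F * _VMYO)
        - Jup * _VNSR / _VMYO
        + Jdiff * _VSS / _VMYO
    )
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    Bcass = 1.0 / (
        1.0
        + BSRmax * KmBSR / ((KmBSR + cass) * (KmBSR + cass))
        + BSLmax * KmBSL / ((KmBSL + cass) * (KmBSL + cass))
    )
    dy[6] = Bcass * (
        -(ICaL - 2.0 * INaCa_ss) * _ACAP / (2.0 * _F * _VSS)
        + Jrel * _VJSR / _VSS
        - Jdiff
    )
    dy[7] = Jup - Jtr * _VJSR / _VNSR
    csqnmax = 10.0
    kmcsqn = 0.8
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / ((kmcsqn + cajsr) * (kmcsqn + cajsr)))
    dy[8] = Bcajsr * (Jtr - Jrel)

    Itot = (
        INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
        + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab
    )
    dy[0] = -(Itot + ist)

    cur[0] = INaL
    cur[1] = ICaL
    cur[2] = IKr
    cur[3] = IKs
    cur[4] = IK1
    cur[5] = Ito
    return Itot


# gate (Rush-Larsen) state indices; everything else is forward Euler
_RL_FIRST = 10
_EULER_IDX = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=np.int64)


@njit(cache=True)
def _advance(y, dy, xinf, xtau, dt):
    for i in range(10):
        y[i] += dt * dy[i]
    for i in range(10, N_STATES):
        y[i] = xinf[i] + (y[i] - xinf[i]) * math.exp(-dt / xtau[i])


@njit(cache=True)
def pace(y, n_beats, bcl, stim_amp, stim_dur, gmult, record_last,
         dt_out, dt_min, dt_max, dv_max):
    """Pace ``n_beats`` beats at cycle length ``bcl`` (ms), mutating ``y``.

    Records the last ``record_last`` beats on a uniform ``dt_out`` grid:
    Vm, [Ca]i and the six block-able currents, plus per-beat fine-grained
    (solver-resolution trapezoid) integrals of (sum of six currents, INaL,
    ICaL) in A*ms/F.  Also returns the per-beat peak Vm and an error code
    (0 = ok, b+1 = non-finite state during beat b).
    """
    n_out = int(round(bcl / dt_out)) + 1
    rec_vm = np.zeros((record_last, n_out))
    rec_cai = np.zeros((record_last, n_out))
    rec_cur = np.zeros((record_last, 6, n_out))
    fine = np.zeros((record_last, 3))
    peaks = np.full(n_beats, -1.0e9)

    dy = np.zeros(N_STATES)
    xinf = np.zeros(N_STATES)
    xtau = np.ones(N_STATES)
    cur = np.zeros(6)

    for b in range(n_beats):
        rec = b - (n_beats - record_last)
        t = 0.0
        ist = stim_amp  # stimulus active on [0, stim_dur)
        _rhs(y, gmult, ist, dy, xinf, xtau, cur)
        vm_prev = y[0]
        cai_prev = y[5]
        cur_prev = cur.copy()
        t_prev = 0.0
        i_out = 0
        if rec >= 0:
            rec_vm[rec, 0] = y[0]
            rec_cai[rec, 0] = y[5]
            for c in range(6):
                rec_cur[rec, c, 0] = cur[c]
            i_out = 1
        if y[0] > peaks[b]:
            peaks[b] = y[0]

        while t < bcl - 1.0e-9:
            adv = abs(dy[0])
            if adv * dt_max > dv_max:
                dt = dv_max / adv
            else:
                dt = dt_max
            if dt < dt_min:
                dt = dt_min
            if t < stim_dur - 1.0e-12 and t + dt > stim_dur:
                dt = stim_dur - t
            if t + dt > bcl:
                dt = bcl - t
            _advance(y, dy, xinf, xtau, dt)
            t = t + dt
            if not (math.isfinite(y[0]) and math.isfinite(y[6])):
                return rec_vm, rec_cai, rec_cur, fine, peaks, b + 1
            ist = stim_amp if t < stim_dur - 1.0e-12 else 0.0
            _rhs(y, gmult, ist, dy, xinf, xtau, cur)
            if y[0] > peaks[b]:
                peaks[b] = y[0]
            if rec >= 0:
                # fine trapezoid over [t_prev, t]
                csum_prev = 0.0
                csum = 0.0
                for c in range(6):
                    csum_prev += cur_prev[c]
                    csum += cur[c]
                fine[rec, 0] += 0.5 * (csum_prev + csum) * dt
                fine[rec, 1] += 0.5 * (cur_prev[0] + cur[0]) * dt
                fine[rec, 2] += 0.5 * (cur_prev[1] + cur[1]) * dt
                # output samples in (t_prev, t]
                while i_out < n_out and i_out * dt_out <= t + 1.0e-9:
                    to = i_out * dt_out
                    w = (to - t_prev) / dt
                    rec_vm[rec, i_out] = vm_prev + w * (y[0] - vm_prev)
                    rec_cai[rec, i_out] = cai_prev + w * (y[5] - cai_prev)
                    for c in range(6):
                        rec_cur[rec, c, i_out] = cur_prev[c] + w * (cur[c] - cur_prev[c])
                    i_out += 1
            t_prev = t
            vm_prev = y[0]
            cai_prev = y[5]
            for c in range(6):
                cur_prev[c] = cur[c]

    return rec_vm, rec_cai, rec_cur, fine, peaks, 0
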