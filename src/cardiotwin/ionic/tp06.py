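"""Ten Tusscher–Panfilov (2006) human ventricular myocyte model.

Nineteen state variables: membrane potential, twelve Hodgkin–Huxley-type
gates, the ryanodine-receptor availability variable, and five ionic
concentrations (subspace/cytosolic/SR calcium, intracellular sodium and
potassium).  Gates are advanced with the Rush–Larsen exponential update;
concentrations use a forward step with the analytic rapid-buffering
correction; the membrane potential uses a forward step of the total
ionic current.  Currents are expressed per unit membrane capacitance
(pA/pF, numerically equal to mV/ms), so a stimulus is specified on the
same scale.

Three transmural variants (epicardial, endocardial, mid-myocardial)
differ only in the slow delayed-rectifier and transient-outward
conductances and in the kinetics of the ``s`` inactivation gate.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "N_STATES",
    "VARIANTS",
    "initial_state",
    "variant_params",
    "step_membrane",
    "reaction_step",
]

N_STATES = 19

# State vector layout
IV, IM, IH, IJ, IXR1, IXR2, IXS, IR, IS, ID, IF, IF2, IFCASS, IRR, \
    ICAI, ICASR, ICASS, INAI, IKI = range(19)

VARIANTS = ("epicardial", "endocardial", "mid-myocardial")

# Physical constants
_RGAS = 8314.472     # J/(kmol K)
_FARADAY = 96485.3415  # C/mol
_TEMP = 310.0        # K
_RTONF = _RGAS * _TEMP / _FARADAY

# Extracellular concentrations (mM)
_KO = 5.4
_NAO = 140.0
_CAO = 2.0

# Cell geometry / buffering
_VC = 0.016404
_VSR = 0.001094
_VSS = 0.00005468
_BUFC = 0.2
_KBUFC = 0.001
_BUFSR = 10.0
_KBUFSR = 0.3
_BUFSS = 0.4
_KBUFSS = 0.00025
_CAPACITANCE = 0.185

# Maximal conductances / fluxes (common to all variants)
_GNA = 14.838
_GK1 = 5.405
_GKR = 0.153
_GCAL = 0.0000398
_GBNA = 0.00029
_GBCA = 0.000592
_GPCA = 0.1238
_KPCA = 0.0005
_GPK = 0.0146
_PKNA = 0.03
_KNAK = 2.724
_KMK = 1.0
_KMNA = 40.0
_KNACA = 1000.0
_KSAT = 0.1
_N_GAMMA = 0.35
_KMNAI = 87.5
_KMCA = 1.38
_VMAXUP = 0.006375
_KUP = 0.00025
_VREL = 0.102
_K1P = 0.15
_K2P = 0.045
_K3 = 0.060
_K4 = 0.005
_EC = 1.5
_MAXSR = 2.5
_MINSR = 1.0
_VLEAK = 0.00036
_VXFER = 0.0038

# Steady state at rest (1 Hz pacing), published model initial conditions.
_INIT = np.array([
    -85.23,      # V (mV)
    0.00172,     # m
    0.7444,      # h
    0.7045,      # j
    0.00621,     # Xr1
    0.4712,      # Xr2
    0.0095,      # Xs
    2.42e-8,     # r
    0.999998,    # s
    3.373e-5,    # d
    0.7888,      # f
    0.9755,      # f2
    0.9953,      # fCass
    0.9073,      # R' (RyR availability)
    0.000126,    # Ca_i (mM)
    3.64,        # Ca_SR (mM)
    0.00036,     # Ca_ss (mM)
    8.604,       # Na_i (mM)
    136.89,      # K_i (mM)
])


def variant_params(variant: str = "epicardial") -> np.ndarray:
    """Per-variant parameters: [Gks, Gto, s_gate_kind].

    ``s_gate_kind`` is 0 for the epicardial/mid-myocardial ``s`` kinetics
    and 1 for the endocardial kinetics.
    """
    if variant == "epicardial":
        return np.array([0.392, 0.294, 0.0])
    if variant == "endocardial":
        return np.array([0.392, 0.073, 1.0])
    if variant == "mid-myocardial":
        return np.array([0.098, 0.294, 0.0])
    raise ValueError(f"unknown cell variant {variant!r}; choose from {VARIANTS}")


def initial_state(variant: str = "epicardial", n_cells: int | None = None) -> np.ndarray:
    """Resting-state vector(s); shape (19,) or (n_cells, 19)."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown cell variant {variant!r}")
    if n_cells is None:
        return _INIT.copy()
    return np.tile(_INIT, (n_cells, 1))


@njit(cache=True)
def _reaction_step_kernel(S, istim, dt, gks, gto, s_endo):  # pragma: no cover
    n = S.shape[0]
    for i in range(n):
        V = S[i, IV]
        m = S[i, IM]; h = S[i, IH]; j = S[i, IJ]
        xr1 = S[i, IXR1]; xr2 = S[i, IXR2]; xs = S[i, IXS]
        rg = S[i, IR]; sg = S[i, IS]
        d = S[i, ID]; f = S[i, IF]; f2 = S[i, IF2]; fcass = S[i, IFCASS]
        rr = S[i, IRR]
        cai = S[i, ICAI]; casr = S[i, ICASR]; cass = S[i, ICASS]
        nai = S[i, INAI]; ki = S[i, IKI]

        ek = _RTONF * np.log(_KO / ki)
        ena = _RTONF * np.log(_NAO / nai)
        eks = _RTONF * np.log((_KO + _PKNA * _NAO) / (ki + _PKNA * nai))
        eca = 0.5 * _RTONF * np.log(_CAO / cai)

        # Fast sodium current
        ina = _GNA * m * m * m * h * j * (V - ena)

        # L-type calcium current (GHK-like driving term)
        # F^2/(R T) == F / RTONF with V expressed in mV
        vshift = V - 15.0
        expv = np.exp(2.0 * vshift / _RTONF)
        if np.abs(vshift) < 1e-6:
            # L'Hopital limit of the GHK factor at V = 15 mV
            ical_drive = 2.0 * _FARADAY * (0.25 * cass - _CAO)
        else:
            ical_drive = 4.0 * vshift * (_FARADAY / _RTONF) \
                * (0.25 * cass * expv - _CAO) / (expv - 1.0)
        ical = _GCAL * d * f * f2 * fcass * ical_drive

        # Transient outward
        ito = gto * rg * sg * (V - ek)

        # Rapid / slow delayed rectifiers
        ikr = _GKR * np.sqrt(_KO / 5.4) * xr1 * xr2 * (V - ek)
        iks = gks * xs * xs * (V - eks)

        # Inward rectifier
        ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - ek - 200.0)))
        bk1 = (3.0 * np.exp(0.0002 * (V - ek + 100.0))
               + np.exp(0.1 * (V - ek - 10.0))) / (1.0 + np.exp(-0.5 * (V - ek)))
        ik1 = _GK1 * ak1 / (ak1 + bk1) * (V - ek)

        # Na/Ca exchanger
        evf = np.exp(_N_GAMMA * V / _RTONF)
        evf1 = np.exp((_N_GAMMA - 1.0) * V / _RTONF)
        inaca = _KNACA * (evf * nai * nai * nai * _CAO
                          - evf1 * _NAO * _NAO * _NAO * cai * 2.5) / \
            ((_KMNAI ** 3 + _NAO ** 3) * (_KMCA + _CAO) * (1.0 + _KSAT * evf1))

        # Na/K pump
        inak = _KNAK * _KO * nai / ((_KO + _KMK) * (nai + _KMNA)) / \
            (1.0 + 0.1245 * np.exp(-0.1 * V / _RTONF)
             + 0.0353 * np.exp(-V / _RTONF))

        ipca = _GPCA * cai / (_KPCA + cai)
        ipk = _GPK * (V - ek) / (1.0 + np.exp((25.0 - V) / 5.98))
        ibna = _GBNA * (V - ena)
        ibca = _GBCA * (V - eca)

        stim = istim[i]
        itot = ikr + iks + ik1 + ito + ina + ibna + ical + ibca + inak \
            + inaca + ipca + ipk - stim

        # --- calcium dynamics ---
        kcasr = _MAXSR - (_MAXSR - _MINSR) / (1.0 + (_EC / casr) ** 2)
        k1 = _K1P / kcasr
        k2 = _K2P * kcasr
        drr = (-k2 * cass * rr + _K4 * (1.0 - rr)) * dt
        rr_new = rr + drr
        oo = k1 * cass * cass * rr_new / (_K3 + k1 * cass * cass)
        irel = _VREL * oo * (casr - cass)
        ileak = _VLEAK * (casr - cai)
        iup = _VMAXUP / (1.0 + (_KUP * _KUP) / (cai * cai))
        ixfer = _VXFER * (cass - cai)

        inv_vcf2 = 1.0 / (2.0 * _VC * _FARADAY)
        inv_vcf = 1.0 / (_VC * _FARADAY)
        inv_vssf2 = 1.0 / (2.0 * _VSS * _FARADAY)

        # SR calcium with rapid CSQN buffering (quadratic solve)
        casrbuf = _BUFSR * casr / (casr + _KBUFSR)
        dcasr = dt * (iup - irel - ileak)
        bjsr = _BUFSR - casrbuf - dcasr - casr + _KBUFSR
        cjsr = _KBUFSR * (casrbuf + dcasr + casr)
        casr_new = (np.sqrt(bjsr * bjsr + 4.0 * cjsr) - bjsr) / 2.0

        # Subspace calcium
        cassbuf = _BUFSS * cass / (cass + _KBUFSS)
        dcass = dt * (-ixfer * (_VC / _VSS) + irel * (_VSR / _VSS)
                      + (-ical * inv_vssf2 * _CAPACITANCE))
        bcss = _BUFSS - cassbuf - dcass - cass + _KBUFSS
        ccss = _KBUFSS * (cassbuf + dcass + cass)
        cass_new = (np.sqrt(bcss * bcss + 4.0 * ccss) - bcss) / 2.0

        # Cytosolic calcium
        caibuf = _BUFC * cai / (cai + _KBUFC)
        dcai = dt * ((-(ibca + ipca - 2.0 * inaca) * inv_vcf2 * _CAPACITANCE)
                     - (iup - ileak) * (_VSR / _VC) + ixfer)
        bc = _BUFC - caibuf - dcai - cai + _KBUFC
        cc = _KBUFC * (caibuf + dcai + cai)
        cai_new = (np.sqrt(bc * bc + 4.0 * cc) - bc) / 2.0

        nai_new = nai + dt * (-(ina + ibna + 3.0 * inak + 3.0 * inaca)
                              * inv_vcf * _CAPACITANCE)
        ki_new = ki + dt * (-(-stim + ik1 + ito + ikr + iks - 2.0 * inak + ipk)
                            * inv_vcf * _CAPACITANCE)

        # --- gates: Rush-Larsen exponential updates ---
        am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
        bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) \
            + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
        tau_m = am * bm
        m_inf = 1.0 / ((1.0 + np.exp((-56.86 - V) / 9.03)) ** 2)

        if V >= -40.0:
            ah = 0.0
            bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
            aj = 0.0
            bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
        else:
            ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
            bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
            aj = (-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V)) \
                * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23)))
            bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
        tau_h = 1.0 / (ah + bh)
        h_inf = 1.0 / ((1.0 + np.exp((V + 71.55) / 7.43)) ** 2)
        tau_j = 1.0 / (aj + bj)
        j_inf = h_inf

        axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
        bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
        tau_xr1 = axr1 * bxr1
        xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))

        axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
        bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
        tau_xr2 = axr2 * bxr2
        xr2_inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))

        axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
        bxs = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
        tau_xs = axs * bxs + 80.0
        xs_inf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))

        r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
        tau_r = 9.5 * np.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8
        if s_endo > 0.5:
            s_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
            tau_s = 1000.0 * np.exp(-(V + 67.0) ** 2 / 1000.0) + 8.0
        else:
            s_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
            tau_s = 85.0 * np.exp(-(V + 45.0) ** 2 / 320.0) \
                + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0

        d_inf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
        ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
        bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
        gd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
        tau_d = ad * bd + gd

        f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
        tau_f = 1102.5 * np.exp(-((V + 27.0) ** 2) / 225.0) \
            + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0)) \
            + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0

        f2_inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
        tau_f2 = 562.0 * np.exp(-((V + 27.0) ** 2) / 240.0) \
            + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0)) \
            + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0))

        fcass_inf = 0.6 / (1.0 + (cass_new / 0.05) ** 2) + 0.4
        tau_fcass = 80.0 / (1.0 + (cass_new / 0.05) ** 2) + 2.0

        S[i, IM] = m_inf - (m_inf - m) * np.exp(-dt / tau_m)
        S[i, IH] = h_inf - (h_inf - h) * np.exp(-dt / tau_h)
        S[i, IJ] = j_inf - (j_inf - j) * np.exp(-dt / tau_j)
        S[i, IXR1] = xr1_inf - (xr1_inf - xr1) * np.exp(-dt / tau_xr1)
        S[i, IXR2] = xr2_inf - (xr2_inf - xr2) * np.exp(-dt / tau_xr2)
        S[i, IXS] = xs_inf - (xs_inf - xs) * np.exp(-dt / tau_xs)
        S[i, IR] = r_inf - (r_inf - rg) * np.exp(-dt / tau_r)
        S[i, IS] = s_inf - (s_inf - sg) * np.exp(-dt / tau_s)
        S[i, ID] = d_inf - (d_inf - d) * np.exp(-dt / tau_d)
        S[i, IF] = f_inf - (f_inf - f) * np.exp(-dt / tau_f)
        S[i, IF2] = f2_inf - (f2_inf - f2) * np.exp(-dt / tau_f2)
        S[i, IFCASS] = fcass_inf - (fcass_inf - fcass) * np.exp(-dt / tau_fcass)

        # clamp gates to [0, 1]
        for g in range(IM, IRR + 1):
            if S[i, g] < 0.0:
                S[i, g] = 0.0
            elif S[i, g] > 1.0:
                S[i, g] = 1.0
        if rr_new < 0.0:
            rr_new = 0.0
        elif rr_new > 1.0:
            rr_new = 1.0
        S[i, IRR] = rr_new

        S[i, ICAI] = cai_new
        S[i, ICASR] = casr_new
        S[i, ICASS] = cass_new
        S[i, INAI] = nai_new
        S[i, IKI] = ki_new
        S[i, IV] = V - dt * itot


def reaction_step(states: np.ndarray, istim: np.ndarray, dt: float,
                  variant: str | np.ndarray = "epicardial") -> None:
    """Advance membrane states of all cells in place by one step of ``dt`` ms."""
    p = variant_params(variant) if isinstance(variant, str) else variant
    _reaction_step_kernel(states, istim, dt, p[0], p[1], p[2])


def step_membrane(state: np.ndarray, stimulus_current: float, dt: float,
                  variant: str = "epicardial") -> np.ndarray:
    """Advance a single myocyte state by one time step.

    ``stimulus_current`` is per unit capacitance (pA/pF); positive values
    depolarize.  Raises if the state has become non-finite.
    """
    if not (0.0 < dt <= 0.05):
        raise ValueError(f"dt must be in (0, 0.05] ms, got {dt}")
    if not np.all(np.isfinite(state)):
        bad = int(np.flatnonzero(~np.isfinite(state))[0])
        raise FloatingPointError(f"non-finite membrane state at index {bad}")
    out = np.atleast_2d(np.array(state, dtype=float))
    reaction_step(out, np.array([stimulus_current]), dt, variant)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("membrane integration diverged")
    return out[0]
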