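"""Hodgkin–Huxley formulation of the spontaneous-AP baseline cell.

The membrane carries the eleven-term current roster

    I_tot = I_Na + I_CaL + I_ha + I_K1 + I_Kr + I_Ks + I_Kur + I_Kto
            + I_bNSC + I_NaK + I_NCX

with ``dV_m/dt = -I_tot/C_m``.  Each gated channel obeys
``I_x = sf_x * Gbar_x * pO * (V_m - E_x)`` with first-order gates
``dpO/dt = alpha(V)*(1-pO) - beta(V)*pO``.  Rate constants are expressed
through steady state and time constant, ``alpha = x_inf/tau`` and
``beta = (1-x_inf)/tau``, which keeps both rates non-negative for any V.

The quantitative choices (conductance densities, gate midpoints, Ca
compartmentation) are this package's own published-style formulation of a
small, spontaneously depolarizing hiPSC-like cardiomyocyte; they are
documented with their rationale in docs/FORMULATION.md.  Units: mV, ms,
pA, nS, pF, mM, pL, amol.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------- state layout
STATE_NAMES = (
    "V", "m", "h", "d", "f", "pa", "pi", "n", "r", "q", "s", "y",
    "Na_i", "K_i", "Ca_jnc", "Ca_iz", "Ca_blk", "Ca_SRup", "Ca_SRrl",
    "crf_NaK", "crf_NCX",
)
N_STATE = len(STATE_NAMES)
IV, IM, IH, ID, IF, IPA, IPI, IN, IR, IQ, IS, IY = range(12)
INAI, IKI, ICAJNC, ICAIZ, ICABLK, ICAUP, ICARL, ICRFNAK, ICRFNCX = range(12, 21)

#: roster order of the total-current sum; channels first, transporters last
CURRENT_NAMES = ("Na", "CaL", "ha", "K1", "Kr", "Ks", "Kur", "Kto",
                 "bNSC", "NaK", "NCX")
#: the nine conductance-scaled channels (transporters are scaled by crf instead)
CHANNEL_NAMES = CURRENT_NAMES[:9]

GATE_NAMES = ("m", "h", "d", "f", "pa", "pi", "n", "r", "q", "s", "y")
#: gates belonging to each gated channel (product of open probabilities)
CHANNEL_GATES = {
    "Na": ("m", "m", "m", "h"),
    "CaL": ("d", "f"),
    "ha": ("y",),
    "K1": (),      # instantaneous rectification, see k1_rectification()
    "Kr": ("pa", "pi"),
    "Ks": ("n",),
    "Kur": ("r",),
    "Kto": ("q", "s"),
    "bNSC": (),    # time-independent net background current, pO == 1
}

RTF = 26.73  # RT/F at 37 C, mV

# ---------------------------------------------------------------- gate kinetics


def _sig(v, vh, k):
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - vh) / k))


def gate_inf(name, v):
    """Steady-state open fraction of gate ``name`` at potential ``v`` (mV)."""
    v = np.asarray(v, dtype=float)
    if name == "m":
        return _sig(v, -40.0, 5.5)
    if name == "h":
        return _sig(v, -68.0, -6.0)
    if name == "d":
        return _sig(v, -22.0, 6.0)
    if name == "f":
        return _sig(v, -30.0, -4.0)
    if name == "pa":
        return _sig(v, -20.0, 8.0)
    if name == "pi":
        return _sig(v, -28.0, -18.0)
    if name == "n":
        return _sig(v, 2.0, 12.0)
    if name == "r":
        return _sig(v, -6.0, 8.0)
    if name == "q":
        return _sig(v, 0.0, 10.0)
    if name == "s":
        return _sig(v, -35.0, -6.0)
    if name == "y":
        return _sig(v, -77.0, -9.0)
    raise KeyError(f"unknown gate {name!r}")


def gate_tau(name, v):
    """Voltage-dependent time constant of gate ``name`` (ms)."""
    v = np.asarray(v, dtype=float)
    if name == "m":
        return 0.07 + 0.45 * np.exp(-(((v + 45.0) / 18.0) ** 2))
    if name == "h":
        return 0.8 + 28.0 * np.exp(-(((v + 65.0) / 12.0) ** 2))
    if name == "d":
        return 0.7 + 1.4 * np.exp(-(((v + 25.0) / 20.0) ** 2))
    if name == "f":
        return 25.0 + 220.0 * np.exp(-(((v + 30.0) / 25.0) ** 2))
    if name == "pa":
        return 50.0 + 400.0 * np.exp(-(((v + 45.0) / 35.0) ** 2))
    if name == "pi":
        return 2.0 + 0.0 * v
    if name == "n":
        return 300.0 + 400.0 * np.exp(-(((v + 20.0) / 40.0) ** 2))
    if name == "r":
        return 3.0 + 8.0 * np.exp(-(((v + 20.0) / 30.0) ** 2))
    if name == "q":
        return 2.0 + 5.0 * np.exp(-(((v + 20.0) / 30.0) ** 2))
    if name == "s":
        return 20.0 + 60.0 * np.exp(-(((v + 45.0) / 20.0) ** 2))
    if name == "y":
        return 150.0 + 500.0 * np.exp(-(((v + 75.0) / 25.0) ** 2))
    raise KeyError(f"unknown gate {name!r}")


def gate_rates(name, v):
    """Opening/closing rates ``(alpha, beta)`` in 1/ms for gate ``name``."""
    xi, tau = gate_inf(name, v), gate_tau(name, v)
    return xi / tau, (1.0 - xi) / tau


def k1_rectification(v, e_k=-87.0):
    """Instantaneous inward-rectifier open fraction of I_K1."""
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - (e_k + 8.0)) / 10.0))


def nak_voltage_factor(v):
    """Voltage dependence of the Na/K pump cycle rate (dimensionless)."""
    return 1.0 / (1.0 + 0.2 * np.exp(-np.asarray(v, dtype=float) / 40.0))


# ------------------------------------------------------------------ parameters
#: default model parameters; keys are stable API
DEFAULT_PARAMS = {
    "C_m": 30.0,                # pF
    # limiting conductances Gbar_x, nS
    "G_Na": 24.0, "G_CaL": 2.6, "G_ha": 0.7, "G_K1": 1.3, "G_Kr": 0.9,
    "G_Ks": 0.25, "G_Kur": 0.18, "G_Kto": 0.15, "G_bNSC": 0.12,
    # transporters
    "maxI_NaK": 4100.0,           # pA at crf = 1 and saturating factors
    "k_NCX": 2200.0,           # pA scale of the NCX turnover expression
    # reversal rules
    "E_CaL": 50.0, "E_ha": -30.0, "E_bNSC": 0.0,   # fixed, mV
    # external ions, mM
    "Na_o": 140.0, "K_o": 5.4, "Ca_o": 1.8,
    # Ca compartment volumes (pL) and linear buffering ratios total/free
    "vol_jnc": 0.01, "vol_iz": 0.10, "vol_blk": 0.50,
    "vol_SRup": 0.06, "vol_SRrl": 0.015,
    "beta_jnc": 12.0, "beta_iz": 20.0, "beta_blk": 50.0,
    "beta_SRup": 1.0, "beta_SRrl": 15.0,
    # Ca cycling
    "v_up": 0.006,              # mM/ms SERCA max in blk units
    "Km_up": 3.0e-4,            # mM
    "tau_tr": 80.0,             # ms SRup -> SRrl transfer
    "k_rel": 2.0,               # 1/ms release rate scale (gated by d)
    "tau_jnc_iz": 0.6,          # ms
    "tau_iz_blk": 3.0,          # ms
    "k_leak": 1.0e-4,           # 1/ms SRup -> blk leak
    # NaK / NCX kinetics
    "Km_NaK_Na": 45.0,
    "ncx_gamma": 0.35, "ncx_Km_Na": 87.5, "ncx_Km_Ca": 1.38, "ncx_ksat": 0.1,
    # ion fractions of the mixed cation currents
    "fNa_ha": 0.5, "fNa_bNSC": 0.7,
    # homeostasis feedback (per-cycle increments)
    "std_Nai": 6.1,             # mM
    "std_Catot": 79.0,          # amol
    "g_NaK_fb": 0.3,            # per mM
    "g_NCX_fb": 0.008,          # per amol
    "crf_floor": 0.05,
}

PARAM_ORDER = tuple(DEFAULT_PARAMS)
PARAM_INDEX = {k: i for i, k in enumerate(PARAM_ORDER)}


def param_vector(params=None):
    """Pack a parameter mapping into the flat float vector the kernel uses."""
    p = dict(DEFAULT_PARAMS)
    if params:
        unknown = set(params) - set(DEFAULT_PARAMS)
        if unknown:
            raise KeyError(f"unknown model parameters: {sorted(unknown)}")
        p.update(params)
    return np.array([float(p[k]) for k in PARAM_ORDER])


def sf_vector(sf=None):
    """9-channel scaling-factor vector in CHANNEL_NAMES order (missing -> 1)."""
    out = np.ones(len(CHANNEL_NAMES))
    if sf:
        for name, value in dict(sf).items():
            if name not in CHANNEL_NAMES:
                raise KeyError(
                    f"{name!r} is not a scalable channel; roster channels are "
                    f"{CHANNEL_NAMES}")
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"sf_{name} must be positive, got {value}")
            out[CHANNEL_NAMES.index(name)] = float(value)
    return out


# ------------------------------------------------------------------ rate table
V_TABLE_MIN, V_TABLE_MAX, V_TABLE_STEP = -150.0, 100.0, 0.05


def build_rate_table(dt):
    """Tabulate gate targets on a uniform V grid for the fixed-step kernel.

    Columns: for each gate (x_inf, exp(-dt/tau)) pairs in GATE_NAMES order,
    then K1 rectification, NaK voltage factor, and the two NCX exponentials.
    """
    v = np.arange(V_TABLE_MIN, V_TABLE_MAX + V_TABLE_STEP / 2, V_TABLE_STEP)
    cols = []
    for g in GATE_NAMES:
        cols.append(gate_inf(g, v))
        cols.append(np.exp(-dt / gate_tau(g, v)))
    cols.append(k1_rectification(v))
    cols.append(nak_voltage_factor(v))
    gamma = DEFAULT_PARAMS["ncx_gamma"]
    cols.append(np.exp(gamma * v / RTF))
    cols.append(np.exp((gamma - 1.0) * v / RTF))
    return np.ascontiguousarray(np.column_stack(cols))


COL_K1, COL_FNAK, COL_NCX1, COL_NCX2 = (len(GATE_NAMES) * 2 + i for i in range(4))


# ---------------------------------------------------------- reference currents

def nernst(z, c_out, c_in):
    """Nernst equilibrium potential (mV) for valence ``z``."""
    if c_in <= 0 or c_out <= 0:
        raise ValueError("Nernst potential needs positive concentrations")
    return RTF / z * np.log(c_out / c_in)


def currents(state, sf=None, params=None):
    """Per-current breakdown (pA, outward positive) at a full state vector.

    Pure-numpy reference implementation of the same expressions the compiled
    kernel integrates; tested against it for consistency.  Returns a dict in
    CURRENT_NAMES order.
    """
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    s9 = sf_vector(sf)
    y = np.asarray(state, dtype=float)
    v = y[IV]
    e_na = nernst(1, p["Na_o"], y[INAI])
    e_k = nernst(1, p["K_o"], y[IKI])

    gates = {n: y[1 + i] for i, n in enumerate(GATE_NAMES)}
    po = {
        "Na": gates["m"] ** 3 * gates["h"],
        "CaL": gates["d"] * gates["f"],
        "ha": gates["y"],
        "K1": float(k1_rectification(v)),
        "Kr": gates["pa"] * gates["pi"],
        "Ks": gates["n"],
        "Kur": gates["r"],
        "Kto": gates["q"] * gates["s"],
        "bNSC": 1.0,
    }
    e_rev = {"Na": e_na, "CaL": p["E_CaL"], "ha": p["E_ha"], "K1": e_k,
             "Kr": e_k, "Ks": e_k, "Kur": e_k, "Kto": e_k, "bNSC": p["E_bNSC"]}
    out = {}
    for i, name in enumerate(CHANNEL_NAMES):
        out[name] = s9[i] * p[f"G_{name}"] * po[name] * (v - e_rev[name])

    f_na = (y[INAI] / (y[INAI] + p["Km_NaK_Na"])) ** 3
    out["NaK"] = (y[ICRFNAK] * p["maxI_NaK"]) * f_na * float(nak_voltage_factor(v))

    ca_iz_free = y[ICAIZ] / p["beta_iz"]
    e1 = np.exp(p["ncx_gamma"] * v / RTF)
    e2 = np.exp((p["ncx_gamma"] - 1.0) * v / RTF)
    num = e1 * y[INAI] ** 3 * p["Ca_o"] - e2 * p["Na_o"] ** 3 * ca_iz_free
    den = ((p["ncx_Km_Na"] ** 3 + p["Na_o"] ** 3)
           * (p["ncx_Km_Ca"] + p["Ca_o"]) * (1.0 + p["ncx_ksat"] * e2))
    out["NCX"] = (y[ICRFNCX] * p["k_NCX"]) * num / den
    return out


def initial_state(params=None):
    """A resting-ish initial state from which the model settles to its rhythm."""
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    y = np.zeros(N_STATE)
    v0 = -75.0
    y[IV] = v0
    for i, g in enumerate(GATE_NAMES):
        y[1 + i] = float(gate_inf(g, v0))
    y[INAI] = p["std_Nai"]
    y[IKI] = 140.0
    y[ICAJNC] = 0.01
    y[ICAIZ] = 0.004
    y[ICABLK] = 0.005
    y[ICAUP] = 0.8
    y[ICARL] = 2.0
    y[ICRFNAK] = 1.0
    y[ICRFNCX] = 1.0
    return y


def ca_total_amol(state, params=None):
    """Total cell Ca (amol): volume-weighted sum over the five compartments."""
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    y = np.asarray(state, dtype=float)
    pairs = ((ICAJNC, "vol_jnc"), (ICAIZ, "vol_iz"), (ICABLK, "vol_blk"),
             (ICAUP, "vol_SRup"), (ICARL, "vol_SRrl"))
    # mM * pL = fmol; report amol
    return 1000.0 * float(sum(y[i] * p[v] for i, v in pairs))
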