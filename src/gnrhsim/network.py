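"""Gonadotrope GnRH-receptor signaling network.

A compartmental ODE model of the canonical Gq-coupled GnRHR cascade:

* ligand binding at the surface, with agonist-induced receptor
  internalization and recycling as the only upstream negative feedback
  (type I mammalian GnRHR lack a C-terminal tail and do not rapidly
  desensitize, so trafficking is the relevant slow feedback);
* PLC activation by occupied receptor;
* cytoplasmic Ca2+ driven by a saturating function of active PLC
  through a release gain that carries a slow, PLC-driven inactivation
  gate (a lumped stand-in for IP3-receptor fast inactivation and store
  depletion — see docs/methods.md for why this incoherent element is
  load-bearing);
* a collapsed Raf/MEK/ERK tier producing ppERK that shuttles between
  cytoplasm and nucleus (PKC requires both DAG, represented by active
  PLC, and Ca2+, so the ERK drive is a product of the two);
* a four-pool NFAT phosphorylation/localization cycle, with
  calcineurin activity a Hill function of Ca2+;
* nuclear Egr1 synthesis driven by nuclear ppERK.

Receptor pools and NFAT pools are conserved exactly by construction.
The state has 12 concentration-like components plus the release gate.

Internalization and recycling rates are exposed as multipliers
(``int_mult``, ``rec_mult``) of base rates, mirroring how trafficking
strength is scanned relative to the wet-lab-fitted "1x" estimate.
Defaults are calibrated so the model reproduces the target ordinal
behaviors (pulse-frequency optima shifting with internalization rate,
bell-shaped Ca2+ frequency responses appearing at 4x internalization
and above, monotonic PLC frequency responses at every multiplier);
``scripts/calibrate_network.py`` re-checks that calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._ode import DEFAULT_ATOL, DEFAULT_RTOL, integrate_pulsed
from .pulses import PulseProtocol, signal_at
from .timecourse import Timecourse

__all__ = [
    "NetworkParams",
    "NetworkState",
    "STATE_NAMES",
    "network_rhs",
    "resting_steady_state",
    "simulate_network",
    "SteadyStateError",
]

STATE_NAMES = (
    "R_surf", "HR", "R_int",
    "PLC_active", "rel_gate", "Ca_cyt",
    "ppERK_cyt", "ppERK_nuc",
    "NFAT_cyt_P", "NFAT_cyt_deP", "NFAT_nuc_deP", "NFAT_nuc_P",
    "Egr1_nuc",
)

MULT_RANGE = (0.001, 32.0)


class SteadyStateError(RuntimeError):
    """Raised when the resting steady state cannot be verified."""


@dataclass(frozen=True)
class NetworkParams:
    """Rate constants and totals for the GnRHR network (min, µM units)."""

    # ligand binding (Kd = koff/kon = 2 nM)
    kon: float = 5e8          # /M/min
    koff: float = 1.0         # /min
    # receptor trafficking; multipliers are folds of the base estimate
    kint_base: float = 0.012  # /min internalization of occupied receptor
    krec_base: float = 0.006  # /min recycling at a full internalized pool
    Krec_m: float = 0.15      # µM half-saturation of the recycling machinery
    int_mult: float = 1.0
    rec_mult: float = 1.0
    Rtot: float = 1.0         # µM-equivalent total receptor
    # PLC
    kact_plc: float = 1.2     # /µM/min, activation by HR
    kdeact_plc: float = 1.2   # /min
    PLCtot: float = 1.0
    # Ca2+ release (gain gated by slow PLC-driven inactivation)
    vrel: float = 1.2         # µM/min maximal release
    Krel: float = 0.17        # µM PLC half-max for release
    hrel: float = 4.0         # Hill coefficient of release on PLC
    Kinact: float = 0.14      # µM PLC half-max for gate inactivation
    hinact: float = 2.0
    gate_min: float = 0.30    # residual gain at full first-stage inactivation
    K_sat: float = 0.47       # µM PLC knee of the saturation drop
    h_sat: float = 8.0        # steepness of the saturation drop
    sat_drop: float = 0.27    # fractional loss of release gain past K_sat
    tau_gate: float = 30.0    # min, gate relaxation time
    kleak: float = 0.04       # µM/min basal leak
    kclear: float = 0.5       # /min Ca2+ clearance
    # ERK tier (PKC needs DAG ~ PLC and Ca2+)
    kerk: float = 0.3         # /min maximal phosphorylation rate
    KP_erk: float = 0.40     # µM PLC half-max in the ERK drive
    hP_erk: float = 5.0       # cascade steepness in the PLC/PKC arm
    KCa_erk: float = 1.3      # µM Ca half-max in the ERK drive
    hCa_erk: float = 3.0
    kdeph_cyt: float = 0.6    # /min cytoplasmic dephosphorylation
    kdeph_nuc: float = 0.05  # /min nuclear dephosphorylation
    kimp_erk: float = 0.1     # /min nuclear import of ppERK
    kexp_erk: float = 0.05    # /min nuclear export of ppERK
    ERKtot: float = 1.0
    # NFAT cycle (calcineurin = Hill of Ca2+)
    KCn: float = 1.8          # µM Ca half-max of calcineurin
    hCn: float = 4.0
    kdeph_nfat_cyt: float = 2.0   # /min * Cn, cytoplasmic dephosphorylation
    kreph_cyt: float = 0.6        # /min cytoplasmic rephosphorylation
    kimp_nfat: float = 0.015      # /min nuclear import of deP NFAT
    kreph_nuc: float = 0.06       # /min nuclear rephosphorylation
    kdeph_nfat_nuc: float = 0.6   # /min * Cn, nuclear dephosphorylation
    kexp_nfat: float = 0.08       # /min export of rephosphorylated NFAT
    NFATtot: float = 1.0
    # Egr1
    ksyn_egr1: float = 0.25   # /min per µM nuclear ppERK
    kdeg_egr1: float = 0.02   # /min

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        lo, hi = MULT_RANGE
        for name in ("int_mult", "rec_mult"):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(
                    f"{name}={v} outside the supported range [{lo}, {hi}]")

    @property
    def kint(self) -> float:
        return self.int_mult * self.kint_base

    @property
    def krec(self) -> float:
        return self.rec_mult * self.krec_base

    def recycle_flux(self, R_int: float) -> float:
        """Saturable recycling: the sorting machinery has finite capacity,
        so flux is Michaelis-Menten in the internalized pool, normalized to
        match ``krec * Rtot`` when the whole pool is internalized."""
        vmax = self.krec * (self.Krec_m + self.Rtot)
        return vmax * R_int / (self.Krec_m + R_int)

    def with_multipliers(self, int_mult: float | None = None,
                         rec_mult: float | None = None) -> "NetworkParams":
        """Copy with new trafficking multipliers."""
        kwargs = {}
        if int_mult is not None:
            kwargs["int_mult"] = int_mult
        if rec_mult is not None:
            kwargs["rec_mult"] = rec_mult
        return replace(self, **kwargs)


@dataclass
class NetworkState:
    """Named view of the 13-component state vector."""

    y: np.ndarray

    def __getattr__(self, name: str):
        try:
            return self.y[STATE_NAMES.index(name)]
        except ValueError:
            raise AttributeError(name) from None

    def nfat_nuclear_fraction(self, params: NetworkParams) -> float:
        return float((self.NFAT_nuc_deP + self.NFAT_nuc_P) / params.NFATtot)


def _erk_drive(P: float, Ca: float, p: NetworkParams) -> float:
    p_h = P ** p.hP_erk
    ca_h = Ca ** p.hCa_erk
    return (p_h / (p.KP_erk ** p.hP_erk + p_h)
            * ca_h / (p.KCa_erk ** p.hCa_erk + ca_h))


def _rhs(t: float, y: np.ndarray, H: float, p: NetworkParams) -> np.ndarray:
    (Rs, HR, Ri, P, h, Ca, Ek, En, NcP, Ncd, Nnd, NnP, G) = y

    bind = p.kon * H * Rs
    unbind = p.koff * HR
    internalize = p.kint * HR
    recycle = p.recycle_flux(Ri)

    dRs = -bind + unbind + recycle
    dHR = bind - unbind - internalize
    dRi = internalize - recycle

    dP = p.kact_plc * HR * (p.PLCtot - P) - p.kdeact_plc * P

    P_h = P ** p.hinact
    h_inf = p.gate_min + (1.0 - p.gate_min) * (
        p.Kinact ** p.hinact / (p.Kinact ** p.hinact + P_h))
    P_s = P ** p.h_sat
    h_inf *= 1.0 - p.sat_drop * P_s / (p.K_sat ** p.h_sat + P_s)
    dh = (h_inf - h) / p.tau_gate

    rel_h = P ** p.hrel
    release = p.vrel * h * rel_h / (p.Krel ** p.hrel + rel_h)
    dCa = p.kleak + release - p.kclear * Ca

    drive = _erk_drive(P, Ca, p)
    dEk = (p.kerk * drive * (p.ERKtot - Ek - En)
           - p.kdeph_cyt * Ek - p.kimp_erk * Ek + p.kexp_erk * En)
    dEn = p.kimp_erk * Ek - p.kexp_erk * En - p.kdeph_nuc * En

    ca_h = Ca ** p.hCn
    Cn = ca_h / (p.KCn ** p.hCn + ca_h)
    deph_c = p.kdeph_nfat_cyt * Cn * NcP
    reph_c = p.kreph_cyt * Ncd
    imp = p.kimp_nfat * Ncd
    reph_n = p.kreph_nuc * Nnd
    deph_n = p.kdeph_nfat_nuc * Cn * NnP
    exp_ = p.kexp_nfat * NnP
    dNcP = -deph_c + reph_c + exp_
    dNcd = deph_c - reph_c - imp
    dNnd = imp - reph_n + deph_n
    dNnP = reph_n - deph_n - exp_

    dG = p.ksyn_egr1 * En - p.kdeg_egr1 * G

    return np.array([dRs, dHR, dRi, dP, dh, dCa, dEk, dEn,
                     dNcP, dNcd, dNnd, dNnP, dG])


def network_rhs(
    state: np.ndarray | NetworkState,
    t: float,
    params: NetworkParams,
    protocol: PulseProtocol,
) -> np.ndarray:
    """State derivative under the protocol's stimulus at time ``t``."""
    y = state.y if isinstance(state, NetworkState) else np.asarray(state, float)
    if np.any(y[: len(STATE_NAMES) - 1] < -1e-9):
        raise ValueError("negative state components violate the model contract")
    return _rhs(t, y, float(signal_at(protocol, t)), params)


def _resting_nfat(p: NetworkParams, Cn0: float) -> np.ndarray:
    """Exact steady state of the linear 4-pool NFAT cycle at fixed Cn."""
    # pools: (cyt_P, cyt_deP, nuc_deP, nuc_P); fluxes as in _rhs
    A = np.array([
        [-p.kdeph_nfat_cyt * Cn0, p.kreph_cyt, 0.0, p.kexp_nfat],
        [p.kdeph_nfat_cyt * Cn0, -(p.kreph_cyt + p.kimp_nfat), 0.0, 0.0],
        [0.0, p.kimp_nfat, -p.kreph_nuc, p.kdeph_nfat_nuc * Cn0],
        [1.0, 1.0, 1.0, 1.0],  # conservation replaces the redundant row
    ])
    b = np.array([0.0, 0.0, 0.0, p.NFATtot])
    return np.linalg.solve(A, b)


def resting_steady_state(
    params: NetworkParams,
    tol: float = 1e-10,
) -> np.ndarray:
    """Steady state with no ligand: the pre-stimulation condition.

    All receptor sits on the surface, PLC is off, Ca2+ equals the
    leak/clearance baseline and NFAT is overwhelmingly cytoplasmic and
    phosphorylated.  The construction is algebraic (the unstimulated
    system is block-triangular); the residual is verified against
    ``tol`` and the state is required to be locally attracting.
    """
    p = params
    Ca0 = p.kleak / p.kclear
    h0 = p.gate_min + (1.0 - p.gate_min)  # h_inf at P = 0
    Cn0 = Ca0 ** p.hCn / (p.KCn ** p.hCn + Ca0 ** p.hCn)
    nfat = _resting_nfat(p, Cn0)
    y = np.array([
        p.Rtot, 0.0, 0.0,       # receptor pools
        0.0, h0, Ca0,           # PLC, gate, Ca
        0.0, 0.0,               # ppERK
        *nfat,
        0.0,                    # Egr1 (no basal ppERK drive)
    ])
    resid = _rhs(0.0, y, 0.0, p)
    resid_norm = float(np.max(np.abs(resid)))
    if resid_norm > tol:
        raise SteadyStateError(
            f"resting-state residual {resid_norm:.3e} exceeds {tol:.1e}")
    # local stability: all Jacobian eigenvalues in the closed left half-plane
    eps = 1e-7
    n = len(y)
    J = np.empty((n, n))
    for j in range(n):
        dy = np.zeros(n)
        dy[j] = eps * max(1.0, abs(y[j]))
        J[:, j] = (_rhs(0.0, y + dy, 0.0, p) - _rhs(0.0, y - dy, 0.0, p)) / (2 * dy[j])
    eig = np.linalg.eigvals(J)
    if np.any(eig.real > 1e-8):
        raise SteadyStateError(
            f"resting state is not attracting (max Re(eig) = {eig.real.max():.3e})")
    nf = (nfat[2] + nfat[3]) / p.NFATtot
    if nf >= 0.05:
        raise SteadyStateError(
            f"resting NFAT nuclear fraction {nf:.3f} >= 0.05; "
            "parameters violate the resting-localization contract")
    return y


def simulate_network(
    params: NetworkParams | None = None,
    protocol: PulseProtocol | None = None,
    dt: float = 0.1,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Timecourse:
    """Integrate the network from rest over the protocol horizon.

    Returns channels ``HR``, ``PLC``, ``Ca``, ``ppERK_nuc``,
    ``NFAT_NF``, ``Egr1`` (the quantities reported in the source
    analyses) plus the raw state columns needed for conservation
    checks, on a uniform grid of step ``dt`` <= 0.1 min.
    """
    params = NetworkParams() if params is None else params
    if protocol is None:
        raise ValueError("a PulseProtocol is required")
    if dt > 0.1:
        raise ValueError(f"grid step must be <= 0.1 min, got {dt}")
    y0 = resting_steady_state(params)
    n = int(round(protocol.horizon / dt))
    t_grid = np.linspace(0.0, protocol.horizon, n + 1)

    def rhs(t, y, stim):
        return _rhs(t, y, stim, params)

    def stim_after(t):
        return float(signal_at(protocol, min(t, protocol.horizon)))

    traj = integrate_pulsed(
        rhs, y0, protocol.edges(), stim_after, t_grid,
        rtol=rtol, atol=atol,
        context={"model": "network", "protocol": protocol,
                 "int_mult": params.int_mult, "rec_mult": params.rec_mult},
    )
    cols = {name: traj[:, i] for i, name in enumerate(STATE_NAMES)}
    nf = (cols["NFAT_nuc_deP"] + cols["NFAT_nuc_P"]) / params.NFATtot
    channels = {
        "HR": cols["HR"],
        "PLC": cols["PLC_active"],
        "Ca": cols["Ca_cyt"],
        "ppERK_nuc": cols["ppERK_nuc"],
        "NFAT_NF": nf,
        "Egr1": cols["Egr1_nuc"],
        # raw pools kept for conservation/diagnostic checks
        "R_surf": cols["R_surf"],
        "R_int": cols["R_int"],
        "ppERK_cyt": cols["ppERK_cyt"],
        "NFAT_cyt_P": cols["NFAT_cyt_P"],
        "NFAT_cyt_deP": cols["NFAT_cyt_deP"],
        "NFAT_nuc_deP": cols["NFAT_nuc_deP"],
        "NFAT_nuc_P": cols["NFAT_nuc_P"],
        "rel_gate": cols["rel_gate"],
    }
    return Timecourse(
        time=t_grid,
        channels=channels,
        meta={
            "model": "network",
            "rtol": rtol,
            "atol": atol,
            "protocol": protocol,
            "int_mult": params.int_mult,
            "rec_mult": params.rec_mult,
            "ca_auc_baseline_subtracted": False,
        },
    )
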