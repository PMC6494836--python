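"""Kinetic ODE models of tetrahydropapaveroline (THP) production pathways.

Three topologies convert L-DOPA into THP via spontaneous Pictet-Spengler
condensation of dopamine with 3,4-dihydroxyphenylacetaldehyde (DHPAA):

* ``MAO_PATH`` -- the nonsymmetrical route: DDC decarboxylates L-DOPA to
  dopamine, and monoamine oxidase (MAO) oxidises dopamine to DHPAA.  MAO is
  promiscuous, so a fixed pool of competing amines inhibits it competitively.
* ``DDC_DHPAAS_PATH`` -- the symmetrical route: DDC produces dopamine while
  3,4-dihydroxyphenylacetaldehyde synthase (DHPAAS) produces DHPAA directly
  from L-DOPA in parallel.
* ``SINGLE_DHPAAS_PATH`` -- a single bifunctional DHPAAS supplies both
  products, partitioned by the aldehyde-branch fraction ``phi_aldehyde``.

All enzymatic velocities are irreversible Michaelis-Menten with competitive
inhibition (the effective Km is multiplied by ``1 + sum(I/Ki)`` over the
active inhibitors).  Condensation is elementary second-order mass action.
DHPAA may additionally be lost to side reactions through a first-order
"drain".  L-DOPA enters as a constant feed that switches off once a
cumulative cap (default 100 mM) has been delivered.

Units: concentrations in mM, time in hours.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp


class PathwayConfigError(ValueError):
    """A PathwaySpec is inconsistent with its declared topology."""


class PathwayValidationError(ValueError):
    """A state or parameter value is outside its admissible domain."""


class SolverError(RuntimeError):
    """ODE integration failed; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class Topology(str, Enum):
    MAO_PATH = "MAO_PATH"
    DDC_DHPAAS_PATH = "DDC_DHPAAS_PATH"
    SINGLE_DHPAAS_PATH = "SINGLE_DHPAAS_PATH"


@dataclass(slots=True)
class PathwayState:
    """Pathway concentrations (mM) and cumulative bookkeeping at time ``t`` (h).

    ``fed`` accumulates L-DOPA delivered by the feed; ``drained`` accumulates
    DHPAA irreversibly lost to side reactions.  Both are needed to close the
    DOPA-equivalent balance ``S + DA + AL + 2*T + drained - fed``.
    """

    t: float = 0.0
    S: float = 0.0       # L-DOPA
    DA: float = 0.0      # dopamine
    AL: float = 0.0      # DHPAA (aldehyde)
    T: float = 0.0       # THP
    fed: float = 0.0
    drained: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.DA, self.AL, self.T, self.fed, self.drained])


@dataclass
class EnzymeParams:
    """Michaelis-Menten parameters: Vmax (mM/h), Km (mM), optional Ki map (mM)."""

    vmax: float
    km: float
    ki: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.vmax < 0:
            raise PathwayValidationError(f"Vmax must be >= 0, got {self.vmax}")
        if self.km <= 0:
            raise PathwayValidationError(f"Km must be > 0, got {self.km}")
        for name, k in self.ki.items():
            if k <= 0:
                raise PathwayValidationError(f"Ki[{name}] must be > 0, got {k}")

    def rate(self, substrate: float, inhibitors: Mapping[str, float] | None = None) -> float:
        """Irreversible MM velocity with competitive inhibition.

        ``inhibitors`` maps inhibitor name -> concentration; names without a
        Ki entry are ignored so callers can pass the full product vector.
        """
        if substrate <= 0:
            return 0.0
        km_eff = self.km
        if inhibitors:
            comp = 0.0
            for name, conc in inhibitors.items():
                ki = self.ki.get(name)
                if ki is not None and conc > 0:
                    comp += conc / ki
            km_eff = self.km * (1.0 + comp)
        return self.vmax * substrate / (km_eff + substrate)


@dataclass
class PathwaySpec:
    """One instantiated pathway model: topology, enzymes, and rate constants.

    ``phi_aldehyde`` is the fraction of total DHPAAS flux routed to the
    aldehyde (synthase) branch; it equals the "% DHPAAS activity" of a
    bifunctional variant divided by 100.  ``amine_pool`` is the effective
    concentration of amines competing with dopamine at MAO.
    """

    topology: Topology
    dhpaas: EnzymeParams | None = None
    ddc: EnzymeParams | None = None
    mao: EnzymeParams | None = None
    phi_aldehyde: float = 1.0
    k_cond: float = 1.0          # mM^-1 h^-1, Pictet-Spengler condensation
    k_drain: float = 0.0         # h^-1, DHPAA loss (0 = drain disabled)
    feed_rate: float = 0.0       # mM/h constant L-DOPA feed
    feed_cap: float = 100.0      # mM cumulative feed ceiling
    feedback: bool = False       # product feedback inhibition on/off
    amine_pool: float = 0.0      # mM competing amines seen by MAO

    def __post_init__(self):
        self.topology = Topology(self.topology)
        if not (0.0 <= self.phi_aldehyde <= 1.0):
            raise PathwayValidationError(
                f"phi_aldehyde must lie in [0, 1], got {self.phi_aldehyde}")
        for name in ("k_cond", "k_drain", "feed_rate", "amine_pool"):
            if getattr(self, name) < 0:
                raise PathwayValidationError(f"{name} must be >= 0")
        if self.feed_cap <= 0:
            raise PathwayValidationError("feed_cap must be > 0")
        need = {
            Topology.MAO_PATH: ("ddc", "mao"),
            Topology.DDC_DHPAAS_PATH: ("ddc", "dhpaas"),
            Topology.SINGLE_DHPAAS_PATH: ("dhpaas",),
        }[self.topology]
        for block in need:
            if getattr(self, block) is None:
                raise PathwayConfigError(
                    f"topology {self.topology.value} requires an {block!r} enzyme block")

    def copy(self) -> "PathwaySpec":
        return copy.deepcopy(self)

    # --- config round-trip ------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {
            "topology": self.topology.value,
            "phi_aldehyde": self.phi_aldehyde,
            "k_cond": self.k_cond,
            "k_drain": self.k_drain,
            "feed_rate": self.feed_rate,
            "feed_cap": self.feed_cap,
            "feedback": self.feedback,
            "amine_pool": self.amine_pool,
        }
        for block in ("dhpaas", "ddc", "mao"):
            enz = getattr(self, block)
            if enz is not None:
                d[block] = {"vmax": enz.vmax, "km": enz.km, "ki": dict(enz.ki)}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PathwaySpec":
        kw = dict(d)
        for block in ("dhpaas", "ddc", "mao"):
            if block in kw and kw[block] is not None:
                b = dict(kw[block])
                b.setdefault("ki", {})
                kw[block] = EnzymeParams(vmax=b["vmax"], km=b["km"], ki=dict(b["ki"]))
        return cls(**kw)


@dataclass
class Trajectory:
    """Solution of one pathway simulation on a uniform time grid."""

    t: np.ndarray
    S: np.ndarray
    DA: np.ndarray
    AL: np.ndarray
    T: np.ndarray
    fed: np.ndarray
    drained: np.ndarray
    spec: PathwaySpec
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    def state(self, i: int) -> PathwayState:
        return PathwayState(self.t[i], self.S[i], self.DA[i], self.AL[i],
                            self.T[i], self.fed[i], self.drained[i])

    @property
    def initial(self) -> PathwayState:
        return self.state(0)

    @property
    def final(self) -> PathwayState:
        return self.state(-1)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, "S": self.S, "DA": self.DA,
                             "AL": self.AL, "T": self.T, "fed": self.fed,
                             "drained": self.drained})


# ---------------------------------------------------------------------------
# rate terms
# ---------------------------------------------------------------------------

def ddc_rate(state: PathwayState, spec: PathwaySpec) -> float:
    """DDC velocity on L-DOPA; dopamine feeds back when feedback is enabled."""
    if spec.ddc is None:
        raise PathwayConfigError("spec has no ddc block")
    inhibitors = {"dopamine": state.DA} if spec.feedback else None
    return spec.ddc.rate(state.S, inhibitors)


def mao_rate(state: PathwayState, spec: PathwaySpec) -> float:
    """MAO velocity on dopamine.

    The fixed ``amine_pool`` competes in every MAO model; DHPAA additionally
    competes when product feedback is enabled.
    """
    if spec.topology is not Topology.MAO_PATH:
        raise PathwayConfigError("mao_rate is only defined for MAO_PATH")
    if spec.mao is None:
        raise PathwayConfigError("spec has no mao block")
    inhibitors = {"amine": spec.amine_pool}
    if spec.feedback:
        inhibitors["dhpaa"] = state.AL
    return spec.mao.rate(state.DA, inhibitors)


def dhpaas_rates(state: PathwayState, spec: PathwaySpec) -> tuple[float, float]:
    """Bifunctional DHPAAS split: (aldehyde-branch, decarboxylation-branch).

    A single MM velocity on L-DOPA is partitioned by ``phi_aldehyde``; both
    components are non-negative and sum to the total velocity.
    """
    if spec.dhpaas is None:
        raise PathwayConfigError("spec has no dhpaas block")
    inhibitors = {"dopamine": state.DA, "dhpaa": state.AL} if spec.feedback else None
    v = spec.dhpaas.rate(state.S, inhibitors)
    phi = spec.phi_aldehyde
    return phi * v, (1.0 - phi) * v


def condensation_rate(state: PathwayState, spec: PathwaySpec) -> float:
    """Spontaneous Pictet-Spengler rate k_cond * [dopamine] * [DHPAA]."""
    if state.DA < 0 or state.AL < 0:
        raise PathwayValidationError("negative concentration in condensation_rate")
    return spec.k_cond * state.DA * state.AL


def feed_term(state: PathwayState, spec: PathwaySpec) -> float:
    """Constant L-DOPA feed, switched off once the cumulative cap is reached."""
    return spec.feed_rate if state.fed < spec.feed_cap else 0.0


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

_IDX = {"S": 0, "DA": 1, "AL": 2, "T": 3, "fed": 4, "drained": 5}


def _rhs(t: float, y, spec: PathwaySpec, feeding: bool):
    # clip solver round-off below zero so MM terms stay defined
    S = y[0] if y[0] > 0 else 0.0
    DA = y[1] if y[1] > 0 else 0.0
    AL = y[2] if y[2] > 0 else 0.0
    st = PathwayState(t, S, DA, AL, y[3], y[4], y[5])

    v_ddc = ddc_rate(st, spec) if spec.ddc is not None else 0.0
    v_mao = mao_rate(st, spec) if spec.topology is Topology.MAO_PATH else 0.0
    if spec.dhpaas is not None:
        v_ald, v_dec = dhpaas_rates(st, spec)
    else:
        v_ald = v_dec = 0.0
    v_cond = spec.k_cond * DA * AL
    v_drain = spec.k_drain * AL
    feed = spec.feed_rate if feeding else 0.0

    return (
        feed - v_ddc - v_ald - v_dec,          # dS/dt
        v_ddc + v_dec - v_mao - v_cond,        # dDA/dt
        v_ald + v_mao - v_cond - v_drain,      # dAL/dt
        v_cond,                                # dT/dt
        feed,                                  # d(fed)/dt
        v_drain,                               # d(drained)/dt
    )


def simulate(spec: PathwaySpec, initial: PathwayState | None = None,
             t_end: float = 50.0, n_points: int = 501,
             rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the pathway ODE over [0, t_end] hours.

    Feeding is handled in two phases: integration runs with the feed active
    until the cumulative-feed event ``fed == feed_cap`` fires, then restarts
    from the crossing time with the feed off, so the delivered substrate never
    overshoots the cap.  A stiff-capable solver (LSODA) with dense output is
    evaluated on a uniform ``n_points`` grid.
    """
    if t_end <= 0:
        raise PathwayValidationError("t_end must be > 0")
    if initial is None:
        initial = PathwayState()
    y0 = initial.as_array()
    if np.any(y0 < 0):
        raise PathwayValidationError("initial state must be non-negative")

    grid = np.linspace(0.0, t_end, n_points)
    out = np.empty((6, n_points))
    diagnostics = {"rtol": rtol, "atol": atol, "segments": [], "method": "LSODA"}

    feeding = spec.feed_rate > 0 and y0[_IDX["fed"]] < spec.feed_cap
    t0 = 0.0
    while True:
        events = None
        if feeding:
            def cap_event(t, y, *_args):
                return y[_IDX["fed"]] - spec.feed_cap
            cap_event.terminal = True
            cap_event.direction = 1
            events = cap_event
        mask = (grid >= t0 - 1e-12) & (grid <= t_end)
        sol = solve_ivp(_rhs, (t0, t_end), y0, method="LSODA",
                        args=(spec, feeding), rtol=rtol, atol=atol,
                        dense_output=True, events=events)
        diagnostics["segments"].append(
            {"t0": t0, "status": sol.status, "nfev": sol.nfev,
             "message": sol.message, "feeding": feeding})
        if sol.status == -1:
            raise SolverError(f"integration failed: {sol.message}", diagnostics)
        seg_end = sol.t[-1]
        sel = mask & (grid <= seg_end + 1e-12)
        if sel.any():
            out[:, sel] = sol.sol(np.clip(grid[sel], t0, seg_end))
        if sol.status == 1:  # feed cap reached; restart without feed
            t0 = seg_end
            y0 = sol.y[:, -1].copy()
            y0[_IDX["fed"]] = spec.feed_cap  # pin to the cap exactly
            feeding = False
            if t0 >= t_end:
                break
            continue
        break

    # scrub solver round-off: tiny negative concentrations are clipped to zero
    out = np.where((out < 0) & (out > -100 * atol), 0.0, out)
    if np.any(out < 0):
        raise SolverError("negative concentrations beyond solver tolerance",
                          diagnostics)
    return Trajectory(t=grid, S=out[0], DA=out[1], AL=out[2], T=out[3],
                      fed=out[4], drained=out[5], spec=spec,
                      diagnostics=diagnostics)


def thp_yield_pct(traj: Trajectory) -> float:
    """Molar THP yield in percent on a DOPA-equivalent basis.

    One THP consumes two L-DOPA equivalents (one via dopamine, one via DHPAA),
    so yield = 100 * 2 * T(t_end) / total DOPA input, where the input counts
    the initial S, DA, AL, 2*T and everything fed during the run.
    """
    if len(traj) == 0:
        raise PathwayValidationError("empty trajectory")
    ini, fin = traj.initial, traj.final
    total_in = ini.S + ini.DA + ini.AL + 2.0 * ini.T + (fin.fed - ini.fed)
    if total_in <= 0:
        raise PathwayValidationError("total DOPA input is zero; yield undefined")
    return 100.0 * 2.0 * fin.T / total_in


def dopa_conservation_residual(traj: Trajectory) -> float:
    """Max relative deviation of the DOPA-equivalent balance along a trajectory.

    The conserved combination is S + DA + AL + 2*T + drained - fed; its value
    at every grid point must match the initial one to solver precision.
    """
    bal = traj.S + traj.DA + traj.AL + 2.0 * traj.T + traj.drained - traj.fed
    ini = traj.initial
    total_in = ini.S + ini.DA + ini.AL + 2.0 * ini.T + (traj.final.fed - ini.fed)
    scale = max(total_in, 1e-12)
    return float(np.max(np.abs(bal - bal[0])) / scale)
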