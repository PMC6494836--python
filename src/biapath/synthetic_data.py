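"""Synthetic-data generators: every input the analyses need, from a seed.

Emulates (a) H2O2-production Michaelis-Menten assay data with CV-scaled
Gaussian noise and injected gross outliers, (b) noisy observations of
simulated pathway trajectories, (c) AAAD-family sequence sets with planted
active-site triads at positions 79/80/192, and (d) the stand-in kinetic
parameter-range tables driving the Monte-Carlo scenario grid.

All generators are pure functions of their spec (seed included); noise is
multiplicative (relative, CV-based) because fluorometric assay error scales
with signal.  Truth values are always returned alongside the noisy data so
downstream checks never re-derive ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enzyme_kinetics import RateDataset
from .monte_carlo import EnsembleSpec, ParameterRange
from .pathway_model import (EnzymeParams, PathwaySpec, PathwayState,
                            Topology, Trajectory, simulate)
from .residue_signature import (AA_ALPHABET, DDC_TRIAD, DHPAAS_TRIAD,
                                TRIAD_POSITIONS, SequenceRecord)

# Wild-type B. mori DHPAAS assay constants used as generator defaults:
# Km 41.7 µM, kcat 6.51 min^-1, specific Vmax 115 nmol H2O2 min^-1 mg^-1
# (so the implied enzyme content is 115/6.51 nmol per mg protein).
WT_KM_UM = 41.7
WT_KCAT_MIN = 6.51
WT_VMAX = 115.0
WT_ENZYME_CONC = WT_VMAX / WT_KCAT_MIN

# Printed (aldehyde-branch Vmax, decarboxylase Vmax) pairs per variant.
VARIANT_VMAX_PAIRS: dict[str, tuple[float, float]] = {
    "WT": (115.0, 5.59),
    "F79Y-Y80F": (82.2, 41.4),
    "N192H": (24.7, 87.6),
    "F79Y-Y80F-N192H": (15.4, 247.0),
}


@dataclass
class MMSimSpec:
    """Michaelis-Menten assay generator spec (concentrations in µM)."""

    km: float = WT_KM_UM
    kcat: float = WT_KCAT_MIN
    enzyme_conc: float = WT_ENZYME_CONC
    substrate: np.ndarray | None = None   # default: 2-fold series spanning Km
    n_replicates: int = 1
    noise_cv: float = 0.0
    outliers: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.substrate is None:
            # 8-point 2-fold dilution series centred on Km
            self.substrate = self.km * 2.0 ** np.arange(-3.0, 5.0)
        self.substrate = np.asarray(self.substrate, dtype=float)
        if not (self.substrate.min() < self.km / 2
                and self.substrate.max() > 2 * self.km):
            raise ValueError("substrate grid must span below Km/2 and above 2*Km")


def gen_mm_dataset(spec: MMSimSpec) -> tuple[RateDataset, dict]:
    """Generate a noisy MM rate dataset plus its ground-truth sidecar.

    v_i = kcat*E0*S_i/(Km+S_i) * (1 + eps_i), eps_i ~ N(0, noise_cv); outlier
    multipliers are applied after the noise.
    """
    rng = np.random.default_rng(spec.seed)
    S = np.tile(spec.substrate, spec.n_replicates)
    rep = np.repeat(np.arange(spec.n_replicates), len(spec.substrate))
    vmax = spec.kcat * spec.enzyme_conc
    v_true = vmax * S / (spec.km + S)
    eps = rng.normal(0.0, spec.noise_cv, size=S.shape) if spec.noise_cv else 0.0
    v = v_true * (1.0 + eps)
    for idx, mult in spec.outliers:
        v[idx] *= mult
    data = RateDataset(substrate=S, rate=v, enzyme_conc=spec.enzyme_conc,
                       replicate_id=rep)
    truth = {"km": spec.km, "kcat": spec.kcat, "vmax": vmax,
             "enzyme_conc": spec.enzyme_conc,
             "outlier_indices": [i for i, _ in spec.outliers]}
    return data, truth


@dataclass
class TrajectorySimSpec:
    """Noisy-observation generator over a pathway simulation."""

    pathway: PathwaySpec
    obs_times: np.ndarray
    noise_cv: float = 0.0
    t_end: float = 50.0
    initial: PathwayState | None = None
    seed: int = 0

    def __post_init__(self):
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        if self.obs_times.min() < 0 or self.obs_times.max() > self.t_end:
            raise ValueError("observation times must lie within [0, t_end]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def gen_trajectory_dataset(spec: TrajectorySimSpec) -> tuple[pd.DataFrame, Trajectory]:
    """Simulate, sample at the observation times, add multiplicative noise.

    Returns (observations, true trajectory); the observation table carries
    one row per time point with noisy S, DA, AL, T columns.
    """
    rng = np.random.default_rng(spec.seed)
    traj = simulate(spec.pathway, initial=spec.initial, t_end=spec.t_end)
    obs = {}
    for name in ("S", "DA", "AL", "T"):
        truth = np.interp(spec.obs_times, traj.t, getattr(traj, name))
        noise = rng.normal(0.0, spec.noise_cv, size=truth.shape) if spec.noise_cv else 0.0
        obs[name] = truth * (1.0 + noise)
    df = pd.DataFrame({"t": spec.obs_times, **obs})
    return df, traj


@dataclass
class MotifFamilySpec:
    """Synthetic AAAD family with planted 79/80/192 triads.

    ``assignments`` maps archetype name -> number of sequences; archetypes
    are "DHPAAS" (F,Y,N), "DDC" (Y,F,H) and "mixed" (Y,Y,N, the isoform-X2
    style motif).  ``mutation_rate`` applies per non-triad site;
    ``mutate_triad`` lets mutations hit the triad positions too.
    """

    ref_length: int = 250
    assignments: dict[str, int] = field(
        default_factory=lambda: {"DHPAAS": 10, "DDC": 10, "mixed": 5})
    mutation_rate: float = 0.0
    mutate_triad: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.ref_length < max(TRIAD_POSITIONS):
            raise ValueError(
                f"reference must be at least {max(TRIAD_POSITIONS)} residues")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must lie in [0, 1)")
        unknown = set(self.assignments) - {"DHPAAS", "DDC", "mixed"}
        if unknown:
            raise ValueError(f"unknown archetypes {sorted(unknown)}")


_TRIADS = {"DHPAAS": DHPAAS_TRIAD, "DDC": DDC_TRIAD, "mixed": ("Y", "Y", "N")}
_EXPECTED_LABEL = {"DHPAAS": "DHPAAS-like", "DDC": "DDC-like",
                   "mixed": "intermediate"}


def gen_motif_family(spec: MotifFamilySpec) -> tuple[SequenceRecord,
                                                     list[SequenceRecord],
                                                     pd.DataFrame]:
    """Generate (reference, family records, truth table).

    The reference is a random canonical-alphabet sequence carrying the
    synthase triad (F79, Y80, N192); every family member is a point-mutated
    copy with its assigned triad planted.  The truth table pairs each id
    with its archetype and the expected classification label.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(sorted(AA_ALPHABET))
    ref = rng.choice(alphabet, size=spec.ref_length)
    for pos, res in zip(TRIAD_POSITIONS, DHPAAS_TRIAD):
        ref[pos - 1] = res
    reference = SequenceRecord("reference_synthetic",
                               "".join(ref))

    triad_idx = np.array([p - 1 for p in TRIAD_POSITIONS])
    records, rows = [], []
    counter = 0
    for archetype, n in spec.assignments.items():
        triad = _TRIADS[archetype]
        for _ in range(n):
            seq = ref.copy()
            if spec.mutation_rate > 0:
                hits = rng.random(spec.ref_length) < spec.mutation_rate
                if not spec.mutate_triad:
                    hits[triad_idx] = False
                for i in np.flatnonzero(hits):
                    choices = alphabet[alphabet != seq[i]]
                    seq[i] = rng.choice(choices)
            for pos, res in zip(TRIAD_POSITIONS, triad):
                seq[pos - 1] = res
            if spec.mutate_triad and spec.mutation_rate > 0:
                for pos in TRIAD_POSITIONS:
                    if rng.random() < spec.mutation_rate:
                        i = pos - 1
                        seq[i] = rng.choice(alphabet[alphabet != seq[i]])
            sid = f"{archetype.lower()}_{counter:03d}"
            counter += 1
            records.append(SequenceRecord(sid, "".join(seq)))
            rows.append({"id": sid, "archetype": archetype,
                         "expected_label": _EXPECTED_LABEL[archetype],
                         "res79": seq[78], "res80": seq[79],
                         "res192": seq[191]})
    truth = pd.DataFrame(rows)
    return reference, records, truth


def write_fasta(records: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


# ---------------------------------------------------------------------------
# parameter-range presets for the Monte-Carlo scenario grid
# ---------------------------------------------------------------------------

# Literature-plausible stand-in ranges (mM, h); log scale wherever the
# plausible span exceeds one order of magnitude.
_SHARED_RANGES = [
    ParameterRange("ddc.vmax", 1.0, 100.0, "log"),
    ParameterRange("ddc.km", 0.01, 1.0, "log"),
    ParameterRange("k_cond", 0.01, 1.0, "log"),
    ParameterRange("feed_rate", 0.5, 4.0, "linear"),
]
_FEEDBACK_RANGES = {
    "ddc": [ParameterRange("ddc.ki.dopamine", 0.01, 1.0, "log")],
    "mao": [ParameterRange("mao.ki.dhpaa", 0.01, 1.0, "log")],
    "dhpaas": [ParameterRange("dhpaas.ki.dopamine", 0.01, 1.0, "log"),
               ParameterRange("dhpaas.ki.dhpaa", 0.01, 1.0, "log")],
}
_DRAIN_RANGE = ParameterRange("k_drain", 0.1, 10.0, "log")


def _base_spec(topology: Topology, drain: bool, feedback: bool) -> PathwaySpec:
    ddc = EnzymeParams(vmax=10.0, km=0.1, ki={"dopamine": 0.1})
    if topology is Topology.MAO_PATH:
        return PathwaySpec(
            topology=topology, ddc=ddc,
            mao=EnzymeParams(vmax=0.5, km=0.2,
                             ki={"amine": 0.1, "dhpaa": 0.1}),
            k_cond=0.1, k_drain=1.0 if drain else 0.0,
            feed_rate=2.0, feedback=feedback, amine_pool=20.0)
    return PathwaySpec(
        topology=topology, ddc=ddc,
        dhpaas=EnzymeParams(vmax=10.0, km=0.0417,
                            ki={"dopamine": 0.1, "dhpaa": 0.1}),
        phi_aldehyde=0.95, k_cond=0.1, k_drain=1.0 if drain else 0.0,
        feed_rate=2.0, feedback=feedback)


scenario_base_spec = _base_spec


def gen_default_ranges(preset: str) -> dict[str, list[ParameterRange]]:
    """Documented stand-in parameter-range tables, keyed by topology.

    ``"fig2-grid"`` covers Vmax, Km, Ki, k_cond, k_drain and feed_rate for
    both the MAO-mediated and the symmetrical DDC-DHPAAS topology.
    ``"adversarial"`` emits degenerate/extreme ranges that exercise the
    error paths of consuming modules.
    """
    if preset == "fig2-grid":
        # MAO is a membrane-bound flavoenzyme with low heterologous specific
        # activity and broad amine specificity: its Vmax range sits an order
        # of magnitude below the soluble PLP enzymes and it faces a large
        # competing amine pool (see docs/methods.md).
        mao = list(_SHARED_RANGES) + [
            ParameterRange("mao.vmax", 0.05, 5.0, "log"),
            ParameterRange("mao.km", 0.01, 1.0, "log"),
            ParameterRange("mao.ki.amine", 0.01, 1.0, "log"),
        ]
        sym = list(_SHARED_RANGES) + [
            ParameterRange("dhpaas.vmax", 1.0, 100.0, "log"),
            ParameterRange("dhpaas.km", 0.01, 1.0, "log"),
        ]
        return {"MAO_PATH": mao, "DDC_DHPAAS_PATH": sym}
    if preset == "adversarial":
        return {"degenerate": [ParameterRange("k_cond", 1.0, 1.0, "linear")],
                "all_zero_vmax": [ParameterRange("ddc.vmax", 0.0, 0.0, "linear"),
                                  ParameterRange("dhpaas.vmax", 0.0, 0.0, "linear")],
                "extreme_stiff": [ParameterRange("k_cond", 1e3, 1e5, "log"),
                                  ParameterRange("dhpaas.vmax", 1e2, 1e3, "log")]}
    raise ValueError(f"unknown preset {preset!r}")


def fig2_scenario_grid(n_iter: int = 200, t_end: float = 50.0,
                       seed: int = 0) -> list[tuple[str, EnsembleSpec]]:
    """The 8-scenario grid {MAO, DDC-DHPAAS} x {drain on/off} x {feedback on/off}.

    Each scenario shares the stand-in range preset, augmented with the drain
    and feedback-Ki ranges where those mechanisms are enabled.
    """
    presets = gen_default_ranges("fig2-grid")
    scenarios = []
    for topo, key in ((Topology.MAO_PATH, "MAO_PATH"),
                      (Topology.DDC_DHPAAS_PATH, "DDC_DHPAAS_PATH")):
        for drain in (False, True):
            for feedback in (False, True):
                ranges = list(presets[key])
                if drain:
                    ranges.append(_DRAIN_RANGE)
                if feedback:
                    ranges += _FEEDBACK_RANGES["ddc"]
                    if topo is Topology.MAO_PATH:
                        ranges += _FEEDBACK_RANGES["mao"]
                    else:
                        ranges += _FEEDBACK_RANGES["dhpaas"]
                label = "{}|drain={}|feedback={}".format(
                    "MAO" if topo is Topology.MAO_PATH else "DDC-DHPAAS",
                    "on" if drain else "off", "on" if feedback else "off")
                base = _base_spec(topo, drain, feedback)
                scenarios.append((label, EnsembleSpec(
                    base=base, ranges=ranges, n_iter=n_iter,
                    t_end=t_end, seed=seed)))
    return scenarios
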