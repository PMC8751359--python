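"""Mass-action model of the full KaiABC phosphorylation/sequestration cycle.

Nine species: free KaiA (``A``), free KaiC in four phosphoforms (``U``,
``T``, ``ST``, ``S``) and, for the two S431-phosphorylated forms, the
KaiB-bound (``BST``, ``BS``) and KaiA-sequestering (``ABST``, ``ABS``)
binding classes.  KaiB is treated as non-limiting and enters implicitly
through pseudo-first-order binding (an explicit-KaiB variant is a config
switch on :func:`build_network`).

The reaction cycle: free KaiA catalyses U -> T phosphorylation; T slowly
autophosphorylates on the second site (T -> ST); KaiB captures
S431-phosphorylated KaiC (ST, S -> BST, BS); KaiBC complexes sequester free
KaiA (BST, BS + A -> ABST, ABS); dephosphorylation proceeds within every
binding class and full dephosphorylation releases KaiB and any sequestered
KaiA back to the free pools.

Rate defaults are *calibrated* values (not measurements): they were fitted
so the baseline limit cycle has a circadian period with a phosphorylation
(rising) phase near 9.5 h, and are frozen here; ``scripts/calibrate_detailed.py``
reproduces the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .simulate import IntegrationError, Trajectory

__all__ = [
    "SPECIES",
    "DetailedParams",
    "Reaction",
    "ReactionNetwork",
    "build_network",
    "rhs_detailed",
    "simulate_detailed",
    "gillespie",
    "atp_scaling",
    "phospho_fraction",
]

SPECIES: Tuple[str, ...] = (
    "A", "U", "T", "ST", "S", "BST", "BS", "ABST", "ABS",
)

#: scale applied to KaiB-KaiC association for the weak-binding mutant
CI_MUTANT_FACTOR = 1e-3


@dataclass(frozen=True)
class DetailedParams:
    """Rates (h^-1; bimolecular a.u.^-1 h^-1) and totals of the cycle.

    ``atp_ratio`` multiplies the KaiA-stimulated phosphorylation rate (the
    simplest mass-action entry point for nucleotide dependence);
    ``ci_mutant`` weakens KaiB-KaiC association by 1e-3.
    """

    k_phos_UT: float = 0.16451   # KaiA-catalysed U -> T (bimolecular in A)
    k_dephos_TU: float = 0.05437  # T -> U
    k_phos_TST: float = 0.02700  # T -> ST (slow second-site)
    k_dephos_T2: float = 0.07298  # second-site dephos (ST -> S, in all classes)
    k_dephos_S: float = 0.11220  # free S -> U
    k_bind_B: float = 0.32810    # KaiB capture of S431-phosphorylated KaiC
    k_release: float = 0.25683   # full dephos of KaiB-bound KaiC (-> U)
    k_seq: float = 10.0          # KaiA sequestration by KaiBC complexes
    A_T: float = 12.12355
    C_T: float = 100.0
    B_T: Optional[float] = None  # None -> KaiB non-limiting (implicit)
    atp_ratio: float = 1.0
    ci_mutant: bool = False

    def __post_init__(self) -> None:
        for name in ("k_phos_UT", "k_dephos_TU", "k_phos_TST", "k_dephos_T2",
                     "k_dephos_S", "k_bind_B", "k_release", "k_seq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.A_T > 0 and self.C_T > 0):
            raise ValueError("A_T and C_T must be > 0")
        if not 0 < self.atp_ratio <= 1:
            raise ValueError("atp_ratio must be in (0, 1]")

    def to_vector(self) -> np.ndarray:
        kB = self.k_bind_B * (CI_MUTANT_FACTOR if self.ci_mutant else 1.0)
        return np.array([
            self.k_phos_UT, self.k_dephos_TU, self.k_phos_TST,
            self.k_dephos_T2, self.k_dephos_S, kB, self.k_release,
            self.k_seq, self.atp_ratio,
        ])

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(len(SPECIES))
        y0[0] = self.A_T
        y0[1] = self.C_T
        return y0


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction (order <= 2)."""

    reactants: Tuple[str, ...]
    products: Tuple[str, ...]
    rate_constant: float
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.reactants) > 2:
            raise ValueError("mass-action order must be <= 2")
        if self.rate_constant < 0:
            raise ValueError("rate_constant must be >= 0")


@dataclass
class ReactionNetwork:
    """Species list plus reactions, with packed arrays for the kernels."""

    species: Sequence[str]
    reactions: List[Reaction]

    def __post_init__(self) -> None:
        index = {s: i for i, s in enumerate(self.species)}
        n_rxn, n_sp = len(self.reactions), len(self.species)
        self.net = np.zeros((n_rxn, n_sp), dtype=np.int64)
        self.r1 = np.full(n_rxn, -1, dtype=np.int64)
        self.r2 = np.full(n_rxn, -1, dtype=np.int64)
        self.rates = np.empty(n_rxn)
        for k, rxn in enumerate(self.reactions):
            for s in rxn.reactants:
                self.net[k, index[s]] -= 1
            for s in rxn.products:
                self.net[k, index[s]] += 1
            if rxn.reactants:
                self.r1[k] = index[rxn.reactants[0]]
            if len(rxn.reactants) == 2:
                self.r2[k] = index[rxn.reactants[1]]
            self.rates[k] = rxn.rate_constant

    def packed(self) -> np.ndarray:
        return _kernels.pack_network(self.r1, self.r2, self.rates, self.net)

    def rhs(self, t, y) -> np.ndarray:
        """Plain mass-action derivative (usable with scipy solvers)."""
        y = np.asarray(y, dtype=float)
        v = self.rates.copy()
        m1 = self.r1 >= 0
        v[m1] *= y[self.r1[m1]]
        m2 = self.r2 >= 0
        v[m2] *= y[self.r2[m2]]
        return v @ self.net

    def conserved_totals(self, y) -> dict:
        y = np.asarray(y, dtype=float)
        idx = {s: i for i, s in enumerate(self.species)}
        kaiC = [s for s in self.species if s != "A"]
        out = {"KaiC": float(sum(y[idx[s]] for s in kaiC))}
        if "A" in idx:
            seq = [s for s in self.species if s.startswith("AB")]
            out["KaiA"] = float(y[idx["A"]] + sum(y[idx[s]] for s in seq))
        return out

    def export_flat(self, path) -> None:
        """Write a flat-text description (species + reactions)."""
        with open(path, "w") as fh:
            fh.write("# species\n")
            for s in self.species:
                fh.write(f"species {s}\n")
            fh.write("# reactions (reactants -> products @ rate)\n")
            for rxn in self.reactions:
                lhs = " + ".join(rxn.reactants) or "0"
                rhs = " + ".join(rxn.products) or "0"
                fh.write(f"reaction {lhs} -> {rhs} @ {rxn.rate_constant!r}"
                         f" # {rxn.label}\n")


def build_network(p: DetailedParams) -> ReactionNetwork:
    """Reaction list for the full cycle (KaiB implicit unless B_T is set)."""
    kB = p.k_bind_B * (CI_MUTANT_FACTOR if p.ci_mutant else 1.0)
    kUT = p.k_phos_UT * p.atp_ratio
    rxns = [
        Reaction(("A", "U"), ("A", "T"), kUT, "KaiA-catalysed T-site phosphorylation"),
        Reaction(("T",), ("U",), p.k_dephos_TU, "T-site dephosphorylation"),
        Reaction(("T",), ("ST",), p.k_phos_TST, "slow S-site phosphorylation"),
        Reaction(("ST",), ("S",), p.k_dephos_T2, "T-site dephosphorylation of ST"),
        Reaction(("S",), ("U",), p.k_dephos_S, "S-site dephosphorylation"),
        Reaction(("BST",), ("BS",), p.k_dephos_T2, "T-site dephosphorylation in KaiBC"),
        Reaction(("ABST",), ("ABS",), p.k_dephos_T2,
                 "T-site dephosphorylation in KaiABC"),
        Reaction(("BS",), ("U",), p.k_release, "full dephosphorylation releases KaiB"),
        Reaction(("ABS",), ("U", "A"), p.k_release,
                 "full dephosphorylation releases KaiB and sequestered KaiA"),
        Reaction(("A", "BST"), ("ABST",), p.k_seq, "KaiBC sequesters free KaiA"),
        Reaction(("A", "BS"), ("ABS",), p.k_seq, "KaiBC sequesters free KaiA"),
    ]
    if p.B_T is None:
        rxns += [
            Reaction(("ST",), ("BST",), kB, "KaiB capture of ST (KaiB implicit)"),
            Reaction(("S",), ("BS",), kB, "KaiB capture of S (KaiB implicit)"),
        ]
        species = list(SPECIES)
    else:
        rxns += [
            Reaction(("B", "ST"), ("BST",), kB, "KaiB capture of ST"),
            Reaction(("B", "S"), ("BS",), kB, "KaiB capture of S"),
            Reaction(("BS",), (), 0.0, "placeholder"),  # replaced below
        ]
        # explicit KaiB: release reactions must return B
        rxns = [r for r in rxns if r.label != "placeholder"]
        rxns = [
            Reaction(("BS",), ("U", "B"), p.k_release,
                     "full dephosphorylation releases KaiB")
            if r.label == "full dephosphorylation releases KaiB" else r
            for r in rxns
        ]
        rxns = [
            Reaction(("ABS",), ("U", "A", "B"), p.k_release,
                     "full dephosphorylation releases KaiB and sequestered KaiA")
            if r.label == "full dephosphorylation releases KaiB and sequestered KaiA"
            else r
            for r in rxns
        ]
        species = list(SPECIES) + ["B"]
    return ReactionNetwork(species=species, reactions=rxns)


def rhs_detailed(t, y, network: ReactionNetwork) -> np.ndarray:
    """Mass-action derivative for a state matching `network.species`."""
    y = np.asarray(y, dtype=float)
    if y.size != len(network.species):
        raise ValueError(
            f"state dimension {y.size} != {len(network.species)} species"
        )
    return network.rhs(t, y)


def atp_scaling(p: DetailedParams, atp_ratio: float) -> DetailedParams:
    """Params with the KaiA-stimulated phosphorylation scaled by atp_ratio."""
    if not 0 < atp_ratio <= 1:
        raise ValueError("atp_ratio must be in (0, 1]")
    return replace(p, atp_ratio=atp_ratio)


def simulate_detailed(p: DetailedParams, t_end: float = 720.0,
                      dt: float = 0.1, y0: Optional[np.ndarray] = None,
                      rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Deterministic trajectory on a uniform grid (compiled fast path)."""
    if y0 is None:
        y0 = p.initial_state()
    tgrid = np.arange(0.0, t_end + dt / 2, dt)
    Y, ok = _kernels.integrate_grid(_kernels.rhs_detailed, p.to_vector(),
                                    np.asarray(y0, float), tgrid, rtol, atol,
                                    50_000_000)
    if not ok:
        raise IntegrationError("detailed-model integration failed")
    return Trajectory(tgrid, Y, SPECIES)


def phospho_fraction(traj: Trajectory, C_T: Optional[float] = None) -> np.ndarray:
    """Fraction of KaiC with at least one site phosphorylated, in [0, 1]."""
    names = list(traj.names)
    phospho = [s for s in names if s not in ("A", "U", "B")]
    total = [s for s in names if s not in ("A", "B")]
    num = sum(traj.series(s) for s in phospho)
    den = C_T if C_T is not None else sum(traj.series(s) for s in total)
    return num / den


def gillespie(network: ReactionNetwork, init_counts, t_end: float,
              seed: int, omega: float = 1.0, dt: float = 0.1) -> Trajectory:
    """Exact SSA sample path (direct method), recorded on a uniform grid.

    `init_counts` are integer molecule counts; `omega` converts
    concentrations to counts (bimolecular propensities scale as 1/omega).
    Identical seeds give identical paths.
    """
    if not network.reactions:
        raise ValueError("empty reaction network")
    x0 = np.asarray(init_counts, dtype=np.int64)
    if x0.size != len(network.species):
        raise ValueError("init_counts dimension mismatch")
    if np.any(x0 < 0):
        raise ValueError("counts must be >= 0")
    tgrid = np.arange(0.0, t_end + dt / 2, dt)
    X = _kernels.gillespie_direct(network.r1, network.r2, network.rates,
                                  network.net, x0, tgrid, float(omega),
                                  int(seed))
    return Trajectory(tgrid, X.astype(float), network.species)
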