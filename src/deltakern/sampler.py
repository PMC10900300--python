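"""Reservoir-Hamiltonian replica-exchange Monte Carlo.

Replicas sample lambda-mixed potentials V = (1 - lambda) V_target +
lambda V_baseline at a single temperature; lambda = 0 is the production
(target) stream.  Moves are global Gaussian Cartesian displacements with
Metropolis acceptance; adjacent replicas attempt exchanges on a fixed
stride with the standard Hamiltonian-RE criterion.  The lambda = 1 slot
may be replaced by a canonical reservoir: an infinite bath of baseline
samples from which a fresh uniform draw replaces the MC move.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .constants import KB_KCAL_MOL_K
from .structures import Ensemble, Structure, write_extxyz

__all__ = [
    "Potential",
    "CallablePotential",
    "DeltaCorrectedPotential",
    "MixedHamiltonian",
    "ReplicaLadder",
    "MCConfig",
    "MCTrajectory",
    "mixed_energy",
    "mc_move",
    "metropolis_accept",
    "exchange_accept",
    "run_resh_re",
    "run_metropolis",
    "remd_temperature_ladder",
]


@runtime_checkable
class Potential(Protocol):
    """Energy backend contract: deterministic, finite on valid structures."""

    name: str

    def evaluate(self, structure: Structure) -> float: ...


@dataclass
class CallablePotential:
    """Adapter wrapping any ``structure -> kcal/mol`` callable."""

    func: object
    name: str = "callable"

    def evaluate(self, structure: Structure) -> float:
        return float(self.func(structure))


@dataclass
class DeltaCorrectedPotential:
    """Baseline potential plus a trained LKR correction (the target level)."""

    baseline: Potential
    model: object  # DeltaModel
    name: str = "baseline+lkr"

    def evaluate(self, structure: Structure) -> float:
        return self.baseline.evaluate(structure) + self.model.predict(structure)[0]

    def correction(self, structure: Structure) -> float:
        return self.model.predict(structure)[0]


@dataclass
class MixedHamiltonian:
    """V = (1 - lambda) V_target + lambda V_baseline, lambda in [0, 1]."""

    lam: float
    v_target: Potential
    v_baseline: Potential

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")

    def evaluate(self, structure: Structure) -> float:
        if self.lam == 0.0:
            e = self.v_target.evaluate(structure)
        elif self.lam == 1.0:
            e = self.v_baseline.evaluate(structure)
        elif (
            isinstance(self.v_target, DeltaCorrectedPotential)
            and self.v_target.baseline is self.v_baseline
        ):
            # shared baseline: evaluate it once, scale only the correction
            e = self.v_baseline.evaluate(structure) + (
                1.0 - self.lam
            ) * self.v_target.correction(structure)
        else:
            e = (1.0 - self.lam) * self.v_target.evaluate(structure) + (
                self.lam
            ) * self.v_baseline.evaluate(structure)
        if not math.isfinite(e):
            raise RuntimeError(
                f"non-finite energy {e} from mixed Hamiltonian at lambda={self.lam}"
            )
        return e


def mixed_energy(h: MixedHamiltonian, structure: Structure) -> float:
    return h.evaluate(structure)


@dataclass
class ReplicaLadder:
    """Lambda schedule (default six values linear on [0, 1]) at one T (K)."""

    lambdas: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    temperature: float = 300.0
    reservoir: Ensemble | None = None

    def __post_init__(self) -> None:
        lams = tuple(float(x) for x in self.lambdas)
        if lams[0] != 0.0 or lams[-1] != 1.0:
            raise ValueError("lambda ladder must start at 0 and end at 1")
        if any(b <= a for a, b in zip(lams, lams[1:])):
            raise ValueError("lambda ladder must be strictly increasing")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.reservoir is not None:
            if len(self.reservoir) == 0:
                raise ValueError("attached reservoir is empty")
            self.reservoir.require_uniform()
        self.lambdas = lams

    @classmethod
    def linear(cls, n: int = 6, temperature: float = 300.0, reservoir=None):
        return cls(tuple(np.linspace(0.0, 1.0, n)), temperature, reservoir)

    @property
    def n_replicas(self) -> int:
        return len(self.lambdas)


@dataclass
class MCConfig:
    """Monte Carlo schedule.

    ``n_steps`` counts per-replica move attempts; exchange sweeps every
    ``exchange_stride`` steps are extra events.  ``step_sigma`` is the sd
    (Angstrom) of the global Gaussian displacement applied to every
    Cartesian coordinate.  The default 0.001 A matches molecular systems
    sampled near 300 K; toy potentials want larger steps.
    """

    n_steps: int = 20_000_000
    exchange_stride: int = 20
    step_sigma: float = 0.001
    seed: int = 0
    temperature: float = 300.0
    snapshot_stride: int = 100
    tune_step: bool = False  # optional 50%-acceptance tuning, off by default

    def __post_init__(self) -> None:
        if min(self.n_steps, self.exchange_stride, self.snapshot_stride) < 1:
            raise ValueError("strides and step counts must be positive")
        if self.step_sigma <= 0 or self.temperature <= 0:
            raise ValueError("step_sigma and temperature must be positive")

    @property
    def beta(self) -> float:
        return 1.0 / (KB_KCAL_MOL_K * self.temperature)


@dataclass
class MCTrajectory:
    """Per-replica snapshot/energy streams plus acceptance bookkeeping."""

    lambdas: tuple[float, ...]
    temperature: float
    seed: int
    snapshot_steps: list[int] = field(default_factory=list)
    snapshots: list[list[np.ndarray]] = field(default_factory=list)
    energies: list[list[float]] = field(default_factory=list)
    move_attempts: np.ndarray | None = None
    move_accepts: np.ndarray | None = None
    exchange_attempts: np.ndarray | None = None
    exchange_accepts: np.ndarray | None = None
    reservoir_draws: int = 0
    elements: tuple[str, ...] = ()

    def move_acceptance(self, replica: int) -> float:
        if self.move_attempts is None or self.move_attempts[replica] == 0:
            return float("nan")
        return self.move_accepts[replica] / self.move_attempts[replica]

    def exchange_acceptance(self, pair: int | None = None) -> float:
        att = self.exchange_attempts
        acc = self.exchange_accepts
        if pair is not None:
            att, acc = att[pair : pair + 1], acc[pair : pair + 1]
        total = att.sum()
        return float(acc.sum() / total) if total else float("nan")

    def lambda0_coords(self) -> list[np.ndarray]:
        """Production-stream snapshots (the lambda = 0 replica)."""
        return self.snapshots[0]

    def lambda0_ensemble(self) -> Ensemble:
        structs = [
            Structure(self.elements, c.copy(), {"step": s})
            for s, c in zip(self.snapshot_steps, self.snapshots[0])
        ]
        return Ensemble.from_structures(structs)

    def write(self, directory) -> None:
        """Per-replica extended-XYZ streams + a whitespace log + manifest."""
        import os

        os.makedirs(directory, exist_ok=True)
        for r in range(len(self.lambdas)):
            structs = [
                Structure(self.elements, c.copy(), {"step": s})
                for s, c in zip(self.snapshot_steps, self.snapshots[r])
            ]
            ens = Ensemble.from_structures(
                structs, e_baseline=self.energies[r]
            )
            write_extxyz(
                ens, os.path.join(directory, f"replica_{r}.extxyz"),
                energy_keys=("energy", "unused"),
            )
        with open(os.path.join(directory, "energies.log"), "w") as fh:
            fh.write("# step " + " ".join(f"E_lam{l:g}" for l in self.lambdas) + "\n")
            for k, step in enumerate(self.snapshot_steps):
                row = " ".join(f"{self.energies[r][k]:.10g}" for r in range(len(self.lambdas)))
                fh.write(f"{step} {row}\n")
        manifest = {
            "lambdas": list(self.lambdas),
            "temperature": self.temperature,
            "seed": self.seed,
            "move_acceptance": [
                self.move_acceptance(r) for r in range(len(self.lambdas))
            ],
            "exchange_acceptance": self.exchange_acceptance()
            if self.exchange_attempts is not None
            else None,
            "reservoir_draws": self.reservoir_draws,
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)


def _bare_structure(elements: tuple[str, ...], coords: np.ndarray) -> Structure:
    """Unvalidated Structure for sampler hot loops (inputs already checked)."""
    s = object.__new__(Structure)
    s.elements = elements
    s.coords = coords
    s.tags = {}
    return s


def mc_move(structure: Structure, config: MCConfig, rng: np.random.Generator) -> Structure:
    """Global Gaussian displacement: every coordinate gets N(0, step_sigma^2)."""
    disp = rng.normal(0.0, config.step_sigma, size=structure.coords.shape)
    return Structure(structure.elements, structure.coords + disp, dict(structure.tags))


def metropolis_accept(delta_e: float, beta: float, rng: np.random.Generator) -> bool:
    """Standard Metropolis criterion min(1, exp(-beta dE))."""
    if delta_e <= 0.0:
        return True
    return rng.random() < math.exp(-beta * delta_e)


def exchange_accept(
    e_i_xi: float,
    e_j_xj: float,
    e_i_xj: float,
    e_j_xi: float,
    beta: float,
    rng: np.random.Generator,
) -> bool:
    """Hamiltonian-RE swap criterion for two replicas at one temperature."""
    delta = (e_i_xj + e_j_xi) - (e_i_xi + e_j_xj)
    return metropolis_accept(delta, beta, rng)


def remd_temperature_ladder(
    n: int = 8, t_min: float = 300.0, t_max: float = 800.0
) -> np.ndarray:
    """Log-spaced temperature ladder T_i = t_min (t_max/t_min)^(i/(n-1)).

    Documents the schedule used to *generate* baseline reservoirs by
    temperature REMD; reservoir generation itself is outside this package
    (reservoirs are read from file or built from fixture potentials).
    """
    return t_min * (t_max / t_min) ** (np.arange(n) / (n - 1))


def run_metropolis(
    potential: Potential,
    config: MCConfig,
    initial: Structure,
    rng: np.random.Generator | None = None,
) -> MCTrajectory:
    """Plain single-chain Metropolis on one potential (reference sampler)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    current = initial.copy()
    e_cur = float(potential.evaluate(current))
    traj = MCTrajectory((0.0,), config.temperature, config.seed,
                        elements=current.elements)
    traj.snapshots = [[]]
    traj.energies = [[]]
    traj.move_attempts = np.zeros(1, dtype=np.int64)
    traj.move_accepts = np.zeros(1, dtype=np.int64)
    traj.exchange_attempts = np.zeros(0, dtype=np.int64)
    traj.exchange_accepts = np.zeros(0, dtype=np.int64)
    beta = config.beta
    sigma = config.step_sigma
    shape = current.coords.shape
    for step in range(1, config.n_steps + 1):
        disp = rng.normal(0.0, sigma, size=shape)
        trial = _bare_structure(current.elements, current.coords + disp)
        e_new = float(potential.evaluate(trial))
        traj.move_attempts[0] += 1
        if metropolis_accept(e_new - e_cur, beta, rng):
            current, e_cur = trial, e_new
            traj.move_accepts[0] += 1
        if step % config.snapshot_stride == 0:
            traj.snapshot_steps.append(step)
            traj.snapshots[0].append(current.coords.copy())
            traj.energies[0].append(e_cur)
    return traj


def run_resh_re(
    ladder: ReplicaLadder,
    config: MCConfig,
    initial: Structure,
    v_target: Potential,
    v_baseline: Potential,
) -> MCTrajectory:
    """Reservoir-Hamiltonian replica-exchange Monte Carlo.

    All replicas start from ``initial`` (the reservoir slot from a fresh
    reservoir draw).  Per-replica RNG streams are spawned from the master
    seed, so runs are bit-reproducible; exchange sweeps alternate
    even/odd nearest-neighbour pairs every ``exchange_stride`` steps.
    """
    n_rep = ladder.n_replicas
    hams = [MixedHamiltonian(l, v_target, v_baseline) for l in ladder.lambdas]
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(n_rep + 1)]
    ex_rng = streams[-1]

    has_reservoir = ladder.reservoir is not None
    res_slot = n_rep - 1 if has_reservoir else -1
    if has_reservoir:
        res_coords = [r.structure.coords for r in ladder.reservoir]
        res_energy = [
            r.e_baseline
            if r.e_baseline is not None
            else v_baseline.evaluate(r.structure)
            for r in ladder.reservoir
        ]

    states = [initial.copy() for _ in range(n_rep)]
    energies = np.empty(n_rep)
    for r in range(n_rep):
        if r == res_slot:
            k = int(streams[r].integers(len(res_coords)))
            states[r] = _bare_structure(initial.elements, res_coords[k].copy())
            energies[r] = res_energy[k]
            continue
        energies[r] = hams[r].evaluate(states[r])

    traj = MCTrajectory(ladder.lambdas, ladder.temperature, config.seed,
                        elements=initial.elements)
    traj.snapshots = [[] for _ in range(n_rep)]
    traj.energies = [[] for _ in range(n_rep)]
    traj.move_attempts = np.zeros(n_rep, dtype=np.int64)
    traj.move_accepts = np.zeros(n_rep, dtype=np.int64)
    traj.exchange_attempts = np.zeros(max(n_rep - 1, 0), dtype=np.int64)
    traj.exchange_accepts = np.zeros(max(n_rep - 1, 0), dtype=np.int64)

    beta = config.beta
    sigma = config.step_sigma
    shape = initial.coords.shape
    elements = initial.elements
    exchange_stride = config.exchange_stride
    snapshot_stride = config.snapshot_stride
    sweep = 0

    for step in range(1, config.n_steps + 1):
        for r in range(n_rep):
            rng = streams[r]
            if r == res_slot:
                k = int(rng.integers(len(res_coords)))
                states[r] = _bare_structure(elements, res_coords[k].copy())
                energies[r] = res_energy[k]
                traj.reservoir_draws += 1
                continue
            disp = rng.normal(0.0, sigma, size=shape)
            trial = _bare_structure(elements, states[r].coords + disp)
            e_new = hams[r].evaluate(trial)
            traj.move_attempts[r] += 1
            if metropolis_accept(e_new - energies[r], beta, rng):
                states[r] = trial
                energies[r] = e_new
                traj.move_accepts[r] += 1
        if exchange_stride and step % exchange_stride == 0:
            start = sweep % 2
            sweep += 1
            for i in range(start, n_rep - 1, 2):
                j = i + 1
                e_i_xj = hams[i].evaluate(states[j])
                e_j_xi = hams[j].evaluate(states[i])
                traj.exchange_attempts[i] += 1
                if exchange_accept(
                    energies[i], energies[j], e_i_xj, e_j_xi, beta, ex_rng
                ):
                    states[i], states[j] = states[j], states[i]
                    energies[i], energies[j] = e_i_xj, e_j_xi
                    traj.exchange_accepts[i] += 1
        if step % snapshot_stride == 0:
            traj.snapshot_steps.append(step)
            for r in range(n_rep):
                traj.snapshots[r].append(states[r].coords.copy())
                traj.energies[r].append(float(energies[r]))
    return traj
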