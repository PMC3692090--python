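"""Eligibility pre-check and steepest-descent minimization.

Protocol defaults: at most 1500 steps, maximum-force convergence threshold
1.0 kJ/mol/nm, nonbonded cutoff 1.4 nm, in vacuo.  "Maximum force" is the
largest Euclidean norm of any per-atom force vector.  The step rule is
GROMACS-style: step along F / max|F|, grow the step 1.2x on an accepted
downhill move, halve it and reject on an uphill one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MinimizationInputError
from .forcefield import Topology, energy_forces
from .registry import Registry
from .structure import Structure

REASON_NONSTANDARD = "non-standard residues or unique ligands"
REASON_MISSING = "missing atoms or residues"
REASON_FORMATTING = "non-standard formatting of PDB file"
REASON_OTHER = "other"


@dataclass(frozen=True)
class MinimizationConfig:
    max_steps: int = 1500
    fmax: float = 1.0          # kJ/mol/nm
    initial_step: float = 0.01  # nm
    cutoff: float = 1.4        # nm
    step_grow: float = 1.2
    step_shrink: float = 0.5
    step_min: float = 1e-10    # nm; below this the run is flagged stalled

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not self.fmax > 0:
            raise ValueError("fmax must be positive")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")


@dataclass
class MinimizationResult:
    positions: np.ndarray
    converged: bool
    stalled: bool
    steps_used: int
    energy_trace: list[float]
    final_energy: float
    final_fmax: float


@dataclass
class EligibilityReport:
    eligible: bool
    reasons: list[str] = field(default_factory=list)
    details: list[str] = field(default_factory=list)


def check_minimizable(structure: Structure, registry: Registry) -> EligibilityReport:
    """Report every reason the structure cannot be minimized (total function).

    A negative report deactivates minimization downstream but never blocks
    the modification output itself.
    """
    reasons: list[str] = []
    details: list[str] = []
    blocks = registry.residue_blocks
    model = structure.first_model

    if model.het_records:
        names = sorted({h.res_name for h in model.het_records})
        reasons.append(REASON_NONSTANDARD)
        details.append(f"HETATM ligand(s) present: {', '.join(names)}")

    for res in model.residues():
        block = blocks.get(res.name)
        where = f"{res.chain_id}:{res.res_seq}{res.i_code} ({res.name})"
        if block is None:
            if REASON_NONSTANDARD not in reasons:
                reasons.append(REASON_NONSTANDARD)
            details.append(f"no building block for residue {where}")
            continue
        present = set(res.atom_names())
        expected = set(block.atom_names())
        if expected - present:
            if REASON_MISSING not in reasons:
                reasons.append(REASON_MISSING)
            details.append(
                f"residue {where} missing atom(s) "
                f"{', '.join(sorted(expected - present))}"
            )
        if present - expected:
            if REASON_FORMATTING not in reasons:
                reasons.append(REASON_FORMATTING)
            details.append(
                f"residue {where} has unexpected atom(s) "
                f"{', '.join(sorted(present - expected))}"
            )
    return EligibilityReport(eligible=not reasons, reasons=reasons, details=details)


def _max_force(forces: np.ndarray) -> float:
    if forces.size == 0:
        return 0.0
    return float(np.max(np.linalg.norm(forces, axis=1)))


def steepest_descent(positions: np.ndarray, topology: Topology,
                     config: MinimizationConfig | None = None) -> MinimizationResult:
    """Deterministic adaptive steepest descent.

    ``steps_used`` counts every iteration, accepted or rejected; the energy
    trace records the starting energy and each accepted step, so it is
    non-increasing by construction.
    """
    if config is None:
        config = MinimizationConfig()
    x = np.array(positions, dtype=float)
    ef = energy_forces(x, topology, cutoff=config.cutoff)
    if not np.isfinite(ef.total):
        raise MinimizationInputError("non-finite energy at starting configuration")

    energy = ef.total
    fmax = _max_force(ef.forces)
    trace = [energy]
    step = config.initial_step
    steps_used = 0
    converged = fmax <= config.fmax
    stalled = False

    while not converged and steps_used < config.max_steps:
        steps_used += 1
        trial = x + step * ef.forces / fmax
        try:
            ef_trial = energy_forces(trial, topology, cutoff=config.cutoff)
            trial_ok = np.isfinite(ef_trial.total)
        except Exception:
            trial_ok = False
        if trial_ok and ef_trial.total < energy:
            x = trial
            ef = ef_trial
            energy = ef_trial.total
            fmax = _max_force(ef.forces)
            trace.append(energy)
            step *= config.step_grow
            if fmax <= config.fmax:
                converged = True
        else:
            step *= config.step_shrink
            if step < config.step_min:
                stalled = True
                break

    return MinimizationResult(
        positions=x,
        converged=converged,
        stalled=stalled,
        steps_used=steps_used,
        energy_trace=trace,
        final_energy=energy,
        final_fmax=fmax,
    )


def format_mdp(config: MinimizationConfig) -> str:
    """Echo of the effective minimization settings, .mdp style."""
    return (
        "; steepest-descent minimization settings (in vacuo, no PBC)\n"
        "integrator      = steep\n"
        f"nsteps          = {config.max_steps}\n"
        f"emtol           = {config.fmax}\n"
        f"emstep          = {config.initial_step}\n"
        f"rvdw            = {config.cutoff}\n"
        f"rcoulomb        = {config.cutoff}\n"
        "pbc             = no\n"
    )
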