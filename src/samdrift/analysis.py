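"""Measurement layer: conservation times, functional-network pruning,
interaction importance, network divergence and robustness assays.

All analyses operate on the type-level interaction sets of an ancestral
lineage (conservation, divergence) or on a single genome re-developed on
tissue templates (pruning, importance, robustness).  Divergence compares
Boolean adjacency matrices — the most conservative, purely qualitative
network comparison — as the mean of the normalized element-wise
differences of the activating and inhibiting presence matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import DevConfig, FitnessConfig, MutationRates, GenomeConfig, \
    N_TF_TYPES, child_seed
from .develop import develop
from .fitness import total_fitness
from .genome import (Genome, Interaction, delete_interaction, genome_to_grn,
                     interaction_counts, mutate)
from .tissue import Tissue

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Conservation along an ancestral trace
# ---------------------------------------------------------------------------

@dataclass
class ConservationRecord:
    interaction: Interaction
    #: maximal runs of consecutive presence, as (start_gen, end_gen) inclusive
    intervals: list[tuple[int, int]]

    @property
    def max_duration(self) -> int:
        """Longest run, in generations (inclusive count)."""
        return max(e - s + 1 for s, e in self.intervals)


def conservation_times(interaction_sets: list[frozenset[Interaction]]
                       ) -> list[ConservationRecord]:
    """Maximal runs of consecutive presence of each type-level interaction
    along a trace (one interaction set per generation).  A single
    generation of absence resets the run."""
    if not interaction_sets:
        return []
    records: dict[Interaction, ConservationRecord] = {}
    open_runs: dict[Interaction, int] = {}
    for g, current in enumerate(interaction_sets):
        for ia in list(open_runs):
            if ia not in current:
                start = open_runs.pop(ia)
                records[ia].intervals.append((start, g - 1))
        for ia in current:
            if ia not in open_runs:
                open_runs[ia] = g
                records.setdefault(ia, ConservationRecord(ia, []))
    last = len(interaction_sets) - 1
    for ia, start in open_runs.items():
        records[ia].intervals.append((start, last))
    return list(records.values())


def conserved_set(interaction_sets: list[frozenset[Interaction]],
                  cutoff: int = 5000) -> frozenset[Interaction]:
    """Interactions with at least one presence run exceeding ``cutoff``
    generations (the conservation cutoff; at full scale the study value is
    5000 generations, chosen below the control maximum)."""
    return frozenset(r.interaction for r in conservation_times(interaction_sets)
                     if r.max_duration > cutoff)


# ---------------------------------------------------------------------------
# Fitness evaluation helpers
# ---------------------------------------------------------------------------

def mean_fitness(genome: Genome, tissues: list[Tissue], dev_config: DevConfig,
                 rng: np.random.Generator, n_reps: int = 5,
                 fitness_config: FitnessConfig | None = None) -> float:
    """Mean fitness over replicate developments (templates drawn from the
    pool, independent noise realizations)."""
    total = 0.0
    for _ in range(n_reps):
        tissue = tissues[int(rng.integers(0, len(tissues)))]
        traj = develop(genome, tissue, dev_config, seed=child_seed(rng))
        total += total_fitness(traj, tissue, fitness_config).F
    return total / n_reps


# ---------------------------------------------------------------------------
# Functional-network pruning
# ---------------------------------------------------------------------------

def prune(genome: Genome, tissues: list[Tissue], dev_config: DevConfig,
          rng: np.random.Generator, n_reps: int = 5, threshold: float = 5.0,
          fitness_config: FitnessConfig | None = None,
          reference_fitness: float | None = None
          ) -> tuple[Genome, frozenset[Interaction]]:
    """Greedy reduction to the functional network.

    Every single-element deletion is evaluated (mean fitness over
    ``n_reps`` developments); the deletion with the highest mean fitness
    is accepted if that fitness stays within ``threshold`` points of the
    original fitness; iterate until no deletion qualifies.  Ties break
    toward the earliest genome position."""
    f0 = reference_fitness
    if f0 is None:
        f0 = mean_fitness(genome, tissues, dev_config, rng, n_reps,
                          fitness_config)
    current = genome.copy()
    while len(current) > 0:
        best_pos, best_f = -1, -np.inf
        for pos in range(len(current)):
            cand = current.copy()
            del cand.elements[pos]
            f = mean_fitness(cand, tissues, dev_config, rng, n_reps,
                             fitness_config)
            if f > best_f + 1e-12:  # strict improvement; ties keep earliest
                best_pos, best_f = pos, f
        if best_pos < 0 or abs(best_f - f0) > threshold:
            break
        del current.elements[best_pos]
        log.debug("pruned element %d, fitness %.3f (reference %.3f)",
                  best_pos, best_f, f0)
    return current, genome_to_grn(current)


# ---------------------------------------------------------------------------
# Importance
# ---------------------------------------------------------------------------

def importance(genome: Genome, interaction: Interaction,
               tissues: list[Tissue], dev_config: DevConfig,
               rng: np.random.Generator, n_reps: int = 500,
               fitness_config: FitnessConfig | None = None,
               reference_fitness: float | None = None,
               clamp: bool = True) -> float:
    """Fraction of fitness lost when an interaction is removed:
    I = (1/R) sum_r (F0 - F_r) / F0 over R replicate developments.

    Removal deletes every TFBS copy realizing the (regulator, target,
    sign) triple.  1 means total loss of fitness, 0 no change.  Negative
    raw values (fitness gains on removal) are clamped for reporting and
    logged."""
    if interaction not in genome_to_grn(genome):
        raise ValueError(f"interaction {interaction} not present in genome")
    f0 = reference_fitness
    if f0 is None:
        f0 = mean_fitness(genome, tissues, dev_config, rng, n_reps,
                          fitness_config)
    if f0 == 0:
        raise ValueError("importance undefined: reference fitness is zero")
    removed = delete_interaction(genome, interaction)
    acc = 0.0
    for _ in range(n_reps):
        tissue = tissues[int(rng.integers(0, len(tissues)))]
        traj = develop(removed, tissue, dev_config, seed=child_seed(rng))
        fr = total_fitness(traj, tissue, fitness_config).F
        acc += (f0 - fr) / f0
    raw = acc / n_reps
    if clamp and not 0.0 <= raw <= 1.0:
        log.info("importance %.4f clamped to [0, 1] for %s", raw, interaction)
        return float(min(max(raw, 0.0), 1.0))
    return float(raw)


# ---------------------------------------------------------------------------
# Divergence
# ---------------------------------------------------------------------------

@dataclass
class BooleanAdjacency:
    """Binary presence matrices, rows = target gene types, columns =
    regulator TF types."""

    activating: np.ndarray
    inhibiting: np.ndarray


def boolean_adjacency(interactions, n_types: int = N_TF_TYPES
                      ) -> BooleanAdjacency:
    act = np.zeros((n_types, n_types), dtype=np.int8)
    inh = np.zeros((n_types, n_types), dtype=np.int8)
    for ia in interactions:
        if ia.sign > 0:
            act[ia.target, ia.regulator] = 1
        else:
            inh[ia.target, ia.regulator] = 1
    return BooleanAdjacency(activating=act, inhibiting=inh)


def _matrix_difference(x: np.ndarray, y: np.ndarray) -> float:
    denom = float((x + y).sum())
    if denom == 0.0:
        return 0.0  # two empty matrices are identical
    return float(np.abs(x - y).sum()) / denom


def divergence(a, b) -> float:
    """Divergence of two interaction sets in [0, 1]: the mean of the
    normalized element-wise differences of their activating and
    inhibiting Boolean adjacency matrices."""
    A = boolean_adjacency(a)
    B = boolean_adjacency(b)
    return 0.5 * (_matrix_difference(A.activating, B.activating)
                  + _matrix_difference(A.inhibiting, B.inhibiting))


def restricted(interactions, allowed) -> frozenset:
    return frozenset(i for i in interactions if i in allowed)


def divergence_series(traces: list[list[frozenset[Interaction]]],
                      mode: str, ca: frozenset[Interaction] | None = None,
                      conserved: frozenset[Interaction] | None = None
                      ) -> dict[str, np.ndarray]:
    """Per-generation divergence curves across clone lineages.

    ``traces`` holds one interaction-set-per-generation list per clone
    lineage (matched lengths; generation 0 = the cloning generation).
    Modes: ``full_CA`` (full network vs the common ancestor),
    ``core_CA`` (restricted to the conserved set vs the CA) and
    ``core_pairwise`` (conserved sets between clone lineages at matched
    generations).  Returns median and IQR across clone (pairs)."""
    lengths = {len(t) for t in traces}
    if len(lengths) != 1:
        raise ValueError("clone traces must have matched lengths")
    n_gen = lengths.pop()
    if mode in ("full_CA", "core_CA") and ca is None:
        raise ValueError("CA interaction set required")
    if mode in ("core_CA", "core_pairwise") and conserved is None:
        raise ValueError("conserved interaction set required")
    curves = []
    if mode == "full_CA":
        for tr in traces:
            curves.append([divergence(s, ca) for s in tr])
    elif mode == "core_CA":
        ca_core = restricted(ca, conserved)
        for tr in traces:
            curves.append([divergence(restricted(s, conserved), ca_core)
                           for s in tr])
    elif mode == "core_pairwise":
        for i in range(len(traces)):
            for j in range(i + 1, len(traces)):
                curves.append([
                    divergence(restricted(traces[i][g], conserved),
                               restricted(traces[j][g], conserved))
                    for g in range(n_gen)])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    arr = np.asarray(curves)
    return {
        "median": np.median(arr, axis=0),
        "q25": np.percentile(arr, 25, axis=0),
        "q75": np.percentile(arr, 75, axis=0),
        "curves": arr,
    }


# ---------------------------------------------------------------------------
# Robustness assay
# ---------------------------------------------------------------------------

@dataclass
class RobustnessResult:
    mutated: np.ndarray      # fitness of offspring that carry mutations
    unmutated: np.ndarray    # fitness of exact genome copies

    def summary(self) -> dict:
        def _s(x):
            if x.size == 0:
                return {"n": 0}
            return {"n": int(x.size), "median": float(np.median(x)),
                    "iqr": float(np.subtract(*np.percentile(x, [75, 25])))}
        return {"mutated": _s(self.mutated), "unmutated": _s(self.unmutated)}


def robustness_assay(genome: Genome, n_offspring: int, tissues: list[Tissue],
                     dev_config: DevConfig, rates: MutationRates,
                     rng: np.random.Generator,
                     genome_config: GenomeConfig | None = None,
                     fitness_config: FitnessConfig | None = None
                     ) -> RobustnessResult:
    """Create offspring through the standard mutation operator, develop
    each once, and partition fitness by whether any mutation was applied.
    The mutated partition measures mutational robustness, the unmutated
    one developmental robustness."""
    mut, unmut = [], []
    for _ in range(n_offspring):
        child, events = mutate(genome, rates, rng, genome_config)
        tissue = tissues[int(rng.integers(0, len(tissues)))]
        traj = develop(child, tissue, dev_config, seed=child_seed(rng))
        f = total_fitness(traj, tissue, fitness_config).F
        (mut if events else unmut).append(f)
    return RobustnessResult(mutated=np.asarray(mut),
                            unmutated=np.asarray(unmut))


def bimodality_coefficient(x: np.ndarray) -> float:
    """Sarle's bimodality coefficient b = (g1^2 + 1) / (g2 + 3 (n-1)^2 /
    ((n-2)(n-3))); values above ~5/9 indicate bimodal or heavily
    skewed-bimodal shapes (a uniform distribution scores exactly 5/9)."""
    from scipy import stats
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, fisher=True, bias=False)
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))
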