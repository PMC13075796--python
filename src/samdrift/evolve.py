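"""Evolutionary loop: generations of development, selection and mutation.

Each generation, every individual develops on a tissue template drawn
uniformly from a pre-generated pool, is scored, and parents are chosen
with probability proportional to fitness (or uniformly in control runs).
Offspring inherit the parent genome with mutations.  The lineage log
records, per generation and individual, the parent pointer, the mutation
events and the fitness, from which any ancestral line can be replayed
exactly (mutation events fully describe their edits).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig, seed_streams, child_seed
from .fitness import total_fitness, select_parents
from .develop import develop
from .genome import (Genome, apply_events, genome_to_grn, init_genome,
                     mutate, Interaction)
from .tissue import Tissue, generate_pool

log = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


@dataclass
class IndividualRecord:
    parent: int
    events: tuple
    fitness: float


@dataclass
class LineageLog:
    """Genealogy of a run: generation 0 genomes plus per-generation
    records sufficient to reconstruct any ancestral line."""

    initial_genomes: list[Genome]
    #: records[g][i] describes individual i of generation g+1
    records: list[list[IndividualRecord]] = field(default_factory=list)
    #: fitness of every individual of generation 0
    initial_fitness: list[float] = field(default_factory=list)
    development_skipped: bool = False

    @property
    def n_generations(self) -> int:
        return len(self.records)

    @property
    def population_size(self) -> int:
        return len(self.initial_genomes)

    def fitness_matrix(self) -> np.ndarray:
        """(n_generations + 1, pop) fitness array."""
        rows = [self.initial_fitness]
        rows += [[r.fitness for r in gen] for gen in self.records]
        return np.asarray(rows)

    def final_fitness(self) -> np.ndarray:
        if not self.records:
            return np.asarray(self.initial_fitness)
        return np.asarray([r.fitness for r in self.records[-1]])

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": CHECKPOINT_VERSION,
            "initial_genomes": [g.to_text() for g in self.initial_genomes],
            "initial_fitness": list(map(float, self.initial_fitness)),
            "development_skipped": self.development_skipped,
            "records": [[[r.parent, _events_plain(r.events), r.fitness]
                         for r in gen] for gen in self.records],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LineageLog":
        def _f(x):
            return float("nan") if x is None else float(x)

        logd = cls(
            initial_genomes=[Genome.from_text(t) for t in d["initial_genomes"]],
            initial_fitness=[_f(x) for x in d["initial_fitness"]],
            development_skipped=d.get("development_skipped", False),
        )
        for gen in d["records"]:
            logd.records.append([
                IndividualRecord(parent=r[0],
                                 events=tuple(tuple(e) for e in r[1]),
                                 fitness=_f(r[2]))
                for r in gen])
        return logd


def _events_plain(events: tuple) -> list:
    return [list(e) for e in events]


@dataclass
class TraceEntry:
    generation: int
    genome: Genome
    interactions: frozenset[Interaction]
    fitness: float


def ancestral_trace(logd: LineageLog, individual: int) -> list[TraceEntry]:
    """The unique parent path from generation 0 to ``individual`` of the
    final generation, with genomes and interaction sets reconstructed by
    replaying the recorded mutation events."""
    n_gen = logd.n_generations
    if not 0 <= individual < logd.population_size:
        raise IndexError("individual index out of range")
    # walk pointers back
    idx = individual
    path = [idx]
    for g in range(n_gen - 1, -1, -1):
        rec = logd.records[g][idx]
        idx = rec.parent
        if not 0 <= idx < logd.population_size:
            raise RuntimeError(f"broken parent pointer at generation {g}")
        path.append(idx)
    path.reverse()  # path[g] = index of the ancestor in generation g
    genome = logd.initial_genomes[path[0]]
    entries = [TraceEntry(0, genome, genome_to_grn(genome),
                          logd.initial_fitness[path[0]])]
    for g in range(n_gen):
        rec = logd.records[g][path[g + 1]]
        genome = apply_events(genome, rec.events)
        entries.append(TraceEntry(g + 1, genome, genome_to_grn(genome),
                                  rec.fitness))
    return entries


def fittest_trace(logd: LineageLog) -> list[TraceEntry]:
    """Ancestral trace of the fittest individual in the final generation
    (the input to the conservation and divergence analyses).  For control
    runs without fitness evaluation, individual 0 is traced."""
    f = logd.final_fitness()
    if np.all(np.isnan(f)):
        return ancestral_trace(logd, 0)
    return ancestral_trace(logd, int(np.nanargmax(f)))


# ---------------------------------------------------------------------------
# The loop
# ---------------------------------------------------------------------------

def evaluate_population(genomes: list[Genome], tissues: list[Tissue],
                        config: RunConfig, dev_rng: np.random.Generator
                        ) -> np.ndarray:
    """Develop every genome on a template drawn from the pool; return
    fitness values."""
    f = np.zeros(len(genomes))
    for i, g in enumerate(genomes):
        tissue = tissues[int(dev_rng.integers(0, len(tissues)))]
        traj = develop(g, tissue, config.dev, seed=child_seed(dev_rng))
        f[i] = total_fitness(traj, tissue, config.fitness).F
    return f


@dataclass
class RunState:
    """Checkpointable state of an evolutionary run."""

    config: RunConfig
    genomes: list[Genome]
    generation: int
    log: LineageLog
    rng_states: dict

    def save(self, path) -> None:
        payload = {
            "version": CHECKPOINT_VERSION,
            "config": self.config.to_dict(),
            "genomes": [g.to_text() for g in self.genomes],
            "generation": self.generation,
            "log": self.log.to_dict(),
            "rng_states": self.rng_states,
        }
        with open(path, "w") as fh:
            json.dump(_jsonable(payload), fh)

    @classmethod
    def load(cls, path) -> "RunState":
        with open(path) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as e:
                raise RuntimeError(f"corrupt checkpoint {path}: {e}") from e
        if payload.get("version") != CHECKPOINT_VERSION:
            raise RuntimeError("unsupported checkpoint version")
        return cls(
            config=RunConfig.from_dict(payload["config"]),
            genomes=[Genome.from_text(t) for t in payload["genomes"]],
            generation=payload["generation"],
            log=LineageLog.from_dict(payload["log"]),
            rng_states=payload["rng_states"],
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _capture_rng_states(streams) -> dict:
    return {name: json.loads(json.dumps(_jsonable(rng.bit_generator.state)))
            for name, rng in streams.items()}


def _restore_rng_states(streams, states) -> None:
    for name, rng in streams.items():
        st = states[name]
        # json round-trips the PCG64 state dict with string keys intact
        rng.bit_generator.state = st


def _evolve_generations(genomes: list[Genome], config: RunConfig,
                        tissues: list[Tissue], streams, logd: LineageLog,
                        n_generations: int,
                        fitness_now: np.ndarray | None = None,
                        progress_every: int = 0) -> list[Genome]:
    """Advance ``n_generations``, appending to ``logd`` in place."""
    pop = len(genomes)
    uniform = config.evo.selection == "uniform"
    skip_dev = config.evo.skip_development
    if fitness_now is None:
        if skip_dev:
            fitness_now = np.full(pop, np.nan)
        else:
            fitness_now = evaluate_population(genomes, tissues, config,
                                              streams["development"])
        if not logd.records and not logd.initial_fitness:
            logd.initial_fitness = [float(x) for x in fitness_now]
            logd.development_skipped = skip_dev

    for gen in range(n_generations):
        if uniform or skip_dev:
            parents = streams["selection"].integers(0, pop, size=pop)
        else:
            parents = select_parents(fitness_now, pop, streams["selection"])
        offspring = []
        all_events = []
        for p in parents:
            child, events = mutate(genomes[int(p)], config.rates,
                                   streams["mutation"], config.genome)
            offspring.append(child)
            all_events.append(tuple(events))
        if skip_dev:
            child_fitness = np.full(pop, np.nan)
        else:
            child_fitness = evaluate_population(offspring, tissues, config,
                                                streams["development"])
        logd.records.append([
            IndividualRecord(parent=int(parents[i]), events=all_events[i],
                             fitness=float(child_fitness[i]))
            for i in range(pop)])
        genomes = offspring
        fitness_now = child_fitness
        if progress_every and (gen + 1) % progress_every == 0:
            mx = np.nan if skip_dev else float(np.nanmax(fitness_now))
            log.info("generation %d: max fitness %.2f",
                     logd.n_generations, mx)
    return genomes


def run_evolution(config: RunConfig, tissues: list[Tissue] | None = None,
                  checkpoint_path=None, progress_every: int = 0
                  ) -> tuple[LineageLog, RunState]:
    """Run a full evolutionary simulation from scratch.

    Returns the lineage log and the final checkpointable state.  Seeds are
    taken from ``config.seed`` and fully determine the run."""
    streams = seed_streams(config.seed)
    if tissues is None:
        tissues = generate_pool(config.evo.n_tissues, config.tissue,
                                config.fitness, streams["tissue"])
    genomes = [init_genome(streams["init"], config.genome)
               for _ in range(config.evo.population_size)]
    logd = LineageLog(initial_genomes=[g.copy() for g in genomes])
    genomes = _evolve_generations(genomes, config, tissues, streams, logd,
                                  config.evo.generations,
                                  progress_every=progress_every)
    state = RunState(config=config, genomes=genomes,
                     generation=logd.n_generations, log=logd,
                     rng_states=_capture_rng_states(streams))
    if checkpoint_path is not None:
        state.save(checkpoint_path)
    return logd, state


def run_control(config: RunConfig, tissues: list[Tissue] | None = None,
                progress_every: int = 0) -> tuple[LineageLog, RunState]:
    """Control run: random reproduction, no selection for a pattern.
    Development is skipped when ``config.evo.skip_development`` is set
    (fitness is then logged as NaN)."""
    cfg = RunConfig.from_dict(config.to_dict())
    cfg.evo.selection = "uniform"
    return run_evolution(cfg, tissues, progress_every=progress_every)


def resume(state: RunState, extra_generations: int,
           tissues: list[Tissue] | None = None) -> tuple[LineageLog, RunState]:
    """Continue a checkpointed run; equals the uninterrupted run because
    the stream states are restored exactly."""
    streams = seed_streams(state.config.seed)
    _restore_rng_states(streams, state.rng_states)
    if tissues is None:
        # tissue pool is reproducible from the tissue stream of the
        # original seed (it is consumed before any evolution randomness)
        fresh = seed_streams(state.config.seed)
        tissues = generate_pool(state.config.evo.n_tissues,
                                state.config.tissue, state.config.fitness,
                                fresh["tissue"])
    logd = state.log
    fitness_now = logd.final_fitness() if logd.n_generations else None
    genomes = _evolve_generations(state.genomes, state.config, tissues,
                                  streams, logd, extra_generations,
                                  fitness_now=np.asarray(fitness_now)
                                  if fitness_now is not None else None)
    return logd, RunState(config=state.config, genomes=genomes,
                          generation=logd.n_generations, log=logd,
                          rng_states=_capture_rng_states(streams))


def clone_and_continue(state: RunState, n_clones: int,
                       extra_generations: int, seeds: list[int],
                       tissues: list[Tissue] | None = None
                       ) -> list[tuple[LineageLog, RunState]]:
    """Clone a checkpointed population into independent continuations
    sharing the common-ancestor state; each clone evolves under its own
    seed."""
    if len(seeds) != n_clones:
        raise ValueError("need one seed per clone")
    out = []
    for seed in seeds:
        cfg = RunConfig.from_dict(state.config.to_dict())
        cfg.seed = int(seed)
        streams = seed_streams(cfg.seed)
        if tissues is None:
            pool = generate_pool(cfg.evo.n_tissues, cfg.tissue, cfg.fitness,
                                 streams["tissue"])
        else:
            pool = tissues
        genomes = [g.copy() for g in state.genomes]
        logd = LineageLog(initial_genomes=[g.copy() for g in genomes])
        genomes = _evolve_generations(genomes, cfg, pool, streams, logd,
                                      extra_generations)
        out.append((logd, RunState(config=cfg, genomes=genomes,
                                   generation=logd.n_generations, log=logd,
                                   rng_states=_capture_rng_states(streams))))
    return out
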