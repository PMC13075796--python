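"""Run configuration: every tunable parameter of the simulator in one place.

A :class:`RunConfig` aggregates the sub-configurations of each stage
(tissue generation, genome/mutation model, developmental dynamics, fitness
evaluation, evolutionary loop).  Named presets reproduce the study
conditions: ``default`` (full scale: 130-cell tissues, 1000 individuals),
``control`` (no selection), ``noise_off`` (deterministic development),
``reduced_grn`` (8 gene types instead of 14 TF species), and ``desk``
(a scaled-down configuration for desktop-scale experiments: 40-cell
tissues, 100 individuals, shortened development).

Seeding: one global seed expands deterministically into independent
per-component streams (tissue, development, mutation, selection) through
:func:`seed_streams`, so partial reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

# ---------------------------------------------------------------------------
# TF type universe (integer identifiers, fixed by the model)
# ---------------------------------------------------------------------------

N_TF_TYPES = 14
DIFFUSING = (0, 1)
CELL_CELL = (2, 3)
DIMER = 7
MONOMERS = (8, 9)
CELL_AUTONOMOUS = (4, 5, 6, 10, 11)
FITNESS_TYPES = (12, 13)  # 12 = organizing centre (OC), 13 = central zone (CZ)
#: gene product types: the dimer (7) exists only as a protein species and can
#: never be transcribed or translated.
SYNTHESIZABLE = tuple(t for t in range(N_TF_TYPES) if t != DIMER)

#: reduced gene complement: 2 diffusing, 2 cell-cell, 2 cell-autonomous and
#: the 2 fitness genes.
REDUCED_GENE_TYPES = (0, 1, 2, 3, 4, 5, 12, 13)


@dataclass
class TissueConfig:
    n_cells: int = 130
    #: half-width of the dome footprint; the dome profile is
    #: y = height - curvature * x^2 with height = curvature * x_max^2 so the
    #: profile meets y = 0 at the domain edge.
    x_max: float = 61.0
    curvature: float = 0.01
    spring_k: float = 1.0
    #: relaxed spring length; if None, uses sqrt(domain_area / n_cells).
    relaxed_length: float | None = None
    relax_steps: int = 500
    relax_dt: float = 0.1
    boundary_force: float = 10.0
    lloyd_steps: int = 2000
    #: L1 (epidermis) includes only the curved dome surface by default.
    l1_include_base: bool = False

    @property
    def height(self) -> float:
        return self.curvature * self.x_max**2


@dataclass
class Bounds:
    lo: float
    hi: float

    def clip(self, x: float) -> float:
        return min(max(x, self.lo), self.hi)


@dataclass
class GenomeConfig:
    """Initial-genome structure and mutable-parameter bounds/defaults."""

    gene_types: tuple[int, ...] = SYNTHESIZABLE
    #: initial TFBS count per gene is drawn uniformly from this inclusive range.
    init_tfbs_min: int = 0
    init_tfbs_max: int = 2
    tau_max_default: float = 5.0
    alpha_default: float = 0.1
    tau_max_bounds: Bounds = field(default_factory=lambda: Bounds(0.0, 10.0))
    alpha_bounds: Bounds = field(default_factory=lambda: Bounds(0.01, 1.0))
    hill_bounds: Bounds = field(default_factory=lambda: Bounds(1.0, 500.0))
    diffusion_default: float = 1.0
    diffusion_bounds: Bounds = field(default_factory=lambda: Bounds(0.0, 5.0))
    association_default: float = 1.0
    dissociation_default: float = 10.0
    dimer_const_bounds: Bounds = field(default_factory=lambda: Bounds(0.01, 100.0))


@dataclass
class MutationRates:
    """Per-event probabilities (at most one mutation per element per
    offspring) and normal step sizes for continuous parameters."""

    gene_deletion: float = 1e-3
    gene_duplication: float = 1e-3
    tau_max_change: float = 1e-3
    alpha_change: float = 1e-3
    #: deletion exceeds duplication so that, together with the constant
    #: de novo inflow, the neutral equilibrium TFBS count
    #: (de_novo / (deletion - duplication) = 25) sits near the initial
    #: genome's complement instead of drifting upward without bound.
    tfbs_deletion: float = 2e-3
    tfbs_duplication: float = 1e-3
    hill_change: float = 1e-3
    sign_flip: float = 1e-3
    type_change: float = 1e-3
    #: de novo TFBS emergence: a per-offspring event inserting one fresh
    #: random TFBS at a uniformly random genome position.  The default
    #: matches the inflow of a 1e-3 per-element event on a ~26-element
    #: genome while keeping the insertion pressure independent of genome
    #: size (a literal per-element insertion rate grows genomes
    #: exponentially).
    de_novo: float = 2.5e-2
    whole_genome_duplication: float = 1e-4
    #: per-offspring probabilities for the global kinetic constants.
    diffusion_change: float = 1e-3
    dimer_const_change: float = 1e-3
    # normal step sizes (sigma) for parameter mutations
    sigma_tau_max: float = 0.5
    sigma_alpha: float = 0.05
    sigma_hill: float = 25.0
    sigma_diffusion: float = 0.1
    sigma_dimer_const: float = 0.5

    def scaled(self, factor: float) -> "MutationRates":
        """All event probabilities multiplied by ``factor`` (sigmas kept)."""
        out = dataclasses.replace(self)
        for f in (
            "gene_deletion", "gene_duplication", "tau_max_change",
            "alpha_change", "tfbs_deletion", "tfbs_duplication",
            "hill_change", "sign_flip", "type_change", "de_novo",
            "whole_genome_duplication", "diffusion_change",
            "dimer_const_change",
        ):
            setattr(out, f, min(1.0, getattr(out, f) * factor))
        return out

    def zeroed(self) -> "MutationRates":
        return self.scaled(0.0)


@dataclass
class DevConfig:
    dt: float = 0.1
    t_end: float = 500.0
    noise: bool = True
    #: protein decay rate (global, not mutable).
    beta: float = 0.1
    #: TF uniformly present at t = 0 in every cell.
    init_tf_type: int = 4
    init_concentration: float = 100.0
    #: TF constitutively produced in the L1 (epidermal) layer.
    l1_tf_type: int = 0
    l1_production: float = 10.0
    #: integer sample times at which fitness is evaluated; two windows.
    fitness_windows: tuple[tuple[int, int], ...] = ((201, 250), (451, 500))

    @property
    def sample_times(self) -> np.ndarray:
        times = []
        for lo, hi in self.fitness_windows:
            times.extend(range(lo, hi + 1))
        return np.asarray(times, dtype=float)

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        times = self.sample_times
        if times.size and self.t_end < times.max():
            raise ValueError("t_end must cover the last fitness sample time")
        # dt must divide the sampling spacing (integer times)
        steps = times / self.dt
        if not np.allclose(steps, np.round(steps), atol=1e-9):
            raise ValueError("dt must divide the fitness sample times")


@dataclass
class ZoneBox:
    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float

    def contains(self, x: float, y: float) -> bool:
        return self.x_lo < x < self.x_hi and self.y_lo < y <= self.y_hi


@dataclass
class FitnessConfig:
    """Zone bounding boxes and the per-cell fitness constants."""

    cz_box: ZoneBox = field(default_factory=lambda: ZoneBox(-15, 15, 28, np.inf))
    cz_oc_box: ZoneBox = field(default_factory=lambda: ZoneBox(-15, 15, 24, 28))
    oc_box: ZoneBox = field(default_factory=lambda: ZoneBox(-15, 15, 16, 24))
    #: correct-protein concentration above which a zone cell scores exactly 100.
    cap: float = 400.0
    #: if False, the cap only saturates the positive term (alternative reading).
    cap_overrides_negative: bool = True


@dataclass
class EvolutionConfig:
    population_size: int = 1000
    generations: int = 50_000
    n_tissues: int = 1000
    #: record a full population snapshot every this many generations.
    checkpoint_every: int = 1000
    #: selection: fitness-proportional ("fitness") or uniform ("uniform").
    selection: str = "fitness"
    #: skip development entirely (control runs do not need fitness).
    skip_development: bool = False


@dataclass
class RunConfig:
    tissue: TissueConfig = field(default_factory=TissueConfig)
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    rates: MutationRates = field(default_factory=MutationRates)
    dev: DevConfig = field(default_factory=DevConfig)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    evo: EvolutionConfig = field(default_factory=EvolutionConfig)
    seed: int = 0
    preset: str = "default"

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(tp, val):
            if dataclasses.is_dataclass(tp) and isinstance(val, dict):
                kwargs = {}
                for f in dataclasses.fields(tp):
                    if f.name in val:
                        ft = f.type if not isinstance(f.type, str) else None
                        kwargs[f.name] = _coerce(f, val[f.name])
                return tp(**kwargs)
            return val

        def _coerce(f, v):
            target = {
                "tissue": TissueConfig, "genome": GenomeConfig,
                "rates": MutationRates, "dev": DevConfig,
                "fitness": FitnessConfig, "evo": EvolutionConfig,
                "tau_max_bounds": Bounds, "alpha_bounds": Bounds,
                "hill_bounds": Bounds, "diffusion_bounds": Bounds,
                "dimer_const_bounds": Bounds, "cz_box": ZoneBox,
                "cz_oc_box": ZoneBox, "oc_box": ZoneBox,
            }.get(f.name)
            if target is not None and isinstance(v, dict):
                return build(target, v)
            if isinstance(v, list):
                return tuple(tuple(x) if isinstance(x, list) else x for x in v)
            return v

        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                kwargs[f.name] = _coerce(f, d[f.name])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert numpy scalars / inf so YAML stays readable."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return float("inf") if obj > 0 else float("-inf")
    return obj


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def default_config(seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed, preset="default")


def control_config(seed: int = 0) -> RunConfig:
    cfg = default_config(seed)
    cfg.preset = "control"
    cfg.evo.selection = "uniform"
    cfg.evo.skip_development = True
    return cfg


def noise_off_config(seed: int = 0) -> RunConfig:
    cfg = default_config(seed)
    cfg.preset = "noise_off"
    cfg.dev.noise = False
    return cfg


def reduced_grn_config(seed: int = 0) -> RunConfig:
    cfg = default_config(seed)
    cfg.preset = "reduced_grn"
    cfg.genome.gene_types = REDUCED_GENE_TYPES
    return cfg


def desk_config(seed: int = 0) -> RunConfig:
    """Desktop-scale preset: 40-cell tissues, 100 individuals, development
    shortened to t_end = 100 with fitness windows [40, 50] and [90, 100]
    (20 sample times), and a small template pool.  Mutation rates are the
    standard ones.  Intended for laptop-scale experiments and tests."""
    cfg = default_config(seed)
    cfg.preset = "desk"
    # desk runs compress ~50k generations into ~1e3; the per-event mutation
    # probabilities are scaled up tenfold so the mutation supply per unit of
    # evolutionary search stays comparable (most offspring still inherit an
    # unmutated genome).  Whole-genome duplication stays at its standard
    # rate: it is a macro-mutation and scaling it with the point-event rates
    # would make repeated doublings routine within a short run.
    wgd = cfg.rates.whole_genome_duplication
    cfg.rates = cfg.rates.scaled(10.0)
    cfg.rates.whole_genome_duplication = wgd
    cfg.tissue.n_cells = 40
    cfg.tissue.lloyd_steps = 300
    cfg.evo.population_size = 100
    cfg.evo.generations = 1500
    cfg.evo.n_tissues = 8
    cfg.evo.checkpoint_every = 250
    cfg.dev.t_end = 100.0
    cfg.dev.dt = 0.2
    cfg.dev.fitness_windows = ((41, 50), (91, 100))
    return cfg


PRESETS = {
    "default": default_config,
    "control": control_config,
    "noise_off": noise_off_config,
    "reduced_grn": reduced_grn_config,
    "desk": desk_config,
}


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

#: named component streams, in a fixed order.
STREAM_NAMES = ("tissue", "init", "development", "mutation", "selection", "analysis")


def seed_streams(seed: int) -> dict[str, np.random.Generator]:
    """Expand one global seed into independent named generators."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STREAM_NAMES))
    return {name: np.random.default_rng(c) for name, c in zip(STREAM_NAMES, children)}


def child_seed(rng: np.random.Generator) -> int:
    """Draw a 31-bit child seed from a generator (for kernel-level RNGs)."""
    return int(rng.integers(0, 2**31 - 1))
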