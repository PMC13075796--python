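"""Genome representation, translation to a GRN, and mutation operators.

A genome is an ordered "beads-on-a-string" sequence of elements: genes
(each encoding one transcription factor of a given type) and transcription
factor binding sites (TFBSs).  Every TFBS regulates the nearest downstream
gene with a sign (+/-) and a Hill constant; TFBSs with no downstream gene
are carried but inert.  Global kinetic constants (diffusion rates of the
two diffusing TF types, dimer association/dissociation) also live on the
genome and are mutable.

The type-level regulatory network is the set of (regulator TF type ->
target gene type, sign) triples; duplicate TFBS copies collapse at the
type level but copy counts remain available for the quantitative
adjacency matrix.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .config import (
    DIFFUSING,
    DIMER,
    N_TF_TYPES,
    GenomeConfig,
    MutationRates,
)

GENOME_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Tfbs:
    tf_type: int
    sign: int  # +1 or -1
    hill: float

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise ValueError("TFBS sign must be +1 or -1")
        if self.hill <= 0:
            raise ValueError("Hill constant must be positive")


@dataclass(frozen=True)
class Gene:
    product_type: int
    tau_max: float
    alpha: float

    def __post_init__(self):
        if self.product_type == DIMER:
            raise ValueError("the dimer TF type cannot be a gene product")
        if self.tau_max < 0 or self.alpha <= 0:
            raise ValueError("invalid gene kinetic parameters")


Element = Tfbs | Gene


@dataclass(frozen=True)
class Interaction:
    """Type-level regulatory interaction: regulator TF -> target gene type."""

    regulator: int
    target: int
    sign: int

    def __iter__(self):
        return iter((self.regulator, self.target, self.sign))


@dataclass
class Genome:
    elements: list[Element] = field(default_factory=list)
    #: diffusion constant per diffusing TF type.
    diffusion: dict[int, float] = field(
        default_factory=lambda: {t: 1.0 for t in DIFFUSING})
    association: float = 1.0
    dissociation: float = 10.0

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def dimer_kd(self) -> float:
        """Equilibrium dissociation constant of the 8+9 heterodimer."""
        return self.dissociation / self.association

    @property
    def genes(self) -> list[Gene]:
        return [e for e in self.elements if isinstance(e, Gene)]

    def copy(self) -> "Genome":
        return Genome(elements=list(self.elements),
                      diffusion=dict(self.diffusion),
                      association=self.association,
                      dissociation=self.dissociation)

    # -- TFBS -> target resolution -----------------------------------------
    def tfbs_targets(self) -> list[tuple[int, Tfbs, Gene | None]]:
        """(position, tfbs, nearest downstream gene or None) for every TFBS."""
        out = []
        pending: list[tuple[int, Tfbs]] = []
        for pos, el in enumerate(self.elements):
            if isinstance(el, Tfbs):
                pending.append((pos, el))
            else:
                for p, t in pending:
                    out.append((p, t, el))
                pending = []
        for p, t in pending:  # inert trailing TFBSs
            out.append((p, t, None))
        out.sort(key=lambda r: r[0])
        return out

    # -- serialization ------------------------------------------------------
    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"# samdrift genome v{GENOME_FORMAT_VERSION}\n")
        d = " ".join(f"{t}:{self.diffusion[t]!r}" for t in sorted(self.diffusion))
        buf.write(f"GLOBAL diffusion {d} association {self.association!r} "
                  f"dissociation {self.dissociation!r}\n")
        for el in self.elements:
            if isinstance(el, Tfbs):
                buf.write(f"TFBS {el.tf_type} {el.sign:+d} {el.hill!r}\n")
            else:
                buf.write(f"GENE {el.product_type} {el.tau_max!r} {el.alpha!r}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "Genome":
        g = cls(elements=[])
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if tok[0] == "GLOBAL":
                kv = tok[1:]
                i = 0
                while i < len(kv):
                    key = kv[i]
                    if key == "diffusion":
                        i += 1
                        g.diffusion = {}
                        while i < len(kv) and ":" in kv[i]:
                            t, v = kv[i].split(":")
                            g.diffusion[int(t)] = float(v)
                            i += 1
                    elif key == "association":
                        g.association = float(kv[i + 1]); i += 2
                    elif key == "dissociation":
                        g.dissociation = float(kv[i + 1]); i += 2
                    else:
                        raise ValueError(f"unknown global field {key!r}")
            elif tok[0] == "TFBS":
                g.elements.append(Tfbs(int(tok[1]), int(tok[2]), float(tok[3])))
            elif tok[0] == "GENE":
                g.elements.append(Gene(int(tok[1]), float(tok[2]), float(tok[3])))
            else:
                raise ValueError(f"unknown genome line {line!r}")
        return g

    def to_dict(self) -> dict:
        return {"version": GENOME_FORMAT_VERSION, "text": self.to_text()}

    @classmethod
    def from_dict(cls, d: dict) -> "Genome":
        return cls.from_text(d["text"])


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def init_genome(rng: np.random.Generator, config: GenomeConfig) -> Genome:
    """One gene of each synthesizable type (per the configured gene set),
    preceded by a random number of random TFBSs."""
    if config.init_tfbs_min < 0 or config.init_tfbs_max < config.init_tfbs_min:
        raise ValueError("invalid initial TFBS count bounds")
    for b in (config.tau_max_bounds, config.alpha_bounds, config.hill_bounds):
        if b.hi < b.lo:
            raise ValueError("invalid parameter bounds")
    elements: list[Element] = []
    for gene_type in config.gene_types:
        n_tfbs = int(rng.integers(config.init_tfbs_min, config.init_tfbs_max + 1))
        for _ in range(n_tfbs):
            elements.append(_random_tfbs(rng, config))
        elements.append(Gene(product_type=int(gene_type),
                             tau_max=config.tau_max_default,
                             alpha=config.alpha_default))
    return Genome(
        elements=elements,
        diffusion={t: config.diffusion_default for t in DIFFUSING},
        association=config.association_default,
        dissociation=config.dissociation_default,
    )


def _random_tfbs(rng: np.random.Generator, config: GenomeConfig) -> Tfbs:
    # any of the 14 TF types may act as a regulator, including the dimer
    return Tfbs(
        tf_type=int(rng.integers(0, N_TF_TYPES)),
        sign=int(rng.choice([-1, 1])),
        hill=float(rng.uniform(config.hill_bounds.lo, config.hill_bounds.hi)),
    )


# ---------------------------------------------------------------------------
# Genome -> GRN
# ---------------------------------------------------------------------------

def genome_to_grn(genome: Genome) -> frozenset[Interaction]:
    """The type-level interaction set encoded by a genome."""
    out = set()
    for _, tfbs, gene in genome.tfbs_targets():
        if gene is not None:
            out.add(Interaction(tfbs.tf_type, gene.product_type, tfbs.sign))
    return frozenset(out)


def interaction_counts(genome: Genome) -> dict[Interaction, int]:
    """TFBS copy number per type-level interaction (quantitative adjacency)."""
    counts: dict[Interaction, int] = {}
    for _, tfbs, gene in genome.tfbs_targets():
        if gene is not None:
            key = Interaction(tfbs.tf_type, gene.product_type, tfbs.sign)
            counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------
# Event records fully describe the edit so a lineage can be replayed:
#   ("gene_del", pos) ("gene_dup", pos) ("tau", pos, new) ("alpha", pos, new)
#   ("tfbs_del", pos) ("tfbs_dup", pos) ("hill", pos, new) ("sign", pos)
#   ("type", pos, new) ("de_novo", pos, tf_type, sign, hill)
#   ("wgd",) ("diffusion", tf_type, new) ("association", new)
#   ("dissociation", new)

MutationEvent = tuple


def clamp_step(value: float, sigma: float, lo: float, hi: float,
               rng: np.random.Generator) -> float:
    """Parameter mutation: add a Normal(0, sigma^2) draw, then clamp the
    result to its closest bound."""
    return float(min(max(value + rng.normal(0.0, sigma), lo), hi))


def _element_event(el: Element, rates: MutationRates,
                   rng: np.random.Generator) -> str | None:
    """Draw at most one event class for one element."""
    if isinstance(el, Gene):
        classes = [("gene_del", rates.gene_deletion),
                   ("gene_dup", rates.gene_duplication),
                   ("tau", rates.tau_max_change),
                   ("alpha", rates.alpha_change)]
    else:
        classes = [("tfbs_del", rates.tfbs_deletion),
                   ("tfbs_dup", rates.tfbs_duplication),
                   ("hill", rates.hill_change),
                   ("sign", rates.sign_flip),
                   ("type", rates.type_change)]
    u = rng.random()
    acc = 0.0
    for name, p in classes:
        acc += p
        if u < acc:
            return name
    return None


def mutate(genome: Genome, rates: MutationRates, rng: np.random.Generator,
           config: GenomeConfig | None = None,
           ) -> tuple[Genome, list[MutationEvent]]:
    """Apply the mutation operators to an offspring genome.

    Each element receives at most one mutation; genome-level events (whole
    genome duplication, global kinetic-constant changes) are drawn
    independently.  Returns the mutated genome and the list of applied
    events (a full description of the edit, replayable with
    :func:`apply_events`)."""
    cfg = config or GenomeConfig()
    events: list[MutationEvent] = []

    # per-element events, positions referring to the current genome; we draw
    # on the original element list and then apply sequentially (deletions /
    # insertions shift positions, so we collect events back-to-front).
    per_el: list[tuple[int, str]] = []
    for pos, el in enumerate(genome.elements):
        ev = _element_event(el, rates, rng)
        if ev is not None:
            per_el.append((pos, ev))

    new = genome.copy()
    # apply from the end so earlier positions stay valid
    for pos, kind in reversed(per_el):
        el = new.elements[pos]
        if kind in ("gene_del", "tfbs_del"):
            events.append((kind, pos))
        elif kind in ("gene_dup", "tfbs_dup"):
            events.append((kind, pos))
        elif kind == "tau":
            nv = clamp_step(el.tau_max, rates.sigma_tau_max,
                            cfg.tau_max_bounds.lo, cfg.tau_max_bounds.hi, rng)
            events.append(("tau", pos, nv))
        elif kind == "alpha":
            nv = clamp_step(el.alpha, rates.sigma_alpha,
                            cfg.alpha_bounds.lo, cfg.alpha_bounds.hi, rng)
            events.append(("alpha", pos, nv))
        elif kind == "hill":
            nv = clamp_step(el.hill, rates.sigma_hill,
                            cfg.hill_bounds.lo, cfg.hill_bounds.hi, rng)
            events.append(("hill", pos, nv))
        elif kind == "sign":
            events.append(("sign", pos))
        elif kind == "type":
            events.append(("type", pos, int(rng.integers(0, N_TF_TYPES))))
        _apply_event(new, events[-1])

    # genome-level events
    if rng.random() < rates.de_novo:
        pos = int(rng.integers(0, len(new.elements) + 1))
        t = _random_tfbs(rng, cfg)
        events.append(("de_novo", pos, t.tf_type, t.sign, t.hill))
        _apply_event(new, events[-1])
    if rng.random() < rates.whole_genome_duplication:
        events.append(("wgd",))
        _apply_event(new, events[-1])
    for t in sorted(new.diffusion):
        if rng.random() < rates.diffusion_change:
            nv = clamp_step(new.diffusion[t], rates.sigma_diffusion,
                            cfg.diffusion_bounds.lo, cfg.diffusion_bounds.hi,
                            rng)
            events.append(("diffusion", t, nv))
            _apply_event(new, events[-1])
    for name in ("association", "dissociation"):
        if rng.random() < rates.dimer_const_change:
            nv = clamp_step(getattr(new, name), rates.sigma_dimer_const,
                            cfg.dimer_const_bounds.lo,
                            cfg.dimer_const_bounds.hi, rng)
            events.append((name, nv))
            _apply_event(new, events[-1])
    return new, events


def _apply_event(genome: Genome, ev: MutationEvent) -> None:
    kind = ev[0]
    els = genome.elements
    if kind in ("gene_del", "tfbs_del"):
        del els[ev[1]]
    elif kind in ("gene_dup", "tfbs_dup"):
        # duplication inserts adjacent to (directly after) the original
        els.insert(ev[1] + 1, els[ev[1]])
    elif kind == "tau":
        els[ev[1]] = replace(els[ev[1]], tau_max=ev[2])
    elif kind == "alpha":
        els[ev[1]] = replace(els[ev[1]], alpha=ev[2])
    elif kind == "hill":
        els[ev[1]] = replace(els[ev[1]], hill=ev[2])
    elif kind == "sign":
        els[ev[1]] = replace(els[ev[1]], sign=-els[ev[1]].sign)
    elif kind == "type":
        els[ev[1]] = replace(els[ev[1]], tf_type=ev[2])
    elif kind == "de_novo":
        els.insert(ev[1], Tfbs(tf_type=ev[2], sign=ev[3], hill=ev[4]))
    elif kind == "wgd":
        els.extend(list(els))
    elif kind == "diffusion":
        genome.diffusion[ev[1]] = ev[2]
    elif kind == "association":
        genome.association = ev[1]
    elif kind == "dissociation":
        genome.dissociation = ev[1]
    else:
        raise ValueError(f"unknown mutation event {ev!r}")


def apply_events(genome: Genome, events: list[MutationEvent]) -> Genome:
    """Replay a recorded event list on a copy of ``genome`` (lineage
    reconstruction)."""
    new = genome.copy()
    for ev in events:
        _apply_event(new, ev)
    return new


def delete_interaction(genome: Genome, interaction: Interaction) -> Genome:
    """Remove every TFBS copy realizing a type-level interaction."""
    kill = {pos for pos, tfbs, gene in genome.tfbs_targets()
            if gene is not None
            and tfbs.tf_type == interaction.regulator
            and gene.product_type == interaction.target
            and tfbs.sign == interaction.sign}
    new = genome.copy()
    new.elements = [e for i, e in enumerate(genome.elements) if i not in kill]
    return new
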