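"""Conserved non-coding sequence (CNS) presence profiles and expression
distance: a generic rewiring analysis on delimited-text tables.

Inputs are a CNS table (one row per cns_id x species x gene, with the
gene's orthogroup), an expression matrix (genes x organs,
variance-stabilized counts) and a rooted species tree (newick).  The
analysis tallies per-orthogroup species-presence patterns (UpSet-style),
flags losses as non-monophyletic presence patterns, and relates
CNS-set similarity between genes (Jaccard) to the Pearson distance of
their organ expression profiles.  A synthetic-fixture generator produces
all three inputs with controlled overlap and correlation structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CNS_COLUMNS = ("cns_id", "orthogroup", "species", "gene")


@dataclass
class CnsTable:
    """Presence records: one row per (cns_id, orthogroup, species, gene)."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = set(CNS_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"CNS table missing columns {sorted(missing)}")
        dup = self.df.duplicated(subset=["cns_id", "gene"])
        if dup.any():
            raise ValueError("duplicate (cns_id, gene) pairs in CNS table")
        og = self.df.groupby("gene")["orthogroup"].nunique()
        if (og > 1).any():
            raise ValueError("each gene must belong to exactly one orthogroup")

    @property
    def species_universe(self) -> frozenset[str]:
        return frozenset(self.df["species"].unique())

    def orthogroups(self) -> list[str]:
        return sorted(self.df["orthogroup"].unique())

    def gene_cns_set(self, gene: str) -> frozenset[str]:
        return frozenset(self.df.loc[self.df["gene"] == gene, "cns_id"])

    @classmethod
    def read(cls, path, sep: str = "\t") -> "CnsTable":
        return cls(pd.read_csv(path, sep=sep, dtype=str))

    def write(self, path, sep: str = "\t") -> None:
        self.df.to_csv(path, sep=sep, index=False)


def read_expression(path, sep: str = "\t") -> pd.DataFrame:
    """Expression matrix: rows = genes (index), columns = organs."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    return df


def read_species_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# Presence profiles and loss calling
# ---------------------------------------------------------------------------

def presence_profiles(table: CnsTable, orthogroup: str
                      ) -> dict[frozenset[str], int]:
    """Species-presence pattern -> number of CNSs showing it (the input of
    an UpSet plot)."""
    if orthogroup not in set(table.df["orthogroup"]):
        raise KeyError(f"unknown orthogroup {orthogroup!r}")
    sub = table.df[table.df["orthogroup"] == orthogroup]
    out: dict[frozenset[str], int] = {}
    for _, grp in sub.groupby("cns_id"):
        pattern = frozenset(grp["species"])
        out[pattern] = out.get(pattern, 0) + 1
    return out


def clades(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Leaf sets of every clade (internal node or single leaf)."""
    out = set()
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        out.add(leaves)
    return out


def flag_losses(pattern: frozenset[str], tree: dendropy.Tree) -> bool:
    """True iff a presence pattern is non-monophyletic on the species tree
    (evidence of CNS loss in some lineage)."""
    if not pattern:
        raise ValueError("empty presence pattern")
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = set(pattern) - leaf_labels
    if unknown:
        raise KeyError(f"species not in tree: {sorted(unknown)}")
    return frozenset(pattern) not in clades(tree)


# ---------------------------------------------------------------------------
# Pairwise metrics
# ---------------------------------------------------------------------------

def cns_set_similarity(set_a, set_b) -> float:
    """Jaccard index of two CNS sets: 0 = disjoint, 1 = identical.
    Two empty sets are identical (similarity 1, logged)."""
    a, b = frozenset(set_a), frozenset(set_b)
    if not a and not b:
        log.info("both CNS sets empty; similarity defined as 1")
        return 1.0
    return len(a & b) / len(a | b)


def expression_distance(expr_a, expr_b) -> float:
    """Pearson distance (1 - Pearson correlation) of two organ-expression
    vectors on the same organ set."""
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("expression vectors must share at least 2 organs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson distance undefined for constant vectors")
    r = stats.pearsonr(a, b).statistic
    return float(1.0 - r)


def pair_table(table: CnsTable, expr: pd.DataFrame, orthogroup: str,
               relations: dict[frozenset[str], str] | None = None
               ) -> pd.DataFrame:
    """All unordered gene pairs of an orthogroup with CNS-set similarity,
    expression Pearson distance, and the supplied ortholog/paralog
    relation label.  Pairs with missing expression are skipped with a
    warning."""
    sub = table.df[table.df["orthogroup"] == orthogroup]
    genes = sorted(sub["gene"].unique())
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            ga, gb = genes[i], genes[j]
            if ga not in expr.index or gb not in expr.index:
                log.warning("missing expression for pair (%s, %s); skipped",
                            ga, gb)
                continue
            sim = cns_set_similarity(table.gene_cns_set(ga),
                                     table.gene_cns_set(gb))
            dist = expression_distance(expr.loc[ga], expr.loc[gb])
            rel = ""
            if relations is not None:
                rel = relations.get(frozenset((ga, gb)), "")
            rows.append({"gene_a": ga, "gene_b": gb, "cns_similarity": sim,
                         "pearson_distance": dist, "relation": rel})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "cns_similarity",
                                       "pearson_distance", "relation"])


# ---------------------------------------------------------------------------
# Synthetic fixture generator
# ---------------------------------------------------------------------------

@dataclass
class SynthCnsConfig:
    n_species: int = 6
    #: paralog families per orthogroup; the orthogroup carries one gene per
    #: family per species (orthologs across species, paralogs within).
    n_families: int = 2
    #: CNSs per family
    n_cns_per_family: int = 20
    #: fraction of each family's CNS complement drawn from a pool shared by
    #: all families (1 -> identical sets across families, 0 -> disjoint).
    overlap: float = 0.5
    #: target pairwise Pearson correlation of expression profiles.
    expression_correlation: float = 0.8
    n_organs: int = 20
    noise_scale: float = 0.05
    orthogroup: str = "OG0"
    #: probability a family CNS is lost in a given species' gene (creates
    #: non-monophyletic presence patterns).
    species_loss_rate: float = 0.1


@dataclass
class SynthCns:
    table: CnsTable
    expression: pd.DataFrame
    tree: dendropy.Tree
    relations: dict[frozenset[str], str] = field(default_factory=dict)


def synth_cns_fixture(config: SynthCnsConfig,
                      rng: np.random.Generator) -> SynthCns:
    """Generate a CNS table, expression matrix and species tree with
    controlled CNS-set overlap and expression correlation."""
    cfg = config
    if not 0 <= cfg.overlap <= 1:
        raise ValueError("overlap must be in [0, 1]")
    n_genes = cfg.n_families * cfg.n_species
    rho = cfg.expression_correlation
    if not -1.0 / max(n_genes - 1, 1) <= rho <= 1:
        raise ValueError("requested correlation matrix is not positive "
                         "semi-definite for this many genes")

    species = [f"sp{i}" for i in range(cfg.n_species)]
    # ladder (caterpillar) species tree
    newick = species[0]
    for s in species[1:]:
        newick = f"({newick},{s})"
    tree = dendropy.Tree.get(data=newick + ";", schema="newick")

    n_shared = int(round(cfg.overlap * cfg.n_cns_per_family))
    shared = [f"cns_shared_{k}" for k in range(n_shared)]
    rows = []
    genes = []
    family_of = {}
    for fam in range(cfg.n_families):
        fam_cns = shared + [f"cns_f{fam}_{k}"
                            for k in range(cfg.n_cns_per_family - n_shared)]
        for sp in species:
            gene = f"g{fam}_{sp}"
            genes.append(gene)
            family_of[gene] = fam
            for cns in fam_cns:
                if rng.random() < cfg.species_loss_rate:
                    continue  # lineage-specific loss
                rows.append({"cns_id": cns, "orthogroup": cfg.orthogroup,
                             "species": sp, "gene": gene})
    table = CnsTable(pd.DataFrame(rows, columns=list(CNS_COLUMNS)))

    # equicorrelated Gaussian organ profiles
    cov = np.full((n_genes, n_genes), rho)
    np.fill_diagonal(cov, 1.0)
    base = rng.multivariate_normal(np.zeros(n_genes), cov,
                                   size=cfg.n_organs, method="cholesky")
    base += cfg.noise_scale * rng.standard_normal(base.shape)
    expr = pd.DataFrame(base.T, index=genes,
                        columns=[f"organ{k}" for k in range(cfg.n_organs)])

    relations = {}
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            same_fam = family_of[genes[i]] == family_of[genes[j]]
            relations[frozenset((genes[i], genes[j]))] = (
                "ortholog" if same_fam else "paralog")
    return SynthCns(table=table, expression=expr, tree=tree,
                    relations=relations)
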