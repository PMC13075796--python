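"""Developmental dynamics: stochastic gene expression on a tissue.

Per cell and per gene copy, mRNA follows

    dG = (tau - alpha G) dt + sqrt(tau) dW1 - sqrt(alpha G) dW2

and per TF species, protein follows

    dP = (upsilon - beta P + L1 production + diffusion) dt
         + sqrt(upsilon) dW3 - sqrt(beta P) dW4

with translation rate upsilon = G (summed over gene copies of the same
product type), diffusion (D_p / A_c) sum_k omega_ck (P_k - P_c) for the
two diffusing TF types, and noise in chemical-Langevin form: independent
Wiener increments for production and decay, realized per Euler step as a
single Gaussian with the summed variance (the distribution of a sum of
independent increments); concentrations are clamped at 0.
Transcription is a saturating Hill response to the summed signed TFBS
contributions; cell-cell TF types act through the neighbour-weighted
concentration; the 8+9 heterodimer is kept at binding equilibrium and
partitioned from the monomer totals each step.

Integration is Euler-Maruyama with a numba-compiled kernel; with noise
off, the same kernel performs the deterministic Euler step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import DevConfig, DIMER, N_TF_TYPES
from .genome import Genome, Tfbs, Gene
from .tissue import Tissue


class IntegrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Reference single-quantity operations (also used by the kernel, inlined)
# ---------------------------------------------------------------------------

def tfbs_contribution(tfbs: Tfbs, p_input: float) -> float:
    """Signed transcriptional activity of one TFBS:
    theta = w P^2 / (P^2 + H^2)."""
    p2 = p_input * p_input
    return tfbs.sign * p2 / (p2 + tfbs.hill * tfbs.hill)


def neighbour_weighted_concentration(tissue: Tissue, cell: int,
                                     p_field: np.ndarray) -> float:
    """Edge-length-weighted mean concentration over a cell's neighbours
    (the input seen by cell-cell TF types)."""
    total_w = 0.0
    acc = 0.0
    for i, j, w in tissue.edges:
        if i == cell:
            acc += w * p_field[j]
            total_w += w
        elif j == cell:
            acc += w * p_field[i]
            total_w += w
    if total_w == 0.0:
        return 0.0
    return acc / total_w


def transcription_rate(gene: Gene, thetas) -> float:
    """tau = tau_max T^2/(T^2+1) with T = max(0, sum of TFBS activities)."""
    T = max(0.0, float(np.sum(thetas)))
    return gene.tau_max * T * T / (T * T + 1.0)


def dimer_partition(total8: float, total9: float, kd: float
                    ) -> tuple[float, float, float]:
    """Equilibrium partition of monomer totals into free monomers and dimer.

    The dimer concentration d solves (total8 - d)(total9 - d) = kd * d,
    taking the root in [0, min(total8, total9)]."""
    s = total8 + total9 + kd
    disc = s * s - 4.0 * total8 * total9
    d = 0.5 * (s - np.sqrt(max(disc, 0.0)))
    d = min(max(d, 0.0), min(total8, total9))
    return total8 - d, total9 - d, d


# ---------------------------------------------------------------------------
# Genome compilation
# ---------------------------------------------------------------------------

@dataclass
class CompiledGenome:
    prod: np.ndarray      # (nG,) product type per gene copy
    tau_max: np.ndarray   # (nG,)
    alpha: np.ndarray     # (nG,)
    ttype: np.ndarray     # (nT,) regulator TF type per functional TFBS
    sign: np.ndarray      # (nT,) float +-1
    hill: np.ndarray      # (nT,)
    gidx: np.ndarray      # (nT,) index into gene arrays
    d0: float
    d1: float
    kd: float


def compile_genome(genome: Genome) -> CompiledGenome:
    genes = []
    gene_pos = {}
    for pos, el in enumerate(genome.elements):
        if isinstance(el, Gene):
            gene_pos[pos] = len(genes)
            genes.append(el)
    ttype, sign, hill, gidx = [], [], [], []
    pending = []
    for pos, el in enumerate(genome.elements):
        if isinstance(el, Tfbs):
            pending.append(el)
        else:
            for t in pending:
                ttype.append(t.tf_type)
                sign.append(float(t.sign))
                hill.append(t.hill)
                gidx.append(gene_pos[pos])
            pending = []
    return CompiledGenome(
        prod=np.array([g.product_type for g in genes], dtype=np.int64),
        tau_max=np.array([g.tau_max for g in genes]),
        alpha=np.array([g.alpha for g in genes]),
        ttype=np.asarray(ttype, dtype=np.int64),
        sign=np.asarray(sign, dtype=np.float64),
        hill=np.asarray(hill, dtype=np.float64),
        gidx=np.asarray(gidx, dtype=np.int64),
        d0=genome.diffusion.get(0, 0.0),
        d1=genome.diffusion.get(1, 0.0),
        kd=genome.dimer_kd,
    )


# ---------------------------------------------------------------------------
# Fast normal variates: ziggurat (Marsaglia & Tsang, 128 layers) driven by
# an xorshift64* stream.  The chemical-Langevin runs draw millions of
# Gaussians per development; this is an order of magnitude faster than the
# library generator inside the kernel.
# ---------------------------------------------------------------------------

def _ziggurat_tables():
    m1 = 2147483648.0
    dn = 3.442619855899
    tn = dn
    vn = 9.91256303526217e-3
    kn = np.zeros(128, dtype=np.int64)
    wn = np.zeros(128)
    fn = np.zeros(128)
    q = vn / np.exp(-0.5 * dn * dn)
    kn[0] = int((dn / q) * m1)
    kn[1] = 0
    wn[0] = q / m1
    wn[127] = dn / m1
    fn[0] = 1.0
    fn[127] = np.exp(-0.5 * dn * dn)
    for i in range(126, 0, -1):
        dn = np.sqrt(-2.0 * np.log(vn / dn + np.exp(-0.5 * dn * dn)))
        kn[i + 1] = int((dn / tn) * m1)
        tn = dn
        fn[i] = np.exp(-0.5 * dn * dn)
        wn[i] = dn / m1
    return kn, wn, fn


_ZIG_KN, _ZIG_WN, _ZIG_FN = _ziggurat_tables()
_ZIG_R = 3.442619855899
_U64_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(inline="always")
def _next_u64(st):
    x = st[0]
    x ^= x >> np.uint64(12)
    x ^= (x << np.uint64(25)) & _U64_MASK
    x ^= x >> np.uint64(27)
    st[0] = x
    return (x * np.uint64(0x2545F4914F6CDD1D)) & _U64_MASK


@njit(inline="always")
def _next_uniform(st):
    return float(_next_u64(st) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(inline="always")
def _randn(st):
    while True:
        u = _next_u64(st)
        hz = np.int32(u & np.uint64(0xFFFFFFFF))
        iz = np.int64(hz) & 127
        ahz = np.int64(hz)
        if ahz < 0:
            ahz = -ahz
        if ahz < _ZIG_KN[iz]:
            return np.float64(hz) * _ZIG_WN[iz]
        if iz == 0:  # base strip: exact tail sampling
            while True:
                x = -np.log(_next_uniform(st)) / _ZIG_R
                y = -np.log(_next_uniform(st))
                if y + y >= x * x:
                    break
            return _ZIG_R + x if hz > 0 else -(_ZIG_R + x)
        x = np.float64(hz) * _ZIG_WN[iz]
        if (_ZIG_FN[iz] + _next_uniform(st) * (_ZIG_FN[iz - 1] - _ZIG_FN[iz])
                < np.exp(-0.5 * x * x)):
            return x
        # else: wedge rejection, resample


# ---------------------------------------------------------------------------
# Numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _simulate(G, P,
              prod, tau_max, alpha,
              ttype, sgn, hill, gidx,
              indptr, nbr, wts, csum, areas, l1mask,
              d0, d1, kd, beta, s_l1, l1_type,
              dt, n_steps, sample_steps, noise, seed):
    nG, C = G.shape
    S = P.shape[0]
    nT = ttype.size
    nS = sample_steps.size
    Gs = np.zeros((nS, nG, C))
    Ps = np.zeros((nS, S, C))
    # seed the xorshift64* noise stream (splitmix64 scramble)
    st = np.empty(1, dtype=np.uint64)
    z = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)) & _U64_MASK
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _U64_MASK
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _U64_MASK
    st[0] = z ^ (z >> np.uint64(31))
    if st[0] == np.uint64(0):
        st[0] = np.uint64(0x9E3779B97F4A7C15)

    free8 = np.zeros(C)
    free9 = np.zeros(C)
    dim = np.zeros(C)
    phat2 = np.zeros(C)
    phat3 = np.zeros(C)
    T = np.zeros((nG, C))
    ups = np.zeros((S, C))
    newG = np.zeros((nG, C))
    newP = np.zeros((S, C))
    si = 0

    for step in range(1, n_steps + 1):
        # dimer equilibrium from monomer totals
        for c in range(C):
            a = P[8, c]
            b = P[9, c]
            s = a + b + kd
            disc = s * s - 4.0 * a * b
            if disc < 0.0:
                disc = 0.0
            d = 0.5 * (s - np.sqrt(disc))
            m = a if a < b else b
            if d < 0.0:
                d = 0.0
            elif d > m:
                d = m
            dim[c] = d
            free8[c] = a - d
            free9[c] = b - d

        # neighbour-weighted input for the cell-cell TF types
        for c in range(C):
            acc2 = 0.0
            acc3 = 0.0
            for e in range(indptr[c], indptr[c + 1]):
                k = nbr[e]
                acc2 += wts[e] * P[2, k]
                acc3 += wts[e] * P[3, k]
            if csum[c] > 0.0:
                phat2[c] = acc2 / csum[c]
                phat3[c] = acc3 / csum[c]
            else:
                phat2[c] = 0.0
                phat3[c] = 0.0

        # transcriptional activity per gene copy
        for g in range(nG):
            for c in range(C):
                T[g, c] = 0.0
        for i in range(nT):
            p = ttype[i]
            h2 = hill[i] * hill[i]
            w = sgn[i]
            g = gidx[i]
            for c in range(C):
                if p == 2:
                    src = phat2[c]
                elif p == 3:
                    src = phat3[c]
                elif p == 7:
                    src = dim[c]
                elif p == 8:
                    src = free8[c]
                elif p == 9:
                    src = free9[c]
                else:
                    src = P[p, c]
                s2 = src * src
                T[g, c] += w * s2 / (s2 + h2)

        # mRNA update
        for g in range(nG):
            for c in range(C):
                t_act = T[g, c]
                if t_act < 0.0:
                    t_act = 0.0
                tau = tau_max[g] * t_act * t_act / (t_act * t_act + 1.0)
                dec = alpha[g] * G[g, c]
                dG = (tau - dec) * dt
                if noise:
                    # production and decay Wiener increments are
                    # independent; their sum is one Gaussian of summed
                    # variance (tau + alpha G) dt
                    var = (tau + dec) * dt
                    if var > 0.0:
                        dG += np.sqrt(var) * _randn(st)
                v = G[g, c] + dG
                newG[g, c] = v if v > 0.0 else 0.0

        # translation input per species (old mRNA)
        for p in range(S):
            for c in range(C):
                ups[p, c] = 0.0
        for g in range(nG):
            for c in range(C):
                ups[prod[g], c] += G[g, c]

        # protein update (species 7 is derived, not integrated)
        for p in range(S):
            if p == 7:
                continue
            Dp = d0 if p == 0 else (d1 if p == 1 else 0.0)
            for c in range(C):
                dec = beta * P[p, c]
                dP = (ups[p, c] - dec) * dt
                if p == l1_type and l1mask[c]:
                    dP += s_l1 * dt
                if Dp > 0.0:
                    diff = 0.0
                    for e in range(indptr[c], indptr[c + 1]):
                        diff += wts[e] * (P[p, nbr[e]] - P[p, c])
                    dP += Dp / areas[c] * diff * dt
                if noise:
                    var = (ups[p, c] + dec) * dt
                    if var > 0.0:
                        dP += np.sqrt(var) * _randn(st)
                v = P[p, c] + dP
                newP[p, c] = v if v > 0.0 else 0.0

        for g in range(nG):
            for c in range(C):
                G[g, c] = newG[g, c]
        for p in range(S):
            if p != 7:
                for c in range(C):
                    P[p, c] = newP[p, c]

        if si < nS and step == sample_steps[si]:
            for g in range(nG):
                for c in range(C):
                    Gs[si, g, c] = G[g, c]
            for p in range(S):
                for c in range(C):
                    Ps[si, p, c] = P[p, c]
            # report the equilibrium dimer for species 7
            for c in range(C):
                a = P[8, c]
                b = P[9, c]
                s = a + b + kd
                disc = s * s - 4.0 * a * b
                if disc < 0.0:
                    disc = 0.0
                d = 0.5 * (s - np.sqrt(disc))
                m = a if a < b else b
                if d < 0.0:
                    d = 0.0
                elif d > m:
                    d = m
                Ps[si, 7, c] = d
            si += 1
    return Gs, Ps


# ---------------------------------------------------------------------------
# Python surface
# ---------------------------------------------------------------------------

@dataclass
class DevState:
    """mRNA (per gene copy) and protein (per TF species) fields at time t.

    Protein rows 8 and 9 hold monomer totals; row 7 holds the equilibrium
    dimer concentration derived from them."""

    G: np.ndarray  # (n_gene_copies, n_cells)
    P: np.ndarray  # (14, n_cells)
    t: float


@dataclass
class Trajectory:
    """Developmental states captured at the fitness sample times."""

    times: np.ndarray          # (n_samples,)
    P: np.ndarray              # (n_samples, 14, n_cells)
    G: np.ndarray              # (n_samples, n_gene_copies, n_cells)
    final: DevState

    @property
    def n_samples(self) -> int:
        return self.times.size


def _tissue_arrays(tissue: Tissue):
    cached = getattr(tissue, "_csr_cache", None)
    if cached is not None:
        return cached
    indptr, nbr, wts = tissue.neighbour_csr()
    csum = np.zeros(tissue.n_cells)
    for c in range(tissue.n_cells):
        csum[c] = wts[indptr[c]:indptr[c + 1]].sum()
    tissue._csr_cache = (indptr, nbr, wts, csum)
    return tissue._csr_cache


def initial_state(genome: Genome, tissue: Tissue, config: DevConfig) -> DevState:
    cg = compile_genome(genome)
    G = np.zeros((cg.prod.size, tissue.n_cells))
    P = np.zeros((N_TF_TYPES, tissue.n_cells))
    P[config.init_tf_type, :] = config.init_concentration
    return DevState(G=G, P=P, t=0.0)


def _run(genome: Genome, tissue: Tissue, config: DevConfig, state: DevState,
         n_steps: int, sample_steps: np.ndarray, seed: int) -> tuple:
    cg = compile_genome(genome)
    indptr, nbr, wts, csum = _tissue_arrays(tissue)
    G = np.array(state.G, dtype=np.float64, copy=True, order="C")
    P = np.array(state.P, dtype=np.float64, copy=True, order="C")
    Gs, Ps = _simulate(
        G, P, cg.prod, cg.tau_max, cg.alpha,
        cg.ttype, cg.sign, cg.hill, cg.gidx,
        indptr, nbr, wts, csum,
        np.ascontiguousarray(tissue.areas, dtype=np.float64),
        np.ascontiguousarray(tissue.l1_mask, dtype=np.bool_),
        cg.d0, cg.d1, cg.kd, config.beta,
        config.l1_production, config.l1_tf_type,
        config.dt, n_steps,
        np.ascontiguousarray(sample_steps, dtype=np.int64),
        config.noise, seed)
    # species 7 is derived: refresh the equilibrium dimer row in the state
    for c in range(P.shape[1]):
        _, _, P[7, c] = dimer_partition(P[8, c], P[9, c], cg.kd)
    return G, P, Gs, Ps


def step(state: DevState, genome: Genome, tissue: Tissue, config: DevConfig,
         rng: np.random.Generator | None = None) -> DevState:
    """One Euler-Maruyama step (deterministic Euler with noise off)."""
    seed = int(rng.integers(0, 2**31 - 1)) if rng is not None else 0
    G, P, _, _ = _run(genome, tissue, config, state, 1,
                      np.empty(0, dtype=np.int64), seed)
    out = DevState(G=G, P=P, t=state.t + config.dt)
    _check_finite(out)
    return out


def develop(genome: Genome, tissue: Tissue, config: DevConfig,
            rng: np.random.Generator | None = None,
            seed: int | None = None) -> Trajectory:
    """Run development from the standard initial condition to t_end,
    capturing the state at every fitness sample time (plus the final
    state)."""
    config.validate()
    if seed is None:
        seed = int(rng.integers(0, 2**31 - 1)) if rng is not None else 0
    state = initial_state(genome, tissue, config)
    n_steps = int(round(config.t_end / config.dt))
    times = config.sample_times
    sample_steps = np.round(times / config.dt).astype(np.int64)
    G, P, Gs, Ps = _run(genome, tissue, config, state, n_steps,
                        sample_steps, seed)
    final = DevState(G=G, P=P, t=config.t_end)
    _check_finite(final)
    return Trajectory(times=times, P=Ps, G=Gs, final=final)


def _check_finite(state: DevState) -> None:
    if not np.isfinite(state.G).all():
        g, c = np.argwhere(~np.isfinite(state.G))[0]
        raise IntegrationError(
            f"non-finite mRNA for gene copy {g}, cell {c} at t={state.t}")
    if not np.isfinite(state.P).all():
        p, c = np.argwhere(~np.isfinite(state.P))[0]
        raise IntegrationError(
            f"non-finite protein for species {p}, cell {c} at t={state.t}")
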