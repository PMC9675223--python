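"""Population-type genetic models and 2-point linkage estimation.

The two-point likelihood for every supported population reduces to a
common algebraic form.  Per individual, an observed two-locus code combo
``o`` constrains a small set of latent meiotic configurations; each
configuration carries ``m`` recombinant meioses out of ``M`` informative
meioses (``M`` = 1 for BC/DH and for RIL/IRIL on the observed-``R``
scale, 2 for F2, and the number of doubly heterozygous parents for a CP
marker pair).  Collecting configurations gives

    P(o | r)  ∝  Σ_m  N[o, m] · r^m · (1 − r)^(M − m)

with integer coefficient tables ``N`` obtained by exhaustive gamete
enumeration.  EM on this form has a closed-form M-step (expected
recombinant meioses divided by total meioses) and is vectorized across
all marker pairs at once, which is what makes whole-matrix 2-point
scans cheap.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .types import CPMarkerInfo, PopulationType, SegregationDataset, MISSING

R_MIN = 1e-6
R_MAX = 0.5
EM_TOL = 1e-8
EM_MAX_ITER = 200
LN10 = np.log(10.0)

# ------------------------------------------------------------------ mapping functions


def haldane_r_to_d(r: float | np.ndarray) -> float | np.ndarray:
    """Haldane map distance in cM: d = -50 ln(1 - 2r).

    r >= 0.5 maps to +inf (with a warning): unlinked loci have no
    finite Haldane distance.
    """
    r = np.asarray(r, dtype=float)
    out = np.full_like(r, np.inf)
    ok = r < 0.5
    if not np.all(ok):
        warnings.warn("r >= 0.5 has infinite Haldane distance")
    out[ok] = -50.0 * np.log1p(-2.0 * r[ok])
    return float(out) if out.ndim == 0 else out


def haldane_d_to_r(d: float | np.ndarray) -> float | np.ndarray:
    """Inverse Haldane: r = (1 - e^(-d/50)) / 2 for d >= 0 cM."""
    d = np.asarray(d, dtype=float)
    out = 0.5 * -np.expm1(-d / 50.0)
    return float(out) if out.ndim == 0 else out


def kosambi_r_to_d(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r))."""
    r = np.asarray(r, dtype=float)
    out = np.full_like(r, np.inf)
    ok = r < 0.5
    out[ok] = 25.0 * np.log((1.0 + 2.0 * r[ok]) / (1.0 - 2.0 * r[ok]))
    return float(out) if out.ndim == 0 else out


def kosambi_d_to_r(d: float | np.ndarray) -> float | np.ndarray:
    d = np.asarray(d, dtype=float)
    out = 0.5 * np.tanh(d / 50.0)
    return float(out) if out.ndim == 0 else out


MAP_FUNCTIONS = {
    "haldane": (haldane_r_to_d, haldane_d_to_r),
    "kosambi": (kosambi_r_to_d, kosambi_d_to_r),
}

# ------------------------------------------------------------------ RIL / IRIL chain

# Haplotypes over two loci: index h = 2*a + b with alleles a, b in {0, 1}.
_PARENTAL_HAPS = (0, 3)
_RECOMB_HAPS = (1, 2)


def _gamete_dist(h1: int, h2: int, r: float) -> np.ndarray:
    """Gamete haplotype distribution of a diploid (h1, h2) at recombination r."""
    a1, b1 = h1 >> 1, h1 & 1
    a2, b2 = h2 >> 1, h2 & 1
    g = np.zeros(4)
    g[(a1 << 1) | b1] += (1 - r) / 2
    g[(a2 << 1) | b2] += (1 - r) / 2
    g[(a1 << 1) | b2] += r / 2
    g[(a2 << 1) | b1] += r / 2
    return g


def _selfing_matrix(r: float) -> np.ndarray:
    """Transition matrix over 16 ordered two-locus genotypes under selfing."""
    T = np.zeros((16, 16))
    for h1, h2 in itertools.product(range(4), repeat=2):
        g = _gamete_dist(h1, h2, r)
        T[4 * h1 + h2] = np.outer(g, g).ravel()
    return T


def _two_locus_genotype_dist(pop: PopulationType, r: float, max_selfing: int = 400) -> np.ndarray:
    """Distribution over 16 ordered two-locus genotypes for a RIL/IRIL line.

    Starts from the F1 (coupling double heterozygote) and iterates the
    per-generation transition: optional random-intermating generations
    (IRIL) after the F2, then selfing to the requested generation or to
    numerical fixation.
    """
    if pop.kind not in ("RIL", "IRIL"):
        raise ValueError("two-locus line distribution defined for RIL/IRIL only")
    dist = np.zeros(16)
    dist[4 * 0 + 3] = 1.0  # F1 = AB/ab in coupling
    T = _selfing_matrix(r)

    if pop.kind == "IRIL":
        dist = dist @ T  # F2
        for _ in range(pop.intermating_generations):
            pool = np.zeros(4)
            for h1, h2 in itertools.product(range(4), repeat=2):
                p = dist[4 * h1 + h2]
                if p > 0:
                    pool += p * _gamete_dist(h1, h2, r)
            dist = np.outer(pool, pool).ravel()
        n_self = max_selfing
        tol = 1e-14
    elif pop.selfing_generations is not None:
        n_self = pop.selfing_generations
        tol = 0.0
    else:
        n_self = max_selfing
        tol = 1e-14

    for _ in range(n_self):
        new = dist @ T
        if tol and np.abs(new - dist).max() < tol:
            dist = new
            break
        dist = new
    return dist


def ril_observed_R(pop: PopulationType, r: float) -> float:
    """Expected recombinant fraction among fixed RIL/IRIL lines.

    For selfing-to-fixation RILs this is the Haldane–Waddington value
    2r/(1+2r); finite-generation RILn and IRIL values are obtained by
    iterating the two-locus genotype transition chain and conditioning
    on double homozygosity.
    """
    r = float(r)
    if not 0.0 <= r <= 0.5:
        raise ValueError("r must lie in [0, 0.5]")
    if pop.kind == "RIL" and pop.selfing_generations is None:
        return 2.0 * r / (1.0 + 2.0 * r)
    dist = _two_locus_genotype_dist(pop, r)
    p_fix = sum(dist[4 * h + h] for h in range(4))
    p_rec = sum(dist[4 * h + h] for h in _RECOMB_HAPS)
    if p_fix <= 0:
        return 0.0
    return p_rec / p_fix


class RilTransform:
    """Fast vectorized r <-> R maps for a RIL/IRIL population.

    Fixation RILs use the closed form; other designs use a monotone
    PCHIP interpolant of the exact chain evaluated on a fine r grid.
    """

    def __init__(self, pop: PopulationType, grid_step: float = 1e-3):
        self.pop = pop
        self._closed = pop.kind == "RIL" and pop.selfing_generations is None
        if not self._closed:
            grid = np.arange(0.0, 0.5 + grid_step / 2, grid_step)
            vals = np.array([ril_observed_R(pop, float(g)) for g in grid])
            self._fwd = PchipInterpolator(grid, vals)
            # R is strictly increasing in r for any sensible design
            self._inv = PchipInterpolator(vals, grid)
            self._rmax = float(vals[-1])

    def R(self, r):
        r = np.asarray(r, dtype=float)
        if self._closed:
            out = 2.0 * r / (1.0 + 2.0 * r)
        else:
            out = self._fwd(np.clip(r, 0.0, 0.5))
        return float(out) if out.ndim == 0 else out

    def r(self, R):
        R = np.asarray(R, dtype=float)
        if self._closed:
            out = np.clip(R, 0.0, 0.5) / np.maximum(2.0 * (1.0 - np.clip(R, 0.0, 0.5)), 1e-12)
        else:
            out = self._inv(np.clip(R, 0.0, self._rmax))
        out = np.clip(out, 0.0, 0.5)
        return float(out) if out.ndim == 0 else out


@lru_cache(maxsize=16)
def _ril_transform_cached(kind: str, selfing, intermating) -> RilTransform:
    return RilTransform(
        PopulationType(kind, selfing_generations=selfing, intermating_generations=intermating)
    )


def ril_transform(pop: PopulationType) -> RilTransform:
    return _ril_transform_cached(pop.kind, pop.selfing_generations, pop.intermating_generations)


# ------------------------------------------------------------------ coefficient tables

# Compatibility of observed inbred codes with ordered single-locus
# genotypes (maternal allele, paternal allele), alleles in {0=A, 1=B}.
_F2_COMPAT = {
    0: {(0, 0)},  # A
    1: {(0, 1), (1, 0)},  # H
    2: {(1, 1)},  # B
    3: {(0, 1), (1, 0), (1, 1)},  # C = not A
    4: {(0, 0), (0, 1), (1, 0)},  # D = not B
}


@lru_cache(maxsize=8)
def _inbred_pair_table(kind: str) -> tuple[np.ndarray, int, int]:
    """(N, M, n_codes) for an inbred population kind.

    ``N`` has shape (n_codes * n_codes, M + 1): configuration counts per
    observed code combo and number of recombinant meioses.  RIL/IRIL
    tables live on the observed-R scale with heterozygous calls treated
    as uninformative (excluded upstream).
    """
    if kind in ("BC", "DH", "RIL", "IRIL"):
        # one meiosis-equivalent; codes A(0), B(2) mapped to compact 0/1
        n_codes, M = 2, 1
        N = np.zeros((4, 2))
        for x1, x2 in itertools.product((0, 1), repeat=2):
            m = int(x1 != x2)
            N[(x1 * 2 + x2), m] += 1
        return N, M, n_codes
    if kind == "F2":
        n_codes, M = 5, 2
        N = np.zeros((25, 3))
        haps = list(itertools.product((0, 1), repeat=2))  # (allele at locus1, locus2)
        for mat, pat in itertools.product(haps, repeat=2):
            m = int(mat[0] != mat[1]) + int(pat[0] != pat[1])
            g1 = (mat[0], pat[0])
            g2 = (mat[1], pat[1])
            for c1 in range(5):
                if g1 not in _F2_COMPAT[c1]:
                    continue
                for c2 in range(5):
                    if g2 in _F2_COMPAT[c2]:
                        N[c1 * 5 + c2, m] += 1
        return N, M, n_codes
    raise ValueError(kind)


def _compact_inbred_codes(dataset: SegregationDataset) -> tuple[np.ndarray, int]:
    """Recode genotypes to the compact alphabet used by the pair tables."""
    kind = dataset.population.kind
    G = dataset.genotypes
    if kind == "F2":
        return G.astype(np.int8), 5
    # A -> 0, B -> 1; H (RIL residual heterozygotes) and dominants -> missing
    out = np.full_like(G, MISSING)
    out[G == 0] = 0
    out[G == 2] = 1
    return out, 2


def _cp_pair_key(info: CPMarkerInfo) -> tuple:
    return (info.parent1, info.parent2, tuple(info.classes))


@lru_cache(maxsize=4096)
def _cp_pair_tables_cached(key_i: tuple, key_j: tuple):
    p1_i, p2_i, cls_i = key_i
    p1_j, p2_j, cls_j = key_j
    het1 = p1_i[0] != p1_i[1] and p1_j[0] != p1_j[1]
    het2 = p2_i[0] != p2_i[1] and p2_j[0] != p2_j[1]
    M = int(het1) + int(het2)
    phase_axes = []
    if het1:
        phase_axes.append((0, 1))
    if het2:
        phase_axes.append((0, 1))
    phase_combos = list(itertools.product(*phase_axes)) if phase_axes else [()]
    idx_i = {c: k for k, c in enumerate(cls_i)}
    idx_j = {c: k for k, c in enumerate(cls_j)}
    Ci, Cj = len(cls_i), len(cls_j)
    tables = {}
    for combo in phase_combos:
        N = np.zeros((Ci * Cj, M + 1))
        it = iter(combo)
        phase1 = next(it) if het1 else None
        phase2 = next(it) if het2 else None
        for u1, v1, u2, v2 in itertools.product((0, 1), repeat=4):
            m = 0
            if het1:
                rec = (u1 != v1) if phase1 == 0 else (u1 == v1)
                m += int(rec)
            if het2:
                rec = (u2 != v2) if phase2 == 0 else (u2 == v2)
                m += int(rec)
            gi = "".join(sorted(p1_i[u1] + p2_i[u2]))
            gj = "".join(sorted(p1_j[v1] + p2_j[v2]))
            N[idx_i[gi] * Cj + idx_j[gj], m] += 1
        tables[combo] = N
    return M, phase_combos, tables, (het1, het2)


def _cp_pair_tables(info_i: CPMarkerInfo, info_j: CPMarkerInfo):
    """Coefficient tables for a CP marker pair, one per relative-phase combo."""
    return _cp_pair_tables_cached(_cp_pair_key(info_i), _cp_pair_key(info_j))


# ------------------------------------------------------------------ vectorized EM


def _informative_class_mask(N: np.ndarray, M: int) -> np.ndarray:
    """True for observed combos whose probability actually depends on r."""
    from math import comb

    binom = np.array([comb(M, m) for m in range(M + 1)], dtype=float)
    binom /= binom.sum()
    mask = np.zeros(N.shape[0], dtype=bool)
    for c in range(N.shape[0]):
        s = N[c].sum()
        if s <= 0:
            continue
        mask[c] = not np.allclose(N[c] / s, binom, atol=1e-12)
    return mask


def _pair_loglik(counts: np.ndarray, N: np.ndarray, M: int, r: np.ndarray) -> np.ndarray:
    """Natural-log likelihood (up to a constant) per pair at rate(s) r."""
    m = np.arange(M + 1)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    W = r[:, None] ** m * (1 - r[:, None]) ** (M - m)  # (P, M+1)
    pclass = W @ N.T  # (P, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(pclass > 0, np.log(np.maximum(pclass, 1e-300)), -690.0)
    return (counts * logp).sum(axis=1)


def _em_pairs(
    counts: np.ndarray,
    N: np.ndarray,
    M: int,
    r0: float = 0.25,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
):
    """Vectorized 2-point EM over many pairs sharing one coefficient table.

    counts: (P, C) observed combo counts per pair; N: (C, M+1).
    Returns (r_hat, lod, n_informative, informative) arrays of length P.
    """
    counts = np.asarray(counts, dtype=float)
    P = counts.shape[0]
    m = np.arange(M + 1, dtype=float)
    valid_class = N.sum(axis=1) > 0
    ntot = counts[:, valid_class].sum(axis=1)
    inf_mask = _informative_class_mask(N, M)
    n_inf = counts[:, inf_mask].sum(axis=1)
    informative = (n_inf > 0) & (ntot > 0) & (M > 0)

    r = np.full(P, r0)
    ll = _pair_loglik(counts, N, M, r)
    for _ in range(max_iter):
        W = r[:, None] ** np.arange(M + 1) * (1 - r[:, None]) ** (M - np.arange(M + 1))
        num = W * m  # weight * m
        pclass = W @ N.T  # (P, C)
        eclass = num @ N.T  # (P, C): Σ_m m N W
        with np.errstate(divide="ignore", invalid="ignore"):
            Em = np.where(pclass > 0, eclass / np.maximum(pclass, 1e-300), 0.0)
        Erec = (counts * Em).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_new = np.where(ntot > 0, Erec / np.maximum(M * ntot, 1e-300), np.nan)
        r_new = np.clip(r_new, R_MIN, R_MAX)
        r = np.where(informative, r_new, r)
        ll_new = _pair_loglik(counts, N, M, r)
        delta = np.abs(ll_new - ll)
        ll = ll_new
        if delta.max(initial=0.0) < tol * max(1.0, np.abs(ll).max(initial=1.0)):
            break

    ll_half = _pair_loglik(counts, N, M, np.full(P, 0.5))
    lod = np.maximum((ll - ll_half) / LN10, 0.0)
    r_out = np.where(informative, r, np.nan)
    lod = np.where(informative, lod, 0.0)
    return r_out, lod, n_inf, informative


# ------------------------------------------------------------------ public 2-point API


@dataclass
class TwoPointResult:
    """Two-point linkage estimate for one marker pair.

    phase: for CP pairs, one character per parent — 'c' coupling,
    'r' repulsion, '-' not applicable; None for inbred populations.
    """

    r_hat: float
    lod: float
    n_informative: int
    informative: bool
    phase: str | None = None
    phase_ambiguous: bool = False


class PopulationModel:
    """Hidden-state bookkeeping shared by 2-point and multipoint code.

    BC/DH: 2 states (transmitted gamete allele).  F2: 4 phase-ordered
    genotypes (maternal allele x paternal allele).  RIL/IRIL: 2
    fixed-line states with the r -> R transition transform.  CP: 4
    states (which homolog each parent transmitted).
    """

    def __init__(self, population: PopulationType):
        self.population = population
        kind = population.kind
        if kind in ("BC", "DH"):
            self.n_states, self.n_chains = 2, 1
        elif kind in ("RIL", "IRIL"):
            self.n_states, self.n_chains = 2, 1
        else:  # F2, CP
            self.n_states, self.n_chains = 4, 2
        self.ril = ril_transform(population) if kind in ("RIL", "IRIL") else None

    def transition(self, r: float) -> np.ndarray:
        """Row-stochastic transition matrix between adjacent loci."""
        rr = self.ril.R(r) if self.ril is not None else r
        T2 = np.array([[1 - rr, rr], [rr, 1 - rr]])
        if self.n_states == 2:
            return T2
        T2r = np.array([[1 - r, r], [r, 1 - r]])
        return np.kron(T2r, T2r)

    @property
    def initial(self) -> np.ndarray:
        return np.full(self.n_states, 1.0 / self.n_states)


def _pair_counts(col_i: np.ndarray, col_j: np.ndarray, n_codes: int) -> np.ndarray:
    """Observed combo counts for one pair, co-typed individuals only."""
    ok = (col_i != MISSING) & (col_j != MISSING)
    combo = col_i[ok].astype(np.int64) * n_codes + col_j[ok].astype(np.int64)
    return np.bincount(combo, minlength=n_codes * n_codes).astype(float)


def estimate_two_point(
    dataset: SegregationDataset, marker_i: str | int, marker_j: str | int
) -> TwoPointResult:
    """Two-point EM estimate of recombination fraction and LOD for a pair.

    For CP pairs the likelihood is maximized jointly over the relative
    parental phase configurations; the reported phase is the argmax.
    For RIL/IRIL the likelihood lives on the observed-R scale and the
    reported r is the inverse transform of the fitted R.
    """
    i = dataset.marker_index(marker_i) if isinstance(marker_i, str) else marker_i
    j = dataset.marker_index(marker_j) if isinstance(marker_j, str) else marker_j
    if i == j:
        raise ValueError("markers must be distinct")
    pop = dataset.population

    if pop.is_cp:
        info_i, info_j = dataset.cp_info[i], dataset.cp_info[j]
        M, combos, tables, (het1, het2) = _cp_pair_tables(info_i, info_j)
        Cj = len(info_j.classes)
        counts = _pair_counts_cp(
            dataset.genotypes[i], dataset.genotypes[j], len(info_i.classes), Cj
        )
        best = None
        lls = []
        for combo in combos:
            N = tables[combo]
            r, lod, n_inf, inf = _em_pairs(counts[None, :], N, M)
            ll = lod[0]  # same baseline across phases, so LOD ranks phases
            lls.append(ll)
            if best is None or ll > best[0] + 1e-12:
                best = (ll, combo, r[0], lod[0], n_inf[0], inf[0])
        ll_sorted = sorted(lls, reverse=True)
        ambiguous = len(lls) > 1 and (ll_sorted[0] - ll_sorted[1]) < 1e-9 and best[5]
        _, combo, r_hat, lod, n_inf, inf = best
        it = iter(combo)
        phase = ""
        phase += ("c" if next(it) == 0 else "r") if het1 else "-"
        phase += ("c" if next(it) == 0 else "r") if het2 else "-"
        if ambiguous:
            phase = "--"
        return TwoPointResult(
            r_hat=float(r_hat) if inf else float("nan"),
            lod=float(lod),
            n_informative=int(n_inf),
            informative=bool(inf),
            phase=phase if inf else None,
            phase_ambiguous=bool(ambiguous),
        )

    G, n_codes = _compact_inbred_codes(dataset)
    N, M, _ = _inbred_pair_table(pop.kind)
    counts = _pair_counts(G[i], G[j], n_codes)
    r, lod, n_inf, inf = _em_pairs(counts[None, :], N, M)
    r_hat = float(r[0])
    if pop.kind in ("RIL", "IRIL") and np.isfinite(r_hat):
        r_hat = float(ril_transform(pop).r(r_hat))
    return TwoPointResult(
        r_hat=r_hat if inf[0] else float("nan"),
        lod=float(lod[0]),
        n_informative=int(n_inf[0]),
        informative=bool(inf[0]),
    )


def _pair_counts_cp(col_i, col_j, Ci: int, Cj: int) -> np.ndarray:
    ok = (col_i != MISSING) & (col_j != MISSING)
    combo = col_i[ok].astype(np.int64) * Cj + col_j[ok].astype(np.int64)
    return np.bincount(combo, minlength=Ci * Cj).astype(float)


def two_point_matrix(dataset: SegregationDataset) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric matrices of pairwise (r_hat, LOD) over all markers.

    Diagonal entries are NaN sentinels; uninformative pairs hold LOD 0
    and r NaN.  Computation is vectorized across pairs grouped by
    coefficient-table signature.
    """
    Mk = dataset.n_markers
    r_mat = np.full((Mk, Mk), np.nan)
    lod_mat = np.zeros((Mk, Mk))
    iu, ju = np.triu_indices(Mk, k=1)
    pop = dataset.population

    if not pop.is_cp:
        G, n_codes = _compact_inbred_codes(dataset)
        N, M, _ = _inbred_pair_table(pop.kind)
        onehot = np.stack([(G == c).astype(np.float32) for c in range(n_codes)])
        counts_full = np.einsum("cmn,dkn->cdmk", onehot, onehot)  # (C, C, Mk, Mk)
        counts = counts_full[:, :, iu, ju].reshape(n_codes * n_codes, -1).T  # (P, C*C)
        r, lod, _, inf = _em_pairs(counts, N, M)
        if pop.kind in ("RIL", "IRIL"):
            ok = np.isfinite(r)
            r[ok] = ril_transform(pop).r(r[ok])
        r_mat[iu, ju] = r
        r_mat[ju, iu] = r
        lod_mat[iu, ju] = lod
        lod_mat[ju, iu] = lod
        return r_mat, lod_mat

    # CP: group pairs by the parental-genotype signature of both markers
    keys = [_cp_pair_key(info) for info in dataset.cp_info]
    max_c = max(len(info.classes) for info in dataset.cp_info)
    G = dataset.genotypes
    onehot = np.stack([(G == c).astype(np.float32) for c in range(max_c)])
    counts_full = np.einsum("cmn,dkn->cdmk", onehot, onehot)

    groups: dict[tuple, list[int]] = {}
    for p in range(len(iu)):
        groups.setdefault((keys[iu[p]], keys[ju[p]]), []).append(p)

    for (key_i, key_j), rows in groups.items():
        M, combos, tables, _ = _cp_pair_tables_cached(key_i, key_j)
        Ci, Cj = len(key_i[2]), len(key_j[2])
        rows = np.asarray(rows)
        sub_i, sub_j = iu[rows], ju[rows]
        counts = (
            counts_full[:Ci, :Cj, sub_i, sub_j].reshape(Ci * Cj, -1).T
        )  # (P_g, Ci*Cj)
        best_lod = np.full(len(rows), -np.inf)
        best_r = np.full(len(rows), np.nan)
        any_inf = np.zeros(len(rows), dtype=bool)
        for combo in combos:
            r, lod, _, inf = _em_pairs(counts, tables[combo], M)
            better = lod > best_lod
            best_lod = np.where(better, lod, best_lod)
            best_r = np.where(better, r, best_r)
            any_inf |= inf
        best_lod = np.where(any_inf, best_lod, 0.0)
        best_r = np.where(any_inf, best_r, np.nan)
        r_mat[sub_i, sub_j] = best_r
        r_mat[sub_j, sub_i] = best_r
        lod_mat[sub_i, sub_j] = best_lod
        lod_mat[sub_j, sub_i] = best_lod
    return r_mat, lod_mat


# ------------------------------------------------------------------ expected joint frequencies


def expected_joint_freqs(
    pop: PopulationType,
    r: float,
    cp_pair: tuple[CPMarkerInfo, CPMarkerInfo] | None = None,
    phases: tuple | None = None,
) -> dict[tuple[str, str], float]:
    """Expected 2-locus observed-class probabilities at recombination r.

    Inbred populations return probabilities over codominant code pairs
    (A/B for BC/DH, A/H/B for F2 and RIL/IRIL; RIL/IRIL include residual
    heterozygosity from the generation scheme).  CP requires the marker
    pair's parental info and a relative phase combo.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError("r must lie in [0, 0.5]")
    kind = pop.kind
    if kind in ("BC", "DH"):
        codes = ("A", "B")
        N, M, n = _inbred_pair_table(kind)
        out = {}
        for c1 in range(2):
            for c2 in range(2):
                w = sum(
                    N[c1 * 2 + c2, m] * r**m * (1 - r) ** (M - m) for m in range(M + 1)
                )
                out[(codes[c1], codes[c2])] = w / 2.0
        return out
    if kind == "F2":
        codes = ("A", "H", "B")
        N, M, n = _inbred_pair_table(kind)
        out = {}
        for c1 in range(3):
            for c2 in range(3):
                w = sum(
                    N[c1 * 5 + c2, m] * r**m * (1 - r) ** (M - m) for m in range(M + 1)
                )
                out[(codes[c1], codes[c2])] = w / 4.0
        return out
    if kind in ("RIL", "IRIL"):
        dist = _two_locus_genotype_dist(pop, r)
        code_of = {0: "A", 1: "H", 2: "B"}  # allele-sum at a locus
        out: dict[tuple[str, str], float] = {}
        for h1 in range(4):
            for h2 in range(4):
                p = dist[4 * h1 + h2]
                if p == 0:
                    continue
                a = (h1 >> 1) + (h2 >> 1)
                b = (h1 & 1) + (h2 & 1)
                key = (code_of[a], code_of[b])
                out[key] = out.get(key, 0.0) + p
        return out
    if kind == "CP":
        if cp_pair is None:
            raise ValueError("CP joint frequencies require the marker pair's parental info")
        info_i, info_j = cp_pair
        M, combos, tables, _ = _cp_pair_tables(info_i, info_j)
        combo = tuple(phases) if phases is not None else combos[0]
        N = tables[combo]
        Cj = len(info_j.classes)
        raw = np.array(
            [
                sum(N[c, m] * r**m * (1 - r) ** (M - m) for m in range(M + 1))
                for c in range(N.shape[0])
            ]
        )
        raw = raw / raw.sum()
        return {
            (info_i.classes[c // Cj], info_j.classes[c % Cj]): float(raw[c])
            for c in range(len(raw))
        }
    raise ValueError(kind)
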