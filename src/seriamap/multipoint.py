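"""Multipoint likelihood of ordered markers as an HMM over loci.

Hidden states follow the transmitted parental material along each
chromosome: 2 states for BC/DH (which F1 gamete allele), 4 phase-ordered
genotypes for F2 (maternal x paternal allele), 2 fixed-line states for
RIL/IRIL (with the r -> R transition transform and residual
heterozygosity absorbed into the emission), and 4 states for CP (which
homolog each parent transmitted).  Transitions between adjacent loci are
governed by per-interval recombination fractions; genotyping errors
enter through an emission error rate ``epsilon``; missing observations
emit 1 for every state, which is how missing data are imputed in all
multipoint computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .models import (
    PopulationModel,
    haldane_d_to_r,
    haldane_r_to_d,
    ril_transform,
)
from .types import MISSING, PopulationType, SegregationDataset

LN10 = np.log(10.0)
DEFAULT_EPSILON = 0.01
EM_TOL_LOG10 = 1e-6
EM_MAX_ITER = 100

# grid of relative positions probed inside an interval when scanning
# candidate insertions; refined by bounded optimization afterwards
T_GRID = np.array([0.02, 0.1, 0.25, 0.5, 0.75, 0.9, 0.98])
# candidate distances (cM) probed beyond the current map ends
END_D_GRID = np.array([0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 12.0, 18.0, 25.0, 35.0])


@dataclass
class MultipointModel:
    """Ordered markers + per-interval recombination fractions.

    ``phases`` (CP only) has one row per locus and one column per
    parent: 0/1 chooses which parental allele sits on homolog 1,
    -1 marks a parent homozygous at that marker (no phase).
    """

    population: PopulationType
    marker_indices: list[int]
    r: np.ndarray
    epsilon: float = DEFAULT_EPSILON
    phases: np.ndarray | None = None
    pmodel: PopulationModel = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        L = len(self.marker_indices)
        if L < 2:
            raise ValueError("a multipoint model needs at least 2 markers")
        if self.r.shape != (L - 1,):
            raise ValueError(f"expected {L - 1} interval r values, got {self.r.shape}")
        if np.any((self.r < 0) | (self.r > 0.5)):
            raise ValueError("interval r values must lie in [0, 0.5]")
        if self.population.is_cp:
            if self.phases is None:
                raise ValueError("CP models require per-marker phases")
            self.phases = np.asarray(self.phases, dtype=np.int8)
            if self.phases.shape != (L, 2):
                raise ValueError("phases must have shape (n_markers, 2)")
        self.pmodel = PopulationModel(self.population)

    @property
    def n_loci(self) -> int:
        return len(self.marker_indices)

    def distances_cM(self) -> np.ndarray:
        return np.asarray(haldane_r_to_d(np.minimum(self.r, 0.499999)))

    def reversed(self) -> "MultipointModel":
        ph = self.phases[::-1].copy() if self.phases is not None else None
        return replace(
            self,
            marker_indices=list(reversed(self.marker_indices)),
            r=self.r[::-1].copy(),
            phases=ph,
        )


# ------------------------------------------------------------------ emissions


def _residual_het(pop: PopulationType) -> float:
    """Expected residual single-locus heterozygosity of a RIL/IRIL line."""
    if pop.kind == "RIL":
        if pop.selfing_generations is None:
            return 0.0
        return 0.5**pop.selfing_generations
    if pop.kind == "IRIL":
        return 0.0  # selfed to fixation after intermating
    return 0.0


def _error_channel(eps: float, k: int) -> np.ndarray:
    """k x k confusion matrix: observed = true w.p. 1-eps, else uniform."""
    if k == 1:
        return np.ones((1, 1))
    C = np.full((k, k), eps / (k - 1))
    np.fill_diagonal(C, 1.0 - eps)
    return C


def emission_table(
    model: MultipointModel, dataset: SegregationDataset, locus: int, eps: float | None = None
) -> np.ndarray:
    """Emission lookup for one locus: rows = observed code (+missing), cols = states.

    The final row is the all-ones missing row, addressed by code -1.
    """
    eps = model.epsilon if eps is None else eps
    pop = model.population
    S = model.pmodel.n_states
    if pop.is_cp:
        m = model.marker_indices[locus]
        info = dataset.cp_info[m]
        K = len(info.classes)
        phase = model.phases[locus]
        pred = np.zeros(4, dtype=int)  # predicted class per state (h1, h2)
        for s in range(4):
            h1, h2 = s >> 1, s & 1
            a1 = info.parent1[(h1 ^ phase[0]) if phase[0] >= 0 else 0]
            a2 = info.parent2[(h2 ^ phase[1]) if phase[1] >= 0 else 0]
            pred[s] = info.class_index(a1 + a2)
        chan = _error_channel(eps, K)
        E = np.ones((K + 1, 4))
        for s in range(4):
            E[:K, s] = chan[pred[s]]
        return E

    kind = pop.kind
    if kind in ("BC", "DH"):
        chan = _error_channel(eps, 2)  # over codes A, B
        E = np.ones((6, 2))
        E[0] = chan[0]  # obs A
        E[2] = chan[1]  # obs B
        return E
    if kind == "F2":
        # states s = 2*mat + pat; true codominant code A/H/B
        true_code = np.array([0, 1, 1, 2])
        chan = _error_channel(eps, 3)  # over A, H, B
        E = np.ones((6, 4))
        for s in range(4):
            p = chan[true_code[s]]  # P(obs A/H/B | state)
            E[0, s], E[1, s], E[2, s] = p[0], p[1], p[2]
            E[3, s] = p[1] + p[2]  # C = not A
            E[4, s] = p[0] + p[1]  # D = not B
        return E
    # RIL / IRIL: 2 fixed-line states, residual hets in the emission
    h = _residual_het(pop)
    chan = _error_channel(eps, 3)
    E = np.ones((6, 2))
    for s, codes in ((0, (0, 1)), (1, (2, 1))):  # (homozygous code, H)
        hom, het = codes
        p = (1 - h) * chan[hom] + h * chan[het]
        E[0, s], E[1, s], E[2, s] = p[0], p[1], p[2]
    return E


def _obs_emissions(
    model: MultipointModel, dataset: SegregationDataset, eps: float | None = None
) -> np.ndarray:
    """Per-locus, per-individual emission vectors, shape (L, n, S)."""
    L = model.n_loci
    n = dataset.n_individuals
    S = model.pmodel.n_states
    out = np.empty((L, n, S))
    for k in range(L):
        table = emission_table(model, dataset, k, eps=eps)
        obs = dataset.genotypes[model.marker_indices[k]].astype(np.int64)
        obs = np.where(obs == MISSING, table.shape[0] - 1, obs)
        out[k] = table[obs]
    return out


def compatibility_tables(model: MultipointModel, dataset: SegregationDataset) -> np.ndarray:
    """Binary compatibility of each observed call with each state (eps = 0)."""
    comp = _obs_emissions(model, dataset, eps=0.0)
    return (comp > 1e-9).astype(float)


def _transitions(model: MultipointModel) -> np.ndarray:
    return np.stack([model.pmodel.transition(float(rk)) for rk in model.r])


# ------------------------------------------------------------------ forward/backward


@dataclass
class _FB:
    a: np.ndarray  # (L, n, S) scaled forward
    b: np.ndarray  # (L, n, S) scaled backward
    c: np.ndarray  # (L, n) per-locus scale factors
    E: np.ndarray  # (L, n, S) per-observation emissions
    loglik10: float

    @property
    def gamma(self) -> np.ndarray:
        return self.a * self.b


def _forward_backward(model: MultipointModel, dataset: SegregationDataset) -> _FB:
    E = _obs_emissions(model, dataset)
    T = _transitions(model)
    L, n, S = E.shape
    a = np.empty((L, n, S))
    c = np.empty((L, n))
    pi = model.pmodel.initial
    cur = pi[None, :] * E[0]
    c[0] = cur.sum(axis=1)
    a[0] = cur / np.maximum(c[0][:, None], 1e-300)
    for k in range(1, L):
        cur = (a[k - 1] @ T[k - 1]) * E[k]
        c[k] = cur.sum(axis=1)
        a[k] = cur / np.maximum(c[k][:, None], 1e-300)
    b = np.empty((L, n, S))
    b[L - 1] = 1.0
    for k in range(L - 2, -1, -1):
        b[k] = (E[k + 1] * b[k + 1]) @ T[k].T
        b[k] /= np.maximum(c[k + 1][:, None], 1e-300)
    loglik10 = float(np.log10(np.maximum(c, 1e-300)).sum())
    return _FB(a=a, b=b, c=c, E=E, loglik10=loglik10)


def multipoint_loglik(model: MultipointModel, dataset: SegregationDataset) -> float:
    """log10 likelihood of the dataset under the ordered model."""
    E = _obs_emissions(model, dataset)
    T = _transitions(model)
    L, n, S = E.shape
    pi = model.pmodel.initial
    cur = pi[None, :] * E[0]
    tot = np.zeros(n)
    s0 = cur.sum(axis=1)
    tot += np.log10(np.maximum(s0, 1e-300))
    cur /= np.maximum(s0[:, None], 1e-300)
    for k in range(1, L):
        cur = (cur @ T[k - 1]) * E[k]
        sk = cur.sum(axis=1)
        tot += np.log10(np.maximum(sk, 1e-300))
        cur /= np.maximum(sk[:, None], 1e-300)
    return float(tot.sum())


def _hamming_matrix(S: int) -> np.ndarray:
    H = np.zeros((S, S))
    for s in range(S):
        for t in range(S):
            H[s, t] = bin(s ^ t).count("1") if S == 4 else float(s != t)
    return H


def em_fit_intervals(
    model: MultipointModel,
    dataset: SegregationDataset,
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL_LOG10,
) -> tuple[np.ndarray, float, bool]:
    """Baum–Welch fit of the per-interval recombination fractions.

    Returns (fitted r, final log10 likelihood, converged flag).  The
    log-likelihood is non-decreasing across iterations; non-convergence
    after ``max_iter`` returns the best-so-far fit with the flag False.
    Missing observations contribute through their flat emission, which
    is how the EM imputes them.
    """
    r = model.r.copy()
    n = dataset.n_individuals
    S = model.pmodel.n_states
    H = _hamming_matrix(S)
    chains = model.pmodel.n_chains
    is_ril = model.pmodel.ril is not None
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        mdl = replace(model, r=r)
        fb = _forward_backward(mdl, dataset)
        if fb.loglik10 < prev_ll - 1e-9:
            break  # numerical stall; keep best-so-far
        if abs(fb.loglik10 - prev_ll) < tol:
            prev_ll = fb.loglik10
            converged = True
            break
        prev_ll = fb.loglik10
        T = _transitions(mdl)
        new_r = np.empty_like(r)
        for k in range(len(r)):
            # xi[s, s'] summed over individuals, normalized per individual
            right = fb.E[k + 1] * fb.b[k + 1] / np.maximum(fb.c[k + 1][:, None], 1e-300)
            xi = np.einsum("ns,st,nt->st", fb.a[k], T[k], right)
            erec = float((xi * H).sum())
            frac = erec / (chains * n)
            if is_ril:
                new_r[k] = model.pmodel.ril.r(min(frac, 0.499999))
            else:
                new_r[k] = frac
        r = np.clip(new_r, 1e-6, 0.5)
    return r, prev_ll, converged


@dataclass
class PosteriorGenotypes:
    """Forward–backward posteriors over hidden states, (L, n, S)."""

    probs: np.ndarray
    marker_indices: list[int]

    def argmax(self) -> np.ndarray:
        """Most probable hidden state per (locus, individual)."""
        return self.probs.argmax(axis=2)


def impute_posteriors(
    model: MultipointModel, dataset: SegregationDataset
) -> PosteriorGenotypes:
    fb = _forward_backward(model, dataset)
    g = fb.gamma
    g = g / np.maximum(g.sum(axis=2, keepdims=True), 1e-300)
    return PosteriorGenotypes(probs=g, marker_indices=list(model.marker_indices))


# ------------------------------------------------------------------ fitted chain + scans


def _cp_phase_variants(
    dataset: SegregationDataset, marker: int
) -> list[np.ndarray]:
    """All phase rows (one per parent) for a CP marker; [-1] where homozygous."""
    info = dataset.cp_info[marker]
    opts1 = (0, 1) if info.het1 else (-1,)
    opts2 = (0, 1) if info.het2 else (-1,)
    return [np.array(p, dtype=np.int8) for p in
            [(a, b) for a in opts1 for b in opts2]]


def candidate_emissions(
    model: MultipointModel, dataset: SegregationDataset, marker: int
) -> tuple[list[np.ndarray], list[np.ndarray | None]]:
    """Per-observation emission vectors (n, S) for a candidate marker.

    Returns one entry per phase variant (a single entry for inbred
    populations, up to four for CP markers).
    """
    if not model.population.is_cp:
        stub = replace(model, marker_indices=[marker, marker], r=np.array([0.25]), phases=None)
        table = emission_table(stub, dataset, 0)
        obs = dataset.genotypes[marker].astype(np.int64)
        obs = np.where(obs == MISSING, table.shape[0] - 1, obs)
        return [table[obs]], [None]
    out, phases = [], []
    for ph in _cp_phase_variants(dataset, marker):
        stub = replace(
            model,
            marker_indices=[marker, marker],
            r=np.array([0.25]),
            phases=np.stack([ph, ph]),
        )
        table = emission_table(stub, dataset, 0)
        obs = dataset.genotypes[marker].astype(np.int64)
        obs = np.where(obs == MISSING, table.shape[0] - 1, obs)
        out.append(table[obs])
        phases.append(ph)
    return out, phases


@dataclass
class InsertionScan:
    """Profile of one candidate marker against a fitted chain.

    ``positions`` lists (kind, index): ('start', -1), ('interval', k)
    for insertion between loci k and k+1, ('end', L-1).  ``dll`` holds
    the log10-likelihood gain at each position (maximized over the
    within-interval position grid and phase variants), ``detail`` the
    maximizing relative position t (intervals) or distance in cM (ends),
    and ``phase`` the maximizing phase row for CP candidates.
    """

    positions: list[tuple[str, int]]
    dll: np.ndarray
    detail: np.ndarray
    phase: list[np.ndarray | None]

    def best(self) -> int:
        return int(np.argmax(self.dll))

    def gap(self) -> float:
        """log10 gap between the best and second-best position."""
        if len(self.dll) < 2:
            return np.inf
        srt = np.sort(self.dll)[::-1]
        return float(srt[0] - srt[1])


class FittedChain:
    """A fitted multipoint model with cached forward/backward factors.

    Supports O(n S^2) evaluation of single-marker insertions at any
    interval without re-running the full chain, which is the workhorse
    of scaffold elongation, framework densification, placement and
    order-robustness checks.
    """

    def __init__(self, model: MultipointModel, dataset: SegregationDataset):
        self.model = model
        self.dataset = dataset
        self.fb = _forward_backward(model, dataset)
        self.loglik10 = self.fb.loglik10
        # right factor at each locus: E_k * b_k / c_k
        self.right = self.fb.E * self.fb.b / np.maximum(self.fb.c[:, :, None], 1e-300)

    @property
    def distances(self) -> np.ndarray:
        return self.model.distances_cM()

    def _trans(self, r: np.ndarray) -> np.ndarray:
        pm = self.model.pmodel
        r = np.atleast_1d(r)
        return np.stack([pm.transition(float(v)) for v in r])

    def _interval_ratio(
        self, k: int, Ec: np.ndarray, ra: float, rb: float
    ) -> np.ndarray:
        """Per-individual likelihood ratio for inserting Ec inside interval k."""
        Ta = self.model.pmodel.transition(ra)
        Tb = self.model.pmodel.transition(rb)
        u = self.fb.a[k] @ Ta  # (n, S)
        v = self.right[k + 1] @ Tb.T  # (n, S)
        return np.maximum((u * Ec * v).sum(axis=1), 1e-300)

    def _end_ratio(self, side: str, Ec: np.ndarray, r: float) -> np.ndarray:
        T = self.model.pmodel.transition(r)
        pi = self.model.pmodel.initial
        if side == "start":
            u = (pi[None, :] * Ec) @ T  # (n, S)
            return np.maximum((u * self.right[0]).sum(axis=1), 1e-300)
        u = self.fb.a[-1] @ T
        return np.maximum((u * Ec).sum(axis=1), 1e-300)

    def insertion_dll(self, pos: tuple[str, int], Ec: np.ndarray, param: float) -> float:
        """log10 likelihood gain at one position; param = t (interval) or d (end)."""
        kind, k = pos
        if kind == "interval":
            d = haldane_r_to_d(min(float(self.model.r[k]), 0.499999))
            t = min(max(param, 1e-4), 1 - 1e-4)
            ra = haldane_d_to_r(t * d)
            rb = haldane_d_to_r((1 - t) * d)
            ratio = self._interval_ratio(k, Ec, float(ra), float(rb))
        else:
            ratio = self._end_ratio(kind, Ec, float(haldane_d_to_r(param)))
        return float(np.log10(ratio).sum())

    def scan_marker(
        self,
        marker: int,
        t_grid: np.ndarray = T_GRID,
        end_d_grid: np.ndarray = END_D_GRID,
        refine_top: int = 2,
    ) -> InsertionScan:
        """Evaluate a candidate at every interval and both map ends."""
        Ecs, phase_rows = candidate_emissions(self.model, self.dataset, marker)
        L = self.model.n_loci
        positions: list[tuple[str, int]] = [("start", -1)]
        positions += [("interval", k) for k in range(L - 1)]
        positions.append(("end", L - 1))
        P = len(positions)
        dll = np.full(P, -np.inf)
        detail = np.zeros(P)
        phase: list[np.ndarray | None] = [None] * P

        d_all = self.distances
        for pi_, pos in enumerate(positions):
            kind, k = pos
            if kind == "interval":
                params = t_grid
            else:
                params = end_d_grid
            for v, Ec in enumerate(Ecs):
                for prm in params:
                    val = self.insertion_dll(pos, Ec, float(prm))
                    if val > dll[pi_]:
                        dll[pi_] = val
                        detail[pi_] = prm
                        phase[pi_] = phase_rows[v]

        # refine the top positions with bounded scalar optimization
        order = np.argsort(dll)[::-1][:refine_top]
        for pi_ in order:
            kind, k = positions[pi_]
            Ec = None
            for v, ph in enumerate(phase_rows):
                if (ph is None and phase[pi_] is None) or (
                    ph is not None and phase[pi_] is not None and np.array_equal(ph, phase[pi_])
                ):
                    Ec = Ecs[v]
                    break
            if Ec is None:
                Ec = Ecs[0]
            if kind == "interval":
                res = minimize_scalar(
                    lambda t: -self.insertion_dll(positions[pi_], Ec, t),
                    bounds=(1e-4, 1 - 1e-4),
                    method="bounded",
                    options={"xatol": 1e-4},
                )
            else:
                res = minimize_scalar(
                    lambda d: -self.insertion_dll(positions[pi_], Ec, d),
                    bounds=(1e-3, 60.0),
                    method="bounded",
                    options={"xatol": 1e-3},
                )
            if -res.fun > dll[pi_]:
                dll[pi_] = -res.fun
                detail[pi_] = float(res.x)
        return InsertionScan(positions=positions, dll=dll, detail=detail, phase=phase)


def infer_phase_on_extension(
    model: MultipointModel,
    dataset: SegregationDataset,
    new_marker: int,
    side: str = "end",
    r_link: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """ML phase of a CP candidate appended at a map end.

    Evaluates every parental phase configuration of the candidate
    (at most 4, 2 if the marker is informative in a single parent) at
    the given linking recombination fraction and returns
    (best phase row, log10 advantage over the runner-up, best dll).
    """
    if not model.population.is_cp:
        raise ValueError("phase inference applies to CP populations only")
    info = dataset.cp_info[new_marker]
    if info.segregation_class == "none":
        raise ValueError("marker is uninformative in both parents")
    chain = FittedChain(model, dataset)
    Ecs, phase_rows = candidate_emissions(model, dataset, new_marker)
    r_link = 0.1 if r_link is None else float(r_link)
    scores = []
    for Ec in Ecs:
        ratio = chain._end_ratio(side, Ec, r_link)
        scores.append(float(np.log10(ratio).sum()))
    order = np.argsort(scores)[::-1]
    best = order[0]
    advantage = (
        scores[best] - scores[order[1]] if len(scores) > 1 else np.inf
    )
    return phase_rows[best], float(max(advantage, 0.0)), float(scores[best])


def estimate_error_rate(
    model: MultipointModel,
    dataset: SegregationDataset,
    rounds: int = 8,
    min_eps: float = 1e-4,
    max_eps: float = 0.2,
) -> tuple[float, MultipointModel]:
    """Joint EM estimate of the emission error rate and interval r's.

    Alternates interval fitting with an emission M-step: the updated
    rate is the posterior-expected fraction of observed calls whose
    hidden state is incompatible with the observed code.  Returns the
    fitted rate and the refitted model carrying it.
    """
    eps = float(np.clip(model.epsilon, min_eps, max_eps))
    mdl = replace(model, epsilon=eps)
    for _ in range(rounds):
        r, _, _ = em_fit_intervals(mdl, dataset, max_iter=25)
        mdl = replace(mdl, r=r)
        fb = _forward_backward(mdl, dataset)
        g = fb.gamma
        g = g / np.maximum(g.sum(axis=2, keepdims=True), 1e-300)
        compat = compatibility_tables(mdl, dataset)
        obs = dataset.genotypes[np.asarray(mdl.marker_indices)] != MISSING
        p_call = (g * compat).sum(axis=2)
        n_obs = max(int(obs.sum()), 1)
        new_eps = float(np.clip(((1.0 - p_call) * obs).sum() / n_obs, min_eps, max_eps))
        if abs(new_eps - eps) < 1e-5:
            eps = new_eps
            break
        eps = new_eps
        mdl = replace(mdl, epsilon=eps)
    return eps, replace(mdl, epsilon=eps)
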