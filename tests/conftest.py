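"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from seriamap.types import (
    CPMarkerInfo,
    PopulationType,
    SegregationDataset,
)


def make_inbred_dataset(kind: str, codes: list[str], **pop_kwargs) -> SegregationDataset:
    """Dataset from rows of code strings, e.g. ['AAB-A', 'ABBHA']."""
    from seriamap.types import CODE_TO_INT, MISSING

    pop = PopulationType(kind, **pop_kwargs) if kind in ("RIL", "IRIL") else PopulationType(kind)
    rows = [
        [MISSING if c == "-" else CODE_TO_INT[c] for c in row] for row in codes
    ]
    n = len(codes[0])
    return SegregationDataset(
        population=pop,
        marker_names=[f"m{k + 1}" for k in range(len(codes))],
        individual_names=[f"i{k + 1}" for k in range(n)],
        genotypes=np.array(rows, dtype=np.int8),
    )


def make_cp_dataset(
    parents: list[tuple[str, str]], codes: list[list[str]]
) -> SegregationDataset:
    """CP dataset from parental genotype strings and offspring genotypes."""
    infos = [CPMarkerInfo(parent1=(p1[0], p1[1]), parent2=(p2[0], p2[1])) for p1, p2 in parents]
    from seriamap.types import MISSING

    rows = []
    for info, row in zip(infos, codes):
        rows.append([MISSING if c == "--" else info.class_index(c) for c in row])
    n = len(codes[0])
    return SegregationDataset(
        population=PopulationType("CP"),
        marker_names=[f"m{k + 1}" for k in range(len(codes))],
        individual_names=[f"i{k + 1}" for k in range(n)],
        genotypes=np.array(rows, dtype=np.int8),
        cp_info=infos,
    )


# ------------------------------------------------------------------ oracles


def f2_joint_freqs_bruteforce(r: float) -> dict[tuple[str, str], float]:
    """Exhaustive 4x4 ordered-gamete enumeration of F2 two-locus classes."""
    haps = list(itertools.product((0, 1), repeat=2))
    code = {0: "A", 1: "H", 2: "B"}
    out: dict[tuple[str, str], float] = {}
    for mat in haps:
        p_mat = ((1 - r) / 2) if mat[0] == mat[1] else (r / 2)
        for pat in haps:
            p_pat = ((1 - r) / 2) if pat[0] == pat[1] else (r / 2)
            key = (code[mat[0] + pat[0]], code[mat[1] + pat[1]])
            out[key] = out.get(key, 0.0) + p_mat * p_pat
    return out


def grid_ml_two_point(loglik_fn, step: float = 1e-4) -> float:
    """Argmax of a scalar log-likelihood over a fine r grid."""
    grid = np.arange(step, 0.5 + step / 2, step)
    vals = np.array([loglik_fn(float(r)) for r in grid])
    return float(grid[int(np.argmax(vals))])


def hmm_loglik_bruteforce(model, dataset) -> float:
    """log10 likelihood by exhaustive summation over hidden sequences."""
    from seriamap.multipoint import _obs_emissions, _transitions

    E = _obs_emissions(model, dataset)
    T = _transitions(model)
    L, n, S = E.shape
    pi = model.pmodel.initial
    total = 0.0
    for i in range(n):
        lik = 0.0
        for seq in itertools.product(range(S), repeat=L):
            p = pi[seq[0]] * E[0, i, seq[0]]
            for k in range(1, L):
                p *= T[k - 1][seq[k - 1], seq[k]] * E[k, i, seq[k]]
            lik += p
        total += np.log10(lik)
    return float(total)


def posterior_bruteforce(model, dataset) -> np.ndarray:
    """Hidden-state posteriors by conditional enumeration, shape (L, n, S)."""
    from seriamap.multipoint import _obs_emissions, _transitions

    E = _obs_emissions(model, dataset)
    T = _transitions(model)
    L, n, S = E.shape
    pi = model.pmodel.initial
    post = np.zeros((L, n, S))
    for i in range(n):
        for seq in itertools.product(range(S), repeat=L):
            p = pi[seq[0]] * E[0, i, seq[0]]
            for k in range(1, L):
                p *= T[k - 1][seq[k - 1], seq[k]] * E[k, i, seq[k]]
            for k in range(L):
                post[k, i, seq[k]] += p
        post[:, i, :] /= post[:, i, :].sum(axis=1, keepdims=True)
    return post


@pytest.fixture(scope="session")
def f2_small_sim():
    """Error-free F2, one 60 cM chromosome at 2 cM spacing, n = 150."""
    from seriamap import SimulationConfig, simulate_pop

    return simulate_pop(
        SimulationConfig(
            population="F2",
            n_individuals=150,
            chrom_lengths_cM=(60.0,),
            marker_spacing_cM=2.0,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def cp_small_sim():
    """Error-free CP, one 60 cM chromosome at 2 cM spacing, n = 150."""
    from seriamap import SimulationConfig, simulate_pop

    return simulate_pop(
        SimulationConfig(
            population="CP",
            n_individuals=150,
            chrom_lengths_cM=(60.0,),
            marker_spacing_cM=2.0,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def bc_chrom_sim():
    """Error-free BC, one 50 cM chromosome at 1 cM spacing, n = 200."""
    from seriamap import SimulationConfig, simulate_pop

    return simulate_pop(
        SimulationConfig(
            population="BC",
            n_individuals=200,
            chrom_lengths_cM=(50.0,),
            marker_spacing_cM=1.0,
            seed=3,
        )
    )
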