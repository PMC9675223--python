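"""Genotyping-error detection and redundant-marker ("twin") handling.

Two complementary detectors are provided.  The model-based detector
flags calls whose observed code is given a near-zero posterior
compatibility under the fitted multipoint error model; the rule-based
detector flags singletons — calls that disagree with both close
flanking markers while the flanks agree with each other, the classic
signature of a miscall masquerading as a double crossover.  Flagged
calls are masked to missing, never rewritten to an imputed value, so
they simply stop contributing to the map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .multipoint import MultipointModel, compatibility_tables, impute_posteriors
from .types import MISSING, SegregationDataset

POSTERIOR_THRESHOLD = 0.05
SINGLETON_WINDOW_CM = 10.0
TWIN_MIN_OVERLAP = 20


@dataclass(frozen=True)
class FlaggedCall:
    marker: int
    individual: int
    code: str
    method: str  # 'posterior' | 'singleton'


def detect_errors_posterior(
    model: MultipointModel,
    dataset: SegregationDataset,
    threshold: float = POSTERIOR_THRESHOLD,
) -> list[FlaggedCall]:
    """Flag calls incompatible with the fitted multipoint model.

    A call is flagged when the posterior probability mass on hidden
    states compatible with the observed code falls below ``threshold``.
    On a dense map a singleton's compatible-state posterior is roughly
    r_left * r_right / eps (double crossover vs miscall), about 0.01 on
    a 1 cM grid with eps = 0.01, so the threshold must sit above that;
    with a fitted eps near zero clean data produces no flags at all.
    Requires a model fitted with a positive emission error rate, since
    with eps = 0 an incompatible call forces the posterior instead of
    exposing itself.
    """
    if model.epsilon <= 0:
        raise ValueError("posterior error detection requires epsilon > 0")
    post = impute_posteriors(model, dataset).probs  # (L, n, S)
    compat = compatibility_tables(model, dataset)  # (L, n, S)
    p_call = (post * compat).sum(axis=2)
    flags: list[FlaggedCall] = []
    for k, m in enumerate(model.marker_indices):
        obs = dataset.genotypes[m]
        bad = (obs != MISSING) & (p_call[k] < threshold)
        for i in np.nonzero(bad)[0]:
            flags.append(
                FlaggedCall(
                    marker=m,
                    individual=int(i),
                    code=dataset.code_string(m, int(i)),
                    method="posterior",
                )
            )
    return flags


# compatible genotype-class sets for inbred codes (A, H, B, C, D)
_INBRED_COMPAT = {0: {0}, 1: {1}, 2: {2}, 3: {1, 2}, 4: {0, 1}}


def _codes_agree(a: int, b: int, is_cp: bool) -> bool:
    if is_cp:
        return a == b
    return bool(_INBRED_COMPAT[a] & _INBRED_COMPAT[b])


def detect_singletons(
    marker_order: list[int],
    positions_cM: np.ndarray,
    dataset: SegregationDataset,
    window_cM: float = SINGLETON_WINDOW_CM,
) -> list[FlaggedCall]:
    """Flag singletons along an ordered, positioned set of markers.

    A call is flagged when both nearest non-missing flanking calls lie
    within ``window_cM``, agree with each other, and disagree with the
    call.  Terminal discordances (a single flank) and calls next to a
    missing flank beyond the window are never flagged.

    Inbred-derived populations only: CP genotype classes cannot be
    compared across markers without phase information (a "disagreement"
    between repulsion-phase neighbors is the expected pattern), so for
    CP data the model-based posterior detector is the applicable method.
    """
    if dataset.population.is_cp:
        raise ValueError(
            "singleton detection is undefined for CP codes; use "
            "detect_errors_posterior"
        )
    positions_cM = np.asarray(positions_cM, dtype=float)
    if len(marker_order) != len(positions_cM):
        raise ValueError("marker_order and positions must align")
    is_cp = dataset.population.is_cp
    G = dataset.genotypes[marker_order]  # (L, n)
    L, n = G.shape
    flags: list[FlaggedCall] = []
    for i in range(n):
        col = G[:, i]
        typed = np.nonzero(col != MISSING)[0]
        for t in range(1, len(typed) - 1):
            k = typed[t]
            left, right = typed[t - 1], typed[t + 1]
            if positions_cM[k] - positions_cM[left] > window_cM:
                continue
            if positions_cM[right] - positions_cM[k] > window_cM:
                continue
            a, b, c = int(col[left]), int(col[k]), int(col[right])
            if not _codes_agree(a, c, is_cp):
                continue
            if _codes_agree(b, a, is_cp) or _codes_agree(b, c, is_cp):
                continue
            m = marker_order[k]
            flags.append(
                FlaggedCall(
                    marker=m,
                    individual=i,
                    code=dataset.code_string(m, i),
                    method="singleton",
                )
            )
    return flags


def mask_flags(dataset: SegregationDataset, flags: list[FlaggedCall]) -> SegregationDataset:
    """Return a copy of the dataset with flagged calls set to missing."""
    out = dataset.subset_markers(list(range(dataset.n_markers)))
    for f in flags:
        out.genotypes[f.marker, f.individual] = MISSING
    return out


def write_error_report(
    flags: list[FlaggedCall], dataset: SegregationDataset, path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# marker\tindividual\tcode\tmethod\n")
        for f in flags:
            fh.write(
                f"{dataset.marker_names[f.marker]}\t"
                f"{dataset.individual_names[f.individual]}\t{f.code}\t{f.method}\n"
            )


# ------------------------------------------------------------------ twins


@dataclass
class TwinGroups:
    """Redundancy groups; each group is mapped at a single position."""

    groups: list[list[int]]  # marker indices, representative first
    representative: dict[int, int]  # member -> representative

    def representatives(self) -> list[int]:
        return [g[0] for g in self.groups]

    def attached_to(self, rep: int) -> list[int]:
        for g in self.groups:
            if g[0] == rep:
                return g[1:]
        return []


def _cp_class_permutations(info) -> list[np.ndarray]:
    """Class-index permutations induced by relabeling alleles within parents."""
    perms = []
    p1, p2 = info.parent1, info.parent2
    opts1 = [(p1, False)] + ([(tuple(reversed(p1)), True)] if info.het1 else [])
    opts2 = [(p2, False)] + ([(tuple(reversed(p2)), True)] if info.het2 else [])
    for q1, s1 in opts1:
        for q2, s2 in opts2:
            if not (s1 or s2):
                continue
            # map each class to the class obtained by swapping allele roles
            mapping = np.arange(len(info.classes))
            ok = True
            for ci, cls in enumerate(info.classes):
                # express cls as one allele from each parent, then swap labels
                done = False
                for a in range(2):
                    for b in range(2):
                        if "".join(sorted(p1[a] + p2[b])) == cls:
                            new = "".join(sorted(q1[a] + q2[b]))
                            if new in info.classes:
                                mapping[ci] = info.classes.index(new)
                                done = True
                            break
                    if done:
                        break
                if not done:
                    ok = False
                    break
            if ok and not np.array_equal(mapping, np.arange(len(info.classes))):
                perms.append(mapping)
    # dedupe
    out = []
    for p in perms:
        if not any(np.array_equal(p, q) for q in out):
            out.append(p)
    return out


def find_twins(
    dataset: SegregationDataset, min_overlap: int = TWIN_MIN_OVERLAP
) -> TwinGroups:
    """Group markers whose segregation patterns are redundant.

    Two markers are twins when their non-missing calls agree on at
    least ``min_overlap`` co-typed individuals and conflict on none —
    for CP markers agreement up to a consistent within-parent allele
    relabeling also counts.  Each group's representative (fewest
    missing calls, ties broken by name) enters the ordering stages;
    the others are re-attached at its position in the total map.
    """
    Mk = dataset.n_markers
    G = dataset.genotypes
    parent = list(range(Mk))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    is_cp = dataset.population.is_cp
    perms_cache: dict[int, list[np.ndarray]] = {}
    for i in range(Mk):
        for j in range(i + 1, Mk):
            if is_cp:
                a, b = dataset.cp_info[i], dataset.cp_info[j]
                if (a.parent1, a.parent2, tuple(a.classes)) != (
                    b.parent1,
                    b.parent2,
                    tuple(b.classes),
                ):
                    continue
            ok = (G[i] != MISSING) & (G[j] != MISSING)
            if int(ok.sum()) < min_overlap:
                continue
            gi, gj = G[i][ok], G[j][ok]
            if np.array_equal(gi, gj):
                union(i, j)
                continue
            if is_cp:
                if i not in perms_cache:
                    perms_cache[i] = _cp_class_permutations(dataset.cp_info[i])
                for perm in perms_cache[i]:
                    if np.array_equal(perm[gi], gj):
                        union(i, j)
                        break

    buckets: dict[int, list[int]] = {}
    for m in range(Mk):
        buckets.setdefault(find(m), []).append(m)
    groups = []
    rep_of: dict[int, int] = {}
    missing = dataset.missing_counts()
    for members in buckets.values():
        rep = min(members, key=lambda m: (missing[m], dataset.marker_names[m]))
        ordered = [rep] + sorted(
            (m for m in members if m != rep), key=lambda m: dataset.marker_names[m]
        )
        groups.append(ordered)
        for m in members:
            rep_of[m] = rep
    groups.sort(key=lambda g: g[0])
    return TwinGroups(groups=groups, representative=rep_of)
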