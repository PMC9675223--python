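"""Mapping-population simulator with known truth, and map-quality metrics.

Meioses are drawn as a crossover count ~ Poisson(L/100) per chromosome
with uniform crossover positions — no interference, which makes the
Haldane function the exact distance model for simulated data.  All
supported population designs are built gamete by gamete: BC (one F1
gamete onto the recurrent parent), DH (one gamete doubled), F2 (two F1
gametes), RILn (selfing lineages), IRIL (random intermating between the
F2 and the selfing phase), and CP (two heterozygous outbred parents
with per-marker informativeness classes and recorded truth phases).
Genotyping errors resample the observed code among the other valid
codes at a uniform or Gamma-distributed per-marker/per-individual rate;
missing data are applied independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .types import (
    CPMarkerInfo,
    GeneticMap,
    LinkageGroup,
    MapEntry,
    MISSING,
    PhysicalMap,
    PopulationType,
    SegregationDataset,
)

# default mix of CP marker informativeness classes:
# female pseudo-testcross (ab x aa), male pseudo-testcross (aa x ab),
# both-informative 3-class (ab x ab), both-informative 4-class (ab x cd)
CP_CLASS_PROBS = {
    "abxaa": 0.30,
    "aaxab": 0.30,
    "abxab": 0.25,
    "abxcd": 0.15,
}


@dataclass
class SimulationConfig:
    """Design of a simulated mapping population.

    chrom_lengths_cM: genetic length of each chromosome; markers are
    laid out regularly at ``marker_spacing_cM`` from 0 to L inclusive.
    error model: mean per-cell rate ``error_rate`` distributed either
    uniformly or as Gamma(shape, mean/shape) across markers or
    individuals (L-shaped for small shape, near-uniform for large).
    """

    population: PopulationType | str
    n_individuals: int
    chrom_lengths_cM: tuple[float, ...] = (100.0, 200.0)
    marker_spacing_cM: float = 1.0
    error_rate: float = 0.0
    error_distribution: str = "uniform"  # uniform | gamma_marker | gamma_individual
    gamma_shape: float = 1.0
    missing_rate: float = 0.0
    cp_class_probs: dict = field(default_factory=lambda: dict(CP_CLASS_PROBS))
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.population, str):
            self.population = PopulationType.parse(self.population)
        if not 0 <= self.error_rate <= 1 or not 0 <= self.missing_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if any(length <= 0 for length in self.chrom_lengths_cM):
            raise ValueError("chromosome lengths must be positive")
        if self.error_distribution not in ("uniform", "gamma_marker", "gamma_individual"):
            raise ValueError(f"unknown error distribution {self.error_distribution!r}")


@dataclass
class SimulatedPopulation:
    """Truth map + observed dataset + error/missing masks."""

    config: SimulationConfig
    truth_map: GeneticMap
    dataset: SegregationDataset
    error_mask: np.ndarray  # (n_markers, n_individuals) bool
    missing_mask: np.ndarray
    truth_phases: np.ndarray | None = None  # CP: (n_markers, 2), -1 where homozygous

    def truth_physical_map(self) -> PhysicalMap:
        """The truth map expressed as an anchor table (positions in cM)."""
        import pandas as pd

        rows = []
        for g in self.truth_map.groups:
            for e in g.entries:
                rows.append(
                    {"marker": e.marker, "chromosome": g.name, "position": e.position}
                )
        return PhysicalMap(
            table=pd.DataFrame(rows, columns=["marker", "chromosome", "position"]),
            unit="cM",
        )


def _marker_grid(config: SimulationConfig) -> list[np.ndarray]:
    out = []
    for L in config.chrom_lengths_cM:
        n = int(round(L / config.marker_spacing_cM))
        out.append(np.linspace(0.0, n * config.marker_spacing_cM, n + 1))
    return out


def _gametes(
    positions: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n meiotic products over one chromosome: 0/1 = transmitted homolog.

    Crossover count ~ Poisson(L/100), positions uniform on [0, L].
    """
    L = positions[-1] if len(positions) else 0.0
    out = np.empty((n, len(positions)), dtype=np.int8)
    n_xo = rng.poisson(max(L, 1e-9) / 100.0, size=n)
    start = rng.integers(0, 2, size=n)
    for g in range(n):
        if n_xo[g] == 0:
            out[g] = start[g]
            continue
        xo = np.sort(rng.uniform(0.0, L, size=n_xo[g]))
        parity = np.searchsorted(xo, positions, side="right") % 2
        out[g] = (start[g] + parity) % 2
    return out


def _self_lineage(
    positions: np.ndarray,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    n_gen: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Self an individual (two haplotypes of homolog indicators) n_gen times."""
    for _ in range(n_gen):
        g = _gametes(positions, 2, rng)
        new_a = np.where(g[0] == 0, hap_a, hap_b)
        new_b = np.where(g[1] == 0, hap_a, hap_b)
        hap_a, hap_b = new_a, new_b
        if np.array_equal(hap_a, hap_b):
            break  # fully fixed; further selfing changes nothing
    return hap_a, hap_b


def _simulate_inbred_chrom(
    pop: PopulationType,
    positions: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Allele-dosage matrix (n_markers, n): 0 = AA, 1 = Aa, 2 = BB-side."""
    kind = pop.kind
    m = len(positions)
    if kind in ("BC", "DH"):
        g = _gametes(positions, n, rng)
        return (g.T * 2).astype(np.int8) if kind == "DH" else g.T.astype(np.int8) * 2
    if kind == "F2":
        g1 = _gametes(positions, n, rng)
        g2 = _gametes(positions, n, rng)
        return (g1 + g2).T.astype(np.int8)
    if kind in ("RIL", "IRIL"):
        if kind == "RIL":
            n_gen = pop.selfing_generations if pop.selfing_generations is not None else 20
            dosage = np.empty((m, n), dtype=np.int8)
            for i in range(n):
                a, b = _self_lineage(positions, np.zeros(m, np.int8), np.ones(m, np.int8), n_gen, rng)
                dosage[:, i] = a + b
            return dosage
        # IRIL: F2 population, t rounds of random intermating, then selfing
        t = pop.intermating_generations
        pool = max(n, 50)
        pop_haps = []
        for _ in range(pool):
            g = _gametes(positions, 2, rng)
            pop_haps.append((g[0], g[1]))
        for _ in range(t):
            new = []
            for _ in range(pool):
                p1, p2 = rng.integers(0, pool, size=2)
                ga = _gametes(positions, 1, rng)[0]
                gb = _gametes(positions, 1, rng)[0]
                h1 = np.where(ga == 0, pop_haps[p1][0], pop_haps[p1][1])
                h2 = np.where(gb == 0, pop_haps[p2][0], pop_haps[p2][1])
                new.append((h1, h2))
            pop_haps = new
        dosage = np.empty((m, n), dtype=np.int8)
        for i in range(n):
            base = pop_haps[rng.integers(0, pool)]
            a, b = _self_lineage(positions, base[0].copy(), base[1].copy(), 20, rng)
            dosage[:, i] = a + b
        return dosage
    raise ValueError(kind)


_DOSAGE_TO_CODE = {0: 0, 1: 1, 2: 2}  # A, H, B


def _draw_cp_marker(
    kind: str, rng: np.random.Generator
) -> CPMarkerInfo:
    if kind == "abxaa":
        return CPMarkerInfo(parent1=("a", "b"), parent2=("a", "a"))
    if kind == "aaxab":
        return CPMarkerInfo(parent1=("a", "a"), parent2=("a", "b"))
    if kind == "abxab":
        return CPMarkerInfo(parent1=("a", "b"), parent2=("a", "b"))
    return CPMarkerInfo(parent1=("a", "b"), parent2=("c", "d"))


def simulate_pop(config: SimulationConfig) -> SimulatedPopulation:
    """Simulate a mapping population from a regular truth map.

    The same seed always yields a bitwise-identical population.
    """
    rng = np.random.default_rng(config.seed)
    pop = config.population
    grids = _marker_grid(config)
    n = config.n_individuals

    marker_names: list[str] = []
    group_entries: list[LinkageGroup] = []
    for ci, grid in enumerate(grids):
        names = [f"c{ci + 1}_m{k:04d}" for k in range(len(grid))]
        marker_names.extend(names)
        group_entries.append(
            LinkageGroup(
                name=f"chr{ci + 1}",
                entries=[
                    MapEntry(marker=nm, position=float(p), status="framework")
                    for nm, p in zip(names, grid)
                ],
            )
        )
    truth_map = GeneticMap(groups=group_entries)
    total_markers = len(marker_names)

    cp_info = None
    truth_phases = None
    if pop.is_cp:
        kinds = list(config.cp_class_probs.keys())
        probs = np.array([config.cp_class_probs[k] for k in kinds], dtype=float)
        probs /= probs.sum()
        blocks = []
        cp_info = []
        truth_phases = np.full((total_markers, 2), -1, dtype=np.int8)
        offset = 0
        for grid in grids:
            m = len(grid)
            # parent homolog haplotypes: allele index (0/1) carried by homolog 0/1
            kidx = rng.choice(len(kinds), size=m, p=probs)
            infos = [_draw_cp_marker(kinds[k], rng) for k in kidx]
            phase1 = rng.integers(0, 2, size=m).astype(np.int8)
            phase2 = rng.integers(0, 2, size=m).astype(np.int8)
            for mk, info in enumerate(infos):
                if not info.het1:
                    phase1[mk] = -1
                if not info.het2:
                    phase2[mk] = -1
            g1 = _gametes(grid, n, rng)  # homolog transmitted by parent 1
            g2 = _gametes(grid, n, rng)
            codes = np.empty((m, n), dtype=np.int8)
            for mk, info in enumerate(infos):
                # homolog h of parent p carries allele index (h ^ phase)
                a_idx = (g1[:, mk] ^ (phase1[mk] if phase1[mk] >= 0 else 0)).astype(int)
                b_idx = (g2[:, mk] ^ (phase2[mk] if phase2[mk] >= 0 else 0)).astype(int)
                for i in range(n):
                    geno = info.parent1[a_idx[i]] + info.parent2[b_idx[i]]
                    codes[mk, i] = info.class_index(geno)
            blocks.append(codes)
            cp_info.extend(infos)
            truth_phases[offset : offset + m, 0] = phase1
            truth_phases[offset : offset + m, 1] = phase2
            offset += m
        genotypes = np.vstack(blocks)
    else:
        blocks = []
        for grid in grids:
            dosage = _simulate_inbred_chrom(pop, grid, n, rng)
            if pop.kind in ("BC", "DH"):
                codes = np.where(dosage == 0, 0, 2).astype(np.int8)
            else:
                codes = dosage.astype(np.int8)  # A=0, H=1, B=2
            blocks.append(codes)
        genotypes = np.vstack(blocks)

    clean = genotypes.copy()

    # missing first, then errors on the remaining cells: disjoint masks
    missing_mask = rng.random((total_markers, n)) < config.missing_rate
    if config.error_rate > 0:
        if config.error_distribution == "uniform":
            rates = np.full((total_markers, n), config.error_rate)
        elif config.error_distribution == "gamma_marker":
            per = rng.gamma(config.gamma_shape, config.error_rate / config.gamma_shape, total_markers)
            rates = np.clip(per, 0, 0.95)[:, None] * np.ones((1, n))
        else:
            per = rng.gamma(config.gamma_shape, config.error_rate / config.gamma_shape, n)
            rates = np.ones((total_markers, 1)) * np.clip(per, 0, 0.95)[None, :]
        error_mask = (rng.random((total_markers, n)) < rates) & ~missing_mask
    else:
        error_mask = np.zeros((total_markers, n), dtype=bool)

    obs = clean.copy()
    if pop.is_cp:
        for mk in range(total_markers):
            k = len(cp_info[mk].classes)
            idx = np.nonzero(error_mask[mk])[0]
            if idx.size and k > 1:
                shift = rng.integers(1, k, size=idx.size)
                obs[mk, idx] = (obs[mk, idx] + shift) % k
            elif k <= 1:
                error_mask[mk] = False
    else:
        valid = np.array([0, 2]) if pop.kind in ("BC", "DH") else np.array([0, 1, 2])
        k = len(valid)
        pos_of = {int(v): p for p, v in enumerate(valid)}
        mi, ii = np.nonzero(error_mask)
        if mi.size:
            cur = np.array([pos_of[int(v)] for v in obs[mi, ii]])
            shift = rng.integers(1, k, size=mi.size)
            obs[mi, ii] = valid[(cur + shift) % k]
    obs[missing_mask] = MISSING

    dataset = SegregationDataset(
        population=pop,
        marker_names=marker_names,
        individual_names=[f"ind{i + 1}" for i in range(n)],
        genotypes=obs,
        cp_info=cp_info,
    )
    return SimulatedPopulation(
        config=config,
        truth_map=truth_map,
        dataset=dataset,
        error_mask=error_mask,
        missing_mask=missing_mask,
        truth_phases=truth_phases,
    )


# ------------------------------------------------------------------ quality metrics


@dataclass
class GroupQuality:
    group: str
    truth_chrom: str | None
    n_shared: int
    spearman_abs: float
    cand_length: float
    truth_covered: float
    truth_full: float


@dataclass
class MapQualityReport:
    """Colinearity, length-ratio and inclusion metrics vs a reference map."""

    groups: list[GroupQuality]
    length_ratio: float  # candidate length / truth length over covered spans
    length_ratio_full: float  # candidate length / full truth length
    inclusion_rate: float
    min_spearman: float

    def summary(self) -> str:
        lines = [
            f"groups matched: {len(self.groups)}",
            f"min |Spearman rho|: {self.min_spearman:.4f}",
            f"length ratio (covered span): {self.length_ratio:.4f}",
            f"length ratio (full truth): {self.length_ratio_full:.4f}",
            f"inclusion rate: {self.inclusion_rate:.4f}",
        ]
        return "\n".join(lines)


def evaluate_map(
    candidate: GeneticMap,
    truth: GeneticMap,
    n_polymorphic: int | None = None,
) -> MapQualityReport:
    """Compare a computed map with its reference.

    Candidate groups are matched to truth chromosomes by shared-marker
    majority.  Per matched group the orientation-free |Spearman rho| of
    positions is reported; the length ratio sums candidate lengths over
    truth lengths restricted to the covered span (the full-span ratio
    is reported alongside); the inclusion rate is mapped markers over
    all polymorphic markers (defaults to the truth marker count).
    """
    truth_pos: dict[str, tuple[str, float]] = {}
    truth_full: dict[str, float] = {}
    for g in truth.groups:
        truth_full[g.name] = g.length
        for e in g.entries:
            truth_pos[e.marker] = (g.name, e.position)

    rows: list[GroupQuality] = []
    spearmans = []
    cand_sum = covered_sum = full_sum = 0.0
    matched_chroms: set[str] = set()
    for g in candidate.groups:
        shared = [(e.marker, e.position) for e in g.entries if e.marker in truth_pos]
        if not shared:
            rows.append(GroupQuality(g.name, None, 0, np.nan, g.length, np.nan, np.nan))
            continue
        chroms = [truth_pos[m][0] for m, _ in shared]
        vals, counts = np.unique(chroms, return_counts=True)
        chrom = str(vals[np.argmax(counts)])
        pairs = [(p, truth_pos[m][1]) for m, p in shared if truth_pos[m][0] == chrom]
        cand_p = np.array([a for a, _ in pairs])
        true_p = np.array([b for _, b in pairs])
        if len(pairs) >= 2 and np.ptp(cand_p) > 0 and np.ptp(true_p) > 0:
            rho = abs(float(spearmanr(cand_p, true_p).statistic))
        else:
            rho = 1.0 if len(pairs) else np.nan
        covered = float(true_p.max() - true_p.min())
        rows.append(
            GroupQuality(
                group=g.name,
                truth_chrom=chrom,
                n_shared=len(pairs),
                spearman_abs=rho,
                cand_length=g.length,
                truth_covered=covered,
                truth_full=truth_full[chrom],
            )
        )
        spearmans.append(rho)
        cand_sum += g.length
        covered_sum += covered
        if chrom not in matched_chroms:
            full_sum += truth_full[chrom]
            matched_chroms.add(chrom)

    if not spearmans:
        return MapQualityReport(rows, np.nan, np.nan, np.nan, np.nan)
    denom = n_polymorphic if n_polymorphic is not None else len(truth_pos)
    inclusion = candidate.n_markers / denom if denom else np.nan
    return MapQualityReport(
        groups=rows,
        length_ratio=cand_sum / covered_sum if covered_sum > 0 else np.nan,
        length_ratio_full=cand_sum / full_sum if full_sum > 0 else np.nan,
        inclusion_rate=inclusion,
        min_spearman=float(np.min(spearmans)),
    )
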