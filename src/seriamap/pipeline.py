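"""`auto_map`: the fully automated pipeline chaining all mapping stages.

load -> twins -> seeds -> scaffolds (seriation, merged) -> assignment
-> framework densification (with error detection) -> placement.
Every stage is also callable on its own for interactive use; auto_map
only wires them together, collects QC outputs and writes the run
directory.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assign_place import (
    AssignmentResult,
    assign_markers,
    place_markers,
)
from .error_handling import (
    FlaggedCall,
    detect_singletons,
    find_twins,
    mask_flags,
    write_error_report,
)
from .io_formats import write_lod_matrix, write_map, write_marey_table
from .models import two_point_matrix
from .multipoint import MultipointModel, em_fit_intervals, estimate_error_rate
from .ordering import (
    FrameworkResult,
    OrderRobustnessReport,
    build_framework,
    build_scaffold,
    generate_seeds,
    merge_scaffolds,
    verify_order_robustness,
)
from .simulate import MapQualityReport, evaluate_map
from .types import GeneticMap, PhysicalMap, SegregationDataset


@dataclass
class MapParams:
    """All pipeline thresholds in one place.

    lod_framework is the order-robustness LOD gate (default 3.0);
    lod_assign / assign_gap govern linkage-group assignment; the
    scaffold window [scaffold_rmin, scaffold_rmax] keeps the seriation
    sparse yet able to reach chromosome ends; epsilon is the emission
    genotyping-error rate used in all multipoint fits.
    """

    lod_framework: float = 3.0
    lod_assign: float = 6.0
    assign_gap: float = 3.0
    seed_lod: float = 6.0
    seed_rmax: float = 0.25
    scaffold_rmin: float = 0.05
    scaffold_rmax: float = 0.25
    scaffold_extend_lod: float = 3.0
    scaffold_tries: int = 15
    epsilon: float = 0.01
    error_correction: bool = True
    posterior_threshold: float = 0.05
    singleton_window_cM: float = 10.0
    singleton_min_eps: float = 0.005
    twin_min_overlap: int = 20
    error_detect_every: int = 30
    merge_lod: float = 10.0
    group_lod: float = 10.0
    epsilon_estimate: bool = True
    seed: int = 0


@dataclass
class AutoMapResult:
    scaffolds: list[MultipointModel]
    frameworks: list[FrameworkResult]
    framework_map: GeneticMap
    total_map: GeneticMap
    assignment: AssignmentResult
    robustness: list[OrderRobustnessReport]
    flags: list[FlaggedCall]
    r_matrix: np.ndarray
    lod_matrix: np.ndarray
    quality_framework: MapQualityReport | None = None
    quality_total: MapQualityReport | None = None
    log: list[str] = field(default_factory=list)


def auto_map(
    dataset: SegregationDataset,
    phymap: PhysicalMap | None = None,
    params: MapParams | None = None,
    truth: GeneticMap | None = None,
    out_dir: str | Path | None = None,
) -> AutoMapResult:
    """Run the complete automatic bin-mapping pipeline.

    Returns scaffolds, the framework map (every marker order-robust at
    ``params.lod_framework``), the total map (framework plus placed
    markers and re-attached twins), per-group robustness reports, the
    error-flag audit trail and the 2-point matrices.  With ``truth``
    given, framework and total maps are scored against it.  The run is
    deterministic for a fixed dataset and parameter set.
    """
    params = params or MapParams()
    t0 = time.time()
    log: list[str] = [
        f"seriamap auto_map | population={dataset.population} "
        f"markers={dataset.n_markers} individuals={dataset.n_individuals}",
        f"params: lod_framework={params.lod_framework} lod_assign={params.lod_assign} "
        f"epsilon={params.epsilon} error_correction={params.error_correction} "
        f"seed={params.seed}",
    ]

    mono = dataset.monomorphic_mask()
    n_poly = int((~mono).sum())
    log.append(f"polymorphic markers: {n_poly} / {dataset.n_markers}")

    twins = find_twins(dataset, min_overlap=params.twin_min_overlap)
    reps = [g[0] for g in twins.groups if not mono[g[0]]]
    log.append(f"twin groups: {len(twins.groups)} ({len(reps)} polymorphic representatives)")

    r_mat, lod_mat = two_point_matrix(dataset)

    eligible = np.zeros(dataset.n_markers, dtype=bool)
    eligible[reps] = True
    seeds = generate_seeds(
        dataset,
        r_mat,
        lod_mat,
        phymap=phymap,
        seed_lod=params.seed_lod,
        seed_rmax=params.seed_rmax,
        seed_rmin=params.scaffold_rmin,
        twins=twins.representative,
        eligible=eligible,
        group_lod=params.group_lod,
    )
    log.append(
        "seeds: "
        + "; ".join(
            f"({dataset.marker_names[i]}, {dataset.marker_names[j]})" for i, j in seeds
        )
    )

    available = eligible.copy()
    scaffolds: list[MultipointModel] = []
    for pair in seeds:
        i, j = pair
        if not (available[i] and available[j]):
            continue
        scaffolds.append(
            build_scaffold(
                pair,
                dataset,
                r_mat,
                lod_mat,
                available,
                robust_lod=params.lod_framework,
                extend_lod=params.scaffold_extend_lod,
                r_window=(params.scaffold_rmin, params.scaffold_rmax),
                epsilon=params.epsilon,
                max_tries=params.scaffold_tries,
            )
        )
    scaffolds = merge_scaffolds(
        scaffolds, dataset, r_mat, lod_mat, merge_lod=params.merge_lod
    )
    scaffolds.sort(key=lambda s: -len(s.marker_indices))
    if params.epsilon_estimate:
        for k, s in enumerate(scaffolds):
            eps, scaffolds[k] = estimate_error_rate(s, dataset)
            log.append(
                f"scaffold LG{k + 1}: {len(s.marker_indices)} markers, "
                f"estimated error rate {eps:.4f}"
            )
    else:
        for k, s in enumerate(scaffolds):
            log.append(f"scaffold LG{k + 1}: {len(s.marker_indices)} markers")

    assignment = assign_markers(
        dataset,
        [s.marker_indices for s in scaffolds],
        lod_mat,
        assign_lod=params.lod_assign,
        assign_gap=params.assign_gap,
        markers=reps,
    )
    n_unlinked = assignment.status.count("unlinked")
    n_ambig = assignment.status.count("ambiguous")
    log.append(f"assignment: {n_unlinked} unlinked, {n_ambig} ambiguous representatives")

    ds = dataset
    frameworks: list[FrameworkResult] = []
    all_flags: list[FlaggedCall] = []
    for g, scaffold in enumerate(scaffolds):
        candidates = [
            m for m in assignment.assigned_to(g) if m not in scaffold.marker_indices
        ]
        fw = build_framework(
            scaffold,
            candidates,
            ds,
            lod_mat,
            lod_threshold=params.lod_framework,
            error_correction=params.error_correction,
            posterior_threshold=params.posterior_threshold,
            error_detect_every=params.error_detect_every,
            estimate_eps=params.epsilon_estimate,
        )
        ds = fw.dataset
        all_flags.extend(fw.flags)
        # the singleton rule cannot distinguish a miscall from a genuine
        # double crossover; apply it only when the fitted error rate says
        # miscalls are actually present, otherwise it deflates clean maps
        if (
            params.error_correction
            and not dataset.population.is_cp
            and fw.model.epsilon >= params.singleton_min_eps
        ):
            dist = fw.model.distances_cM()
            cum = np.concatenate([[0.0], np.cumsum(dist)])
            singles = detect_singletons(
                fw.model.marker_indices, cum, ds, window_cM=params.singleton_window_cM
            )
            if singles:
                ds = mask_flags(ds, singles)
                all_flags.extend(singles)
                from dataclasses import replace as _replace

                r, _, _ = em_fit_intervals(fw.model, ds, max_iter=40)
                fw.model = _replace(fw.model, r=r)
                fw.dataset = ds
        frameworks.append(fw)
        log.append(
            f"framework LG{g + 1}: {len(fw.model.marker_indices)} markers "
            f"({len(fw.rejected)} left for placement, {len(fw.flags)} flagged "
            f"calls, error rate {fw.model.epsilon:.4f})"
        )

    robustness = [
        verify_order_robustness(fw.model, ds, params.lod_framework) for fw in frameworks
    ]
    for k, rep in enumerate(robustness):
        log.append(f"robustness LG{k + 1}: min gap {rep.min_gap:.2f} (pass={rep.passed})")

    fw_groups = []
    total_groups = []
    for g, fw in enumerate(frameworks):
        name = f"LG{g + 1}"
        scaffold_set = set(scaffolds[g].marker_indices) & set(fw.model.marker_indices)
        leftovers = [
            m
            for m in assignment.assigned_to(g)
            if m not in fw.model.marker_indices
        ]
        total_groups.append(
            place_markers(
                fw.model,
                leftovers,
                ds,
                group_name=name,
                twins=twins,
                scaffold_set=scaffold_set,
            )
        )
        fw_groups.append(
            place_markers(fw.model, [], ds, group_name=name, scaffold_set=scaffold_set)
        )
    framework_map = GeneticMap(fw_groups)
    the_total = GeneticMap(total_groups)
    log.append(
        f"framework map: {framework_map.n_markers} markers, "
        f"{framework_map.total_length:.1f} cM; total map: {the_total.n_markers} markers"
    )

    quality_fw = quality_total = None
    if truth is not None:
        quality_fw = evaluate_map(framework_map, truth, n_polymorphic=n_poly)
        quality_total = evaluate_map(the_total, truth, n_polymorphic=n_poly)
        log.append("framework quality: " + quality_fw.summary().replace("\n", " | "))
        log.append("total quality: " + quality_total.summary().replace("\n", " | "))

    log.append(f"elapsed: {time.time() - t0:.1f} s")
    result = AutoMapResult(
        scaffolds=scaffolds,
        frameworks=frameworks,
        framework_map=framework_map,
        total_map=the_total,
        assignment=assignment,
        robustness=robustness,
        flags=all_flags,
        r_matrix=r_mat,
        lod_matrix=lod_mat,
        quality_framework=quality_fw,
        quality_total=quality_total,
        log=log,
    )
    if out_dir is not None:
        _write_outputs(result, dataset, phymap, Path(out_dir))
    return result


def _write_outputs(
    result: AutoMapResult,
    dataset: SegregationDataset,
    phymap: PhysicalMap | None,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if result.framework_map.groups:
        write_map(result.framework_map, out_dir / "framework.map")
    if result.total_map.groups:
        write_map(result.total_map, out_dir / "total.map")
    with open(out_dir / "robustness.tsv", "w", encoding="utf-8") as fh:
        fh.write("# group\tmarker\tgap_log10\tthreshold\tpass\n")
        for k, rep in enumerate(result.robustness):
            for name, gap in zip(rep.marker_names, rep.gaps):
                ok = "yes" if gap >= rep.threshold - 1e-9 else "no"
                fh.write(f"LG{k + 1}\t{name}\t{gap:.4f}\t{rep.threshold:.2f}\t{ok}\n")
    write_error_report(result.flags, dataset, out_dir / "errors.tsv")
    write_lod_matrix(dataset, out_dir / "lod_matrix.tsv", lod=result.lod_matrix)
    if phymap is not None and len(phymap):
        write_marey_table(result.total_map, phymap, out_dir / "marey.tsv")
    with open(out_dir / "run.log", "w", encoding="utf-8") as fh:
        fh.write("\n".join(result.log) + "\n")
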