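"""Readers and writers for segregation data, anchor maps and map/QC tables.

Dialects
--------
``.raw`` (inbred-derived populations, MapMaker-compatible subset)::

    data type F2
    3 2
    *m1 A H B
    *m2 A - B

First line declares the population type (``BC``, ``DH``, ``F2``,
``RIL``/``RIL6``, ``IRIL2``), second line gives ``n_individuals
n_markers``, then one line per marker: ``*name`` followed by one code
per individual (space-separated, or a single unbroken code string).

``.gen`` (cross-pollinated full-sib families)::

    data type CP
    3 2
    *m1 abxaa
    ab aa --
    *m2 abxcd
    ac bd ad

Each marker carries both parental genotypes (``<P1>x<P2>``) and the
offspring unordered allele pairs, ``--`` for missing.

All output tables are tab-separated UTF-8 with ``#``-prefixed comments.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CODE_TO_INT,
    MISSING,
    _MISSING_TOKENS,
    CPMarkerInfo,
    GeneticMap,
    LinkageGroup,
    MapEntry,
    PhysicalMap,
    PopulationType,
    SegregationDataset,
    _norm_genotype,
)


class FormatError(ValueError):
    """A segregation-data or map file violates its dialect."""


def _data_lines(path: str | Path) -> list[str]:
    lines = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            lines.append(line)
    return lines


def _parse_header(lines: list[str], path) -> tuple[PopulationType, int, int]:
    if len(lines) < 2:
        raise FormatError(f"{path}: missing header lines")
    first = lines[0].split()
    if len(first) < 3 or first[0].lower() != "data" or first[1].lower() != "type":
        raise FormatError(f"{path}: first line must be 'data type <poptype>'")
    pop = PopulationType.parse(first[2])
    counts = lines[1].split()
    if len(counts) != 2:
        raise FormatError(f"{path}: second line must be '<n_ind> <n_mark>'")
    return pop, int(counts[0]), int(counts[1])


def read_raw(path: str | Path) -> SegregationDataset:
    """Read inbred-population segregation data in the ``.raw`` dialect."""
    lines = _data_lines(path)
    pop, n_ind, n_mark = _parse_header(lines, path)
    if pop.is_cp:
        raise FormatError(f"{path}: CP data must use the .gen dialect")
    alphabet = pop.alphabet
    names: list[str] = []
    rows: list[list[int]] = []
    for line in lines[2:]:
        if not line.startswith("*"):
            raise FormatError(f"{path}: expected marker line starting with '*', got {line!r}")
        toks = line[1:].split()
        name, codes = toks[0], toks[1:]
        if len(codes) == 1 and len(codes[0]) == n_ind and n_ind > 1:
            codes = list(codes[0])  # unbroken code string
        if len(codes) != n_ind:
            raise FormatError(
                f"{path}: marker {name!r} has {len(codes)} codes, header declares {n_ind}"
            )
        row = []
        for i, c in enumerate(codes):
            cu = c.upper()
            if cu in _MISSING_TOKENS or c in _MISSING_TOKENS:
                row.append(MISSING)
            elif cu in alphabet:
                row.append(CODE_TO_INT[cu])
            else:
                raise FormatError(
                    f"{path}: unknown code {c!r} at marker {name!r}, individual {i + 1} "
                    f"(alphabet of {pop}: {sorted(alphabet)})"
                )
        names.append(name)
        rows.append(row)
    if len(names) != n_mark:
        raise FormatError(f"{path}: {len(names)} markers found, header declares {n_mark}")
    ds = SegregationDataset(
        population=pop,
        marker_names=names,
        individual_names=[f"ind{i + 1}" for i in range(n_ind)],
        genotypes=np.array(rows, dtype=np.int8),
    )
    return ds


def read_gen(path: str | Path) -> SegregationDataset:
    """Read CP segregation data in the ``.gen`` dialect.

    Per-marker segregation classes (female-, male- or both-informative)
    are derived from the parental genotypes; offspring codes are checked
    against the parental alleles.
    """
    lines = _data_lines(path)
    pop, n_ind, n_mark = _parse_header(lines, path)
    if not pop.is_cp:
        raise FormatError(f"{path}: .gen dialect requires 'data type CP'")
    names: list[str] = []
    infos: list[CPMarkerInfo] = []
    rows: list[list[int]] = []
    i = 2
    while i < len(lines):
        line = lines[i]
        if not line.startswith("*"):
            raise FormatError(f"{path}: expected marker line starting with '*', got {line!r}")
        toks = line[1:].split()
        name = toks[0]
        spec = "".join(toks[1:]).lower()
        if "x" not in spec:
            raise FormatError(f"{path}: marker {name!r}: parental spec must be '<P1>x<P2>'")
        p1s, p2s = spec.split("x", 1)
        if len(p1s) != 2 or len(p2s) != 2:
            raise FormatError(f"{path}: marker {name!r}: parental genotypes must be 2 alleles")
        info = CPMarkerInfo(parent1=(p1s[0], p1s[1]), parent2=(p2s[0], p2s[1]))
        codes: list[str] = []
        i += 1
        while i < len(lines) and len(codes) < n_ind and not lines[i].startswith("*"):
            codes.extend(lines[i].split())
            i += 1
        if len(codes) != n_ind:
            raise FormatError(
                f"{path}: marker {name!r} has {len(codes)} offspring codes, "
                f"header declares {n_ind}"
            )
        row = []
        valid = set(info.classes)
        for j, c in enumerate(codes):
            if c in _MISSING_TOKENS:
                row.append(MISSING)
                continue
            g = _norm_genotype(c.lower())
            if g not in valid:
                raise FormatError(
                    f"{path}: marker {name!r}, individual {j + 1}: offspring genotype "
                    f"{c!r} is impossible under parents {p1s}x{p2s} "
                    f"(putative non-Mendelian call)"
                )
            row.append(info.class_index(g))
        names.append(name)
        infos.append(info)
        rows.append(row)
    if len(names) != n_mark:
        raise FormatError(f"{path}: {len(names)} markers found, header declares {n_mark}")
    return SegregationDataset(
        population=pop,
        marker_names=names,
        individual_names=[f"ind{i + 1}" for i in range(n_ind)],
        genotypes=np.array(rows, dtype=np.int8),
        cp_info=infos,
    )


def write_raw(dataset: SegregationDataset, path: str | Path) -> None:
    """Write an inbred dataset in the ``.raw`` dialect."""
    if dataset.population.is_cp:
        raise ValueError("CP datasets are written with write_gen")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"data type {dataset.population}\n")
        fh.write(f"{dataset.n_individuals} {dataset.n_markers}\n")
        for m, name in enumerate(dataset.marker_names):
            codes = " ".join(dataset.code_string(m, i) for i in range(dataset.n_individuals))
            fh.write(f"*{name} {codes}\n")


def write_gen(dataset: SegregationDataset, path: str | Path) -> None:
    """Write a CP dataset in the ``.gen`` dialect."""
    if not dataset.population.is_cp:
        raise ValueError("only CP datasets are written with write_gen")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("data type CP\n")
        fh.write(f"{dataset.n_individuals} {dataset.n_markers}\n")
        for m, name in enumerate(dataset.marker_names):
            info = dataset.cp_info[m]
            p1 = "".join(info.parent1)
            p2 = "".join(info.parent2)
            fh.write(f"*{name} {p1}x{p2}\n")
            fh.write(" ".join(dataset.code_string(m, i) for i in range(dataset.n_individuals)))
            fh.write("\n")


def write_dataset(dataset: SegregationDataset, path: str | Path) -> None:
    """Dispatch to :func:`write_raw` or :func:`write_gen` by population."""
    if dataset.population.is_cp:
        write_gen(dataset, path)
    else:
        write_raw(dataset, path)


def read_segregation(path: str | Path) -> SegregationDataset:
    """Read either dialect, dispatching on the declared population type."""
    lines = _data_lines(path)
    pop, _, _ = _parse_header(lines, path)
    return read_gen(path) if pop.is_cp else read_raw(path)


def read_physical_map(path: str | Path) -> PhysicalMap:
    """Read a marker/chromosome/position anchor table (phyMap-style)."""
    rows = []
    for line in _data_lines(path):
        toks = line.split()
        if len(toks) < 3:
            raise FormatError(f"{path}: expected 'marker chromosome position', got {line!r}")
        try:
            pos = float(toks[2])
        except ValueError:
            if not rows:  # tolerate a single header line
                continue
            raise FormatError(f"{path}: non-numeric position {toks[2]!r}") from None
        rows.append({"marker": toks[0], "chromosome": toks[1], "position": pos})
    table = pd.DataFrame(rows, columns=["marker", "chromosome", "position"])
    return PhysicalMap(table=table)


def write_physical_map(phymap: PhysicalMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# marker\tchromosome\tposition\n")
        for _, row in phymap.table.iterrows():
            fh.write(f"{row['marker']}\t{row['chromosome']}\t{row['position']:.6f}\n")


# ---------------------------------------------------------------- maps


def write_map(genetic_map: GeneticMap, path: str | Path) -> None:
    """Write a genetic map as a tab-separated table.

    Columns: group, marker, cumulative position (cM), status
    (scaffold/framework/placed), and for placed markers the flanking
    framework markers defining the bin.
    """
    if not genetic_map.groups:
        raise ValueError("refusing to write an empty map")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# group\tmarker\tposition_cM\tstatus\tbin_left\tbin_right\n")
        for g in genetic_map.groups:
            for e in g.entries:
                fh.write(
                    f"{g.name}\t{e.marker}\t{e.position:.9f}\t{e.status}\t"
                    f"{e.bin_left or '.'}\t{e.bin_right or '.'}\n"
                )


def read_map(path: str | Path) -> GeneticMap:
    """Read a map written by :func:`write_map` (round-trip identity)."""
    groups: dict[str, list[MapEntry]] = {}
    order: list[str] = []
    for line in _data_lines(path):
        toks = line.split("\t")
        if len(toks) != 6:
            raise FormatError(f"{path}: expected 6 tab-separated fields, got {line!r}")
        gname, marker, pos, status, bl, br = toks
        if gname not in groups:
            groups[gname] = []
            order.append(gname)
        groups[gname].append(
            MapEntry(
                marker=marker,
                position=float(pos),
                status=status,
                bin_left=None if bl == "." else bl,
                bin_right=None if br == "." else br,
            )
        )
    return GeneticMap([LinkageGroup(name, groups[name]) for name in order])


def write_lod_matrix(
    dataset: SegregationDataset,
    path: str | Path,
    lod: np.ndarray | None = None,
) -> None:
    """Write the pairwise 2-point LOD matrix (heat-map input).

    Diagonal cells carry the sentinel ``NA`` (a self-pair has no LOD).
    If ``lod`` is not given the matrix is computed from the dataset.
    """
    if lod is None:
        from .models import two_point_matrix

        _, lod = two_point_matrix(dataset)
    names = dataset.marker_names
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("marker\t" + "\t".join(names) + "\n")
        for i, name in enumerate(names):
            cells = ["NA" if i == j else f"{lod[i, j]:.4f}" for j in range(len(names))]
            fh.write(name + "\t" + "\t".join(cells) + "\n")


def write_marey_table(
    genetic_map: GeneticMap, phymap: PhysicalMap, path: str | Path
) -> pd.DataFrame:
    """Write genetic-vs-physical positions for markers present in both.

    The table drives a Marey map: genetic position against physical
    position, whose slope is the local recombination rate.
    """
    rows = []
    for g in genetic_map.groups:
        for e in g.entries:
            chrom = phymap.chromosome_of(e.marker)
            if chrom is None:
                continue
            rows.append(
                {
                    "marker": e.marker,
                    "phys_chromosome": chrom,
                    "phys_position": phymap.position_of(e.marker),
                    "genetic_group": g.name,
                    "genetic_position": e.position,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "marker",
            "phys_chromosome",
            "phys_position",
            "genetic_group",
            "genetic_position",
        ],
    )
    if table.empty:
        warnings.warn("no markers shared between genetic map and physical map")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + "\t".join(table.columns) + "\n")
        for _, row in table.iterrows():
            fh.write(
                f"{row['marker']}\t{row['phys_chromosome']}\t{row['phys_position']:.6f}\t"
                f"{row['genetic_group']}\t{row['genetic_position']:.6f}\n"
            )
    return table


def write_graphical_genotypes(
    dataset: SegregationDataset, genetic_map: GeneticMap, path: str | Path
) -> None:
    """Write map-ordered genotype codes per individual (graphical genotypes).

    One row per mapped marker: group, position, then the observed code of
    every individual in dataset order.  Rendering is left to the caller.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# group\tmarker\tposition_cM\t" + "\t".join(dataset.individual_names) + "\n")
        for g in genetic_map.groups:
            for e in g.entries:
                try:
                    m = dataset.marker_index(e.marker)
                except KeyError:
                    continue
                codes = "\t".join(
                    dataset.code_string(m, i) for i in range(dataset.n_individuals)
                )
                fh.write(f"{g.name}\t{e.marker}\t{e.position:.4f}\t{codes}\n")
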