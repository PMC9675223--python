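"""Linkage-group assignment and bin placement of non-framework markers.

Every polymorphic marker is assigned to the linkage group holding its
best 2-point LOD partner (subject to a minimum LOD and a gap over the
runner-up group), then markers that did not enter the framework are
*placed*: evaluated by multipoint likelihood at every framework
interval and recorded in the maximizing bin with an ML within-bin
position.  The framework skeleton and its cumulative positions are
frozen by construction — placement adds rows, never moves them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .error_handling import TwinGroups
from .models import haldane_r_to_d
from .multipoint import FittedChain, MultipointModel
from .types import GeneticMap, LinkageGroup, MapEntry, SegregationDataset

ASSIGN_LOD = 6.0
ASSIGN_GAP = 3.0


@dataclass
class AssignmentResult:
    """Per-marker linkage-group assignment.

    status: 'assigned' (clear winner), 'ambiguous' (>= 2 groups within
    the gap), 'unlinked' (best LOD below the threshold).
    """

    marker_indices: list[int]
    best_group: np.ndarray  # group index, -1 if none
    best_lod: np.ndarray
    second_lod: np.ndarray
    status: list[str]

    def assigned_to(self, group: int) -> list[int]:
        return [
            m
            for k, m in enumerate(self.marker_indices)
            if self.status[k] == "assigned" and self.best_group[k] == group
        ]


def assign_markers(
    dataset: SegregationDataset,
    groups: list[list[int]],
    lod_mat: np.ndarray,
    assign_lod: float = ASSIGN_LOD,
    assign_gap: float = ASSIGN_GAP,
    markers: list[int] | None = None,
) -> AssignmentResult:
    """Assign markers to linkage groups by best 2-point LOD.

    ``groups`` holds the marker indices of each built group (scaffold
    or framework).  A marker already inside a group is trivially
    assigned to it.
    """
    if markers is None:
        markers = list(range(dataset.n_markers))
    member_of = {}
    for g, members in enumerate(groups):
        for m in members:
            member_of[m] = g
    best_group = np.full(len(markers), -1, dtype=int)
    best_lod = np.zeros(len(markers))
    second_lod = np.zeros(len(markers))
    status: list[str] = []
    for k, m in enumerate(markers):
        if m in member_of:
            best_group[k] = member_of[m]
            best_lod[k] = np.inf
            status.append("assigned")
            continue
        lods = np.array(
            [np.max(lod_mat[m, members]) if members else 0.0 for members in groups]
        )
        order = np.argsort(-lods)
        best_group[k] = order[0]
        best_lod[k] = lods[order[0]]
        second_lod[k] = lods[order[1]] if len(lods) > 1 else 0.0
        if best_lod[k] < assign_lod:
            best_group[k] = -1
            status.append("unlinked")
        elif best_lod[k] - second_lod[k] < assign_gap:
            status.append("ambiguous")
        else:
            status.append("assigned")
    return AssignmentResult(
        marker_indices=list(markers),
        best_group=best_group,
        best_lod=best_lod,
        second_lod=second_lod,
        status=status,
    )


@dataclass
class BinPlacement:
    marker: int
    bin_left: int | None  # framework marker indices flanking the bin
    bin_right: int | None
    offset_cM: float  # from the left flank (or before the first marker)
    dll: float


def place_markers(
    framework: MultipointModel,
    assigned_non_framework: list[int],
    dataset: SegregationDataset,
    group_name: str = "LG1",
    twins: TwinGroups | None = None,
    scaffold_set: set[int] | None = None,
) -> LinkageGroup:
    """Place leftover markers into framework bins; build the total map group.

    Each marker is evaluated at every interval (and beyond both ends)
    of the framework and recorded at its maximum-likelihood position.
    Markers falling before the first framework marker are truncated to
    position 0 so the group origin — and every framework position —
    stays untouched.  Twins are re-attached at their representative's
    position.
    """
    chain = FittedChain(framework, dataset)
    dist = framework.distances_cM()
    cum = np.concatenate([[0.0], np.cumsum(dist)])
    names = dataset.marker_names
    scaffold_set = scaffold_set or set()

    entries: list[MapEntry] = []
    for k, m in enumerate(framework.marker_indices):
        status = "scaffold" if m in scaffold_set else "framework"
        entries.append(MapEntry(marker=names[m], position=float(cum[k]), status=status))

    placements: list[BinPlacement] = []
    for m in assigned_non_framework:
        scan = chain.scan_marker(int(m), refine_top=1)
        best = scan.best()
        kind, k = scan.positions[best]
        if kind == "start":
            placements.append(
                BinPlacement(
                    marker=m,
                    bin_left=None,
                    bin_right=framework.marker_indices[0],
                    offset_cM=0.0,  # truncated to the group origin
                    dll=float(scan.dll[best]),
                )
            )
        elif kind == "end":
            placements.append(
                BinPlacement(
                    marker=m,
                    bin_left=framework.marker_indices[-1],
                    bin_right=None,
                    offset_cM=float(scan.detail[best]),
                    dll=float(scan.dll[best]),
                )
            )
        else:
            t = float(scan.detail[best])
            placements.append(
                BinPlacement(
                    marker=m,
                    bin_left=framework.marker_indices[k],
                    bin_right=framework.marker_indices[k + 1],
                    offset_cM=t * float(dist[k]),
                    dll=float(scan.dll[best]),
                )
            )

    fw_pos = {m: float(cum[k]) for k, m in enumerate(framework.marker_indices)}
    placed_pos: dict[int, float] = {}
    for p in placements:
        if p.bin_left is None:
            pos = 0.0
        else:
            pos = fw_pos[p.bin_left] + p.offset_cM
        placed_pos[p.marker] = pos
        entries.append(
            MapEntry(
                marker=names[p.marker],
                position=pos,
                status="placed",
                bin_left=names[p.bin_left] if p.bin_left is not None else None,
                bin_right=names[p.bin_right] if p.bin_right is not None else None,
            )
        )

    if twins is not None:
        anchored = {e.marker for e in entries}
        by_name = {names[m]: m for m in range(dataset.n_markers)}
        for e in list(entries):
            rep = by_name.get(e.marker)
            if rep is None:
                continue
            for tw in twins.attached_to(rep):
                if names[tw] in anchored:
                    continue
                entries.append(
                    MapEntry(
                        marker=names[tw],
                        position=e.position,
                        status="placed",
                        bin_left=e.bin_left if e.status == "placed" else e.marker,
                        bin_right=e.bin_right if e.status == "placed" else e.marker,
                    )
                )
                anchored.add(names[tw])

    status_rank = {"scaffold": 0, "framework": 0, "placed": 1}
    entries.sort(key=lambda e: (e.position, status_rank[e.status], e.marker))
    return LinkageGroup(name=group_name, entries=entries)


def framework_group(
    framework: MultipointModel,
    dataset: SegregationDataset,
    group_name: str = "LG1",
    scaffold_set: set[int] | None = None,
) -> LinkageGroup:
    """Linkage group holding only the framework skeleton."""
    return place_markers(
        framework, [], dataset, group_name=group_name, scaffold_set=scaffold_set
    )


def total_map(groups: list[LinkageGroup]) -> GeneticMap:
    return GeneticMap(groups=groups)
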