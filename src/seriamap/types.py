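"""Core containers: population types, segregation datasets, genetic maps."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Canonical genotype codes for inbred-derived populations.  C = "not A"
# (dominant B allele visible), D = "not B"; '-' is missing.
INBRED_CODES = ("A", "H", "B", "C", "D")
CODE_TO_INT = {c: i for i, c in enumerate(INBRED_CODES)}
INT_TO_CODE = {i: c for c, i in CODE_TO_INT.items()}
MISSING = -1

# Alphabets of observable codes per population kind.
ALPHABETS = {
    "BC": {"A", "B"},
    "DH": {"A", "B"},
    "F2": {"A", "B", "H", "C", "D"},
    "RIL": {"A", "B", "H"},
    "IRIL": {"A", "B", "H"},
}

_MISSING_TOKENS = {"-", "--", "U", "NA", ".", "?"}

_POP_RE = re.compile(r"^(BC|DH|F2|CP)$|^(RIL)(\d*)$|^(IRIL)(\d+)$", re.IGNORECASE)


@dataclass(frozen=True)
class PopulationType:
    """Mating design of a biparental mapping population.

    kind
        One of ``BC``, ``DH``, ``F2``, ``RIL``, ``IRIL``, ``CP``.
    selfing_generations
        For RIL: number of selfing generations applied to the F1
        (``1`` would be an F2).  ``None`` means selfed to fixation.
    intermating_generations
        For IRIL: generations of random intermating inserted between
        the F2 and the selfing phase.
    """

    kind: str
    selfing_generations: int | None = None
    intermating_generations: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("BC", "DH", "F2", "RIL", "IRIL", "CP"):
            raise ValueError(f"unknown population kind {self.kind!r}")

    @classmethod
    def parse(cls, token: str) -> "PopulationType":
        m = _POP_RE.match(token.strip())
        if m is None:
            raise ValueError(f"cannot parse population type {token!r}")
        if m.group(1):
            return cls(m.group(1).upper())
        if m.group(2):
            gens = int(m.group(3)) if m.group(3) else None
            return cls("RIL", selfing_generations=gens)
        return cls("IRIL", intermating_generations=int(m.group(5)))

    def __str__(self) -> str:
        if self.kind == "RIL" and self.selfing_generations is not None:
            return f"RIL{self.selfing_generations}"
        if self.kind == "IRIL":
            return f"IRIL{self.intermating_generations}"
        return self.kind

    @property
    def is_cp(self) -> bool:
        return self.kind == "CP"

    @property
    def alphabet(self) -> set[str]:
        if self.is_cp:
            raise ValueError("CP codes are per-marker allele pairs, not a fixed alphabet")
        return ALPHABETS[self.kind]


def _norm_genotype(g: str) -> str:
    """Canonical unordered allele pair, e.g. 'ba' -> 'ab'."""
    if len(g) != 2:
        raise ValueError(f"genotype {g!r} is not a two-allele string")
    return "".join(sorted(g))


@dataclass
class CPMarkerInfo:
    """Parental genotypes and offspring genotype classes for one CP marker."""

    parent1: tuple[str, str]
    parent2: tuple[str, str]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.parent1 = tuple(sorted(self.parent1))  # type: ignore[assignment]
        self.parent2 = tuple(sorted(self.parent2))  # type: ignore[assignment]
        if not self.classes:
            self.classes = sorted(
                {_norm_genotype(a + b) for a in self.parent1 for b in self.parent2}
            )

    @property
    def het1(self) -> bool:
        return self.parent1[0] != self.parent1[1]

    @property
    def het2(self) -> bool:
        return self.parent2[0] != self.parent2[1]

    @property
    def segregation_class(self) -> str:
        """'female', 'male', 'both' informativeness, or 'none'."""
        if self.het1 and self.het2:
            return "both"
        if self.het1:
            return "female"
        if self.het2:
            return "male"
        return "none"

    def class_index(self, genotype: str) -> int:
        return self.classes.index(_norm_genotype(genotype))


@dataclass
class SegregationDataset:
    """Marker x individual genotype observations for one mapping population.

    ``genotypes`` is an int8 matrix of shape (n_markers, n_individuals).
    For inbred-derived populations the entries are indices into
    :data:`INBRED_CODES` (A=0, H=1, B=2, C=3, D=4) with -1 for missing.
    For CP populations the entries index the marker's offspring genotype
    classes (``cp_info[m].classes``), again with -1 for missing.
    """

    population: PopulationType
    marker_names: list[str]
    individual_names: list[str]
    genotypes: np.ndarray
    cp_info: list[CPMarkerInfo] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    # -- basic shape -------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_names)

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"marker {name!r} not in dataset") from None

    def validate(self) -> None:
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("marker names are not unique")
        if len(set(self.individual_names)) != len(self.individual_names):
            raise ValueError("individual names are not unique")
        if self.n_markers < 2 or self.n_individuals < 1:
            raise ValueError("need at least 2 markers and 1 individual")
        if self.genotypes.shape != (self.n_markers, self.n_individuals):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{self.n_markers} markers x {self.n_individuals} individuals"
            )
        if self.population.is_cp:
            if self.cp_info is None or len(self.cp_info) != self.n_markers:
                raise ValueError("CP dataset requires per-marker parental info")
            for m, info in enumerate(self.cp_info):
                k = len(info.classes)
                col = self.genotypes[m]
                bad = (col < -1) | (col >= k)
                if bad.any():
                    raise ValueError(
                        f"marker {self.marker_names[m]!r}: class index out of range"
                    )
        else:
            allowed = {CODE_TO_INT[c] for c in self.population.alphabet} | {MISSING}
            present = set(np.unique(self.genotypes).tolist())
            extra = present - allowed
            if extra:
                codes = {INT_TO_CODE.get(v, str(v)) for v in extra}
                raise ValueError(
                    f"codes {sorted(codes)} not in the {self.population} alphabet"
                )

    # -- summaries ---------------------------------------------------
    def missing_counts(self) -> np.ndarray:
        return (self.genotypes == MISSING).sum(axis=1)

    def monomorphic_mask(self) -> np.ndarray:
        """True for markers whose non-missing calls show a single class.

        For F2, dominant codes are resolved conservatively: a marker is
        monomorphic only if all calls are mutually compatible with one
        genotype class.
        """
        out = np.zeros(self.n_markers, dtype=bool)
        for m in range(self.n_markers):
            col = self.genotypes[m]
            obs = col[col != MISSING]
            if obs.size == 0:
                out[m] = True
                continue
            if self.population.is_cp:
                out[m] = np.unique(obs).size <= 1 or self.cp_info[m].segregation_class == "none"
            else:
                # compatible genotype sets: A={A}, H={H}, B={B}, C={H,B}, D={A,H}
                comp = {0: {0}, 1: {1}, 2: {2}, 3: {1, 2}, 4: {0, 1}}
                common = {0, 1, 2}
                for v in np.unique(obs):
                    common &= comp[int(v)]
                out[m] = len(common) > 0
        return out

    def subset_markers(self, indices: list[int] | np.ndarray) -> "SegregationDataset":
        indices = list(indices)
        return SegregationDataset(
            population=self.population,
            marker_names=[self.marker_names[i] for i in indices],
            individual_names=list(self.individual_names),
            genotypes=self.genotypes[indices].copy(),
            cp_info=[self.cp_info[i] for i in indices] if self.cp_info else None,
        )

    def code_string(self, m: int, i: int) -> str:
        """Observed code at (marker m, individual i) as written in files."""
        v = int(self.genotypes[m, i])
        if v == MISSING:
            return "-" if not self.population.is_cp else "--"
        if self.population.is_cp:
            return self.cp_info[m].classes[v]
        return INT_TO_CODE[v]


@dataclass
class PhysicalMap:
    """Anchor map: per marker a chromosome label and a position.

    Position units (bp or cM) are recorded but never interpreted; the
    table is only used to guide seed drawing and for Marey tables.
    """

    table: pd.DataFrame  # columns: marker, chromosome, position
    unit: str = "unknown"

    def __post_init__(self) -> None:
        req = ["marker", "chromosome", "position"]
        if list(self.table.columns[:3]) != req:
            self.table.columns = req + list(self.table.columns[3:])
        if self.table["marker"].duplicated().any():
            dup = self.table.loc[self.table["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"marker {dup!r} appears more than once in physical map")
        if len(self.table) and (self.table["position"].astype(float) < 0).any():
            raise ValueError("physical positions must be non-negative")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"].astype(str)))

    def chromosome_of(self, marker: str) -> str | None:
        hit = self.table.loc[self.table["marker"] == marker, "chromosome"]
        return str(hit.iloc[0]) if len(hit) else None

    def position_of(self, marker: str) -> float | None:
        hit = self.table.loc[self.table["marker"] == marker, "position"]
        return float(hit.iloc[0]) if len(hit) else None


STATUSES = ("scaffold", "framework", "placed")


@dataclass
class MapEntry:
    marker: str
    position: float  # cumulative cM within the linkage group, first = 0
    status: str  # scaffold | framework | placed
    bin_left: str | None = None  # flanking framework markers (placed only)
    bin_right: str | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass
class LinkageGroup:
    name: str
    entries: list[MapEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check_positions()

    def _check_positions(self) -> None:
        pos = [e.position for e in self.entries]
        if pos and pos[0] > 1e-9:
            raise ValueError(f"group {self.name}: first position must be 0")
        if any(b < a - 1e-9 for a, b in zip(pos, pos[1:])):
            raise ValueError(f"group {self.name}: positions must be non-decreasing")

    @property
    def markers(self) -> list[str]:
        return [e.marker for e in self.entries]

    @property
    def positions(self) -> np.ndarray:
        return np.array([e.position for e in self.entries], dtype=float)

    @property
    def length(self) -> float:
        return self.entries[-1].position if self.entries else 0.0

    def framework_entries(self) -> list[MapEntry]:
        return [e for e in self.entries if e.status in ("scaffold", "framework")]


@dataclass
class GeneticMap:
    """Ordered linkage groups with cumulative cM positions per marker."""

    groups: list[LinkageGroup] = field(default_factory=list)

    @property
    def n_markers(self) -> int:
        return sum(len(g.entries) for g in self.groups)

    @property
    def marker_set(self) -> set[str]:
        return {e.marker for g in self.groups for e in g.entries}

    @property
    def total_length(self) -> float:
        return sum(g.length for g in self.groups)

    def group_of(self, marker: str) -> str | None:
        for g in self.groups:
            if marker in g.markers:
                return g.name
        return None

    def position_of(self, marker: str) -> tuple[str, float] | None:
        for g in self.groups:
            for e in g.entries:
                if e.marker == marker:
                    return g.name, e.position
        return None

    def framework_view(self) -> "GeneticMap":
        """Map restricted to scaffold/framework markers, positions rebased to 0."""
        out = []
        for g in self.groups:
            fw = g.framework_entries()
            if not fw:
                continue
            base = fw[0].position
            out.append(
                LinkageGroup(
                    g.name,
                    [MapEntry(e.marker, e.position - base, e.status) for e in fw],
                )
            )
        return GeneticMap(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for e in g.entries:
                rows.append(
                    {
                        "group": g.name,
                        "marker": e.marker,
                        "position": e.position,
                        "status": e.status,
                        "bin_left": e.bin_left or "",
                        "bin_right": e.bin_right or "",
                    }
                )
        return pd.DataFrame(
            rows, columns=["group", "marker", "position", "status", "bin_left", "bin_right"]
        )
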