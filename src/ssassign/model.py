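"""Core value types shared across the package."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .atoms import AA1, ONE_TO_THREE


@dataclass
class Peak:
    """One picked resonance: a ppm coordinate per axis, optional height/label."""

    position: tuple[float, ...]
    height: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.position = tuple(float(p) for p in self.position)
        if not all(math.isfinite(p) for p in self.position):
            raise ValueError(f"non-finite peak position {self.position}")


@dataclass
class PeakList:
    """All peaks picked from one experiment's spectrum."""

    experiment_name: str
    dimensionality: int
    axis_nuclei: tuple[str, ...]
    peaks: list[Peak] = field(default_factory=list)
    axis_offsets: tuple[float, ...] = ()
    skipped_lines: int = 0
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.axis_offsets:
            self.axis_offsets = (0.0,) * self.dimensionality
        if len(self.axis_nuclei) != self.dimensionality:
            raise ValueError("axis_nuclei length must equal dimensionality")
        for pk in self.peaks:
            if len(pk.position) != self.dimensionality:
                raise ValueError(
                    f"peak {pk.position} does not match dimensionality "
                    f"{self.dimensionality}"
                )

    def with_offsets_applied(self) -> "PeakList":
        """Return a copy with axis offsets subtracted from every position
        (offsets reset to zero)."""
        if all(o == 0.0 for o in self.axis_offsets):
            return self
        peaks = [
            Peak(
                tuple(p - o for p, o in zip(pk.position, self.axis_offsets)),
                pk.height,
                pk.label,
            )
            for pk in self.peaks
        ]
        return PeakList(
            self.experiment_name, self.dimensionality, self.axis_nuclei,
            peaks, (0.0,) * self.dimensionality, self.skipped_lines, self.source,
        )


@dataclass
class ProteinSequence:
    residues: str
    first_index: int = 1

    def __post_init__(self) -> None:
        bad = [r for r in self.residues if r not in AA1]
        if bad:
            raise ValueError(f"unknown residue code(s): {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.residues)

    def type_at(self, index: int) -> str:
        """One-letter code at a sequence position (using the numbering origin)."""
        return self.residues[index - self.first_index]

    def positions(self) -> range:
        return range(self.first_index, self.first_index + len(self.residues))

    def three_letter(self, index: int) -> str:
        return ONE_TO_THREE[self.type_at(index)]


@dataclass(frozen=True)
class ShiftEntry:
    residue_index: int
    residue_type: str  # one-letter
    atom: str
    ppm: float


class ShiftTable:
    """Reference chemical shifts: (residue index, type, atom) -> ppm."""

    def __init__(self, entries: Iterable[ShiftEntry]):
        self.entries: list[ShiftEntry] = list(entries)
        self._map = {(e.residue_index, e.atom): e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, residue_index: int, atom: str) -> Optional[float]:
        e = self._map.get((residue_index, atom))
        return e.ppm if e is not None else None

    def residue_type(self, residue_index: int) -> Optional[str]:
        for e in self.entries:
            if e.residue_index == residue_index:
                return e.residue_type
        return None

    def residue_indices(self) -> list[int]:
        return sorted({e.residue_index for e in self.entries})


# ---------------------------------------------------------------------------
# Spin systems

@dataclass(frozen=True)
class Contribution:
    """Audit-trail record: one peak axis feeding one slot of a spin system."""

    experiment: str
    peak_index: int
    axis_index: int
    side: str       # 'root' | 'own' | 'prev'
    atom: str       # canonical atom name, or 'CX' when unresolved
    value: float


@dataclass
class RootTriple:
    co_prev: float
    n: float
    ca: float
    support: list[Contribution] = field(default_factory=list)
    weight: int = 1


@dataclass
class SpinSystem:
    """One pseudo-residue row of the spin-system matrix: shifts of residue i
    plus the carbons of residue i-1 reached through CO(i-1)/N(i)/CA(i)."""

    id: int
    root: RootTriple
    own: dict[str, float] = field(default_factory=dict)    # atoms of residue i
    prev: dict[str, float] = field(default_factory=dict)   # atoms of residue i-1
    own_cx: list[float] = field(default_factory=list)      # unresolved carbons, residue i
    prev_cx: list[float] = field(default_factory=list)     # unresolved carbons, residue i-1
    support: list[Contribution] = field(default_factory=list)


@dataclass
class SpinSystemMatrix:
    systems: list[SpinSystem]
    tol_c: float
    tol_n: float
    quality: float = float("nan")

    def __len__(self) -> int:
        return len(self.systems)


@dataclass(frozen=True)
class DiPeptideLink:
    """Evidence that the residue of `to_id` directly follows that of `from_id`."""

    from_id: int
    to_id: int
    deltas: dict[str, float]
    score: float


@dataclass
class AssignmentCandidate:
    system_id: int
    position: Optional[int]   # None = the reserved unassigned slot
    probability: float


@dataclass
class ResidueAssignment:
    residue_index: int
    residue_type: str
    atoms: dict[str, tuple[float, float]]  # atom -> (ppm, probability)
    best_probability: float
    system_id: Optional[int] = None


@dataclass
class ConvergenceRecord:
    rounds: int
    bp_iterations: list[int]
    converged: bool
    final_message_delta: float


@dataclass
class AssignmentResult:
    residues: dict[int, ResidueAssignment]
    candidates: dict[int, list[AssignmentCandidate]]  # system id -> marginals
    offsets: dict[str, dict[str, float]]  # experiment -> nucleus -> ppm
    convergence: Optional[ConvergenceRecord] = None
    sequence: Optional[ProteinSequence] = None
    assigned_systems: dict[int, int] = field(default_factory=dict)  # position -> system id
    final_matrix: Optional["SpinSystemMatrix"] = None  # matrix of the last round

    def iter_shifts(self):
        """Yield (residue_index, residue_type, atom, ppm, probability)."""
        for idx in sorted(self.residues):
            ra = self.residues[idx]
            for atom in sorted(ra.atoms):
                ppm, prob = ra.atoms[atom]
                yield idx, ra.residue_type, atom, ppm, prob

    def n_shifts(self) -> int:
        return sum(len(ra.atoms) for ra in self.residues.values())
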