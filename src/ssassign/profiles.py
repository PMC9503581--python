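"""Registry of the supported solid-state NMR experiments.

Each experiment is a connectivity template: per axis, a set of atom roles and
a residue offset (0 for residue i, -1 for the preceding residue). Role tokens:

* ``N``  — backbone amide nitrogen
* ``CA`` / ``CB`` / ``CO`` — the named backbone carbons (``CO`` = carbonyl)
* ``CX`` — any carbon at positions A, B, D, E, G or H (so CA and CB are
  included, the carbonyl and zeta carbons are not)

Slash notation in the printed profile string ("CX/O") means the union of the
named roles on a single axis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .atoms import cx_atoms
from .model import ProteinSequence


@dataclass(frozen=True)
class Axis:
    roles: frozenset[str]
    offset: int  # 0 or -1

    @property
    def nucleus(self) -> str:
        return "15N" if self.roles == {"N"} else "13C"


@dataclass(frozen=True)
class ExperimentProfile:
    name: str            # registry key, e.g. "NCACB-3D"
    display: str         # profile string as conventionally printed
    dimensionality: int
    axes: tuple[Axis, ...]
    minimum_set: bool = False

    @property
    def axis_nuclei(self) -> tuple[str, ...]:
        return tuple(ax.nucleus for ax in self.axes)


def _ax(roles: str, offset: int) -> Axis:
    return Axis(frozenset(roles.split("/")), offset)


_ROWS: list[ExperimentProfile] = [
    ExperimentProfile("CC", "CX/O(i)-CX/O(i)", 2,
                      (_ax("CX/CO", 0), _ax("CX/CO", 0)), True),
    ExperimentProfile("NCA", "N(i)-CA(i)", 2,
                      (_ax("N", 0), _ax("CA", 0)), True),
    ExperimentProfile("NCACB-2D", "N(i)-CA/B(i)", 2,
                      (_ax("N", 0), _ax("CA/CB", 0))),
    ExperimentProfile("NCO", "N(i)-CO(i-1)", 2,
                      (_ax("N", 0), _ax("CO", -1)), True),
    ExperimentProfile("NCACO", "N(i)-CA(i)-CO(i)", 3,
                      (_ax("N", 0), _ax("CA", 0), _ax("CO", 0))),
    ExperimentProfile("NCACB-3D", "N(i)-CA(i)-CA/B(i)", 3,
                      (_ax("N", 0), _ax("CA", 0), _ax("CA/CB", 0))),
    ExperimentProfile("NCACX", "N(i)-CA(i)-CX(i)", 3,
                      (_ax("N", 0), _ax("CA", 0), _ax("CX", 0)), True),
    ExperimentProfile("NCOCX", "N(i)-CO(i-1)-CX/C(i-1)", 3,
                      (_ax("N", 0), _ax("CO", -1), _ax("CX/CO", -1)), True),
    ExperimentProfile("NCOCA", "N(i)-CO(i-1)-CA(i-1)", 3,
                      (_ax("N", 0), _ax("CO", -1), _ax("CA", -1))),
    ExperimentProfile("NCOCACB", "N(i)-CO(i-1)-CA/B(i-1)", 3,
                      (_ax("N", 0), _ax("CO", -1), _ax("CA/CB", -1))),
    ExperimentProfile("CANCO", "CA(i)-N(i)-CO(i-1)", 3,
                      (_ax("CA", 0), _ax("N", 0), _ax("CO", -1))),
    ExperimentProfile("CANCOCX", "CA(i)-N(i)-CX/O(i-1)", 3,
                      (_ax("CA", 0), _ax("N", 0), _ax("CX/CO", -1)), True),
    ExperimentProfile("CANCOCA", "CA(i)-N(i)-CA/O(i-1)", 3,
                      (_ax("CA", 0), _ax("N", 0), _ax("CA/CO", -1))),
    ExperimentProfile("CANCOCACB", "CA(i)-N(i)-CO/A/B(i-1)", 3,
                      (_ax("CA", 0), _ax("N", 0), _ax("CO/CA/CB", -1))),
]

REGISTRY: dict[str, ExperimentProfile] = {p.name: p for p in _ROWS}

MINIMUM_SET: tuple[str, ...] = tuple(p.name for p in _ROWS if p.minimum_set)


class UnknownExperimentError(KeyError):
    pass


def normalize_name(name: str) -> str:
    """Map user spellings ("2D-NCA", "nca", "3D-NCACB") to registry keys."""
    tok = name.strip().upper().replace("_", "-")
    dim_hint = None
    for prefix in ("2D-", "3D-"):
        if tok.startswith(prefix):
            dim_hint = int(prefix[0])
            tok = tok[3:]
    if tok == "NCACB":
        # ambiguous row: 2D and 3D variants both exist; plain name -> 3D
        return f"NCACB-{dim_hint or 3}D"
    if tok in REGISTRY:
        return tok
    raise UnknownExperimentError(
        f"unknown experiment {name!r}; supported: {', '.join(sorted(REGISTRY))}"
    )


def get_profile(name: str) -> ExperimentProfile:
    key = normalize_name(name)
    profile = REGISTRY[key]
    return profile


def _covers(sup: ExperimentProfile, sub: ExperimentProfile) -> bool:
    """True when `sup`'s projection contains every axis of `sub`."""
    used: set[int] = set()
    for ax in sub.axes:
        hit = None
        for j, bx in enumerate(sup.axes):
            if j in used:
                continue
            if bx.offset == ax.offset and ax.roles <= bx.roles:
                hit = j
                break
        if hit is None:
            return False
        used.add(hit)
    return True


@dataclass
class ValidationReport:
    ok: bool
    missing: list[str]
    unknown: list[str]
    satisfied_by_superset: dict[str, str]

    def __bool__(self) -> bool:
        return self.ok


def validate_experiment_set(names: list[str]) -> ValidationReport:
    """Check a user experiment list against the minimum required set.

    A missing minimum-set member counts as satisfied when a provided
    higher-dimensional experiment's projection contains it.
    """
    known: list[ExperimentProfile] = []
    unknown: list[str] = []
    for n in names:
        try:
            known.append(get_profile(n))
        except UnknownExperimentError:
            unknown.append(n)
    present = {p.name for p in known}
    missing: list[str] = []
    via_superset: dict[str, str] = {}
    for req in MINIMUM_SET:
        if req in present:
            continue
        sub = REGISTRY[req]
        sup = next((p for p in known if _covers(p, sub)), None)
        if sup is not None:
            via_superset[req] = sup.name
        else:
            missing.append(req)
    return ValidationReport(not missing, missing, unknown, via_superset)


@dataclass(frozen=True)
class PeakTemplate:
    """One predicted sequential cross-peak: per axis, which residue and atom."""

    residues: tuple[int, ...]
    atoms: tuple[str, ...]


def _axis_atoms(ax: Axis, res_type: str) -> tuple[str, ...]:
    from .atoms import HEAVY_ATOMS
    out: list[str] = []
    inventory = HEAVY_ATOMS[res_type]
    for role in sorted(ax.roles):
        if role == "N":
            out.append("N")
        elif role == "CO":
            out.append("C")
        elif role == "CX":
            out.extend(cx_atoms(res_type))
        elif role in inventory:
            out.append(role)
    # stable dedup
    seen: set[str] = set()
    uniq = [a for a in out if not (a in seen or seen.add(a))]
    return tuple(uniq)


def expected_peaks(profile: ExperimentProfile,
                   sequence: ProteinSequence) -> list[PeakTemplate]:
    """Enumerate every sequential cross-peak the profile predicts.

    Residues lacking an atom (glycine CB) contribute no template for it; a
    residue with no predecessor produces nothing for profiles with an
    offset -1 axis. Templates whose axes would all read the same atom of the
    same residue (pure diagonal, relevant for CC) are dropped.
    """
    needs_prev = any(ax.offset == -1 for ax in profile.axes)
    out: list[PeakTemplate] = []
    for i in sequence.positions():
        if needs_prev and i == sequence.first_index:
            continue
        per_axis: list[list[tuple[int, str]]] = []
        ok = True
        for ax in profile.axes:
            ridx = i + ax.offset
            atoms = _axis_atoms(ax, sequence.type_at(ridx))
            if not atoms:
                ok = False
                break
            per_axis.append([(ridx, a) for a in atoms])
        if not ok:
            continue
        stack: list[list[tuple[int, str]]] = [[]]
        for choices in per_axis:
            stack = [acc + [c] for acc in stack for c in choices]
        for combo in stack:
            if len(set(combo)) == 1 and len(combo) > 1:
                continue  # diagonal
            out.append(PeakTemplate(tuple(r for r, _ in combo),
                                    tuple(a for _, a in combo)))
    return out
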