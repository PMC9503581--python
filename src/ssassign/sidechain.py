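"""Side-chain carbon assignment on top of a backbone assignment.

Candidate side-chain shifts come from the unresolved-carbon bags of the
residue's own spin system (and of the successor's preceding-residue bag),
plus 2D carbon-carbon peaks anchored at an already-assigned carbon of the
residue. Candidates are matched one-to-one to the residue type's unassigned
carbons by maximizing the summed log Gaussian density; each match carries
probability = backbone probability x its normalized match posterior.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .atoms import carbons
from .config import PipelineConfig
from .model import AssignmentResult, PeakList, SpinSystemMatrix
from .profiles import get_profile
from .statistics import ShiftStatistics

log = logging.getLogger(__name__)

_FLOOR = 1e-6  # density below this never matches

# stereo/degenerate pairs that may share one candidate value
_DEGENERATE_PAIRS = [("CD1", "CD2"), ("CE1", "CE2"), ("CG1", "CG2"),
                     ("CZ2", "CZ3")]


def _similarity_classes(targets: list[str], res_type: str,
                        stats: ShiftStatistics) -> list[list[str]]:
    """Partition target atoms into classes of overlapping reference
    statistics (|mean difference| <= 1.5 x the larger sd, transitively)."""
    parent = {t: t for t in targets}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, a in enumerate(targets):
        ma = stats.mean_sd(res_type, a)
        if ma is None:
            continue
        for b in targets[i + 1:]:
            mb = stats.mean_sd(res_type, b)
            if mb is None:
                continue
            if abs(ma[0] - mb[0]) <= 1.5 * max(ma[1], mb[1]):
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for t in targets:
        groups.setdefault(find(t), []).append(t)
    return list(groups.values())


def _ambiguity_units(members: list[str]) -> int:
    """Distinct alternatives within a class once twin pairs are pinned by
    the ascending-shift convention."""
    units = 0
    seen: set[str] = set()
    twin = {}
    for a1, a2 in _DEGENERATE_PAIRS:
        twin[a1], twin[a2] = a2, a1
    for t in members:
        if t in seen:
            continue
        tw = twin.get(t)
        if tw in members:
            seen.update((t, tw))
        else:
            seen.add(t)
        units += 1
    return max(1, units)


def _cc_candidates(peaklist: PeakList, anchors: list[float], tol: float
                   ) -> list[float]:
    """Partner coordinates of CC peaks whose other coordinate hits an
    already-assigned carbon."""
    out = []
    for pk in peaklist.peaks:
        a, b = pk.position
        if any(abs(a - x) <= tol for x in anchors):
            out.append(b)
        elif any(abs(b - x) <= tol for x in anchors):
            out.append(a)
    return out


def _dedup(values: list[float], tol: float) -> list[float]:
    out: list[float] = []
    for v in sorted(values):
        if not out or abs(v - out[-1]) > tol:
            out.append(v)
        else:
            out[-1] = (out[-1] + v) / 2.0
    return out


def assign_sidechains(result: AssignmentResult, matrix: SpinSystemMatrix,
                      peaklists: list[PeakList], stats: ShiftStatistics,
                      tol: float,
                      config: Optional[PipelineConfig] = None
                      ) -> AssignmentResult:
    """Augment `result` in place with side-chain carbon assignments for
    residues whose backbone probability clears the side-chain cutoff."""
    config = config or PipelineConfig()
    by_id = {s.id: s for s in matrix.systems}
    successor = {pos - 1: sid for pos, sid in result.assigned_systems.items()}
    cc_lists = [pl for pl in peaklists
                if get_profile(pl.experiment_name).name == "CC"]

    for pos in sorted(result.residues):
        ra = result.residues[pos]
        if ra.best_probability < config.sidechain_cutoff:
            continue
        assigned = {atom: ppm for atom, (ppm, _) in ra.atoms.items()}
        targets = [a for a in carbons(ra.residue_type) if a not in assigned]
        if not targets:
            continue
        # own-strip carbons are the cleanest source; the successor's
        # preceding-residue bag and CC peaks are progressively looser
        cand: list[float] = []
        sid = result.assigned_systems.get(pos)
        if sid is not None:
            cand += by_id[sid].own_cx
        if not cand:
            succ = successor.get(pos)
            if succ is not None:
                cand += by_id[succ].prev_cx
        anchors = [v for a, v in assigned.items() if a != "N"]
        if not cand:
            # carbon-carbon 2D peaks are a fallback only: their anchoring is
            # loose enough to pull in carbons of shift-degenerate residues
            for pl in cc_lists:
                cand += _cc_candidates(pl, anchors, tol)
        cand = [v for v in _dedup(cand, tol)
                if not any(abs(v - x) <= tol for x in anchors)]
        if not cand:
            continue

        classes = _similarity_classes(targets, ra.residue_type, stats)
        dens = np.array([[stats.density(v, ra.residue_type, a) for a in targets]
                         for v in cand])
        cost = -np.log(np.maximum(dens, 1e-300))
        rows, cols = linear_sum_assignment(cost)
        matched: dict[str, tuple[float, float]] = {}
        for r, c in zip(rows, cols):
            d = dens[r, c]
            if d < _FLOOR:
                continue
            # posterior over statistically distinct alternatives: atoms with
            # overlapping reference distributions form one ambiguity class.
            # A twin pair (CD1/CD2 etc.) counts as a single unit because the
            # ascending-shift tie-break pins the swap; larger classes keep
            # their residual ambiguity as a probability discount.
            class_max = {}
            for ci, members in enumerate(classes):
                class_max[ci] = max(dens[r, targets.index(t)] for t in members)
            total = sum(class_max.values())
            my_class = next(ci for ci, members in enumerate(classes)
                            if targets[c] in members)
            units = _ambiguity_units(classes[my_class])
            posterior = (class_max[my_class] / total / units) if total > 0 else 0.0
            matched[targets[c]] = (cand[r], min(1.0, posterior))

        # declared tie-break: within a degenerate pair, ascending ppm maps to
        # ascending atom name
        for a1, a2 in _DEGENERATE_PAIRS:
            if a1 in matched and a2 in matched:
                (v1, p1), (v2, p2) = matched[a1], matched[a2]
                if v1 > v2:
                    matched[a1], matched[a2] = (v2, p2), (v1, p1)
            elif a1 in targets and a2 in targets:
                # single candidate for an unresolvable pair: share it
                hit = a1 if a1 in matched else (a2 if a2 in matched else None)
                if hit is not None:
                    other = a2 if hit == a1 else a1
                    matched[other] = matched[hit]

        for atom, (ppm, posterior) in matched.items():
            prob = min(ra.best_probability, ra.best_probability * posterior)
            ra.atoms[atom] = (ppm, prob)
    return result
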