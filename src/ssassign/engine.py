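"""Backbone assignment: spin-system linking, pentapeptide candidates, loopy
belief propagation over placements, referencing-offset estimation and the
outer convergence loop.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .atoms import HEAVY_ATOMS
from .config import PipelineConfig
from .factor_graph import PairwiseMRF
from .model import (
    AssignmentCandidate,
    AssignmentResult,
    ConvergenceRecord,
    DiPeptideLink,
    PeakList,
    ProteinSequence,
    ResidueAssignment,
    SpinSystemMatrix,
)
from .statistics import ShiftStatistics

log = logging.getLogger(__name__)

_DENSITY_FLOOR = 1e-4   # below this a carbon is considered unexplained
_CX_MISS_PENALTY = 1e-3  # per unexplained carbon in typing / linking
_CENSOR_FLOOR = 1e-6    # outlier censoring: extreme values stop discriminating
_NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# di-peptide linking

def _carbon_sets(sys):
    """(own values, prev values) with named atoms labelled, CX bags appended."""
    own = dict(sys.own)
    prev = dict(sys.prev)
    return own, prev


def link_spin_systems(matrix: SpinSystemMatrix, tol: float,
                      config: Optional[PipelineConfig] = None
                      ) -> list[DiPeptideLink]:
    """Propose sequential links: system B follows system A when B's
    preceding-residue carbons agree with A's own carbons.

    Named atoms present on both sides must each agree within `tol`; leftover
    unresolved carbons are greedily paired by proximity. The score is a
    Gaussian kernel over the matched deltas (sigma = tol / 2) damped by a
    fixed penalty for every preceding-residue value left unexplained.
    """
    config = config or PipelineConfig()
    sigma = tol / 2.0
    out: list[DiPeptideLink] = []
    systems = matrix.systems
    for a in systems:
        a_named = dict(a.own)
        a_pool = sorted(set(a.own_cx) | set(a_named.values()))
        for b in systems:
            if a.id == b.id:
                continue
            deltas: dict[str, float] = {}
            ok = True
            used: set[float] = set()
            for atom in ("CA", "CB", "C"):
                if atom in a_named and atom in b.prev:
                    d = a_named[atom] - b.prev[atom]
                    if abs(d) > tol + 1e-9:
                        ok = False
                        break
                    deltas[atom] = d
                    used.add(a_named[atom])
            if not ok:
                continue
            # unresolved preceding-residue carbons against A's carbon pool
            unmatched = 0
            b_rest = [v for at, v in b.prev.items() if at not in deltas]
            b_rest += list(b.prev_cx)
            avail = [v for v in a_pool if v not in used]
            for k, v in enumerate(sorted(b_rest)):
                best = None
                for w in avail:
                    d = abs(v - w)
                    if d <= tol + 1e-9 and (best is None or d < abs(v - best)):
                        best = w
                if best is None:
                    unmatched += 1
                else:
                    avail.remove(best)
                    deltas[f"CX{k}"] = v - best
            if not deltas:
                continue
            ss = sum(d * d for d in deltas.values())
            score = math.exp(-ss / (2.0 * sigma * sigma))
            score *= config.unmatched_penalty ** unmatched
            if score > 0.0:
                out.append(DiPeptideLink(a.id, b.id, deltas, score))
    out.sort(key=lambda ln: (ln.from_id, ln.to_id))
    return out


# ---------------------------------------------------------------------------
# typing

def _side_loglik(named: dict[str, float], cx: list[float], n_val: Optional[float],
                 res_type: str, stats: ShiftStatistics) -> float:
    """Log-likelihood that one side of a spin system is the given residue type."""
    inventory = HEAVY_ATOMS[res_type]
    total = 0.0
    taken: set[str] = set()
    obs = dict(named)
    if n_val is not None:
        obs["N"] = n_val
    for atom, ppm in obs.items():
        if atom not in inventory:
            return _NEG_INF
        # censored below the floor: a far outlier counts equally against
        # every type that possesses the atom instead of dominating the score
        d = max(stats.density(ppm, res_type, atom), _CENSOR_FLOOR)
        total += math.log(d)
        taken.add(atom)
    remaining = [a for a in inventory if a not in taken and a != "N"]
    for v in sorted(cx):
        best_atom, best_d = None, _DENSITY_FLOOR
        for a in remaining:
            d = stats.density(v, res_type, a)
            if d > best_d:
                best_atom, best_d = a, d
        if best_atom is None:
            total += math.log(_CX_MISS_PENALTY)
        else:
            total += math.log(best_d)
            remaining.remove(best_atom)
    return total


def _unary_table(matrix: SpinSystemMatrix, sequence: ProteinSequence,
                 stats: ShiftStatistics) -> np.ndarray:
    """log unary score U[system, position] for placements at positions with a
    predecessor; -inf where typing forbids the placement."""
    positions = list(sequence.positions())[1:]
    types = sorted(set(sequence.residues))
    U = np.full((len(matrix.systems), len(positions)), _NEG_INF)
    for si, sys in enumerate(matrix.systems):
        own_l = {t: _side_loglik(sys.own, sys.own_cx, sys.root.n, t, stats)
                 for t in types}
        prev_named = {a: v for a, v in sys.prev.items()}
        prev_l = {t: _side_loglik(prev_named, sys.prev_cx, None, t, stats)
                  for t in types}
        for pi, p in enumerate(positions):
            lo = own_l[sequence.type_at(p)]
            lp = prev_l[sequence.type_at(p - 1)]
            if lo > _NEG_INF and lp > _NEG_INF:
                U[si, pi] = lo + lp
    return U


# ---------------------------------------------------------------------------
# pentapeptide fragments

@dataclass
class Fragment:
    """A chain of linked spin systems scored against sequence windows."""

    members: tuple[int, ...]
    placements: dict[int, float] = field(default_factory=dict)  # start pos -> score

    def best_placement(self) -> Optional[tuple[int, float]]:
        if not self.placements:
            return None
        start = max(self.placements, key=lambda s: (self.placements[s], -s))
        return start, self.placements[start]


def generate_pentapeptides(links: list[DiPeptideLink], matrix: SpinSystemMatrix,
                           sequence: ProteinSequence, stats: ShiftStatistics,
                           config: Optional[PipelineConfig] = None,
                           unary: Optional[np.ndarray] = None) -> list[Fragment]:
    """Chain links into fragments of 1-5 systems and score every placement
    against equal-length sequence windows; placements below the configured
    floor are pruned."""
    config = config or PipelineConfig()
    if unary is None:
        unary = _unary_table(matrix, sequence, stats)
    id_to_row = {s.id: i for i, s in enumerate(matrix.systems)}
    positions = list(sequence.positions())[1:]
    pos_index = {p: i for i, p in enumerate(positions)}

    adj: dict[int, list[tuple[int, float]]] = {}
    for ln in links:
        adj.setdefault(ln.from_id, []).append((ln.to_id, ln.score))
    for k in adj:
        adj[k] = sorted(adj[k], key=lambda t: -t[1])[:3]

    chains: list[tuple[tuple[int, ...], float]] = []
    budget = 50000
    for s in matrix.systems:
        stack = [((s.id,), 1.0)]
        while stack and len(chains) < budget:
            members, w = stack.pop()
            chains.append((members, w))
            if len(members) == 5:
                continue
            for to_id, sc in adj.get(members[-1], []):
                if to_id not in members:
                    stack.append((members + (to_id,), w * sc))

    floor_log = math.log(config.fragment_floor)
    n_pos = len(positions)
    frags: list[Fragment] = []
    for members, link_w in chains:
        if link_w <= 0:
            continue
        m = len(members)
        n_starts = n_pos - m + 1
        if n_starts <= 0:
            continue
        totals = np.full(n_starts, math.log(link_w))
        for k, mid in enumerate(members):
            totals += unary[id_to_row[mid], k:k + n_starts]
        finite = np.isfinite(totals)
        if not finite.any():
            continue
        best = totals[finite].max()
        keep = finite & (totals - best >= floor_log)
        frag = Fragment(members)
        # linear scale, relative to the fragment's best placement
        frag.placements = {positions[i]: math.exp(totals[i] - best)
                           for i in np.nonzero(keep)[0]}
        frags.append(frag)
    return frags


# ---------------------------------------------------------------------------
# belief propagation over placements

@dataclass
class BPOutput:
    candidates: dict[int, list[AssignmentCandidate]]
    iterations: int
    converged: bool
    final_delta: float
    domains: dict[int, list[Optional[int]]]


def run_belief_propagation(matrix: SpinSystemMatrix, links: list[DiPeptideLink],
                           sequence: ProteinSequence, stats: ShiftStatistics,
                           config: Optional[PipelineConfig] = None,
                           fragments: Optional[list[Fragment]] = None
                           ) -> BPOutput:
    """Marginal placement probabilities for every spin system.

    One variable per system; its domain is the pruned set of candidate
    positions plus a reserved unassigned slot. Link factors reward
    consecutive placement of linked systems, soft-exclusion factors penalize
    two systems claiming one position.
    """
    config = config or PipelineConfig()
    positions = list(sequence.positions())[1:]
    if not positions:
        positions = list(sequence.positions())  # single-residue sequence
    U = _unary_table(matrix, sequence, stats) if len(list(sequence.positions())) > 1 \
        else np.zeros((len(matrix.systems), 1))
    if U.shape[1] != len(positions):  # single-residue corner
        U = np.zeros((len(matrix.systems), len(positions)))

    frag_boost: dict[int, set[int]] = {}
    if fragments:
        for fr in fragments:
            top = sorted(fr.placements.items(), key=lambda kv: -kv[1])[:2]
            for start, _ in top:
                for k, mid in enumerate(fr.members):
                    frag_boost.setdefault(mid, set()).add(start + k)

    domains: dict[int, list[Optional[int]]] = {}
    unaries: dict[int, np.ndarray] = {}
    pooled: list[float] = []
    for si, sys in enumerate(matrix.systems):
        row = U[si]
        order = np.argsort(-row)
        keep = [positions[i] for i in order[:config.max_candidates]
                if row[i] > _NEG_INF]
        for p in sorted(frag_boost.get(sys.id, ())):
            if p not in keep and p in positions and \
                    row[positions.index(p)] > _NEG_INF:
                keep.append(p)
        keep.sort()
        if keep:
            vals = np.array([row[positions.index(p)] for p in keep])
            vals = np.exp(vals - vals.max())
        else:
            vals = np.array([])
        domains[sys.id] = keep
        unaries[sys.id] = vals
        pooled.extend(vals.tolist())

    p5 = float(np.percentile(pooled, 5)) if pooled else 1.0
    mrf = PairwiseMRF()
    var_of: dict[int, int] = {}
    for sys in matrix.systems:
        vals = unaries[sys.id]
        best = vals.max() if vals.size else 1.0
        pseudo = min(max(p5, 1e-12), 0.05 * best)
        unary = np.concatenate([vals, [pseudo]])
        domains[sys.id] = domains[sys.id] + [None]
        var_of[sys.id] = mrf.add_variable(unary)

    for ln in links:
        da, db = domains[ln.from_id], domains[ln.to_id]
        psi = np.ones((len(da), len(db)))
        for i, pa in enumerate(da):
            if pa is None:
                continue
            for j, pb in enumerate(db):
                if pb == pa + 1:
                    psi[i, j] = 1.0 + config.link_strength * ln.score
        mrf.add_edge(var_of[ln.from_id], var_of[ln.to_id], psi)

    ids = [s.id for s in matrix.systems]
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            da, db = domains[ids[ai]], domains[ids[bi]]
            shared = (set(da) & set(db)) - {None}
            if not shared:
                continue
            psi = np.ones((len(da), len(db)))
            for p in shared:
                psi[da.index(p), db.index(p)] = config.exclusion_penalty
            mrf.add_edge(var_of[ids[ai]], var_of[ids[bi]], psi)

    res = mrf.run_bp(config.bp_max_iters, config.bp_damping, config.bp_message_tol)
    if not res.converged:
        log.warning("belief propagation stopped at %d iterations "
                    "(final delta %.2e)", res.iterations, res.final_delta)

    candidates: dict[int, list[AssignmentCandidate]] = {}
    for sys in matrix.systems:
        marg = res.marginals[var_of[sys.id]]
        cands = [AssignmentCandidate(sys.id, p, float(q))
                 for p, q in zip(domains[sys.id], marg)]
        cands.sort(key=lambda c: (-c.probability, c.position is None,
                                  c.position if c.position is not None else 0))
        candidates[sys.id] = cands
    return BPOutput(candidates, res.iterations, res.converged, res.final_delta,
                    domains)


# ---------------------------------------------------------------------------
# result extraction

def _extract_result(matrix: SpinSystemMatrix, bp: BPOutput,
                    sequence: ProteinSequence) -> AssignmentResult:
    by_id = {s.id: s for s in matrix.systems}
    order = sorted(
        bp.candidates,
        key=lambda sid: -max((c.probability for c in bp.candidates[sid]
                              if c.position is not None), default=0.0),
    )
    taken: dict[int, int] = {}
    placement: dict[int, tuple[int, float]] = {}
    for sid in order:
        for cand in bp.candidates[sid]:
            if cand.position is None:
                break  # unassigned outranks remaining positions
            if cand.position not in taken:
                taken[cand.position] = sid
                placement[sid] = (cand.position, cand.probability)
                break

    atom_values: dict[tuple[int, str], list[tuple[float, float]]] = {}
    for sid, (pos, prob) in placement.items():
        sys = by_id[sid]
        atom_values.setdefault((pos, "N"), []).append((sys.root.n, prob))
        for atom, v in sys.own.items():
            atom_values.setdefault((pos, atom), []).append((v, prob))
        for atom, v in sys.prev.items():
            atom_values.setdefault((pos - 1, atom), []).append((v, prob))

    residues: dict[int, ResidueAssignment] = {}
    valid = set(sequence.positions())
    for (pos, atom), vals in sorted(atom_values.items()):
        if pos not in valid:
            continue
        rtype = sequence.type_at(pos)
        if atom not in HEAVY_ATOMS[rtype]:
            continue
        ppm = sum(v for v, _ in vals) / len(vals)
        prob = max(q for _, q in vals)
        ra = residues.get(pos)
        if ra is None:
            ra = ResidueAssignment(pos, rtype, {}, 0.0)
            residues[pos] = ra
        ra.atoms[atom] = (ppm, prob)
    for pos, ra in residues.items():
        sid = taken.get(pos)
        ra.system_id = sid
        if sid is not None:
            ra.best_probability = placement[sid][1]
        else:
            ra.best_probability = max(q for _, q in ra.atoms.values())

    return AssignmentResult(
        residues=residues, candidates=bp.candidates, offsets={},
        sequence=sequence, assigned_systems=taken,
    )


def _recover_orphan_nitrogens(result: AssignmentResult, peaklists: list[PeakList],
                              matrix: SpinSystemMatrix, tol_c: float,
                              tol_n: float) -> None:
    """Fill N for residues that have a CA but no spin system of their own
    (typically the N-terminal residue) from N(i)-CA(i) experiment peaks whose
    nitrogen is not claimed by any assigned system."""
    from .assembly import _anchor_kinds
    from .profiles import get_profile

    by_id = {s.id: s for s in matrix.systems}
    claimed = [(by_id[sid].root.n, by_id[sid].root.ca)
               for sid in result.assigned_systems.values()]
    for pos, ra in result.residues.items():
        if "N" in ra.atoms or "CA" not in ra.atoms:
            continue
        ca, ca_prob = ra.atoms["CA"]
        hits: list[float] = []
        for pl in peaklists:
            profile = get_profile(pl.experiment_name)
            kinds = _anchor_kinds(profile)
            by_kind = {v: k for k, v in kinds.items()}
            if "N" not in by_kind or "CA" not in by_kind:
                continue
            for pk in pl.peaks:
                n_v = pk.position[by_kind["N"]]
                ca_v = pk.position[by_kind["CA"]]
                if abs(ca_v - ca) <= tol_c and \
                        not any(abs(n_v - cn) <= tol_n and abs(ca_v - cc) <= tol_c
                                for cn, cc in claimed):
                    hits.append(n_v)
        if hits:
            ra.atoms["N"] = (sum(hits) / len(hits), ca_prob)


# ---------------------------------------------------------------------------
# referencing offsets

def detect_reference_offset(result: AssignmentResult, matrix: SpinSystemMatrix,
                            stats: ShiftStatistics,
                            peaklists: list[PeakList],
                            config: Optional[PipelineConfig] = None
                            ) -> dict[str, dict[str, float]]:
    """Median per-experiment referencing offset from predicted-vs-observed
    peak positions; small or statistically insignificant offsets report 0.

    Sequential cross-peaks are predicted from the confidently assigned
    shifts, matched to the experiment's observed peaks within a search
    window, and the per-axis residuals pooled per nucleus. Comparing against
    the consensus carried by the assignment makes a mis-referenced
    experiment stand out even when its strips failed to attach at the
    working tolerance.
    """
    from .profiles import expected_peaks, get_profile

    config = config or PipelineConfig()
    seq = result.sequence
    if seq is None:
        return {pl.experiment_name: {nuc: 0.0 for nuc in set(pl.axis_nuclei)}
                for pl in peaklists}
    shifts: dict[tuple[int, str], float] = {}
    for pos, ra in result.residues.items():
        for atom, (ppm, prob) in ra.atoms.items():
            if prob >= config.offset_confidence:
                shifts[(pos, atom)] = ppm

    window = 1.5  # ppm search radius; must exceed any plausible offset
    offsets: dict[str, dict[str, float]] = {}
    for pl in peaklists:
        profile = get_profile(pl.experiment_name)
        preds = []
        for tmpl in expected_peaks(profile, seq):
            vals = [shifts.get((r, a))
                    for r, a in zip(tmpl.residues, tmpl.atoms)]
            if None not in vals:
                preds.append(vals)
        per_nuc: dict[str, float] = {nuc: 0.0 for nuc in set(pl.axis_nuclei)}
        if preds and pl.peaks:
            pred = np.asarray(preds)
            obs = np.asarray([pk.position for pk in pl.peaks])
            # Chebyshev-nearest observed peak for every predicted peak
            diff = obs[None, :, :] - pred[:, None, :]
            cheb = np.max(np.abs(diff), axis=2)
            nearest = np.argmin(cheb, axis=1)
            ok = cheb[np.arange(len(pred)), nearest] <= window
            residual = diff[np.arange(len(pred)), nearest]
            for axis, nuc in enumerate(pl.axis_nuclei):
                vals = residual[ok, axis]
                if len(vals) < config.offset_min_atoms:
                    if len(vals):
                        log.warning("%s/%s: only %d matched peak(s); "
                                    "offset set to 0",
                                    pl.experiment_name, nuc, len(vals))
                    continue
                med = float(np.median(vals))
                # noise guard: the median must clear the report floor and
                # ~3 standard errors (MAD-based) to count as a real
                # referencing error
                mad = float(np.median(np.abs(vals - med)))
                se = 1.86 * mad / np.sqrt(len(vals))
                if abs(med) >= max(config.offset_report_floor, 3.0 * se):
                    per_nuc[nuc] = med
        offsets[pl.experiment_name] = per_nuc
    return offsets


# ---------------------------------------------------------------------------
# outer loop

class TerminateAssignment(RuntimeError):
    """Raised when re-assembly drops below the quality gate."""


def iterate_assignment(matrix: SpinSystemMatrix, peaklists: list[PeakList],
                       sequence: ProteinSequence, stats: ShiftStatistics,
                       config: Optional[PipelineConfig] = None
                       ) -> AssignmentResult:
    """BP -> offset detection -> re-assembly rounds until the best-probability
    assignment map stops changing (or the round limit is reached)."""
    from .assembly import assemble, assess_quality, gate_quality

    config = config or PipelineConfig()
    if not matrix.systems:
        raise TerminateAssignment("empty spin-system matrix: "
                                  "more information is required")
    tol_c, tol_n = matrix.tol_c, matrix.tol_n
    cumulative: dict[str, dict[str, float]] = {
        pl.experiment_name: {nuc: 0.0 for nuc in set(pl.axis_nuclei)}
        for pl in peaklists
    }
    current = [pl for pl in peaklists]
    prev_map: Optional[dict[int, int]] = None
    bp_iters: list[int] = []
    result: Optional[AssignmentResult] = None
    converged = False
    final_delta = float("nan")

    for round_no in range(1, config.max_rounds + 1):
        links = link_spin_systems(matrix, tol_c, config)
        frags = generate_pentapeptides(links, matrix, sequence, stats, config)
        bp = run_belief_propagation(matrix, links, sequence, stats, config, frags)
        bp_iters.append(bp.iterations)
        final_delta = bp.final_delta
        result = _extract_result(matrix, bp, sequence)
        _recover_orphan_nitrogens(result, current, matrix, tol_c, tol_n)

        if prev_map == result.assigned_systems:
            converged = True
            break
        offsets = detect_reference_offset(result, matrix, stats, current, config)
        any_offset = any(abs(v) > 0 for per in offsets.values()
                         for v in per.values())
        if not any_offset:
            # data will not change and the pipeline is deterministic, so the
            # next round would reproduce this map exactly: converged
            converged = True
            break
        prev_map = dict(result.assigned_systems)
        # apply detected offsets and re-assemble
        corrected: list[PeakList] = []
        for pl in current:
            per = offsets.get(pl.experiment_name, {})
            for nuc, v in per.items():
                cumulative[pl.experiment_name][nuc] += v
            axis_offsets = tuple(per.get(nuc, 0.0) for nuc in pl.axis_nuclei)
            pl2 = PeakList(pl.experiment_name, pl.dimensionality, pl.axis_nuclei,
                           pl.peaks, axis_offsets, pl.skipped_lines, pl.source)
            corrected.append(pl2.with_offsets_applied())
        current = corrected
        matrix = assemble(current, tol_c, tol_n, stats)
        q = assess_quality(matrix, sequence, config=config)
        gate = gate_quality(q, config.quality_threshold)
        if not gate.proceed:
            raise TerminateAssignment(gate.message)

    assert result is not None
    result.final_matrix = matrix
    result.offsets = {
        exp: {nuc: (v if abs(v) >= config.offset_report_floor else 0.0)
              for nuc, v in per.items()}
        for exp, per in cumulative.items()
    }
    result.convergence = ConvergenceRecord(
        rounds=len(bp_iters), bp_iterations=bp_iters,
        converged=converged, final_message_delta=final_delta,
    )
    return result
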