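"""Spin-system matrix assembly.

A spin system is anchored by a root triple — CO(i-1), N(i), CA(i) — found
either directly in an experiment that correlates all three, or by joining
N/CO- and N/CA-bearing experiments on the shared nitrogen. Strip peaks from
the remaining experiments are then attached to each root through their
anchor coordinates, filling the own-residue and preceding-residue slots of
the matrix row. Assembly is repeated over a grid of spectral tolerances and
the grid point with the best data-quality score wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import PipelineConfig
from .model import (
    Contribution,
    PeakList,
    ProteinSequence,
    RootTriple,
    SpinSystem,
    SpinSystemMatrix,
)
from .profiles import get_profile
from .statistics import ShiftStatistics

log = logging.getLogger(__name__)


def _anchor_kinds(profile):
    """axis index -> 'N' | 'CA' | 'CO' for unambiguous anchor axes."""
    kinds = {}
    for k, ax in enumerate(profile.axes):
        if ax.roles == {"N"} and ax.offset == 0:
            kinds[k] = "N"
        elif ax.roles == {"CA"} and ax.offset == 0:
            kinds[k] = "CA"
        elif ax.roles == {"CO"} and ax.offset == -1:
            kinds[k] = "CO"
    return kinds


def _cluster(items, tols):
    """Greedy centroid clustering of coordinate tuples.

    items: list of (coords tuple, weight, payload list); tols: per-coordinate
    merge tolerance. Returns list of (centroid, weight, payloads).
    """
    clusters: list[list] = []  # [sum coords, weight, payloads]
    for coords, w, payload in items:
        hit = None
        for cl in clusters:
            cen = tuple(s / cl[1] for s in cl[0])
            if all(abs(c - x) <= t for c, x, t in zip(cen, coords, tols)):
                hit = cl
                break
        if hit is None:
            clusters.append([tuple(w * c for c in coords), w, list(payload)])
        else:
            hit[0] = tuple(s + w * c for s, c in zip(hit[0], coords))
            hit[1] += w
            hit[2].extend(payload)
    return [(tuple(s / w for s in sums), w, payloads)
            for sums, w, payloads in clusters]


def find_roots(peaklists: list[PeakList], tol_c: float, tol_n: float,
               min_join_support: int = 2) -> list[RootTriple]:
    """Locate CO(i-1)/N(i)/CA(i) root triples.

    Direct roots come from experiments whose profile carries all three anchor
    roles on unambiguous axes; further roots are built by joining projected
    (N, CO-1) and (N, CA) peak pairs on the nitrogen coordinate (one-to-one,
    nearest-nitrogen pairing). Joined roots supported by fewer than
    `min_join_support` projections in total are discarded. Near duplicates
    are merged to their support-weighted centroid.
    """
    raw: list[tuple[tuple[float, float, float], int, list[Contribution]]] = []
    nco_pairs: list[tuple[tuple[float, float], int, list[Contribution]]] = []
    nca_pairs: list[tuple[tuple[float, float], int, list[Contribution]]] = []

    for pl in peaklists:
        profile = get_profile(pl.experiment_name)
        kinds = _anchor_kinds(profile)
        by_kind = {v: k for k, v in kinds.items()}
        has = set(kinds.values())
        for ip, pk in enumerate(pl.peaks):
            if {"N", "CA", "CO"} <= has:
                co, n, ca = (pk.position[by_kind["CO"]],
                             pk.position[by_kind["N"]],
                             pk.position[by_kind["CA"]])
                sup = [Contribution(pl.experiment_name, ip, by_kind[a], "root",
                                    {"N": "N", "CA": "CA", "CO": "C"}[a],
                                    pk.position[by_kind[a]])
                       for a in ("CO", "N", "CA")]
                raw.append(((co, n, ca), 1, sup))
            elif {"N", "CO"} <= has:
                n, co = pk.position[by_kind["N"]], pk.position[by_kind["CO"]]
                sup = [Contribution(pl.experiment_name, ip, by_kind["N"], "root", "N", n),
                       Contribution(pl.experiment_name, ip, by_kind["CO"], "root", "C", co)]
                nco_pairs.append(((n, co), 1, sup))
            elif {"N", "CA"} <= has:
                n, ca = pk.position[by_kind["N"]], pk.position[by_kind["CA"]]
                sup = [Contribution(pl.experiment_name, ip, by_kind["N"], "root", "N", n),
                       Contribution(pl.experiment_name, ip, by_kind["CA"], "root", "CA", ca)]
                nca_pairs.append(((n, ca), 1, sup))

    # dedupe projections (a 3D experiment projects one (N, CO) per strip peak)
    nco = _cluster(sorted(nco_pairs, key=lambda it: it[0]), (tol_n, tol_c))
    nca = _cluster(sorted(nca_pairs, key=lambda it: it[0]), (tol_n, tol_c))

    # strict one-to-one join on the nitrogen, closest pairs first: real
    # projections pair with their true partners, stray peaks are left to
    # pair among themselves (and are then dropped by the support threshold)
    cand: list[tuple[float, int, int]] = []
    for i, ((n1, _co), _w, _s) in enumerate(nco):
        for j, ((n2, _ca), _w2, _s2) in enumerate(nca):
            d = abs(n1 - n2)
            if d <= tol_n:
                cand.append((d, i, j))
    cand.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _d, i, j in cand:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        pairs.append((i, j))
    # triple validators: peaks correlating CA(i)/N(i)/CO(i-1) on one spectrum
    # (directly or through a CX/O axis) confirm that a joined (CO, N, CA)
    # candidate belongs to a single residue and is not a chimeric cross-join
    validators: list[tuple[float, float, float]] = [c for c, _w, _s in raw]
    for pl in peaklists:
        profile = get_profile(pl.experiment_name)
        kinds = _anchor_kinds(profile)
        by_kind = {v: k for k, v in kinds.items()}
        if "CA" not in by_kind or "N" not in by_kind or "CO" in by_kind:
            continue
        co_axes = [k for k, ax in enumerate(profile.axes)
                   if k not in kinds and ax.offset == -1 and "CO" in ax.roles]
        for pk in pl.peaks:
            for k in co_axes:
                validators.append((pk.position[k],
                                   pk.position[by_kind["N"]],
                                   pk.position[by_kind["CA"]]))

    def _validated(co: float, n: float, ca: float) -> bool:
        return any(abs(co - vc) <= tol_c and abs(n - vn) <= tol_n
                   and abs(ca - va) <= tol_c
                   for vc, vn, va in validators)

    for i, j in sorted(pairs):
        (n1, co), w1, sup1 = nco[i]
        (n2, ca), w2, sup2 = nca[j]
        if w1 + w2 < min_join_support:
            continue  # likely a pairing of stray (false-positive) peaks
        n = (w1 * n1 + w2 * n2) / (w1 + w2)
        if validators and not _validated(co, n, ca):
            continue
        raw.append(((co, n, ca), 1, sup1 + sup2))

    if not raw:
        log.warning("no root triples found in %d peak list(s)", len(peaklists))
        return []

    raw.sort(key=lambda it: (it[0][1], it[0][2], it[0][0]))
    merged = _cluster(raw, (tol_c, tol_n, tol_c))
    roots = [RootTriple(co_prev=c[0], n=c[1], ca=c[2], support=sup, weight=w)
             for c, w, sup in merged]
    roots.sort(key=lambda r: (r.n, r.ca, r.co_prev))
    return roots


def _resolve_slot(candidates, stats: Optional[ShiftStatistics], atom: str,
                  tol_c: float):
    """Collapse candidate (value, weight, anchor_dist) tuples for one slot.

    Within-tolerance candidates average. Conflicting clusters are ranked by
    how tightly their peaks matched the root anchors (exact matches beat
    cross-attached strays), then by support, then by closeness to the
    reference statistics.
    """
    clusters: list[list] = []  # [sum v*w, sum w, min anchor dist]
    for v, w, a in sorted(candidates):
        if clusters and abs(v - clusters[-1][0] / clusters[-1][1]) <= tol_c:
            cl = clusters[-1]
            cl[0] += v * w
            cl[1] += w
            cl[2] = min(cl[2], a)
        else:
            clusters.append([v * w, w, a])
    if len(clusters) == 1:
        return clusters[0][0] / clusters[0][1], 0
    best = min(clusters, key=lambda cl: (
        round(cl[2], 2), -cl[1],
        -(stats.max_density(cl[0] / cl[1], atom) if stats else 0.0),
    ))
    return best[0] / best[1], len(clusters) - 1


def attach_correlations(roots: list[RootTriple], peaklists: list[PeakList],
                        tol_c: float, tol_n: float,
                        stats: Optional[ShiftStatistics] = None
                        ) -> SpinSystemMatrix:
    """Attach strip peaks from every experiment to each root triple.

    A peak attaches when all of the profile's anchor coordinates match the
    root within tolerance (two anchors for 3D experiments; single-anchor 2D
    experiments attach only when the nitrogen match is unique). Remaining
    axes fill named slots where the role set allows, otherwise the value
    lands in the unresolved-carbon (CX) bag of the appropriate side.
    """
    conflicts = 0
    # named-slot candidates per root: (side, atom) -> list of (value, weight)
    slot_cand: list[dict] = [dict() for _ in roots]
    cx_cand: list[dict] = [{"own": [], "prev": []} for _ in roots]
    ab_cand: list[dict] = [{"own": [], "prev": []} for _ in roots]  # CA-or-CB values
    supports: list[list[Contribution]] = [list(r.support) for r in roots]

    root_n = np.array([r.n for r in roots])
    root_ca = np.array([r.ca for r in roots])
    root_co = np.array([r.co_prev for r in roots])

    for pl in peaklists:
        profile = get_profile(pl.experiment_name)
        kinds = _anchor_kinds(profile)
        contrib_axes = [k for k in range(profile.dimensionality) if k not in kinds]
        if not contrib_axes or "N" not in kinds.values():
            continue  # nothing to add (pure-root or unanchored experiment)
        if not pl.peaks:
            continue
        pos = np.array([pk.position for pk in pl.peaks])
        masks = []
        for k, kind in kinds.items():
            if kind == "N":
                masks.append(np.abs(pos[:, k, None] - root_n[None, :]) <= tol_n)
            elif kind == "CA":
                masks.append(np.abs(pos[:, k, None] - root_ca[None, :]) <= tol_c)
            else:
                masks.append(np.abs(pos[:, k, None] - root_co[None, :]) <= tol_c)
        match = masks[0]
        for m in masks[1:]:
            match = match & m
        if len(kinds) == 1:
            # ambiguous single-anchor (2D) experiment: unique matches only
            unique = match.sum(axis=1) == 1
            match = match & unique[:, None]
        pk_idx, rt_idx = np.nonzero(match)
        for ip, ir in zip(pk_idx.tolist(), rt_idx.tolist()):
            root = roots[ir]
            # normalized anchor mismatch: 0 for an exact strip match; used to
            # rank conflicting contributions (cross-attached strays score high)
            adist = 0.0
            for k, kind in kinds.items():
                if kind == "N":
                    adist = max(adist, abs(float(pos[ip, k]) - root.n) / tol_n)
                elif kind == "CA":
                    adist = max(adist, abs(float(pos[ip, k]) - root.ca) / tol_c)
                else:
                    adist = max(adist, abs(float(pos[ip, k]) - root.co_prev) / tol_c)
            for k in contrib_axes:
                v = float(pos[ip, k])
                ax = profile.axes[k]
                side = "own" if ax.offset == 0 else "prev"
                roles = ax.roles
                atom = None
                to_ab = to_cx = False
                if "CA" in roles and ax.offset == 0 and abs(v - root.ca) <= tol_c:
                    atom = "CA"
                elif "CO" in roles and ax.offset == -1 and abs(v - root.co_prev) <= tol_c:
                    atom = "C"
                elif roles == {"CA"}:
                    atom = "CA"
                elif roles == {"CO"}:
                    atom = "C"
                elif roles in ({"CA", "CB"}, {"CO", "CA", "CB"}):
                    if ax.offset == 0:
                        atom = "CB"       # root CA already peeled off above
                    else:
                        to_ab = True      # CA(i-1) vs CB(i-1): resolved later
                elif roles == {"CA", "CO"}:
                    atom = "CA"
                elif "CX" in roles:
                    to_cx = True
                else:
                    continue
                if atom is not None:
                    slot_cand[ir].setdefault((side, atom), []).append(
                        (v, 1.0, adist))
                    supports[ir].append(Contribution(
                        pl.experiment_name, ip, k, side, atom, v))
                elif to_ab:
                    ab_cand[ir][side].append((v, pl.experiment_name, ip, k, adist))
                elif to_cx:
                    # skip duplicates of the root coordinates
                    if side == "own" and abs(v - root.ca) <= tol_c:
                        continue
                    cx_cand[ir][side].append((v, pl.experiment_name, ip, k))

    systems: list[SpinSystem] = []
    for ir, root in enumerate(roots):
        own: dict[str, float] = {}
        prev: dict[str, float] = {}
        sup = supports[ir]

        # resolve directly-named slots (CA, C) first: the resolved preceding
        # CA anchors the CA-or-CB split below
        cb_pool: dict[str, list] = {"own": [], "prev": []}
        for (side, atom), cands in sorted(slot_cand[ir].items()):
            if atom == "CB":
                cb_pool[side].extend(cands)
                continue
            value, n_conf = _resolve_slot(cands, stats, atom, tol_c)
            conflicts += n_conf
            (own if side == "own" else prev)[atom] = value

        # CA-or-CB contributions: named only when a direct CA measurement
        # (NCOCA-style axis) anchors the split, otherwise order-free CX bag
        for side, bag in ab_cand[ir].items():
            target = own if side == "own" else prev
            known_ca = target.get("CA")
            for v, exp, ipk, k, adist in sorted(bag):
                if known_ca is None:
                    cx_cand[ir][side].append((v, None, None, None))
                    sup.append(Contribution(exp, ipk, k, side, "CX", v))
                elif abs(v - known_ca) <= tol_c:
                    sup.append(Contribution(exp, ipk, k, side, "CA", v))
                else:
                    cb_pool[side].append((v, 1.0, adist))
                    sup.append(Contribution(exp, ipk, k, side, "CB", v))

        for side, cands in cb_pool.items():
            if not cands:
                continue
            value, n_conf = _resolve_slot(cands, stats, "CB", tol_c)
            conflicts += n_conf
            (own if side == "own" else prev)["CB"] = value

        own.setdefault("CA", root.ca)
        prev.setdefault("C", root.co_prev)

        cx_merged: dict[str, list[float]] = {}
        for side in ("own", "prev"):
            vals = []
            for v, exp, ipk, k in cx_cand[ir][side]:
                vals.append(((v,), 1, []))
                if exp is not None:
                    sup.append(Contribution(exp, ipk, k, side, "CX", v))
            target = own if side == "own" else prev
            merged = [c[0][0] for c in sorted(_cluster(sorted(vals), (tol_c,)))]
            cx_merged[side] = sorted(
                v for v in merged
                if not any(abs(v - x) <= tol_c for x in target.values())
            )

        systems.append(SpinSystem(
            id=ir, root=root, own=own, prev=prev,
            own_cx=cx_merged["own"], prev_cx=cx_merged["prev"], support=sup,
        ))

    if conflicts:
        log.info("resolved %d conflicting slot value(s)", conflicts)
    return SpinSystemMatrix(systems, tol_c, tol_n)


def assess_quality(matrix: SpinSystemMatrix, sequence: ProteinSequence,
                   profiles=None, links=None,
                   config: Optional[PipelineConfig] = None) -> float:
    """Data-quality score in [0, 1]: geometric mean of the spin-system yield
    and the di-peptide link yield, each capped at 1 against the counts the
    sequence predicts."""
    if len(sequence) == 0:
        raise ValueError("empty sequence")

    def _yield(found: int, expected: int) -> float:
        # symmetric ratio: overshoot (spurious systems/links) degrades the
        # score the same way a shortfall does, so the tolerance optimizer
        # can see over-split matrices
        if found == 0:
            return 0.0
        return min(found / expected, expected / found)

    expected_systems = max(1, len(sequence) - 1)
    q_sys = _yield(len(matrix.systems), expected_systems)
    if q_sys == 0.0:
        matrix.quality = 0.0
        return 0.0
    if links is None:
        from .engine import link_spin_systems
        links = link_spin_systems(matrix, matrix.tol_c,
                                  config=config or PipelineConfig())
    expected_links = max(1, len(sequence) - 2)
    q_link = _yield(len(links), expected_links)
    q = float(np.sqrt(q_sys * q_link))
    matrix.quality = q
    return q


def assemble(peaklists, tol_c, tol_n, stats=None,
             min_system_support: int = 6) -> SpinSystemMatrix:
    """find_roots + attach_correlations, dropping barely-supported systems
    (stray false-positive pairings attract almost no strip peaks)."""
    roots = find_roots(peaklists, tol_c, tol_n)
    matrix = attach_correlations(roots, peaklists, tol_c, tol_n, stats)
    kept = [s for s in matrix.systems if len(s.support) >= min_system_support]
    if len(kept) < len(matrix.systems):
        log.info("dropped %d spin system(s) with support < %d",
                 len(matrix.systems) - len(kept), min_system_support)
        for new_id, s in enumerate(kept):
            s.id = new_id
        matrix = SpinSystemMatrix(kept, tol_c, tol_n)
    return matrix


def optimize_tolerances(peaklists: list[PeakList], sequence: ProteinSequence,
                        config: Optional[PipelineConfig] = None,
                        stats: Optional[ShiftStatistics] = None):
    """Assemble at every grid point and keep the best-quality matrix.

    Returns (matrix, (tol_c, tol_n), trace) where trace lists
    ((tol_c, tol_n), quality) for every grid point, in evaluation order.
    Ties break toward the smallest tolerances (strict improvement required).
    """
    config = config or PipelineConfig()
    best = None
    best_tol = None
    trace = []
    for tol_c in config.carbon_grid:
        for tol_n in config.nitrogen_grid:
            matrix = assemble(peaklists, tol_c, tol_n, stats)
            q = assess_quality(matrix, sequence, config=config)
            trace.append(((tol_c, tol_n), q))
            if best is None or q > best.quality + 1e-12:
                best, best_tol = matrix, (tol_c, tol_n)
    return best, best_tol, trace


@dataclass(frozen=True)
class GateDecision:
    proceed: bool
    quality: float
    message: str


def gate_quality(quality: float, threshold: float = 0.3) -> GateDecision:
    """Proceed iff quality >= threshold (closed lower bound)."""
    if quality >= threshold:
        return GateDecision(True, quality, "ok")
    return GateDecision(
        False, quality,
        "data quality too low: more information is required "
        f"(quality {quality:.3f} < threshold {threshold:.3f})",
    )
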