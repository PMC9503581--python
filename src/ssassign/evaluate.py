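"""Scoring an assignment against a reference shift table: completeness,
correctness, probability bins, and candidate-count curves."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .atoms import nucleus
from .model import AssignmentResult, ShiftTable

DEFAULT_MATCH_TOL = {"13C": 0.3, "15N": 0.5}


def format_percent(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage rounded to the requested number of decimals."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return round(100.0 * numerator / denominator, decimals)


@dataclass
class Ratio:
    percent: float
    numerator: int
    denominator: int


def _best_shifts(result: AssignmentResult, cutoff: float):
    """(residue, atom) -> (ppm, prob) for the highest-probability assignment
    of every atom, filtered at the cutoff."""
    out = {}
    for idx, _rtype, atom, ppm, prob in result.iter_shifts():
        if prob >= cutoff:
            out[(idx, atom)] = (ppm, prob)
    return out


def completeness(result: AssignmentResult, reference: ShiftTable,
                 cutoff: float = 0.6) -> Ratio:
    """Fraction of reference shifts carrying a valid (above-cutoff)
    assignment; only the top candidate per atom counts."""
    if len(reference) == 0:
        raise ValueError("empty reference table")
    given = _best_shifts(result, cutoff)
    ref_keys = {(e.residue_index, e.atom) for e in reference.entries}
    num = sum(1 for key in given if key in ref_keys)
    den = len(reference)
    return Ratio(format_percent(num, den), num, den)


def correctness(result: AssignmentResult, reference: ShiftTable,
                cutoff: float = 0.6,
                match_tol: Optional[dict[str, float]] = None
                ) -> Optional[Ratio]:
    """Fraction of given (above-cutoff) assignments whose shift matches the
    reference within tolerance; None when nothing is given."""
    if len(reference) == 0:
        raise ValueError("empty reference table")
    match_tol = match_tol or DEFAULT_MATCH_TOL
    given = _best_shifts(result, cutoff)
    if not given:
        return None
    num = 0
    for (idx, atom), (ppm, _prob) in given.items():
        ref = reference.get(idx, atom)
        if ref is not None and abs(ppm - ref) <= match_tol[nucleus(atom)]:
            num += 1
    den = len(given)
    return Ratio(format_percent(num, den), num, den)


# ---------------------------------------------------------------------------
# probability bins (bar-graph categories)

BIN_GREEN = "green"   # p in (0.99, 1]
BIN_CYAN = "cyan"     # p in [0.85, 0.99]
BIN_YELLOW = "yellow"  # p in [0.5, 0.85)
BIN_RED = "red"       # p in [0, 0.5)
BIN_GRAY = "gray"     # no assignment


def probability_bin(p: Optional[float]) -> str:
    if p is None:
        return BIN_GRAY
    if p > 0.99:
        return BIN_GREEN
    if p >= 0.85:
        return BIN_CYAN
    if p >= 0.5:
        return BIN_YELLOW
    return BIN_RED


def probability_bins(result: AssignmentResult) -> dict[int, str]:
    """Per-residue bar-graph color from the residue's best probability."""
    out: dict[int, str] = {}
    positions = (result.sequence.positions() if result.sequence is not None
                 else sorted(result.residues))
    for pos in positions:
        ra = result.residues.get(pos)
        out[pos] = probability_bin(ra.best_probability if ra else None)
    return out


# ---------------------------------------------------------------------------
# candidate curves

@dataclass
class CurvePoint:
    threshold: float
    all: int
    given: int
    correct: int
    incorrect: int
    completeness: Optional[float]
    correctness: Optional[float]


def _candidate_records(result: AssignmentResult, reference: ShiftTable,
                       match_tol: dict[str, float]):
    """(probability, correct?) per atom-level top assignment."""
    records = []
    for idx, _rtype, atom, ppm, prob in result.iter_shifts():
        ref = reference.get(idx, atom)
        good = ref is not None and abs(ppm - ref) <= match_tol[nucleus(atom)]
        records.append((prob, good))
    return records


def candidate_curves(results: list[AssignmentResult],
                     references: list[ShiftTable],
                     match_tol: Optional[dict[str, float]] = None,
                     step: float = 0.05) -> list[CurvePoint]:
    """Counts of all/given/correct/incorrect assignments at each probability
    threshold from 1.0 down to 0.0, pooled over the provided result set."""
    if not results or len(results) != len(references):
        raise ValueError("need one reference per result")
    match_tol = match_tol or DEFAULT_MATCH_TOL
    records = []
    ref_total = 0
    for res, ref in zip(results, references):
        records.extend(_candidate_records(res, ref, match_tol))
        ref_total += len(ref)
    n_steps = int(round(1.0 / step))
    points: list[CurvePoint] = []
    for k in range(n_steps, -1, -1):
        thr = round(k * step, 10)
        given = [(p, g) for p, g in records if p >= thr]
        n_correct = sum(1 for _, g in given if g)
        n_given = len(given)
        points.append(CurvePoint(
            threshold=thr,
            all=len(records),
            given=n_given,
            correct=n_correct,
            incorrect=n_given - n_correct,
            completeness=(format_percent(n_given, ref_total)
                          if ref_total else None),
            correctness=(format_percent(n_correct, n_given)
                         if n_given else None),
        ))
    return points


def evaluation_report(result: AssignmentResult, reference: ShiftTable,
                      cutoff: float = 0.6,
                      match_tol: Optional[dict[str, float]] = None) -> dict:
    comp = completeness(result, reference, cutoff)
    corr = correctness(result, reference, cutoff, match_tol)
    return {
        "cutoff": cutoff,
        "completeness_percent": comp.percent,
        "completeness": [comp.numerator, comp.denominator],
        "correctness_percent": corr.percent if corr else None,
        "correctness": [corr.numerator, corr.denominator] if corr else None,
        "bins": {str(k): v for k, v in probability_bins(result).items()},
    }
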