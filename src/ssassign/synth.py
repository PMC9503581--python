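"""Synthetic peak-list generation from an assigned shift table.

Only sequential (i, i-1) cross-peaks are produced, instantiated at the table
values, with controllable Gaussian jitter, random peak dropout, uniform
false positives and per-experiment referencing offsets. Everything is
reproducible from the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .formats.nmrstar import extract_sequence, load_shift_table
from .model import Peak, PeakList, ProteinSequence, ShiftEntry, ShiftTable
from .profiles import ExperimentProfile, expected_peaks
from .statistics import ShiftStatistics

log = logging.getLogger(__name__)


@dataclass
class SyntheticOptions:
    jitter_c: float = 0.0        # ppm sd on carbon axes
    jitter_n: float = 0.0        # ppm sd on nitrogen axes
    missing_rate: float = 0.0    # probability a true peak is dropped
    false_positive_rate: float = 0.0  # expected spurious peaks per true peak
    offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing rate must be in [0, 1]")
        if self.false_positive_rate < 0 or self.jitter_c < 0 or self.jitter_n < 0:
            raise ValueError("rates and jitter must be non-negative")


def generate_peaklists(shift_table: ShiftTable, sequence: ProteinSequence,
                       profiles: list[ExperimentProfile],
                       options: Optional[SyntheticOptions] = None
                       ) -> dict[str, PeakList]:
    """Instantiate every sequential cross-peak template at the table values.

    Templates touching a shift missing from the table are skipped (and
    counted in the log). Degradation order: jitter, dropout, false
    positives, then per-experiment offsets.
    """
    options = options or SyntheticOptions()
    if len(shift_table) == 0:
        raise ValueError("empty shift table")
    out: dict[str, PeakList] = {}
    root = np.random.SeedSequence(options.seed)
    children = root.spawn(len(profiles))
    for profile, child in zip(profiles, children):
        rng = np.random.default_rng(child)
        nuclei = profile.axis_nuclei
        positions: list[tuple[float, ...]] = []
        skipped = 0
        for tmpl in expected_peaks(profile, sequence):
            vals = []
            for ridx, atom in zip(tmpl.residues, tmpl.atoms):
                v = shift_table.get(ridx, atom)
                if v is None:
                    vals = None
                    break
                vals.append(v)
            if vals is None:
                skipped += 1
                continue
            positions.append(tuple(vals))
        if skipped:
            log.info("%s: skipped %d template(s) with missing shifts",
                     profile.name, skipped)
        peaks: list[Peak] = []
        for pos in positions:
            jit = tuple(
                v + (rng.normal(0.0, options.jitter_n) if nuc == "15N"
                     else rng.normal(0.0, options.jitter_c))
                if (options.jitter_n if nuc == "15N" else options.jitter_c) > 0
                else v
                for v, nuc in zip(pos, nuclei)
            )
            if options.missing_rate > 0 and rng.random() < options.missing_rate:
                continue
            peaks.append(Peak(jit, 1.0))
        if options.false_positive_rate > 0 and positions:
            n_fp = rng.poisson(options.false_positive_rate * len(positions))
            arr = np.array(positions)
            lo, hi = arr.min(axis=0), arr.max(axis=0)
            for _ in range(n_fp):
                peaks.append(Peak(tuple(rng.uniform(lo, hi)), 1.0))
        per = options.offsets.get(profile.name, {})
        if any(per.values()):
            peaks = [
                Peak(tuple(v + per.get(nuc, 0.0)
                           for v, nuc in zip(pk.position, nuclei)), pk.height)
                for pk in peaks
            ]
        out[profile.name] = PeakList(profile.name, profile.dimensionality,
                                     nuclei, peaks)
    return out


def fetch_or_load_bmrb(source) -> tuple[ShiftTable, ProteinSequence]:
    """Read a locally saved NMR-STAR deposition (no network access here:
    downloading the entry is the user's step). Residues without any C/N
    shifts are reported in the log."""
    table = load_shift_table(source)
    sequence = extract_sequence(source)
    covered = set(table.residue_indices())
    missing = [p for p in sequence.positions() if p not in covered]
    if missing:
        log.info("%s: %d residue(s) have no C/N shifts", source, len(missing))
    return table, sequence


def write_manifest(path, options: SyntheticOptions, experiments: list[str]) -> None:
    payload = {
        "seed": options.seed,
        "jitter_c": options.jitter_c,
        "jitter_n": options.jitter_n,
        "missing_rate": options.missing_rate,
        "false_positive_rate": options.false_positive_rate,
        "offsets": options.offsets,
        "experiments": experiments,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# fixture helper: tables with unique, well-separated shifts

def synthetic_shift_table(sequence: ProteinSequence, stats: ShiftStatistics,
                          seed: int = 0,
                          carbon_separation: float = 0.8,
                          nitrogen_separation: float = 1.2) -> ShiftTable:
    """Build a physically plausible shift table with unique, well-separated
    shifts for parameter-recovery fixtures.

    Values are drawn near the reference statistics (truncated at 2 sd) and
    re-drawn until the joint uniqueness constraints hold: no two residues
    share both their N and CA coordinates, or their whole (CA, CB, C)
    profile, within the separation margins; carbons within one residue stay
    distinguishable. Within degenerate atom pairs (CG1/CG2 etc.) the lower
    shift goes to the lower atom name, matching the assigner's declared
    tie-break.
    """
    from .atoms import HEAVY_ATOMS
    rng = np.random.default_rng(seed)
    c_sep, n_sep = carbon_separation, nitrogen_separation
    placed: dict[int, dict[str, float]] = {}

    def draw(pos: int) -> dict[str, float]:
        vals: dict[str, float] = {}
        for atom in HEAVY_ATOMS[sequence.type_at(pos)]:
            ms = stats.mean_sd(sequence.type_at(pos), atom)
            if ms is None:
                continue
            mean, sd = ms
            z = float(np.clip(rng.normal(), -2.0, 2.0))
            vals[atom] = round(mean + z * min(sd, 3.0), 3)
        return vals

    def ok(pos: int, vals: dict[str, float]) -> bool:
        carbons_here = [v for a, v in vals.items() if a != "N"]
        for i, v in enumerate(carbons_here):
            for w in carbons_here[i + 1:]:
                if abs(v - w) < 0.7:
                    return False
        for qpos, other in placed.items():
            if "N" in vals and "N" in other and "CA" in vals and "CA" in other:
                if abs(vals["N"] - other["N"]) < n_sep and \
                        abs(vals["CA"] - other["CA"]) < c_sep:
                    return False
            close = True
            for a in ("CA", "CB", "C"):
                va, vb = vals.get(a), other.get(a)
                if va is not None and vb is not None and abs(va - vb) >= c_sep:
                    close = False
                    break
            if close:
                return False
        return True

    for pos in sequence.positions():
        vals = draw(pos)
        for _ in range(500):
            if ok(pos, vals):
                break
            vals = draw(pos)
        placed[pos] = vals

    values: dict[tuple[int, str], float] = {
        (pos, atom): v for pos, vals in placed.items()
        for atom, v in vals.items()
    }
    # enforce the degenerate-pair ordering rule
    for (a1, a2) in [("CD1", "CD2"), ("CE1", "CE2"), ("CG1", "CG2"),
                     ("CZ2", "CZ3")]:
        for pos in sequence.positions():
            v1, v2 = values.get((pos, a1)), values.get((pos, a2))
            if v1 is not None and v2 is not None and v1 > v2:
                values[(pos, a1)], values[(pos, a2)] = v2, v1
    entries = [ShiftEntry(pos, sequence.type_at(pos), atom, v)
               for (pos, atom), v in sorted(values.items())]
    return ShiftTable(entries)
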