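"""Gaussian chemical-shift reference statistics and amino-acid typing.

The bundled snapshot (``data/shift_stats.tsv``) provides a mean/sd per
(residue type, atom) pair; a user table in the same 5-column format can
replace it. Typing treats atoms as independent Gaussians (diagonal model):
the likelihood of a residue type given observed shifts is the product of the
per-atom densities, and is exactly zero when an observed atom does not exist
in that type (a CB observation rules out glycine).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .atoms import AA1, HEAVY_ATOMS, canonical_atom

log = logging.getLogger(__name__)

SD_FLOOR_CARBON = 0.3
SD_FLOOR_NITROGEN = 0.5


def _sd_floor(atom: str) -> float:
    return SD_FLOOR_NITROGEN if atom.startswith("N") else SD_FLOOR_CARBON


@dataclass
class ShiftStatistics:
    entries: dict[tuple[str, str], tuple[float, float, int]]
    source: str = "bundled"
    _cache: dict = field(default_factory=dict, repr=False)

    def mean_sd(self, res_type: str, atom: str) -> Optional[tuple[float, float]]:
        e = self.entries.get((res_type, canonical_atom(atom)))
        return (e[0], e[1]) if e else None

    def density(self, ppm: float, res_type: str, atom: str) -> float:
        """Gaussian density of an observed shift under one (type, atom) entry;
        0.0 when the type lacks the atom."""
        e = self.entries.get((res_type, canonical_atom(atom)))
        if e is None:
            return 0.0
        mean, sd, _ = e
        z = (ppm - mean) / sd
        return math.exp(-0.5 * z * z) / (sd * math.sqrt(2.0 * math.pi))

    def max_density(self, ppm: float, atom: str) -> float:
        """Best density over all 20 types (used for slot-conflict arbitration)."""
        return max(self.density(ppm, t, atom) for t in AA1)


def _parse_rows(lines, source: str) -> ShiftStatistics:
    entries: dict[tuple[str, str], tuple[float, float, int]] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{source}:{lineno}: expected 5 columns, got {len(parts)}")
        res, atom, mean_s, sd_s, count_s = parts
        res = res.upper()
        atom = canonical_atom(atom)
        try:
            mean, sd, count = float(mean_s), float(sd_s), int(count_s)
        except ValueError as exc:
            raise ValueError(f"{source}:{lineno}: {exc}") from exc
        floor = _sd_floor(atom)
        if sd < floor:
            log.warning("%s:%d: sd %.3f below floor, clamped to %.2f",
                        source, lineno, sd, floor)
            sd = floor
        entries[(res, atom)] = (mean, sd, count)
    return ShiftStatistics(entries, source)


def load_statistics(path: Optional[str] = None) -> ShiftStatistics:
    """Load the bundled statistics snapshot, or a user 5-column table."""
    if path is None:
        ref = resources.files("ssassign.data").joinpath("shift_stats.tsv")
        stats = _parse_rows(ref.read_text().splitlines(), "bundled")
    else:
        with open(path) as fh:
            stats = _parse_rows(fh, str(path))
    return stats


def type_likelihood(observed: dict[str, float], res_type: str,
                    stats: ShiftStatistics) -> float:
    """Product of per-atom Gaussian densities for one residue type.

    Atoms absent from the observation map are marginalized out; an observed
    atom the type does not possess makes the likelihood 0.
    """
    if not observed:
        raise ValueError("observed map must be non-empty")
    score = 1.0
    inventory = HEAVY_ATOMS[res_type]
    for atom, ppm in observed.items():
        atom = canonical_atom(atom)
        if atom not in inventory:
            return 0.0
        score *= stats.density(ppm, res_type, atom)
        if score == 0.0:
            return 0.0
    return score


def type_posterior(observed: dict[str, float], stats: ShiftStatistics,
                   prior: Optional[dict[str, float]] = None) -> dict[str, float]:
    """Normalized posterior over the 20 residue types."""
    if prior is None:
        prior = {t: 1.0 / len(AA1) for t in AA1}
    if not observed:
        z = sum(prior.get(t, 0.0) for t in AA1)
        return {t: prior.get(t, 0.0) / z for t in AA1}
    raw = {t: prior.get(t, 0.0) * type_likelihood(observed, t, stats) for t in AA1}
    z = sum(raw.values())
    if z == 0.0:
        log.warning("all residue types have zero likelihood; returning uniform")
        return {t: 1.0 / len(AA1) for t in AA1}
    return {t: v / z for t, v in raw.items()}


def sequence_composition_prior(residues: str) -> dict[str, float]:
    counts = {t: residues.count(t) for t in AA1}
    total = max(1, sum(counts.values()))
    return {t: c / total for t, c in counts.items()}
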