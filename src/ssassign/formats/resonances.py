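"""Sparky resonance-list writer/reader: one "G1 N 108.95" line per atom."""

from __future__ import annotations

from pathlib import Path

from ..model import AssignmentResult


def write_sparky_resonances(result: AssignmentResult, path) -> None:
    lines = []
    for idx, res, atom, ppm, _prob in result.iter_shifts():
        lines.append(f"{res}{idx} {atom} {ppm:.3f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_sparky_resonances(path) -> list[tuple[str, int, str, float]]:
    """Return (residue type, residue index, atom, ppm) tuples."""
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        group, atom, ppm = line.split()
        out.append((group[0], int(group[1:]), atom, float(ppm)))
    return out
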