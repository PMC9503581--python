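"""Peak-list readers/writers: Sparky ``.list``, XEASY ``.peaks``, and the
tab-separated ``.txt`` dialect (position columns, then an optional height).

All dialects are whitespace tolerant; unparseable lines are skipped and
counted on the returned ``PeakList``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

from ..model import Peak, PeakList
from ..profiles import ExperimentProfile, get_profile

log = logging.getLogger(__name__)

_EXT_FORMATS = {".list": "sparky", ".peaks": "xeasy", ".txt": "tabular"}


class PeakFormatError(ValueError):
    pass


def _try_float(tok: str) -> Optional[float]:
    try:
        return float(tok)
    except ValueError:
        return None


def _parse_sparky(lines, dim: int):
    peaks, skipped = [], 0
    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        toks = line.split()
        label = None
        if _try_float(toks[0]) is None:
            if toks[0].lower() == "assignment":  # header line
                continue
            label = toks[0]
            toks = toks[1:]
        vals = [_try_float(t) for t in toks]
        if len(vals) < dim or any(v is None for v in vals[:dim]):
            skipped += 1
            continue
        height = vals[dim] if len(vals) > dim and vals[dim] is not None else None
        peaks.append(Peak(tuple(vals[:dim]), height, label))
    return peaks, skipped


def _parse_xeasy(lines, dim: int):
    peaks, skipped = [], 0
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        # index, w1..wn, color, spectrum-type, intensity, ...
        if len(toks) < 1 + dim or _try_float(toks[0]) is None:
            skipped += 1
            continue
        vals = [_try_float(t) for t in toks[1:1 + dim]]
        if any(v is None for v in vals):
            skipped += 1
            continue
        height = None
        if len(toks) >= 1 + dim + 3:
            height = _try_float(toks[1 + dim + 2])
        peaks.append(Peak(tuple(vals), height))
    return peaks, skipped


def _parse_tabular(lines, dim: int):
    peaks, skipped = [], 0
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        vals = [_try_float(t) for t in line.split()]
        if len(vals) < dim or any(v is None for v in vals[:dim]):
            skipped += 1
            continue
        height = vals[dim] if len(vals) > dim else None
        peaks.append(Peak(tuple(vals[:dim]), height))
    return peaks, skipped


_PARSERS = {"sparky": _parse_sparky, "xeasy": _parse_xeasy, "tabular": _parse_tabular}


def read_peak_list(path, experiment_name: str,
                   format_hint: Optional[str] = None,
                   axis_order: Optional[Sequence[int]] = None) -> PeakList:
    """Read one peak-list file for a named experiment.

    Format is inferred from the extension (.list/.peaks/.txt) unless
    `format_hint` names one of sparky/xeasy/tabular. `axis_order` permutes file
    columns onto the profile's axis order: entry k is the file column holding
    profile axis k.
    """
    path = Path(path)
    profile = get_profile(experiment_name)
    fmt = (format_hint or _EXT_FORMATS.get(path.suffix.lower()))
    if fmt not in _PARSERS:
        raise PeakFormatError(
            f"cannot infer peak-list format for {path.name!r}; "
            f"pass format_hint of sparky, xeasy or tabular"
        )
    with open(path) as fh:
        peaks, skipped = _PARSERS[fmt](fh, profile.dimensionality)
    if skipped:
        log.warning("%s: skipped %d unparseable line(s)", path, skipped)
    if axis_order is not None:
        if sorted(axis_order) != list(range(profile.dimensionality)):
            raise PeakFormatError(f"axis_order must permute 0..{profile.dimensionality - 1}")
        peaks = [Peak(tuple(p.position[j] for j in axis_order), p.height, p.label)
                 for p in peaks]
    return PeakList(profile.name, profile.dimensionality, profile.axis_nuclei,
                    peaks, skipped_lines=skipped, source=str(path))


def write_peak_list(peaklist: PeakList, path, fmt: str = "sparky") -> None:
    """Write a peak list in the Sparky or XEASY dialect."""
    path = Path(path)
    dim = peaklist.dimensionality
    lines: list[str] = []
    if fmt == "sparky":
        ws = " ".join(f"w{k + 1}" for k in range(dim))
        lines.append(f"{'Assignment':>17} {ws} Data Height")
        lines.append("")
        for pk in peaklist.peaks:
            label = pk.label or "-".join("?" * dim)
            coords = " ".join(f"{v:9.3f}" for v in pk.position)
            height = f" {pk.height:14.4e}" if pk.height is not None else ""
            lines.append(f"{label:>17} {coords}{height}")
    elif fmt == "xeasy":
        lines.append(f"# Number of dimensions {dim}")
        for i, pk in enumerate(peaklist.peaks, start=1):
            coords = " ".join(f"{v:8.3f}" for v in pk.position)
            h = pk.height if pk.height is not None else 0.0
            lines.append(f"{i:4d} {coords} 1 U {h:14.4e} 0.00e+00 - 0 0 0 0")
    else:
        raise PeakFormatError(f"unsupported output format {fmt!r}")
    path.write_text("\n".join(lines) + "\n")


def check_consistency(peaklist: PeakList, profile: ExperimentProfile) -> None:
    if peaklist.dimensionality != profile.dimensionality:
        raise PeakFormatError(
            f"{peaklist.source or peaklist.experiment_name}: file dimensionality "
            f"{peaklist.dimensionality} conflicts with profile "
            f"{profile.name} ({profile.dimensionality}D)"
        )
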