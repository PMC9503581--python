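"""Minimal NMR-STAR 2.1 / 3.1 support for assigned chemical-shift tables.

Only the pieces the pipeline needs are implemented: reading an assigned
chemical shift loop (plus, when present, the one-letter entity sequence),
and writing shift tables in both dialects. A 4-column plain-text table
(``index  residue  atom  ppm``) is accepted as a fallback input.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

from ..atoms import AA1, ONE_TO_THREE, THREE_TO_ONE, canonical_atom
from ..model import AssignmentResult, ProteinSequence, ShiftEntry, ShiftTable

log = logging.getLogger(__name__)


class StarFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tokenizer

def _tokenize(text: str):
    """Yield STAR tokens: bare words, quoted strings, and ;-delimited blocks."""
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(";"):
            block = []
            i += 1
            while i < len(lines) and not lines[i].startswith(";"):
                block.append(lines[i])
                i += 1
            yield "\n".join(block)
            i += 1
            continue
        j = 0
        n = len(line)
        while j < n:
            ch = line[j]
            if ch.isspace():
                j += 1
                continue
            if ch == "#":
                break
            if ch in "'\"":
                k = line.find(ch, j + 1)
                if k == -1:
                    k = n
                yield line[j + 1:k]
                j = k + 1
                continue
            k = j
            while k < n and not line[k].isspace():
                k += 1
            yield line[j:k]
            j = k
        i += 1


def _loops(tokens: list[str]):
    """Yield (tags, rows) for every loop in a token stream."""
    i = 0
    n = len(tokens)
    while i < n:
        if tokens[i].lower() != "loop_":
            i += 1
            continue
        i += 1
        tags: list[str] = []
        while i < n and tokens[i].startswith("_"):
            tags.append(tokens[i])
            i += 1
        values: list[str] = []
        while i < n and tokens[i].lower() not in ("stop_", "loop_") \
                and not tokens[i].startswith("_"):
            values.append(tokens[i])
            i += 1
        if i < n and tokens[i].lower() == "stop_":
            i += 1
        if tags and values:
            ncol = len(tags)
            rows = [values[k:k + ncol] for k in range(0, len(values) - ncol + 1, ncol)]
            yield tags, rows


_SHIFT_TAGSETS = [
    # (seq, comp, atom, value) — NMR-STAR 3.1
    ("_atom_chem_shift.seq_id", "_atom_chem_shift.comp_id",
     "_atom_chem_shift.atom_id", "_atom_chem_shift.val"),
    ("_atom_chem_shift.comp_index_id", "_atom_chem_shift.comp_id",
     "_atom_chem_shift.atom_id", "_atom_chem_shift.val"),
    # NMR-STAR 2.1
    ("_residue_seq_code", "_residue_label", "_atom_name", "_chem_shift_value"),
]


def _res_one_letter(label: str) -> Optional[str]:
    label = label.upper()
    if label in THREE_TO_ONE:
        return THREE_TO_ONE[label]
    if len(label) == 1 and label in AA1:
        return label
    return None


def _entries_from_loops(text: str) -> Optional[list[ShiftEntry]]:
    tokens = list(_tokenize(text))
    for tags, rows in _loops(tokens):
        low = [t.lower() for t in tags]
        for tagset in _SHIFT_TAGSETS:
            try:
                cols = [low.index(t) for t in tagset]
            except ValueError:
                continue
            entries: list[ShiftEntry] = []
            for row in rows:
                if len(row) < len(tags):
                    continue
                try:
                    idx = int(row[cols[0]])
                    ppm = float(row[cols[3]])
                except ValueError:
                    continue
                res = _res_one_letter(row[cols[1]])
                atom = canonical_atom(row[cols[2]])
                if res is None or atom[0] not in "CN":
                    continue
                entries.append(ShiftEntry(idx, res, atom, ppm))
            if entries:
                return entries
    return None


def _entries_from_tabular(text: str) -> Optional[list[ShiftEntry]]:
    entries: list[ShiftEntry] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            return None
        try:
            idx, ppm = int(parts[0]), float(parts[3])
        except ValueError:
            return None
        res = _res_one_letter(parts[1])
        if res is None:
            return None
        atom = canonical_atom(parts[2])
        if atom[0] not in "CN":
            continue
        entries.append(ShiftEntry(idx, res, atom, ppm))
    return entries or None


def load_shift_table(path) -> ShiftTable:
    """Read carbon/nitrogen shifts from an NMR-STAR 2.1/3.1 file or a simple
    4-column table. Proton rows are dropped."""
    text = Path(path).read_text()
    entries = _entries_from_loops(text)
    if entries is None:
        entries = _entries_from_tabular(text)
    if entries is None:
        raise StarFormatError(f"{path}: no parsable chemical-shift loop found")
    return ShiftTable(entries)


def extract_sequence(path) -> ProteinSequence:
    """Entity one-letter sequence when deposited; otherwise rebuilt from the
    shift loop (gaps filled with the nearest residue numbering)."""
    text = Path(path).read_text()
    tokens = list(_tokenize(text))
    for i, tok in enumerate(tokens):
        if tok.lower() in ("_entity.polymer_seq_one_letter_code",
                           "_mol_residue_sequence") and i + 1 < len(tokens):
            raw = "".join(tokens[i + 1].split())
            if raw and all(c.upper() in AA1 or c == "X" for c in raw):
                seq = raw.upper().replace("X", "G")  # placeholder for unknowns
                return ProteinSequence(seq, 1)
    table = load_shift_table(path)
    idxs = table.residue_indices()
    if not idxs:
        raise StarFormatError(f"{path}: cannot recover a sequence")
    first, last = idxs[0], idxs[-1]
    residues = []
    for i in range(first, last + 1):
        residues.append(table.residue_type(i) or "G")
    return ProteinSequence("".join(residues), first)


# ---------------------------------------------------------------------------
# writers

def write_shift_table(result: AssignmentResult, dialect: str, path) -> None:
    """Write assigned shifts as NMR-STAR ('2.1' or '3.1'); the assignment
    probability rides along in the final loop column (3.1) or as comment
    lines (2.1)."""
    rows = list(result.iter_shifts())
    if not rows:
        raise ValueError("refusing to write an empty shift table")
    out: list[str] = []
    if dialect == "3.1":
        out += [
            "data_assigned_shifts", "",
            "save_assigned_chemical_shifts",
            "   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts",
            "", "   loop_",
            "      _Atom_chem_shift.ID",
            "      _Atom_chem_shift.Seq_ID",
            "      _Atom_chem_shift.Comp_ID",
            "      _Atom_chem_shift.Atom_ID",
            "      _Atom_chem_shift.Atom_type",
            "      _Atom_chem_shift.Val",
            "      _Atom_chem_shift.Assign_fig_of_merit",
            "",
        ]
        for k, (idx, res, atom, ppm, prob) in enumerate(rows, start=1):
            out.append(
                f"      {k:5d} {idx:4d} {ONE_TO_THREE[res]} {atom:<4s} "
                f"{atom[0]} {ppm:9.3f} {prob:6.3f}"
            )
        out += ["", "   stop_", "", "save_", ""]
    elif dialect == "2.1":
        out += [
            "data_assigned_shifts", "",
            "save_assigned_chemical_shifts",
            "   _Saveframe_category   assigned_chemical_shifts",
            "", "   loop_",
            "      _Atom_shift_assign_ID",
            "      _Residue_seq_code",
            "      _Residue_label",
            "      _Atom_name",
            "      _Atom_type",
            "      _Chem_shift_value",
            "      _Chem_shift_value_error",
            "",
        ]
        for k, (idx, res, atom, ppm, prob) in enumerate(rows, start=1):
            out.append(
                f"      {k:5d} {idx:4d} {ONE_TO_THREE[res]} {atom:<4s} "
                f"{atom[0]} {ppm:9.3f} 0.0"
            )
        out += ["", "   stop_", ""]
        out.append("# assignment probabilities")
        for idx, res, atom, ppm, prob in rows:
            out.append(f"# prob {idx} {atom} {prob:.3f}")
        out += ["", "save_", ""]
    else:
        raise ValueError(f"unknown NMR-STAR dialect {dialect!r} (use '2.1' or '3.1')")
    Path(path).write_text("\n".join(out))


def write_tabular(table: ShiftTable, path) -> None:
    lines = [f"{e.residue_index} {ONE_TO_THREE[e.residue_type]} {e.atom} {e.ppm:.3f}"
             for e in table.entries]
    Path(path).write_text("\n".join(lines) + "\n")
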