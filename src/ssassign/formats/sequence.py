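"""Plain-text protein sequence reader (one- or three-letter codes)."""

from __future__ import annotations

from pathlib import Path

from ..atoms import AA1, THREE_TO_ONE
from ..model import ProteinSequence


class SequenceParseError(ValueError):
    pass


def parse_sequence(text: str, first_index: int = 1) -> ProteinSequence:
    tokens: list[tuple[str, int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#")[0].split(">")[0] if line.startswith(">") else line
        for tok in line.split():
            tokens.append((tok, lineno))
    if not tokens:
        raise SequenceParseError("empty sequence file")
    # Three-letter form: every token is a known 3-letter code.
    if all(len(t) == 3 and t.upper() in THREE_TO_ONE for t, _ in tokens):
        residues = "".join(THREE_TO_ONE[t.upper()] for t, _ in tokens)
        return ProteinSequence(residues, first_index)
    residues = []
    for tok, lineno in tokens:
        for ch in tok:
            cu = ch.upper()
            if cu.isdigit():
                continue  # allow residue numbering interleaved with the codes
            if cu not in AA1:
                raise SequenceParseError(
                    f"line {lineno}: unknown residue code {ch!r}"
                )
            residues.append(cu)
    return ProteinSequence("".join(residues), first_index)


def read_sequence(path, first_index: int = 1) -> ProteinSequence:
    return parse_sequence(Path(path).read_text(), first_index)
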