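"""Sequence reading, structure-sequence stitching and window extraction."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Tuple, Union

from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_3to1

logger = logging.getLogger(__name__)

#: Placeholder letter for window positions outside the sequence.  Kept
#: distinct from X (unknown residue) and FASTA-safe.
GAP = "-"

VALID_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence; letters from the 20 canonical plus X."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValueError("empty sequence")
        bad = set(self.residues) - VALID_LETTERS
        if bad:
            raise ValueError(f"invalid residue letters: {sorted(bad)}")

    @property
    def L(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class WindowedItem:
    """One residue or residue pair with its window context letters."""

    centers: Tuple[int, ...]
    contexts: Tuple[str, ...]  # one string of length 2w+1 per center


def read_fasta(path: Union[str, Path]) -> list[ProteinSequence]:
    """Read all records of a FASTA file.

    Identifiers are the header up to the first whitespace.  Duplicate
    identifiers are suffixed ``.2``, ``.3``, ... with a warning; internal
    whitespace in sequence lines is dropped with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out: list[ProteinSequence] = []
    counts: dict[str, int] = {}
    for rec in records:
        seq = str(rec.seq)
        if " " in seq or "\t" in seq:
            logger.warning("%s: internal whitespace in record %s removed", path, rec.id)
            seq = "".join(seq.split())
        ident = rec.id
        counts[ident] = counts.get(ident, 0) + 1
        if counts[ident] > 1:
            logger.warning("%s: duplicate identifier %s, suffixing", path, ident)
            ident = f"{ident}.{counts[ident]}"
        out.append(ProteinSequence(identifier=ident, residues=seq.upper()))
    return out


def write_fasta(sequences: Sequence[ProteinSequence], path: Union[str, Path],
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.identifier}\n")
            for k in range(0, len(seq), width):
                fh.write(seq.residues[k:k + width] + "\n")


def stitch_structure_sequence(
    residue_records: Sequence[Tuple[str, int, str]],
    identifier: str = "structure",
) -> Tuple[ProteinSequence, dict[int, int]]:
    """Concatenate structure residues (possibly with numbering gaps).

    ``residue_records`` are ordered ``(chain, structure_residue_number,
    aa)`` tuples where ``aa`` is a 1- or 3-letter code.  Returns the
    stitched sequence and a map from output position (1-based) to the
    structure residue number.  Unknown 3-letter codes become X with a
    warning.
    """
    if not residue_records:
        raise ValueError("no residue records to stitch")
    letters = []
    fragments: dict[int, int] = {}
    for pos, (chain, resnum, aa) in enumerate(residue_records, start=1):
        code = aa.strip().upper()
        if len(code) == 3:
            letter = _THREE_TO_ONE.get(code)
            if letter is None:
                logger.warning("unknown residue code %r at %s:%s, using X",
                               aa, chain, resnum)
                letter = "X"
        elif len(code) == 1 and code in VALID_LETTERS:
            letter = code
        else:
            logger.warning("unknown residue code %r at %s:%s, using X",
                           aa, chain, resnum)
            letter = "X"
        letters.append(letter)
        fragments[pos] = resnum
    return ProteinSequence(identifier, "".join(letters)), fragments


def extract_windowed(
    seq: ProteinSequence,
    targets: Sequence[Union[int, Tuple[int, int]]],
    w: int,
) -> list[WindowedItem]:
    """Window context of single residues or residue pairs.

    Each center yields the ``2w + 1`` letters ``center - w .. center + w``,
    with '-' where the window runs past either sequence end.
    """
    if w < 0:
        raise ValueError(f"window half-width must be >= 0, got {w}")
    L = seq.L
    items: list[WindowedItem] = []
    for target in targets:
        centers = target if isinstance(target, tuple) else (target,)
        for c in centers:
            if not (1 <= c <= L):
                raise ValueError(f"target residue {c} outside 1..{L}")
        contexts = tuple(
            "".join(
                seq.residues[p - 1] if 1 <= p <= L else GAP
                for p in range(c - w, c + w + 1)
            )
            for c in centers
        )
        items.append(WindowedItem(centers=tuple(centers), contexts=contexts))
    return items


def windowed_to_tsv(items: Sequence[WindowedItem], path: Union[str, Path]) -> None:
    """Write windowed items as TSV: center position(s), then context letters."""
    with open(path, "w") as fh:
        for item in items:
            cols = [",".join(str(c) for c in item.centers)]
            cols += list(item.contexts)
            fh.write("\t".join(cols) + "\n")
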