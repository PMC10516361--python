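"""Structure-to-sequence residue numbering correspondence.

Experimentally resolved structures routinely miss residues (disordered
loops, cleaved tags), so the structure-derived sequence is an imperfect
substring pattern of the full FASTA sequence and residue numbers disagree.
:func:`map_residues` aligns the two sequences globally and converts the
alignment into a bidirectional number map.

Identity scoring (no substitution matrix) is used on purpose: the two
sequences come from the same protein, so any mismatch flags a real
discrepancy (engineering artifact, sequence-version drift), not homologous
substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

from Bio import Align

from resconn.seqops import ProteinSequence


@dataclass
class ResidueMap:
    """Bidirectional structure-number <-> FASTA-position correspondence.

    ``forward`` and ``reverse`` are mutually inverse on mapped residues;
    aligned columns whose letters differ are still mapped but listed in
    ``mismatches``.  Residues opposite an alignment gap go to the unmapped
    lists.
    """

    forward: dict[int, int]              # structure residue number -> FASTA pos
    reverse: dict[int, int]              # FASTA pos -> structure residue number
    mismatches: list[Tuple[int, int]]    # (structure number, FASTA pos)
    unmapped_structure: list[int]
    unmapped_fasta: list[int]


def _make_aligner(match: float, mismatch: float,
                  gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def map_residues(
    structure_seq: Union[str, ProteinSequence],
    fasta_seq: Union[str, ProteinSequence],
    structure_numbering: Optional[Sequence[int]] = None,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> ResidueMap:
    """Map structure residue numbers to FASTA positions by global alignment.

    ``structure_numbering`` gives the structure residue number of each
    letter of ``structure_seq`` in order (defaults to 1..len).  Scoring
    defaults: match +1, mismatch -1, gap open -2, gap extend -1.  Among
    equal-scoring alignments the aligner's first traceback is taken, which
    is deterministic for fixed inputs and scores.
    """
    s = structure_seq.residues if isinstance(structure_seq, ProteinSequence) else structure_seq
    f = fasta_seq.residues if isinstance(fasta_seq, ProteinSequence) else fasta_seq
    if not s or not f:
        raise ValueError("both sequences must be non-empty")
    if structure_numbering is None:
        structure_numbering = list(range(1, len(s) + 1))
    if len(structure_numbering) != len(s):
        raise ValueError("numbering length must equal structure sequence length")

    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    alignment = next(iter(aligner.align(s, f)))

    forward: dict[int, int] = {}
    reverse: dict[int, int] = {}
    mismatches: list[Tuple[int, int]] = []
    mapped_struct: set[int] = set()
    mapped_fasta: set[int] = set()

    # aligned blocks: pairs of [start, end) ranges in both sequences
    for (s_beg, s_end), (f_beg, f_end) in zip(*alignment.aligned):
        for offset in range(s_end - s_beg):
            si, fi = s_beg + offset, f_beg + offset
            snum, fpos = structure_numbering[si], fi + 1
            forward[snum] = fpos
            reverse[fpos] = snum
            mapped_struct.add(si)
            mapped_fasta.add(fi)
            if s[si] != f[fi]:
                mismatches.append((snum, fpos))

    unmapped_structure = [structure_numbering[si]
                          for si in range(len(s)) if si not in mapped_struct]
    unmapped_fasta = [fi + 1 for fi in range(len(f)) if fi not in mapped_fasta]
    return ResidueMap(forward=forward, reverse=reverse, mismatches=mismatches,
                      unmapped_structure=unmapped_structure,
                      unmapped_fasta=unmapped_fasta)


def map_to_tsv(
    rmap: ResidueMap,
    structure_seq: Union[str, ProteinSequence],
    fasta_seq: Union[str, ProteinSequence],
    structure_numbering: Optional[Sequence[int]],
    path: Union[str, Path],
) -> None:
    """Write the map as 4-column TSV: structure_number, structure_aa,
    fasta_position, fasta_aa ('-' where unmapped)."""
    s = structure_seq.residues if isinstance(structure_seq, ProteinSequence) else structure_seq
    f = fasta_seq.residues if isinstance(fasta_seq, ProteinSequence) else fasta_seq
    if structure_numbering is None:
        structure_numbering = list(range(1, len(s) + 1))
    num_to_letter = dict(zip(structure_numbering, s))
    with open(path, "w") as fh:
        fh.write("structure_number\tstructure_aa\tfasta_position\tfasta_aa\n")
        for si, snum in enumerate(structure_numbering):
            fpos = rmap.forward.get(snum)
            if fpos is None:
                fh.write(f"{snum}\t{s[si]}\t-\t-\n")
            else:
                fh.write(f"{snum}\t{s[si]}\t{fpos}\t{f[fpos - 1]}\n")
        for fpos in rmap.unmapped_fasta:
            fh.write(f"-\t-\t{fpos}\t{f[fpos - 1]}\n")
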