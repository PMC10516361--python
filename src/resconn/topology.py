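"""Membrane-topology segments: XML parsing, relabeling, encoding and QC.

Structure-based topology annotation (TMDET/PDBTM style) types each
contiguous residue segment of a chain with a one-letter region code:

====  ==================
code  region
====  ==================
H     alpha-helix (TM)
B     beta-strand (TM)
C     coil
I     membrane-inside
L     loop
F     interfacial
U     unknown
1     side 1 of the membrane
2     side 2 of the membrane
====  ==================

Structure-based placement cannot tell which membrane side is cytoplasmic;
:func:`redistribute_nontm` resolves side1/side2 (and loop/unknown) into
cytoplasmic/extracellular by majority vote against a sequence-based
predicted topology (inside/outside/TM segments, e.g. TMHMM-like output).

:func:`qc_filter` screens structure metadata records (method, resolution,
length, TM-helix count and lengths) against a criteria set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

from lxml import etree

logger = logging.getLogger(__name__)

REGION_CODES = {
    "H": "alpha-helix",
    "B": "beta-strand",
    "C": "coil",
    "I": "membrane-inside",
    "L": "loop",
    "F": "interfacial",
    "U": "unknown",
    "1": "side1",
    "2": "side2",
}

#: Codes kept verbatim by redistribution (membrane-associated regions).
TM_PASSTHROUGH = frozenset("HBFIC")
#: Codes eligible for cytoplasmic/extracellular relabeling.
RELABELABLE = frozenset("12LU")

CYTOPLASMIC = "cytoplasmic"
EXTRACELLULAR = "extracellular"
UNKNOWN_SIDE = "unknown"

_PRED_LABELS = {"inside", "outside", "TM"}
_PRED_TO_SIDE = {"inside": CYTOPLASMIC, "outside": EXTRACELLULAR}


@dataclass(frozen=True)
class TopologySegment:
    """A contiguous typed residue segment in structure numbering."""

    chain: str
    beg: int
    end: int
    code: str

    def __post_init__(self) -> None:
        if self.beg > self.end:
            raise ValueError(f"segment begin {self.beg} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.beg + 1


@dataclass(frozen=True)
class PredictedTopology:
    """Ordered, non-overlapping (beg, end, label) segments; labels
    inside / outside / TM."""

    segments: Tuple[Tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for beg, end, label in self.segments:
            if label not in _PRED_LABELS:
                raise ValueError(f"unknown predicted label {label!r}")
            if beg > end:
                raise ValueError(f"predicted segment begin {beg} > end {end}")
            if beg <= prev_end:
                raise ValueError("predicted segments must be ascending, non-overlapping")
            prev_end = end


def parse_topology_xml(path: Union[str, Path]) -> dict[str, list[TopologySegment]]:
    """Parse region-annotated topology XML into per-chain segment lists.

    Expected dialect::

        <topology>
          <chain id="A">
            <region beg="1" end="9" type="1"/>
            ...
          </chain>
        </topology>

    Segments come back in document order.  An unrecognized ``type``
    attribute becomes code U with a warning; malformed XML or a segment
    with ``beg > end`` raises.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: malformed XML: {exc}") from exc
    chains: dict[str, list[TopologySegment]] = {}
    for chain_el in tree.getroot().iter("chain"):
        chain_id = chain_el.get("id", "")
        chains.setdefault(chain_id, [])
        for region in chain_el.iter("region"):
            beg = int(region.get("beg"))
            end = int(region.get("end"))
            code = region.get("type", "U")
            if code not in REGION_CODES:
                logger.warning("%s: unknown region type %r in chain %s, using U",
                               path, code, chain_id)
                code = "U"
            if beg > end:
                raise ValueError(
                    f"{path}: region begin {beg} > end {end} in chain {chain_id}"
                )
            chains[chain_id].append(
                TopologySegment(chain=chain_id, beg=beg, end=end, code=code)
            )
    return chains


def write_topology_xml(
    chains: dict[str, Sequence[TopologySegment]],
    path: Union[str, Path],
) -> None:
    """Serialize per-chain segments to the dialect read by
    :func:`parse_topology_xml` (bit-compatible round trip)."""
    root = etree.Element("topology")
    for chain_id, segments in chains.items():
        chain_el = etree.SubElement(root, "chain", id=chain_id)
        for seg in segments:
            etree.SubElement(chain_el, "region",
                             beg=str(seg.beg), end=str(seg.end), type=seg.code)
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


def _overlap(beg1: int, end1: int, beg2: int, end2: int) -> int:
    return max(0, min(end1, end2) - max(beg1, beg2) + 1)


def redistribute_nontm(
    segments: Sequence[TopologySegment],
    predicted: PredictedTopology,
) -> list[TopologySegment]:
    """Relabel non-TM segments as cytoplasmic/extracellular.

    Membrane-associated codes (H, B, F, I, C) pass through unchanged.  A
    side1/side2/loop/unknown segment takes the side covering the majority
    of its residues under the predicted topology (inside -> cytoplasmic,
    outside -> extracellular); ties and segments with no overlapping
    prediction become ``unknown``.  Segment boundaries are never altered.
    """
    out: list[TopologySegment] = []
    for seg in segments:
        if seg.code not in RELABELABLE:
            out.append(seg)
            continue
        counts = {CYTOPLASMIC: 0, EXTRACELLULAR: 0}
        for beg, end, label in predicted.segments:
            side = _PRED_TO_SIDE.get(label)
            if side is not None:
                counts[side] += _overlap(seg.beg, seg.end, beg, end)
        if counts[CYTOPLASMIC] > counts[EXTRACELLULAR]:
            code = CYTOPLASMIC
        elif counts[EXTRACELLULAR] > counts[CYTOPLASMIC]:
            code = EXTRACELLULAR
        else:
            code = UNKNOWN_SIDE
        out.append(TopologySegment(chain=seg.chain, beg=seg.beg,
                                   end=seg.end, code=code))
    return out


def per_residue_topology(
    segments: Sequence[TopologySegment],
    L: int,
) -> list[str]:
    """Per-residue label vector of length L.

    Residues take the code of the covering segment; uncovered residues are
    U.  When segments overlap, the later one in document order wins, with a
    warning.  A segment extending past L raises.
    """
    labels = ["U"] * L
    for seg in segments:
        if seg.beg < 1 or seg.end > L:
            raise ValueError(f"segment {seg.beg}-{seg.end} outside 1..{L}")
        for pos in range(seg.beg, seg.end + 1):
            if labels[pos - 1] != "U":
                logger.warning("overlap at residue %d: %s overwritten by %s",
                               pos, labels[pos - 1], seg.code)
            labels[pos - 1] = seg.code
    return labels


@dataclass(frozen=True)
class QCRecord:
    """Structure metadata for one protein chain/entry."""

    identifier: str
    method: Optional[str] = None
    resolution: Optional[float] = None  # angstrom; None for e.g. NMR
    length: Optional[int] = None
    tm_helix_count: Optional[int] = None
    tm_helix_lengths: Optional[Tuple[int, ...]] = None


@dataclass(frozen=True)
class QCCriteria:
    """Screening thresholds; an unset (None) field is not tested."""

    allowed_methods: Optional[frozenset[str]] = None
    max_resolution: Optional[float] = None
    min_length: Optional[int] = None
    max_length: Optional[int] = None
    min_tm_helix_count: Optional[int] = None
    max_tm_helix_count: Optional[int] = None
    min_tm_helix_length: Optional[int] = None
    max_tm_helix_length: Optional[int] = None

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.min_length, self.max_length, "length"),
            (self.min_tm_helix_count, self.max_tm_helix_count, "tm_helix_count"),
            (self.min_tm_helix_length, self.max_tm_helix_length, "tm_helix_length"),
        ):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"contradictory {name} criteria: min {lo} > max {hi}")


def _check_record(rec: QCRecord, crit: QCCriteria) -> list[str]:
    reasons: list[str] = []

    def need(field_name: str):
        value = getattr(rec, field_name)
        if value is None:
            reasons.append(f"missing:{field_name}")
        return value

    if crit.allowed_methods is not None:
        method = need("method")
        if method is not None and method not in crit.allowed_methods:
            reasons.append("method")
    if crit.max_resolution is not None:
        res = need("resolution")
        if res is not None and res > crit.max_resolution:
            reasons.append("resolution")
    if crit.min_length is not None or crit.max_length is not None:
        length = need("length")
        if length is not None:
            if crit.min_length is not None and length < crit.min_length:
                reasons.append("length")
            elif crit.max_length is not None and length > crit.max_length:
                reasons.append("length")
    if crit.min_tm_helix_count is not None or crit.max_tm_helix_count is not None:
        count = need("tm_helix_count")
        if count is not None:
            if crit.min_tm_helix_count is not None and count < crit.min_tm_helix_count:
                reasons.append("tm_helix_count")
            elif crit.max_tm_helix_count is not None and count > crit.max_tm_helix_count:
                reasons.append("tm_helix_count")
    if crit.min_tm_helix_length is not None or crit.max_tm_helix_length is not None:
        lengths = need("tm_helix_lengths")
        if lengths is not None:
            lo_bad = crit.min_tm_helix_length is not None and any(
                h < crit.min_tm_helix_length for h in lengths)
            hi_bad = crit.max_tm_helix_length is not None and any(
                h > crit.max_tm_helix_length for h in lengths)
            if lo_bad or hi_bad:
                reasons.append("tm_helix_length")
    return reasons


def qc_filter(
    records: Sequence[QCRecord],
    criteria: QCCriteria,
) -> Tuple[list[QCRecord], dict[str, list[str]]]:
    """Screen records against the criteria.

    A record passes iff it satisfies every set criterion; a record missing
    a field that a set criterion tests fails with reason
    ``missing:<field>``.  Returns the passing records and, for every
    record, its (possibly empty) list of failure reasons.
    """
    passing: list[QCRecord] = []
    reasons: dict[str, list[str]] = {}
    for rec in records:
        rec_reasons = _check_record(rec, criteria)
        reasons[rec.identifier] = rec_reasons
        if not rec_reasons:
            passing.append(rec)
    return passing, reasons
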