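"""Seeded synthetic fixture bundles: every module testable offline.

The generator emulates the input ecosystem of a membrane-protein feature
pipeline: random protein sequences; symmetric pair-score matrices with
uniform(0, 1) background and optionally spiked "contact" pairs; topology
annotations alternating side1 / TM-helix / side2 along the chain; a
sequence-based predicted topology consistent with the annotation (side1 ->
inside, side2 -> outside, helix -> TM) up to a configurable corruption
rate; and a structure-metadata table for quality control.  A single seed
governs everything and regeneration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from resconn.seqops import ProteinSequence, write_fasta
from resconn.topology import (
    PredictedTopology,
    QCRecord,
    TopologySegment,
    write_topology_xml,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_METHODS = ("X-ray", "NMR", "EM")


@dataclass
class FixtureBundle:
    """Paths and in-memory objects of one generated bundle."""

    out_dir: Path
    fasta_path: Path
    matrix_paths: dict[str, Path]
    topology_xml_path: Path
    predicted_path: Path
    qc_path: Path
    manifest_path: Path
    sequences: list[ProteinSequence]
    topologies: dict[str, list[TopologySegment]]
    predicted: dict[str, PredictedTopology]
    qc_records: list[QCRecord]
    manifest: dict


def _random_topology(rng: np.random.Generator, L: int, chain: str
                     ) -> list[TopologySegment]:
    """Alternating side1 / H / side2 / H / side1 ... segments covering 1..L."""
    segments: list[TopologySegment] = []
    pos = 1
    side_cycle = ("1", "2")
    k = 0
    while pos <= L:
        side = side_cycle[k % 2]
        side_len = int(rng.integers(3, 12))
        end = min(pos + side_len - 1, L)
        segments.append(TopologySegment(chain=chain, beg=pos, end=end, code=side))
        pos = end + 1
        if pos > L:
            break
        helix_len = int(rng.integers(15, 26))
        end = min(pos + helix_len - 1, L)
        segments.append(TopologySegment(chain=chain, beg=pos, end=end, code="H"))
        pos = end + 1
        k += 1
    return segments


def _predicted_from_topology(
    rng: np.random.Generator,
    segments: list[TopologySegment],
    corruption_rate: float,
) -> PredictedTopology:
    label_map = {"1": "inside", "2": "outside", "H": "TM"}
    flip = {"inside": "outside", "outside": "inside"}
    pred = []
    for seg in segments:
        label = label_map[seg.code]
        if label != "TM" and rng.random() < corruption_rate:
            label = flip[label]
        pred.append((seg.beg, seg.end, label))
    return PredictedTopology(segments=tuple(pred))


def _write_matrix(path: Path, rng: np.random.Generator, seq: ProteinSequence,
                  contact_fraction: float, contact_mean: float) -> None:
    """FreeContact-style file: 'i aa_i j aa_j score' for every pair i < j."""
    L = seq.L
    with open(path, "w") as fh:
        for i in range(1, L + 1):
            for j in range(i + 1, L + 1):
                if contact_fraction > 0 and rng.random() < contact_fraction:
                    # spiked contact pair: uniform around the elevated mean
                    score = contact_mean + (rng.random() - 0.5) * 0.2
                else:
                    score = rng.random()
                fh.write(f"{i} {seq.residues[i - 1]} {j} {seq.residues[j - 1]} "
                         f"{score:.6f}\n")


def generate_fixtures(
    seed: int,
    L: int = 100,
    n_proteins: int = 3,
    contact_fraction: float = 0.05,
    contact_mean: float = 1.5,
    corruption_rate: float = 0.0,
    out_dir: Union[str, Path] = "fixtures",
) -> FixtureBundle:
    """Generate a complete, seeded fixture bundle under ``out_dir``.

    ``L`` is the length of each random protein (minimum 10),
    ``contact_fraction`` the share of pairs spiked to a higher mean score,
    and ``corruption_rate`` the per-segment probability that the predicted
    topology contradicts the structural annotation.
    """
    if L < 10:
        raise ValueError(f"sequence length must be >= 10, got {L}")
    if n_proteins < 1:
        raise ValueError(f"need at least one protein, got {n_proteins}")
    if not (0.0 <= corruption_rate <= 1.0):
        raise ValueError(f"corruption rate must be in [0, 1], got {corruption_rate}")
    if not (0.0 <= contact_fraction <= 1.0):
        raise ValueError(f"contact fraction must be in [0, 1], got {contact_fraction}")

    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sequences: list[ProteinSequence] = []
    matrix_paths: dict[str, Path] = {}
    topologies: dict[str, list[TopologySegment]] = {}
    predicted: dict[str, PredictedTopology] = {}
    qc_records: list[QCRecord] = []

    for p in range(n_proteins):
        ident = f"prot{p + 1:03d}"
        letters = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        seq = ProteinSequence(identifier=ident, residues=letters)
        sequences.append(seq)

        mpath = out_dir / f"{ident}.scores"
        _write_matrix(mpath, rng, seq, contact_fraction, contact_mean)
        matrix_paths[ident] = mpath

        segs = _random_topology(rng, L, chain=ident)
        topologies[ident] = segs
        predicted[ident] = _predicted_from_topology(rng, segs, corruption_rate)

        helix_lengths = tuple(len(s) for s in segs if s.code == "H")
        method = _METHODS[int(rng.integers(0, len(_METHODS)))]
        resolution = None if method == "NMR" else round(float(rng.uniform(1.2, 4.5)), 2)
        qc_records.append(QCRecord(
            identifier=ident, method=method, resolution=resolution,
            length=L, tm_helix_count=len(helix_lengths),
            tm_helix_lengths=helix_lengths,
        ))

    fasta_path = out_dir / "sequences.fasta"
    write_fasta(sequences, fasta_path)

    topology_xml_path = out_dir / "topology.xml"
    write_topology_xml(topologies, topology_xml_path)

    predicted_path = out_dir / "predicted_topology.tsv"
    with open(predicted_path, "w") as fh:
        fh.write("protein\tbeg\tend\tlabel\n")
        for ident, pt in predicted.items():
            for beg, end, label in pt.segments:
                fh.write(f"{ident}\t{beg}\t{end}\t{label}\n")

    qc_path = out_dir / "qc_metadata.tsv"
    with open(qc_path, "w") as fh:
        fh.write("identifier\tmethod\tresolution\tlength\ttm_helix_count\t"
                 "tm_helix_lengths\n")
        for rec in qc_records:
            res = "" if rec.resolution is None else f"{rec.resolution:.2f}"
            lengths = ",".join(str(h) for h in rec.tm_helix_lengths)
            fh.write(f"{rec.identifier}\t{rec.method}\t{res}\t{rec.length}\t"
                     f"{rec.tm_helix_count}\t{lengths}\n")

    manifest = {
        "seed": seed,
        "L": L,
        "n_proteins": n_proteins,
        "contact_fraction": contact_fraction,
        "contact_mean": contact_mean,
        "corruption_rate": corruption_rate,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return FixtureBundle(
        out_dir=out_dir, fasta_path=fasta_path, matrix_paths=matrix_paths,
        topology_xml_path=topology_xml_path, predicted_path=predicted_path,
        qc_path=qc_path, manifest_path=manifest_path, sequences=sequences,
        topologies=topologies, predicted=predicted, qc_records=qc_records,
        manifest=manifest,
    )


def read_predicted_topology(path: Union[str, Path]) -> dict[str, PredictedTopology]:
    """Read the 4-column predicted-topology table written by the generator."""
    per_protein: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            ident, beg, end, label = line.rstrip("\n").split("\t")
            per_protein.setdefault(ident, []).append((int(beg), int(end), label))
    return {ident: PredictedTopology(segments=tuple(segs))
            for ident, segs in per_protein.items()}


def read_qc_table(path: Union[str, Path]) -> list[QCRecord]:
    """Read the QC metadata table written by the generator."""
    records: list[QCRecord] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            ident, method, res, length, count, lengths = line.rstrip("\n").split("\t")
            records.append(QCRecord(
                identifier=ident,
                method=method or None,
                resolution=float(res) if res else None,
                length=int(length) if length else None,
                tm_helix_count=int(count) if count else None,
                tm_helix_lengths=tuple(int(h) for h in lengths.split(",") if h)
                if lengths else None,
            ))
    return records
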