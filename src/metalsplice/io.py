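"""Readers and writers for the pipeline's file formats.

Exons travel as FASTA with the flanking intron sequence in lowercase and
the exon core in uppercase, the description line carrying
``exon_id|gene|group``.  Everything else is plain TSV with a header row.
All round-trips are lossless for the fields the analyses consume.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from metalsplice.exons import CoordinatingResidue, ExonRecord
from metalsplice.hexamers import (
    CodonFrequencyProfile,
    HexamerScoreTable,
    HexamerSets,
)
from metalsplice.inclusion import InclusionRecord
from metalsplice.splice_signals import BranchpointCall
from metalsplice.disorder import AMINO_ACIDS, CodonUsage, DisorderScale


# -- exons ------------------------------------------------------------------


def write_exon_fasta(exons: Iterable[ExonRecord], path: str | Path) -> None:
    records = []
    for e in exons:
        seq = e.upstream_intron.lower() + e.seq.upper() + e.downstream_intron.lower()
        records.append(
            SeqRecord(Seq(seq), id=f"{e.exon_id}|{e.gene}|{e.group}", description="")
        )
    SeqIO.write(records, str(path), "fasta")


def read_exon_fasta(path: str | Path) -> list[ExonRecord]:
    exons = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"{path}: FASTA id {rec.id!r} is not exon_id|gene|group"
            )
        exon_id, gene, group = parts
        raw = str(rec.seq)
        first_upper = next((i for i, c in enumerate(raw) if c.isupper()), None)
        if first_upper is None:
            raise ValueError(f"{path}: record {exon_id} has no uppercase exon core")
        last_upper = max(i for i, c in enumerate(raw) if c.isupper())
        exons.append(
            ExonRecord(
                exon_id=exon_id,
                gene=gene,
                seq=raw[first_upper : last_upper + 1],
                upstream_intron=raw[:first_upper],
                downstream_intron=raw[last_upper + 1 :],
                group=group,
            )
        )
    return exons


def write_exon_tsv(exons: Iterable[ExonRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["exon_id", "gene", "group", "seq", "upstream_intron",
             "downstream_intron", "strand"]
        )
        for e in exons:
            w.writerow(
                [e.exon_id, e.gene, e.group, e.seq, e.upstream_intron,
                 e.downstream_intron, e.strand]
            )


def read_exon_tsv(path: str | Path) -> list[ExonRecord]:
    with open(path, newline="") as fh:
        return [
            ExonRecord(
                exon_id=row["exon_id"],
                gene=row["gene"],
                seq=row["seq"],
                upstream_intron=row.get("upstream_intron", ""),
                downstream_intron=row.get("downstream_intron", ""),
                group=row["group"],
                strand=row.get("strand", "+"),
            )
            for row in csv.DictReader(fh, delimiter="\t")
        ]


# -- residues ---------------------------------------------------------------

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def write_residue_tsv(
    residues: Iterable[CoordinatingResidue], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["protein_id", "residue_pos", "residue", "metal", "cmm_status",
             "homology_extended", "codon_start_in_exon", "near_junction"]
        )
        for r in residues:
            w.writerow(
                [r.protein_id, r.residue_pos, r.residue, r.metal, r.cmm_status,
                 str(r.homology_extended).lower(),
                 "" if r.codon_start_in_exon is None else r.codon_start_in_exon,
                 str(r.near_junction).lower()]
            )


def read_residue_tsv(path: str | Path) -> list[CoordinatingResidue]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            start = row.get("codon_start_in_exon", "")
            out.append(
                CoordinatingResidue(
                    protein_id=row["protein_id"],
                    residue_pos=int(row["residue_pos"]),
                    residue=row["residue"],
                    metal=row["metal"],
                    cmm_status=row.get("cmm_status", "unassessed"),
                    homology_extended=_BOOL[row.get("homology_extended", "false")],
                    codon_start_in_exon=int(start) if start else None,
                    near_junction=_BOOL[row.get("near_junction", "false")],
                )
            )
    return out


# -- hexamer tables ---------------------------------------------------------


def write_score_table(table: HexamerScoreTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["hexamer", "ese_score", "ess_score", "class"])
        for hexamer in sorted(table.entries):
            ese, ess, cls = table.entries[hexamer]
            w.writerow([hexamer, repr(ese), repr(ess), cls])


def write_hexamer_sets(sets: HexamerSets, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["hexamer", "set"])
        for h in sorted(sets.ese_set):
            w.writerow([h, "ESE"])
        for h in sorted(sets.ess_set):
            w.writerow([h, "ESS"])


def write_codon_profile(profile: CodonFrequencyProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


# -- inclusion --------------------------------------------------------------


def write_psi_tsv(records: Iterable[InclusionRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["exon_id", "tissue", "value", "source", "category"])
        for r in records:
            w.writerow([r.exon_id, r.tissue, repr(r.value), r.source, r.category])


def read_psi_tsv(path: str | Path) -> list[InclusionRecord]:
    with open(path, newline="") as fh:
        return [
            InclusionRecord(
                exon_id=row["exon_id"],
                tissue=row["tissue"],
                value=float(row["value"]),
                source=row.get("source", "psi_table"),
                category=row.get("category", "PSI"),
            )
            for row in csv.DictReader(fh, delimiter="\t")
        ]


def read_psi_wide(path: str | Path) -> list[InclusionRecord]:
    """VastDB-style wide table: exon_id column + one column per tissue."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    long = df.melt(id_vars="exon_id", var_name="tissue", value_name="value")
    long = long.dropna(subset=["value"])
    return [
        InclusionRecord(row.exon_id, row.tissue, float(row.value))
        for row in long.itertuples()
    ]


# -- branchpoints, scales, usage -------------------------------------------


def read_branchpoint_tsv(path: str | Path) -> dict[str, list[BranchpointCall]]:
    """Imported branchpoint predictions: intron_id, pos_relative_to_3ss,
    score, method."""
    out: dict[str, list[BranchpointCall]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row["intron_id"], []).append(
                BranchpointCall(
                    pos=int(row["pos_relative_to_3ss"]),
                    score=float(row["score"]),
                    method=row.get("method", "imported"),
                )
            )
    return out


def read_disorder_scale(path: str | Path, name: str | None = None) -> DisorderScale:
    values: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            values[row["aa"]] = float(row["value"])
    return DisorderScale(name or Path(path).stem, values)


def write_disorder_scale(scale: DisorderScale, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["aa", "value"])
        for aa in AMINO_ACIDS:
            w.writerow([aa, repr(scale.values[aa])])


def read_codon_usage(path: str | Path, context: str | None = None) -> CodonUsage:
    weights: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            weights[row["codon"]] = float(row["value"])
    return CodonUsage(context or Path(path).stem, weights)
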