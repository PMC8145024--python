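"""Readers and writers for the pipeline's plain-text interchange formats.

Matrices travel as TSV (probes x samples) with a parallel boolean mask TSV;
sequences as FASTA with ``>gene|region`` / ``>mirna_id`` headers; gene sets
as GMT; known-association miRNA lists as one id per line.  Floats are
written with a fixed "%.6g" format so reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hybridization import TranscriptRegion
from .preprocessing import ExpressionMatrix

FLOAT_FMT = "%.6g"

__all__ = [
    "write_table",
    "write_expression",
    "read_expression",
    "write_phenotypes",
    "read_phenotypes",
    "write_region_fasta",
    "read_region_fasta",
    "write_mirna_fasta",
    "read_mirna_fasta",
    "write_id_list",
    "read_id_list",
    "write_hits",
    "read_hits",
]


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_expression(matrix: ExpressionMatrix, values_path, mask_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="probe_id", float_format=FLOAT_FMT)
    matrix.present.astype(int).to_csv(mask_path, sep="\t", index_label="probe_id")


def read_expression(values_path, mask_path=None) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    present = None
    if mask_path is not None:
        present = pd.read_csv(mask_path, sep="\t", index_col="probe_id").astype(bool)
    return ExpressionMatrix(values, present)


def write_phenotypes(fetuses, path) -> None:
    from .phenotype import fetuses_to_frame

    write_table(fetuses_to_frame(fetuses), path)


def read_phenotypes(path):
    from .phenotype import frame_to_fetuses

    return frame_to_fetuses(pd.read_csv(path, sep="\t"))


def write_region_fasta(gene_regions: dict, path) -> None:
    records = []
    for gene in sorted(gene_regions):
        for region in gene_regions[gene]:
            records.append(
                SeqRecord(Seq(region.sequence), id=f"{gene}|{region.region}", description="")
            )
    SeqIO.write(records, str(path), "fasta")


def read_region_fasta(path) -> dict:
    regions: dict[str, list[TranscriptRegion]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _, region = rec.id.partition("|")
        if not region:
            raise ValueError(f"region FASTA header must be gene|region, got {rec.id!r}")
        regions.setdefault(gene, []).append(TranscriptRegion(gene, region, str(rec.seq)))
    return regions


def write_mirna_fasta(sequences: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=mid, description="") for mid, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_mirna_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_id_list(ids, path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


def read_id_list(path) -> list:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_hits(hits: pd.DataFrame, path) -> None:
    """Hit table with the field convention of exported coordinates: 1-based inclusive."""
    out = hits.copy()
    if len(out):
        out["start_1based"] = out["target_start"] + 1
        out["end_1based"] = out["target_end"]
    else:
        out["start_1based"] = pd.Series(dtype=int)
        out["end_1based"] = pd.Series(dtype=int)
    cols = [
        "mirna_id",
        "gene_id",
        "region",
        "start_1based",
        "end_1based",
        "mfe",
        "pairing",
        "mirna_direction",
        "gene_direction",
    ]
    write_table(out[cols], path)


def read_hits(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if len(table):
        table["target_start"] = table["start_1based"] - 1
        table["target_end"] = table["end_1based"]
    return table
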