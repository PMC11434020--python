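"""Plain-text readers and writers for the pipeline's three data layers.

* beta matrices: CSV with sample_id + label + one column per site, and a
  BED-like coordinate sidecar TSV (chrom, 1-based pos, site id);
* methylation-annotated sequences: FASTA plus a sidecar TSV of 1-based
  methylated-C positions;
* stool cohorts: a single CSV with class, stage, marker Ct columns and
  ACTB_Ct.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mdre import Fragment, MethylSequence
from .simulate import MethylationMatrix

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_methyl_sequence",
    "read_methyl_sequence",
    "write_fragments",
    "write_cohort",
    "read_cohort",
]


def write_matrix(matrix: MethylationMatrix, csv_path, coords_path) -> None:
    df = matrix.betas.copy()
    df.insert(0, "label", matrix.labels)
    df.insert(0, "sample_id", df.index)
    df.to_csv(csv_path, index=False)
    coords = matrix.coords.reset_index()
    coords.columns = ["site_id", "chrom", "pos"]
    coords[["chrom", "pos", "site_id"]].to_csv(coords_path, sep="\t", index=False)


def read_matrix(csv_path, coords_path) -> MethylationMatrix:
    df = pd.read_csv(csv_path).set_index("sample_id")
    labels = df.pop("label")
    coords = pd.read_csv(coords_path, sep="\t").set_index("site_id")[["chrom", "pos"]]
    return MethylationMatrix(df, labels, coords).validate()


def write_methyl_sequence(seq: MethylSequence, fasta_path, sidecar_path) -> None:
    SeqIO.write([SeqRecord(Seq(seq.sequence), id=seq.name, description="")], fasta_path, "fasta")
    pd.DataFrame({"name": seq.name, "position": sorted(seq.methylated_cpgs)}).to_csv(
        sidecar_path, sep="\t", index=False
    )


def read_methyl_sequence(fasta_path, sidecar_path) -> list[MethylSequence]:
    marks = pd.read_csv(sidecar_path, sep="\t")
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        pos = marks.loc[marks["name"] == rec.id, "position"].astype(int).tolist()
        out.append(MethylSequence(rec.id, str(rec.seq), frozenset(pos)))
    return out


def write_fragments(fragments: list[Fragment], parent_name: str, fasta_path) -> None:
    records = [
        SeqRecord(
            Seq(f.sequence),
            id=f"{parent_name}:{f.start}-{f.end}",
            description="cut_5prime" if f.five_prime_is_cut else "native_5prime",
        )
        for f in fragments
    ]
    SeqIO.write(records, fasta_path, "fasta")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    if "ACTB_Ct" not in df.columns:
        raise ValueError("cohort CSV lacks an ACTB_Ct column")
    return df
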