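"""Readers and writers for every on-disk artifact the pipeline touches.

Formats: FASTA (via Biopython), the TRANSFAC matrix dialect for PWMs, and
headered TSV for the dinucleotide property table, the motif catalog, the
TF/TFBS conservation table and labeled instance sets. Two fixtures ship with
the package: the 270-row TF/TFBS conservation table (printed in full in the
source study) and a default 38-attribute dinucleotide property table (a
synthetic stand-in; see :func:`load_default_property_table`).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import Instance, InstanceSet, SequenceRecord
from .features import PWM, DinucleotidePropertyTable, MotifCatalog

__all__ = [
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_transfac_pwm",
    "write_transfac_pwm",
    "read_property_table",
    "load_default_property_table",
    "read_motif_catalog",
    "write_motif_catalog",
    "read_conservation_table",
    "load_conservation_fixture",
    "read_instance_sets",
    "write_instance_sets",
]


class FormatError(ValueError):
    """A file did not conform to its declared format."""


def read_fasta(path: str | Path, moltype: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into validated records (order preserved, uppercased).

    DNA records must be unambiguous ACGT (lowercase folded); 'U' and IUPAC
    ambiguity codes are rejected because these records feed the scoring
    functions directly.
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"{path}: record #{len(records) + 1} has an empty header")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        try:
            records.append(SequenceRecord(rec.id, seq, moltype))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from None
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


def read_transfac_pwm(path: str | Path, background: np.ndarray | None = None) -> PWM:
    """Read a TRANSFAC-dialect matrix: a ``P0 A C G T`` header then numbered
    count rows. Counts are column-order A C G T and are normalized per row;
    matrices already expressed as frequencies (rows summing to ~1) pass
    through unchanged by that normalization.
    """
    rows: list[list[float]] = []
    name = ""
    in_matrix = False
    with open(path) as handle:
        for line in handle:
            parts = line.split()
            if not parts:
                continue
            tag = parts[0].upper()
            if tag in ("P0", "PO"):
                in_matrix = True
                continue
            if tag in ("NA", "ID", "AC"):
                if len(parts) > 1 and not name:
                    name = parts[1]
                continue
            if in_matrix and tag[0].isdigit():
                try:
                    counts = [float(x) for x in parts[1:5]]
                except (ValueError, IndexError):
                    raise FormatError(f"{path}: unreadable matrix row {parts[0]}") from None
                if len(counts) < 4:
                    raise FormatError(f"{path}: matrix row {parts[0]} has fewer than 4 counts")
                if sum(counts) <= 0:
                    raise FormatError(
                        f"{path}: matrix row {parts[0]} does not sum to a positive total"
                    )
                rows.append(counts)
            elif tag == "XX" and rows:
                break
    if not rows:
        raise FormatError(f"{path}: no matrix rows found (missing P0 header?)")
    kwargs = {} if background is None else {"background": background}
    return PWM(np.array(rows), name=name, **kwargs)


def write_transfac_pwm(pwm: PWM, path: str | Path, counts_scale: int = 100) -> None:
    with open(path, "w") as handle:
        if pwm.name:
            handle.write(f"NA {pwm.name}\n")
        handle.write("P0 A C G T\n")
        for j, row in enumerate(pwm.freqs, start=1):
            vals = " ".join(f"{v * counts_scale:.4f}" for v in row)
            handle.write(f"{j:02d} {vals}\n")
        handle.write("XX\n")


def read_property_table(path: str | Path) -> DinucleotidePropertyTable:
    """Read a dinucleotide property TSV: attribute name column then one column
    per dinucleotide (all 16 must be present)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    first = df.columns[0]
    dinucs = DinucleotidePropertyTable.DINUCS
    missing = [d for d in dinucs if d not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing dinucleotide column(s) {missing}")
    attributes = df[first].tolist()
    if len(set(attributes)) != len(attributes):
        raise FormatError(f"{path}: duplicate attribute name")
    values = df[dinucs].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError(f"{path}: non-numeric or missing property value")
    return DinucleotidePropertyTable(attributes, values)


def load_default_property_table() -> DinucleotidePropertyTable:
    """The bundled default property table (38 attributes x 16 dinucleotides).

    This table is a synthetic stand-in for a curated compendium of
    conformational and physicochemical dinucleotide scales: three rows are the
    unified nearest-neighbor thermodynamic parameters (duplex free energy,
    enthalpy, entropy; SantaLucia 1998), the remaining 35 are synthetic scales
    frozen from a seeded draw with literature-like ranges. Downstream code is
    agnostic to the values; only the table shape and attribute identity
    matter.
    """
    ref = resources.files("tfbslens.data").joinpath(
        "dinucleotide_properties_synthetic.tsv"
    )
    with resources.as_file(ref) as p:
        return read_property_table(p)


def read_motif_catalog(path: str | Path, similarity_threshold: float = 0.95) -> MotifCatalog:
    """Read a conserved-motif TSV with columns ``consensus`` and ``score``."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return MotifCatalog([], similarity_threshold)
    if not {"consensus", "score"} <= set(df.columns):
        raise FormatError(f"{path}: motif catalog needs 'consensus' and 'score' columns")
    try:
        motifs = [
            (str(row.consensus).upper(), float(row.score)) for row in df.itertuples()
        ]
        return MotifCatalog(motifs, similarity_threshold)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_motif_catalog(catalog: MotifCatalog, path: str | Path) -> None:
    pd.DataFrame(catalog.motifs, columns=["consensus", "score"]).to_csv(
        path, sep="\t", index=False
    )


def read_conservation_table(path: str | Path) -> pd.DataFrame:
    """Read a TF/TFBS conservation TSV (tf_id, tf_score, tfbs_score).

    tf_id must be unique; scores must be numeric with no gaps; tf_score lies
    in [0, 1] and tfbs_score is non-negative.
    """
    df = pd.read_csv(path, sep="\t", dtype={"tf_id": str})
    needed = {"tf_id", "tf_score", "tfbs_score"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: conservation table needs columns {sorted(needed)}")
    for col in ("tf_score", "tfbs_score"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "tf_id"].iloc[0]
            raise FormatError(f"{path}: non-numeric {col} for TF {bad!r}")
        df[col] = vals
    if df["tf_id"].duplicated().any():
        dup = df.loc[df["tf_id"].duplicated(), "tf_id"].iloc[0]
        raise FormatError(f"{path}: duplicate tf_id {dup!r}")
    if ((df["tf_score"] < 0) | (df["tf_score"] > 1)).any():
        raise FormatError(f"{path}: tf_score outside [0, 1]")
    if (df["tfbs_score"] < 0).any():
        raise FormatError(f"{path}: negative tfbs_score")
    return df.reset_index(drop=True)


def load_conservation_fixture() -> pd.DataFrame:
    """The packaged 270-TF conservation table.

    Per-TF ortholog-based conservation scores paired with the mean evolution
    feature of the TF's binding sites, as published for 270 mammalian TFs.
    """
    ref = resources.files("tfbslens.data").joinpath("tf_tfbs_conservation.tsv")
    with resources.as_file(ref) as p:
        return read_conservation_table(p)


def read_instance_sets(path: str | Path) -> list[InstanceSet]:
    """Read labeled instance sets from TSV (set_id, instance_id, label, sequence)."""
    df = pd.read_csv(path, sep="\t", dtype={"set_id": str, "instance_id": str})
    needed = {"set_id", "instance_id", "label", "sequence"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: instance table needs columns {sorted(needed)}")
    sets = []
    for set_id, group in df.groupby("set_id", sort=False):
        try:
            instances = [
                Instance(row.instance_id, str(row.sequence).upper(), int(row.label))
                for row in group.itertuples()
            ]
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from None
        sets.append(InstanceSet(set_id, instances))
    return sets


def write_instance_sets(sets: list[InstanceSet], path: str | Path) -> None:
    rows = [
        (s.set_id, inst.id, inst.label, inst.sequence)
        for s in sets
        for inst in s.instances
    ]
    pd.DataFrame(rows, columns=["set_id", "instance_id", "label", "sequence"]).to_csv(
        path, sep="\t", index=False
    )
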