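"""Readers/writers for the external formats the pipeline touches.

All genomic coordinates are 0-based, half-open ``[start, end)`` throughout
the package; conversion to 1-based inclusive happens only at the GFF3
boundary.  DNA may contain ``N`` (excluded from GC computations); protein
sequences use the 20 standard residues plus ``X``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import dendropy
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

Lifestyle = Literal["temperate", "virulent", "unknown"]
LIFESTYLES = ("temperate", "virulent", "unknown")

#: dendropy trees are the package-wide phylogeny container.
PhyloTree = dendropy.Tree


def gc_fraction(seq: str) -> float:
    """GC fraction of a DNA string, ignoring N in numerator and denominator."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


@dataclass
class GenomeRecord:
    """One phage genome: sequence plus survey metadata.

    ``cluster_label`` follows the phagesDB convention (phages sharing a
    large gene fraction with at least one other member; isolated genomes
    are "singleton").
    """

    genome_id: str
    sequence: str
    name: str = ""
    host_genus: str | None = None
    cluster_label: str | None = None
    lifestyle: str = "unknown"

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.genome_id
        if self.lifestyle not in LIFESTYLES:
            raise ValueError(f"invalid lifestyle {self.lifestyle!r}")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        return gc_fraction(self.sequence)


@dataclass
class ProteinRecord:
    """A protein sequence with its source compartment (phage/bacteria/plasmid)."""

    protein_id: str
    sequence: str
    source_group: str = "phage"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.rstrip("*")
        if not self.sequence:
            raise ValueError(f"empty protein sequence for {self.protein_id!r}")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"non-amino-acid characters {sorted(bad)} in {self.protein_id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a genome."""

    genome_id: str
    start: int
    end: int
    strand: str = "both"  # {+, -, both}

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "both"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.genome_id == other.genome_id
            and self.start < other.end
            and other.start < self.end
        )


def read_fasta(path: str | Path, alphabet: str = "dna") -> list:
    """Read a FASTA file into GenomeRecords (dna) or ProteinRecords (protein).

    Sequences are uppercased; for DNA, ``U`` is mapped to ``T``.  Record ids
    are the first whitespace-delimited token of the header.  Duplicate ids
    and out-of-alphabet characters (other than N for DNA / X for protein)
    raise ``ValueError``.
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"alphabet must be 'dna' or 'protein', got {alphabet!r}")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet == "dna":
            seq = seq.replace("U", "T")
            _check_alphabet(seq, DNA_ALPHABET, rec.id)
            records.append(
                GenomeRecord(genome_id=rec.id, sequence=seq, name=rec.description)
            )
        else:
            stripped = seq.rstrip("*")
            _check_alphabet(stripped, PROTEIN_ALPHABET, rec.id)
            records.append(ProteinRecord(protein_id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def _check_alphabet(seq: str, alphabet: set, rec_id: str) -> None:
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(
                f"record {rec_id!r}: invalid character {ch!r} at position {pos}"
            )


def write_fasta(records: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid = getattr(rec, "genome_id", None) or getattr(rec, "protein_id")
            fh.write(f">{rid}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a TSV of genome metadata.

    Requires a ``genome_id`` column; ``host_genus``, ``cluster`` and
    ``lifestyle`` are optional.  Lifestyle values outside
    {temperate, virulent} are mapped to "unknown" with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "genome_id" not in df.columns:
        raise ValueError(f"metadata {path} lacks required column 'genome_id'")
    for col in ("host_genus", "cluster", "lifestyle"):
        if col not in df.columns:
            df[col] = None
    bad = df["lifestyle"].notna() & ~df["lifestyle"].isin(["temperate", "virulent"])
    if bad.any():
        logger.warning(
            "mapping %d unrecognized lifestyle values to 'unknown': %s",
            bad.sum(),
            sorted(df.loc[bad, "lifestyle"].unique()),
        )
    df.loc[bad, "lifestyle"] = "unknown"
    df["lifestyle"] = df["lifestyle"].fillna("unknown")
    return df[["genome_id", "host_genus", "cluster", "lifestyle"]
              + [c for c in df.columns
                 if c not in ("genome_id", "host_genus", "cluster", "lifestyle")]]


def apply_metadata(genomes: list, metadata: pd.DataFrame) -> None:
    """Fill host_genus/cluster_label/lifestyle of GenomeRecords in place."""
    meta = metadata.set_index("genome_id")
    for g in genomes:
        if g.genome_id in meta.index:
            row = meta.loc[g.genome_id]
            g.host_genus = row.get("host_genus") or g.host_genus
            g.cluster_label = row.get("cluster") or g.cluster_label
            g.lifestyle = row.get("lifestyle") or "unknown"


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Serialize a tree as newick with branch lengths at 6 significant digits.

    Every leaf must carry a taxon label; the output round-trips through
    :func:`read_newick` with identical topology and branch lengths (1e-6).
    """
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree has an unlabeled leaf")
    s = tree.as_string(
        schema="newick",
        real_value_format_specifier=".6g",
        suppress_rooting=True,
    )
    Path(path).write_text(s)


def read_newick(path: str | Path,
                taxon_namespace: dendropy.TaxonNamespace | None = None) -> PhyloTree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", taxon_namespace=taxon_namespace
    )


def write_gff3(rows: pd.DataFrame, path: str | Path, region_id: str,
               region_length: int) -> None:
    """Write locus annotation rows (0-based half-open) as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {region_id} 1 {region_length}\n")
        for _, r in rows.iterrows():
            attrs = f"ID={r['gene_id']};product={r['label']}"
            fh.write(
                "\t".join(
                    [
                        region_id, "phagetf", "CDS",
                        str(int(r["start"]) + 1), str(int(r["end"])),
                        ".", r["strand"], "0", attrs,
                    ]
                )
                + "\n"
            )


def write_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """Write a TSV with header row, optionally preceded by '#' comment lines."""
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
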