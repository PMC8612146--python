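"""Post-processing of conserved-domain hit tables into a TF-domain matrix.

A conserved-domain scan (e.g. RPS-BLAST against CDD) reports the same
biological domain several times under different source databases (Pfam,
COG, Smart, TIGR) at overlapping coordinates.  This module filters hits
to a transcription-factor catalog, collapses cross-database duplicates
into per-locus records, builds the genomes x unique-TF-domain count
matrix with a prevalence floor, and computes domain co-occurrence
correlations.

Hit tables are plain DataFrames with columns
``genome_id, domain_id, source_db, start, end, strand, evalue``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HIT_COLUMNS = ["genome_id", "domain_id", "source_db", "start", "end",
               "strand", "evalue"]

#: domain-id -> unique TF family, covering the cross-database aliases the
#: synthetic generator emits plus a few common phage TF families; user
#: catalogs (e.g. curated from a real screen) can replace it everywhere.
DEFAULT_TF_CATALOG = {
    "pfam02467": "WhiB", "COG1318": "WhiB", "SM_WhiB": "WhiB",
    "TIGR03557": "WhiB",
    "pfam11774": "Lsr2", "COG4677": "Lsr2", "SM_Lsr2": "Lsr2",
    "TIGR_Lsr2": "Lsr2",
    "pfam13411": "MerR", "COG0789": "MerR",
    "pfam01381": "Cro/CI", "COG1396": "Cro/CI",
    "pfam12844": "HTH_19", "pfam01047": "MarR", "pfam00440": "TetR",
    "pfam01022": "ArsR", "pfam00392": "GntR", "pfam04967": "HTH_10",
    "pfam01402": "RHH_1", "pfam01527": "HTH_Tnp_1", "pfam05043": "Mga",
}


@dataclass
class TFDomainMatrix:
    """Genomes x collapsed-TF-family count matrix with prevalence fractions."""

    counts: pd.DataFrame  # index genome_id, columns family labels, int counts
    prevalence: pd.Series  # family -> fraction of genomes with >= 1 locus

    @property
    def genomes(self) -> list:
        return list(self.counts.index)

    @property
    def domains(self) -> list:
        return list(self.counts.columns)


def read_hit_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a domain-hit TSV; ``column_map`` renames foreign headers
    (e.g. an RPS-BLAST outfmt-6 export) onto the canonical columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table lacks columns {sorted(missing)}")
    return df[HIT_COLUMNS]


def filter_hits(hits: pd.DataFrame, tf_catalog: dict | set,
                evalue_max: float = 1e-3) -> pd.DataFrame:
    """Keep hits whose domain id is in the TF catalog at E <= evalue_max.

    Input row order is preserved.  The default screening threshold is
    the conserved-domain scan's E-value cutoff of 0.001.
    """
    if not tf_catalog:
        raise ValueError("TF catalog is empty")
    ids = set(tf_catalog)
    keep = hits["domain_id"].isin(ids) & (hits["evalue"] <= evalue_max)
    return hits.loc[keep].reset_index(drop=True)


def _overlap_ge(s1, e1, s2, e2, min_frac: float) -> bool:
    ov = min(e1, e2) - max(s1, s2)
    shorter = min(e1 - s1, e2 - s2)
    return shorter > 0 and ov / shorter >= min_frac


def collapse_overlapping(hits: pd.DataFrame, tf_catalog: dict,
                         min_overlap_fraction: float = 0.5) -> pd.DataFrame:
    """Group per-genome hits into loci by single-linkage coordinate overlap.

    Two hits join the same locus when their intervals overlap by at least
    ``min_overlap_fraction`` of the shorter one (directly or through a
    chain).  Each locus becomes one record labeled with the TF family of
    its lowest-E-value member.
    """
    if not 0.0 < min_overlap_fraction <= 1.0:
        raise ValueError("min_overlap_fraction must lie in (0, 1]")
    out = []
    for gid, sub in hits.groupby("genome_id", sort=True):
        sub = sub.sort_values(["start", "end"], kind="mergesort").reset_index(drop=True)
        n = len(sub)
        group = list(range(n))  # union-find over hit rows

        def find(i):
            while group[i] != i:
                group[i] = group[group[i]]
                i = group[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if _overlap_ge(sub.start[i], sub.end[i],
                               sub.start[j], sub.end[j], min_overlap_fraction):
                    group[find(j)] = find(i)
        members: dict[int, list[int]] = {}
        for i in range(n):
            members.setdefault(find(i), []).append(i)
        for rows in members.values():
            block = sub.iloc[rows]
            best = block.loc[block["evalue"].idxmin()]
            out.append(
                {
                    "genome_id": gid,
                    "family": tf_catalog.get(best["domain_id"], best["domain_id"]),
                    "start": int(block["start"].min()),
                    "end": int(block["end"].max()),
                    "n_hits": len(block),
                    "best_evalue": float(block["evalue"].min()),
                    "source_dbs": ",".join(sorted(block["source_db"].unique())),
                }
            )
    columns = ["genome_id", "family", "start", "end", "n_hits",
               "best_evalue", "source_dbs"]
    return (
        pd.DataFrame(out, columns=columns)
        .sort_values(["genome_id", "start"], kind="mergesort")
        .reset_index(drop=True)
    )


def build_matrix(collapsed: pd.DataFrame, prevalence_min: int = 10,
                 genome_ids: list | None = None) -> TFDomainMatrix:
    """Count collapsed loci per genome and family; drop rare families.

    Families present in fewer than ``prevalence_min`` genomes are dropped
    (>=, i.e. a family in exactly ``prevalence_min`` genomes is kept).
    ``genome_ids`` fixes the full genome universe so genomes without any
    locus appear as all-zero rows and prevalence denominators are right.
    """
    if genome_ids is None:
        genome_ids = sorted(collapsed["genome_id"].unique())
    counts = (
        collapsed.groupby(["genome_id", "family"]).size().unstack(fill_value=0)
        .reindex(index=genome_ids, fill_value=0)
    )
    counts.columns.name = None
    counts.index.name = "genome_id"
    genomes_with = (counts > 0).sum(axis=0)
    keep = genomes_with[genomes_with >= prevalence_min].index
    counts = counts[sorted(keep)]
    prevalence = (counts > 0).sum(axis=0) / len(genome_ids)
    return TFDomainMatrix(counts=counts.astype(int), prevalence=prevalence)


def cooccurrence(matrix: TFDomainMatrix) -> pd.DataFrame:
    """Pearson correlation between domain count columns.

    Zero-variance columns yield NaN rows/columns (not 0); the diagonal of
    informative columns is 1.
    """
    if matrix.counts.shape[1] < 2:
        raise ValueError("co-occurrence needs at least 2 domain columns")
    if matrix.counts.shape[0] < 3:
        raise ValueError("co-occurrence needs at least 3 genomes")
    return matrix.counts.astype(float).corr(method="pearson")
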