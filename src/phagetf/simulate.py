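"""Synthetic actinobacteriophage genome collections with ground truth.

The generator emulates the statistical structure the survey pipeline
relies on: cluster-structured genome relatedness (independent random
ancestors per cluster, star-shaped descent within a cluster),
per-cluster background GC, implanted regulator ORFs (WhiB-like /
Lsr2-like) at controlled amino-acid divergence with 0-2 copies per
genome, AT-rich dips upstream of Lsr2-like implants, direct terminal
repeats (DTR) that duplicate a gene copy at both genome ends, and
lifestyle labels whose temperate odds are shifted for implant carriers.

Everything is deterministic given ``SimulationConfig.seed`` and the
ground truth (implant coordinates, divergences, labels, cluster tree) is
returned alongside the genomes for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io_formats import GenomeRecord, GenomicInterval, PhyloTree
from .libraries import mutate_protein, seed_protein

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_HOST_GENERA = [
    "Mycobacterium", "Gordonia", "Streptomyces", "Arthrobacter",
    "Microbacterium", "Corynebacterium", "Rhodococcus", "Propionibacterium",
]
#: margin (bp) kept between an implant and the genome ends / other features,
#: so that 5 kb context windows around implants are always well-defined
EDGE_MARGIN_BP = 6000

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_SYNONYMS: dict[str, list[str]] = {}
for codon, aa in _TABLE11.forward_table.items():
    _SYNONYMS.setdefault(aa, []).append(codon)
_STOP_CODONS = list(_TABLE11.stop_codons)


@dataclass(frozen=True)
class ImplantSpec:
    """One implant-plan entry: applied to every genome of a cluster."""

    cluster: int
    gene: str  # {"whiB-like", "lsr2-like"}
    copies: int  # 0..2
    aa_divergence: float  # [0, 0.75] vs the family seed protein


@dataclass(frozen=True)
class ATDip:
    depth: float  # GC reduction vs background, in [0, 0.4]
    width_bp: int


@dataclass
class SimulationConfig:
    n_clusters: int = 2
    genomes_per_cluster: int = 5
    genome_length_bp: int = 50_000
    cluster_gc: list = field(default_factory=lambda: [0.55, 0.62])
    within_cluster_divergence: float = 0.02
    implant_plan: list = field(default_factory=list)  # list[ImplantSpec]
    at_dip: ATDip = field(default_factory=lambda: ATDip(depth=0.15, width_bp=300))
    dtr_length_bp: int = 0
    lifestyle_odds: float = 1.0
    base_temperate_odds: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.genomes_per_cluster < 1:
            raise ValueError("need at least one cluster and one genome per cluster")
        if len(self.cluster_gc) != self.n_clusters:
            raise ValueError("cluster_gc must have one entry per cluster")
        if not all(0.0 < gc < 1.0 for gc in self.cluster_gc):
            raise ValueError("cluster_gc entries must lie in (0, 1)")
        if not 0.0 <= self.within_cluster_divergence <= 0.3:
            raise ValueError("within_cluster_divergence must lie in [0, 0.3]")
        if not 0.0 <= self.at_dip.depth <= 0.4:
            raise ValueError("at_dip depth must lie in [0, 0.4]")
        if self.dtr_length_bp < 0:
            raise ValueError("dtr_length_bp must be >= 0")
        if self.dtr_length_bp >= self.genome_length_bp // 2:
            raise ValueError("dtr_length_bp must be < genome_length/2")
        if self.lifestyle_odds < 0:
            raise ValueError("lifestyle_odds must be >= 0")
        plan = []
        for entry in self.implant_plan:
            if not isinstance(entry, ImplantSpec):
                entry = ImplantSpec(*entry)
            if entry.copies not in (0, 1, 2):
                raise ValueError("implant copies must be 0, 1 or 2")
            if not 0.0 <= entry.aa_divergence <= 0.75:
                raise ValueError("aa_divergence must lie in [0, 0.75]")
            if not 0 <= entry.cluster < self.n_clusters:
                raise ValueError(f"implant cluster {entry.cluster} out of range")
            plan.append(entry)
        self.implant_plan = plan

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if "at_dip" in raw:
            raw["at_dip"] = ATDip(**raw["at_dip"])
        if "implant_plan" in raw:
            raw["implant_plan"] = [ImplantSpec(**e) for e in raw["implant_plan"]]
        return cls(**raw)


@dataclass
class Implant:
    gene: str
    interval: GenomicInterval
    strand: str
    aa_divergence: float
    copy_index: int
    in_dtr: bool
    protein: str
    dip_interval: GenomicInterval | None = None


@dataclass
class GenomeTruth:
    genome_id: str
    cluster: int
    lifestyle: str
    implants: list


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every simulated collection."""

    genomes: dict  # genome_id -> GenomeTruth
    cluster_tree: PhyloTree

    def implant_count(self, genome_id: str) -> int:
        return len(self.genomes[genome_id].implants)

    def carriers(self) -> set:
        return {g for g, t in self.genomes.items() if t.implants}

    def to_json(self, path: str | Path) -> None:
        payload = {
            gid: {
                "cluster": t.cluster,
                "lifestyle": t.lifestyle,
                "implants": [
                    {
                        "gene": im.gene,
                        "start": im.interval.start,
                        "end": im.interval.end,
                        "strand": im.strand,
                        "aa_divergence": im.aa_divergence,
                        "copy_index": im.copy_index,
                        "in_dtr": im.in_dtr,
                        "protein": im.protein,
                    }
                    for im in t.implants
                ],
            }
            for gid, t in self.genomes.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def back_translate(protein: str, gc: float, rng: np.random.Generator) -> str:
    """Back-translate a protein with codon choice biased by background GC.

    Each synonymous codon is weighted by the product of per-base
    probabilities under the background composition (G/C at gc/2 each, A/T
    at (1-gc)/2 each); a stop codon drawn the same way is appended.
    """

    def pick(codons: list[str]) -> str:
        w = np.array(
            [
                np.prod([gc / 2 if b in "GC" else (1 - gc) / 2 for b in c])
                for c in codons
            ]
        )
        return codons[rng.choice(len(codons), p=w / w.sum())]

    parts = [pick(_SYNONYMS[aa]) for aa in protein]
    parts.append(pick(_STOP_CODONS))
    return "".join(parts)


def _random_codes(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _mutate_codes(codes: np.ndarray, p_sub: float,
                  rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(len(codes)) < p_sub
    shifts = rng.integers(1, 4, size=int(mask.sum()))
    out[mask] = (out[mask] + shifts) % 4
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def simulate_collection(
    config: SimulationConfig,
) -> tuple[list, pd.DataFrame, SyntheticTruth]:
    """Simulate a genome collection; returns (genomes, metadata, truth)."""
    rng = np.random.default_rng(config.seed)
    L = config.genome_length_bp
    dtr = config.dtr_length_bp
    genomes: list[GenomeRecord] = []
    truth_genomes: dict[str, GenomeTruth] = {}

    plan_by_cluster: dict[int, list[ImplantSpec]] = {}
    for entry in config.implant_plan:
        plan_by_cluster.setdefault(entry.cluster, []).append(entry)

    for ci in range(config.n_clusters):
        gc_bg = config.cluster_gc[ci]
        ancestor = _random_codes(L, gc_bg, rng)
        cluster_label = chr(ord("A") + ci % 26) + ("" if ci < 26 else str(ci // 26))
        genus = _HOST_GENERA[ci % len(_HOST_GENERA)]
        for gi in range(config.genomes_per_cluster):
            gid = f"sim{ci:02d}_{gi:02d}"
            seq = list(_codes_to_str(
                _mutate_codes(ancestor, config.within_cluster_divergence, rng)
            ))
            implants = _place_implants(
                seq, plan_by_cluster.get(ci, []), gc_bg, config, rng, gid
            )
            if dtr > 0:
                implants = _apply_dtr(seq, implants, dtr, L, gid)
            carrier = bool(implants)
            odds = config.base_temperate_odds * (
                config.lifestyle_odds if carrier else 1.0
            )
            p_temp = odds / (1.0 + odds) if odds > 0 else 0.0
            lifestyle = "temperate" if rng.random() < p_temp else "virulent"
            genomes.append(
                GenomeRecord(
                    genome_id=gid,
                    sequence="".join(seq),
                    host_genus=genus,
                    cluster_label=cluster_label,
                    lifestyle=lifestyle,
                )
            )
            truth_genomes[gid] = GenomeTruth(
                genome_id=gid, cluster=ci, lifestyle=lifestyle, implants=implants
            )

    metadata = pd.DataFrame(
        {
            "genome_id": [g.genome_id for g in genomes],
            "host_genus": [g.host_genus for g in genomes],
            "cluster": [g.cluster_label for g in genomes],
            "lifestyle": [g.lifestyle for g in genomes],
        }
    )
    truth = SyntheticTruth(
        genomes=truth_genomes, cluster_tree=_cluster_tree(config, truth_genomes)
    )
    return genomes, metadata, truth


def _place_implants(seq, entries, gc_bg, config, rng, gid) -> list:
    """Write implant ORFs (and upstream AT dips) into ``seq`` in place."""
    L = len(seq)
    dtr = config.dtr_length_bp
    occupied: list[tuple[int, int]] = []
    implants: list[Implant] = []
    dtr_slot_used = False
    for entry in entries:
        seed = seed_protein(entry.gene)
        for copy_index in range(entry.copies):
            protein = mutate_protein(seed, entry.aa_divergence, rng)
            nt = back_translate(protein, gc_bg, rng)
            if len(nt) > L:
                raise ValueError("implant longer than genome")
            strand = "+" if rng.random() < 0.5 else "-"
            dip_w = config.at_dip.width_bp if entry.gene == "lsr2-like" else 0
            in_dtr = dtr > 0 and not dtr_slot_used
            start = _pick_position(len(nt), dip_w, L, dtr, in_dtr, occupied, rng)
            if in_dtr:
                dtr_slot_used = True
            end = start + len(nt)
            seq[start:end] = list(nt if strand == "+" else revcomp(nt))
            dip_iv = None
            if dip_w > 0 and config.at_dip.depth > 0:
                dip_gc = max(0.0, gc_bg - config.at_dip.depth)
                if strand == "+":
                    ds, de = start - dip_w, start
                else:
                    ds, de = end, end + dip_w
                seq[ds:de] = list(_codes_to_str(_random_codes(dip_w, dip_gc, rng)))
                dip_iv = GenomicInterval(gid, ds, de, strand)
                occupied.append((ds, de))
            occupied.append((start, end))
            implants.append(
                Implant(
                    gene=entry.gene,
                    interval=GenomicInterval(gid, start, end, strand),
                    strand=strand,
                    aa_divergence=entry.aa_divergence,
                    copy_index=copy_index,
                    in_dtr=in_dtr,
                    protein=protein,
                    dip_interval=dip_iv,
                )
            )
    return implants


def _pick_position(nt_len, dip_w, L, dtr, in_dtr, occupied, rng) -> int:
    """Uniform non-overlapping placement with the module's margin rules.

    The margin around an in-repeat implant exceeds the 500 bp gene pad so
    both repeat copies see identical extended-locus sequence.
    """
    pad = max(dip_w + 100, 600)
    if in_dtr:
        lo, hi = pad, dtr - nt_len - pad
        if hi <= lo:
            raise ValueError("dtr_length_bp too small for an in-repeat implant")
    else:
        lo = max(EDGE_MARGIN_BP, dtr + pad)
        hi = L - nt_len - EDGE_MARGIN_BP - (dtr + pad if dtr else 0)
        if hi <= lo:
            raise ValueError("genome too short for requested implants")
    for _ in range(200):
        start = int(rng.integers(lo, hi + 1))
        span = (start - pad, start + nt_len + pad)
        if all(span[1] <= s or e <= span[0] for s, e in occupied):
            return start
    raise ValueError("could not place implant without overlap")


def _apply_dtr(seq, implants, dtr, L, gid) -> list:
    """Copy the first ``dtr`` bases over the genome tail; mirror truth."""
    seq[L - dtr:] = seq[:dtr]
    mirrored = []
    for im in implants:
        if im.interval.end <= dtr:
            im.in_dtr = True
            shift = L - dtr
            mirrored.append(
                Implant(
                    gene=im.gene,
                    interval=GenomicInterval(
                        gid, im.interval.start + shift, im.interval.end + shift,
                        im.strand,
                    ),
                    strand=im.strand,
                    aa_divergence=im.aa_divergence,
                    copy_index=im.copy_index,
                    in_dtr=True,
                    protein=im.protein,
                    dip_interval=None if im.dip_interval is None else
                    GenomicInterval(
                        gid, im.dip_interval.start + shift,
                        im.dip_interval.end + shift, im.strand,
                    ),
                )
            )
    return implants + mirrored


def _cluster_tree(config, truth_genomes) -> PhyloTree:
    """Star of clusters; star of genomes within each cluster."""
    w = max(config.within_cluster_divergence, 1e-6)
    parts = []
    for ci in range(config.n_clusters):
        members = [g for g, t in truth_genomes.items() if t.cluster == ci]
        parts.append("(" + ",".join(f"{m}:{w}" for m in members) + "):0.5")
    newick = "(" + ",".join(parts) + ");"
    return dendropy.Tree.get(data=newick, schema="newick")


#: cross-database aliases for the implanted regulator families, as a
#: conserved-domain screen would report them
DOMAIN_ALIASES = {
    "whiB-like": {"Pfam": "pfam02467", "COG": "COG1318",
                  "Smart": "SM_WhiB", "TIGR": "TIGR03557"},
    "lsr2-like": {"Pfam": "pfam11774", "COG": "COG4677",
                  "Smart": "SM_Lsr2", "TIGR": "TIGR_Lsr2"},
}
SOURCE_DBS = ["Pfam", "COG", "Smart", "TIGR"]


def emit_domain_hits(
    truth: SyntheticTruth,
    redundancy: int = 1,
    decoy_rate: float = 0.0,
    genome_length_bp: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulated conserved-domain hit table for the implants in ``truth``.

    Each implant yields ``redundancy`` rows with distinct source databases
    and coordinates jittered by at most 10 bp; ``decoy_rate`` is the
    expected number of off-catalog decoy hits per genome.
    """
    if redundancy < 1 or redundancy > len(SOURCE_DBS):
        raise ValueError(f"redundancy must be in 1..{len(SOURCE_DBS)}")
    rng = np.random.default_rng(seed)
    rows = []
    for gid, t in truth.genomes.items():
        for im in t.implants:
            for db in SOURCE_DBS[:redundancy]:
                jitter_s = int(rng.integers(0, 11))
                jitter_e = int(rng.integers(0, 11))
                rows.append(
                    {
                        "genome_id": gid,
                        "domain_id": DOMAIN_ALIASES[im.gene][db],
                        "source_db": db,
                        "start": max(0, im.interval.start - jitter_s),
                        "end": im.interval.end + jitter_e,
                        "strand": im.strand,
                        "evalue": 10.0 ** -rng.uniform(6, 30),
                    }
                )
        for _ in range(rng.poisson(decoy_rate)):
            s = int(rng.integers(0, max(1, (genome_length_bp or 50_000) - 200)))
            rows.append(
                {
                    "genome_id": gid,
                    "domain_id": f"decoy{rng.integers(100):03d}",
                    "source_db": SOURCE_DBS[rng.integers(len(SOURCE_DBS))],
                    "start": s,
                    "end": s + int(rng.integers(100, 400)),
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "evalue": 10.0 ** -rng.uniform(4, 10),
                }
            )
    columns = ["genome_id", "domain_id", "source_db", "start", "end",
               "strand", "evalue"]
    return pd.DataFrame(rows, columns=columns)
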