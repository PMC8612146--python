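"""WhiB/Lsr2 homolog detection pipeline.

Stages, composed by :func:`run_detection`:

1. translated search: each protein query is aligned (Smith-Waterman,
   BLOSUM62, gaps 11/1) against all six reading frames of the genome;
   hits are kept at E <= 1e-5 (Karlin-Altschul statistics) and mapped
   back to genome coordinates.
2. merge: overlapping or bookended hit intervals are merged,
   strand-ignorant, into candidate loci.
3. extend: each locus is padded by 500 bp per side to recover complete
   gene sequences (a separate 5 kb pad defines the context locus used by
   the synteny module).
4. translate: all ORFs (start ATG/GTG/TTG to stop, translation table 11,
   >= 30 aa) within the extended locus, both strands.
5. reciprocal filter: each candidate ORF protein is aligned back against
   the query library; the locus passes if its best candidate reaches
   E <= 1e-5, and that best-scoring protein is retained for the locus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import alignment
from .io_formats import GenomeRecord, GenomicInterval, ProteinRecord
from .simulate import revcomp


@dataclass
class PipelineParams:
    evalue_max: float = 1e-5
    gene_pad_bp: int = 500
    context_pad_bp: int = 5000
    min_len_aa: int = 30


@dataclass
class SearchHit:
    query_id: str
    interval: GenomicInterval
    frame: int  # {-3..-1, +1..+3}
    raw_score: float
    bitscore: float
    evalue: float


@dataclass
class OrfCandidate:
    interval: GenomicInterval
    strand: str
    protein: str


@dataclass
class HomologLocus:
    locus_id: str
    genome_id: str
    merged_interval: GenomicInterval
    extended_interval: GenomicInterval
    context_interval: GenomicInterval
    orf_interval: GenomicInterval
    strand: str
    protein: str
    best_query_id: str
    best_identity: float
    best_evalue: float
    passed_reciprocal: bool


def six_frame_translations(seq: str) -> list:
    """(frame, protein) for frames +1..+3 and -1..-3; stops kept as '*'.

    Codons containing N translate to X.
    """
    frames = []
    rc = revcomp(seq)
    for f in range(3):
        fwd = str(Seq(seq[f:len(seq) - (len(seq) - f) % 3]).translate(table=11))
        rev = str(Seq(rc[f:len(rc) - (len(rc) - f) % 3]).translate(table=11))
        frames.append((f + 1, fwd))
        frames.append((-(f + 1), rev))
    return frames


def _frame_to_genome(frame: int, p_start: int, p_end: int, L: int) -> tuple[int, int, str]:
    """Map a protein-coordinate range in a reading frame to genome coords."""
    if frame > 0:
        off = frame - 1
        return off + 3 * p_start, off + 3 * p_end, "+"
    off = -frame - 1
    return L - (off + 3 * p_end), L - (off + 3 * p_start), "-"


def translated_search(
    genome: GenomeRecord,
    queries: list,
    evalue_max: float = 1e-5,
    max_hits_per_frame: int = 8,
) -> list:
    """Smith-Waterman search of protein queries against all six frames.

    The E-value search space is (query length) x (genome length in bp),
    as in a translated nucleotide search.  Scores are computed first via
    the traceback-free fast path; alignments are only materialized for
    frames that reach the E-value threshold.  Because Smith-Waterman
    reports a single optimal alignment, each significant hit's footprint
    is masked with X and the frame re-searched, so multiple gene copies
    in one reading frame are all found.
    """
    if not queries:
        raise ValueError("query library is empty")
    L = genome.length_bp
    hits: list[SearchHit] = []
    frames = six_frame_translations(genome.sequence)
    for query in queries:
        qseq = query.sequence
        for frame, prot in frames:
            target = prot
            for _ in range(max_hits_per_frame):
                if len(target) == 0:
                    break
                score = alignment.local_score(target, qseq)
                bitscore, evalue = alignment.karlin_altschul_evalue(
                    score, len(qseq), L
                )
                if evalue > evalue_max:
                    break
                aln = alignment.local_align(target, qseq)
                blocks = aln.aligned[0]
                p_start, p_end = int(blocks[0][0]), int(blocks[-1][1])
                g_start, g_end, strand = _frame_to_genome(
                    frame, p_start, p_end, L
                )
                hits.append(
                    SearchHit(
                        query_id=query.protein_id,
                        interval=GenomicInterval(
                            genome.genome_id, g_start, g_end, strand
                        ),
                        frame=frame,
                        raw_score=score,
                        bitscore=bitscore,
                        evalue=evalue,
                    )
                )
                target = (
                    target[:p_start] + "X" * (p_end - p_start) + target[p_end:]
                )
    return hits


def merge_loci(hits: list) -> list:
    """Merge overlapping or bookended hit intervals, ignoring strand.

    Follows the samtools-merge convention: [a, b) and [b, c) fuse.
    Output is sorted and pairwise disjoint.
    """
    if not hits:
        return []
    intervals = sorted(
        (h.interval for h in hits), key=lambda iv: (iv.start, iv.end)
    )
    genome_ids = {iv.genome_id for iv in intervals}
    if len(genome_ids) != 1:
        raise ValueError("merge_loci expects hits on a single genome")
    gid = genome_ids.pop()
    merged = []
    cur_s, cur_e = intervals[0].start, intervals[0].end
    for iv in intervals[1:]:
        if iv.start <= cur_e:  # overlap or bookended
            cur_e = max(cur_e, iv.end)
        else:
            merged.append(GenomicInterval(gid, cur_s, cur_e))
            cur_s, cur_e = iv.start, iv.end
    merged.append(GenomicInterval(gid, cur_s, cur_e))
    return merged


def extend_locus(interval: GenomicInterval, pad_bp: int, genome_length: int) -> GenomicInterval:
    """Pad an interval by ``pad_bp`` per side, clamped to [0, genome_length)."""
    if pad_bp < 0:
        raise ValueError("pad_bp must be >= 0")
    if interval.end > genome_length:
        raise ValueError("interval extends beyond the genome")
    return GenomicInterval(
        interval.genome_id,
        max(0, interval.start - pad_bp),
        min(genome_length, interval.end + pad_bp),
        interval.strand,
    )


_STARTS = ("ATG", "GTG", "TTG")
_STOPS = ("TAA", "TAG", "TGA")


def _orfs_one_strand(sub: str, min_len_aa: int):
    """(start, end, protein) of complete ORFs on the forward strand of sub.

    end includes the stop codon; alternative starts translate as M.
    Within a frame, an ORF opens at the first start codon after the
    previous stop (longest-ORF-per-stop convention).
    """
    n = len(sub)
    for f in range(3):
        pos = f
        orf_start = None
        while pos + 3 <= n:
            codon = sub[pos:pos + 3]
            if orf_start is None and codon in _STARTS:
                orf_start = pos
            if codon in _STOPS and orf_start is not None:
                aa_len = (pos - orf_start) // 3
                if aa_len >= min_len_aa:
                    body = sub[orf_start + 3:pos]
                    prot = "M" + str(Seq(body).translate(table=11))
                    yield orf_start, pos + 3, prot
                orf_start = None
            elif codon in _STOPS:
                orf_start = None
            pos += 3


def extract_orf_protein(
    genome: GenomeRecord, extended: GenomicInterval, min_len_aa: int = 30
) -> list:
    """All complete ORFs >= min_len_aa within the extended interval.

    Both strands, translation table 11; returned longest-first.
    """
    sub = genome.sequence[extended.start:extended.end]
    candidates = []
    for s, e, prot in _orfs_one_strand(sub, min_len_aa):
        candidates.append(
            OrfCandidate(
                GenomicInterval(genome.genome_id, extended.start + s,
                                extended.start + e, "+"),
                "+", prot,
            )
        )
    rc = revcomp(sub)
    m = len(sub)
    for s, e, prot in _orfs_one_strand(rc, min_len_aa):
        candidates.append(
            OrfCandidate(
                GenomicInterval(genome.genome_id, extended.start + m - e,
                                extended.start + m - s, "-"),
                "-", prot,
            )
        )
    candidates.sort(key=lambda c: (-len(c.protein), c.interval.start, c.strand))
    return candidates


def reciprocal_best_hit(
    protein: str, library: list, search_space: int | None = None
) -> tuple[str, float, float, float]:
    """Best library hit of a candidate protein.

    Returns (query_id, raw_score, identity, evalue); the E-value search
    space is len(protein) x total library residues, emulating a protein
    database search.  Ties break on raw score, then query id.
    """
    if not library:
        raise ValueError("reciprocal library is empty")
    n_db = search_space or sum(len(p.sequence) for p in library)
    best = None
    for rec in library:
        score = alignment.local_score(rec.sequence, protein)
        _, evalue = alignment.karlin_altschul_evalue(score, len(protein), n_db)
        key = (evalue, -score, rec.protein_id)
        if best is None or key < best[0]:
            best = (key, rec, score, evalue)
    _, rec, score, evalue = best
    aln = alignment.local_align(rec.sequence, protein)
    identity = alignment.alignment_identity(aln)
    return rec.protein_id, score, identity, evalue


def reciprocal_filter(
    candidates: list, library: list, evalue_max: float = 1e-5
) -> tuple[OrfCandidate | None, str, float, float, bool]:
    """Pick the best candidate ORF of a locus and decide if it passes.

    Every candidate is scored against the whole library; the locus keeps
    exactly one protein — the candidate with the lowest best-hit E-value
    (ties: higher raw score, then shorter start coordinate) — and passes
    iff that E-value is <= ``evalue_max``.
    """
    if not library:
        raise ValueError("reciprocal library is empty")
    best = None
    for cand in candidates:
        qid, score, ident, evalue = reciprocal_best_hit(cand.protein, library)
        key = (evalue, -score, cand.interval.start)
        if best is None or key < best[0]:
            best = (key, cand, qid, ident, evalue)
    if best is None:
        return None, "", 0.0, 1.0, False
    _, cand, qid, ident, evalue = best
    return cand, qid, ident, evalue, evalue <= evalue_max


def detect_in_genome(
    genome: GenomeRecord, queries: list, params: PipelineParams
) -> list:
    """Run the full pipeline on one genome; returns passing HomologLoci."""
    hits = translated_search(genome, queries, params.evalue_max)
    loci = []
    seen_orfs = set()
    for i, merged in enumerate(merge_loci(hits)):
        extended = extend_locus(merged, params.gene_pad_bp, genome.length_bp)
        context = extend_locus(merged, params.context_pad_bp, genome.length_bp)
        candidates = extract_orf_protein(genome, extended, params.min_len_aa)
        cand, qid, ident, evalue, passed = reciprocal_filter(
            candidates, queries, params.evalue_max
        )
        if cand is None or not passed:
            continue
        orf_key = (cand.interval.start, cand.interval.end, cand.strand)
        if orf_key in seen_orfs:
            continue
        seen_orfs.add(orf_key)
        loci.append(
            HomologLocus(
                locus_id=f"{genome.genome_id}_L{i:02d}",
                genome_id=genome.genome_id,
                merged_interval=merged,
                extended_interval=extended,
                context_interval=context,
                orf_interval=cand.interval,
                strand=cand.strand,
                protein=cand.protein,
                best_query_id=qid,
                best_identity=ident,
                best_evalue=evalue,
                passed_reciprocal=passed,
            )
        )
    return loci


def locus_table(loci: list) -> pd.DataFrame:
    rows = [
        {
            "locus_id": lc.locus_id,
            "genome_id": lc.genome_id,
            "merged_start": lc.merged_interval.start,
            "merged_end": lc.merged_interval.end,
            "extended_start": lc.extended_interval.start,
            "extended_end": lc.extended_interval.end,
            "orf_start": lc.orf_interval.start,
            "orf_end": lc.orf_interval.end,
            "strand": lc.strand,
            "best_query": lc.best_query_id,
            "identity": round(lc.best_identity, 6),
            "evalue": lc.best_evalue,
            "protein": lc.protein,
        }
        for lc in loci
    ]
    columns = ["locus_id", "genome_id", "merged_start", "merged_end",
               "extended_start", "extended_end", "orf_start", "orf_end",
               "strand", "best_query", "identity", "evalue", "protein"]
    df = pd.DataFrame(rows, columns=columns)
    counts = df.groupby("genome_id")["locus_id"].count()
    df["copies_in_genome"] = df["genome_id"].map(counts)
    return df


def run_detection(
    genomes: list, query_library: list, params: PipelineParams | None = None,
    metadata: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Detect homologs across a genome collection.

    Returns the locus table plus a summary with carrier counts, the
    copy-number histogram, and group-size-normalized carrier proportions
    per host genus and per cluster when metadata is given.
    """
    params = params or PipelineParams()
    all_loci: list[HomologLocus] = []
    for genome in genomes:
        all_loci.extend(detect_in_genome(genome, query_library, params))
    table = locus_table(all_loci)
    carriers = set(table["genome_id"]) if len(table) else set()
    summary: dict = {
        "n_genomes": len(genomes),
        "n_loci": int(len(table)),
        "n_carriers": len(carriers),
        "carrier_fraction": len(carriers) / len(genomes) if genomes else 0.0,
        "copy_number_histogram": (
            table.groupby("genome_id")["locus_id"].count().value_counts()
            .sort_index().to_dict()
        ),
    }
    if metadata is not None:
        for col, key in (("host_genus", "by_host_genus"), ("cluster", "by_cluster")):
            meta = metadata.set_index("genome_id")[col]
            groups: dict = {}
            for genome in genomes:
                label = meta.get(genome.genome_id)
                if label is None or label != label:
                    continue
                g = groups.setdefault(str(label), {"n": 0, "carriers": 0})
                g["n"] += 1
                g["carriers"] += genome.genome_id in carriers
            for g in groups.values():
                g["normalized_pct"] = round(100.0 * g["carriers"] / g["n"], 2)
            summary[key] = groups
    return table, summary
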