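"""Synthetic protein query and annotation libraries.

The detection pipeline needs a WhiB-family and an Lsr2-family query
library and the context annotator needs a library of common phage
neighborhood proteins (integrase, excisionase, ...).  The sequences here
are synthetic stand-ins generated deterministically from fixed seeds:
they have realistic lengths and composition but are random proteins, not
curated biological sequences.  Real user-supplied FASTA libraries can be
passed to every consumer in their place.
"""

from __future__ import annotations

import numpy as np

from .io_formats import ProteinRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# mildly non-uniform composition (hydrophobics and A/G/L common, W/C rare)
_AA_WEIGHTS = np.array(
    [8.3, 1.4, 5.4, 6.8, 3.9, 7.1, 2.2, 6.0, 5.8, 9.7,
     2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9]
)
_AA_WEIGHTS = _AA_WEIGHTS / _AA_WEIGHTS.sum()


def random_protein(length: int, rng: np.random.Generator) -> str:
    """A random protein of the given length, starting with M."""
    body = rng.choice(list(AMINO_ACIDS), size=length - 1, p=_AA_WEIGHTS)
    return "M" + "".join(body)


def mutate_protein(seq: str, aa_divergence: float,
                   rng: np.random.Generator) -> str:
    """Substitute an exact count of positions to hit a target divergence.

    Exactly ``round(aa_divergence * len(seq))`` positions (never the
    initial M, which anchors the start codon) are replaced by a residue
    different from the original, so the realized p-distance to ``seq``
    equals the target up to rounding.
    """
    if not 0.0 <= aa_divergence <= 1.0:
        raise ValueError("aa_divergence must be in [0, 1]")
    n_mut = round(aa_divergence * len(seq))
    n_mut = min(n_mut, len(seq) - 1)
    positions = rng.choice(np.arange(1, len(seq)), size=n_mut, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def protein_family(seed_protein: str, n: int, divergence: float,
                   rng: np.random.Generator, prefix: str = "fam",
                   source_group: str = "phage") -> list[ProteinRecord]:
    """``n`` relatives of a seed protein at a given divergence from it."""
    return [
        ProteinRecord(
            protein_id=f"{prefix}_{i}",
            sequence=mutate_protein(seed_protein, divergence, rng),
            source_group=source_group,
        )
        for i in range(n)
    ]


def _family_library(tag: str, length: int, n: int, seed: int,
                    divergence: float = 0.35) -> list[ProteinRecord]:
    rng = np.random.default_rng(seed)
    seed_protein = random_protein(length, rng)
    members = [ProteinRecord(protein_id=f"{tag}_seed", sequence=seed_protein)]
    members += protein_family(seed_protein, n - 1, divergence, rng, prefix=tag)
    return members


def whib_library(n: int = 4) -> list[ProteinRecord]:
    """Synthetic WhiB-like query library (~100 aa members).

    WhiB-family regulators are small actinobacterial iron-sulfur-cluster
    transcription factors of roughly 80-120 residues; the stand-ins here
    only mimic that length scale.
    """
    return _family_library("whiB", length=100, n=n, seed=20467)


def lsr2_library(n: int = 4) -> list[ProteinRecord]:
    """Synthetic Lsr2-like query library (~115 aa members).

    Lsr2 is an actinobacterial nucleoid-associated xenogeneic silencer of
    roughly 110 residues.
    """
    return _family_library("lsr2", length=115, n=n, seed=11774)


#: neighborhood-annotation labels and synthetic protein lengths
ANNOTATION_DOMAINS = {
    "Phage_integrase": 240,
    "HTH_17_excisionase": 70,
    "HTH_3_cro": 60,
    "ParA": 200,
    "ParB": 180,
    "Glutaredoxin": 85,
    "Primase": 230,
    "Helicase": 260,
    "DNA_polymerase": 280,
    "Ku": 220,
    "RNase_T": 180,
    "SSB": 110,
}


def annotation_library() -> list[ProteinRecord]:
    """Synthetic stand-in library for neighborhood gene annotation.

    One deterministic random protein per common phage-neighborhood domain
    label; used to annotate ORFs in extended loci in place of external
    databases.
    """
    records = []
    for i, (label, length) in enumerate(sorted(ANNOTATION_DOMAINS.items())):
        rng = np.random.default_rng(90000 + i)
        records.append(
            ProteinRecord(protein_id=label, sequence=random_protein(length, rng))
        )
    return records


def seed_protein(gene: str) -> str:
    """The seed protein implanted by the simulator for a gene family."""
    if gene == "whiB-like":
        return whib_library(1)[0].sequence
    if gene == "lsr2-like":
        return lsr2_library(1)[0].sequence
    raise ValueError(f"unknown gene family {gene!r}")
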