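"""Sequence analytics over LINE-1 locus families.

A LINE-1 "locus family" is a set of genomic copies whose ORF1p/ORF2p
protein sequences differ from a reference element (or consensus) by only
~0.5–2.5%.  This module provides the analytics that such families require:

* in-silico tryptic digestion with the proline rule and missed cleavages,
* global alignment of each locus to a reference ORF protein,
* per-locus variant counting and per-position identity profiles,
* antibody epitope conservation scanning across a family,
* 1-based amino-acid ↔ nucleotide coordinate mapping within an ORF,
* two-step orthogonalization of a redundant locus database against a set
  of observed peptides.

Alignment is pairwise (star topology to the reference) rather than a full
multiple alignment: at these divergence levels the per-locus variant
counts are identical and no external MSA engine is needed.  A pre-aligned
FASTA can be supplied instead where an existing multiple alignment must be
reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Seq import Seq

GAP = "-"


@dataclass
class LocusRecord:
    """One genomic LINE-1 locus with its ORF protein sequence."""

    locus_id: str
    subfamily: str
    orf_label: str
    protein: str
    nucleotide: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.protein:
            raise ValueError(f"locus {self.locus_id!r}: empty protein")
        if self.orf_label not in ("ORF1", "ORF2"):
            raise ValueError(f"locus {self.locus_id!r}: orf_label must be ORF1 or ORF2")
        if self.nucleotide is not None:
            if len(self.nucleotide) != 3 * len(self.protein):
                raise ValueError(
                    f"locus {self.locus_id!r}: nucleotide length must be 3x protein length"
                )
            translated = str(Seq(self.nucleotide).translate())
            if translated != self.protein:
                raise ValueError(
                    f"locus {self.locus_id!r}: nucleotide does not translate to protein"
                )


@dataclass
class Epitope:
    """A linear antibody epitope anchored on the reference ORF protein."""

    name: str
    sequence: str
    reference_start: Optional[int] = None  # 1-based; located by search when absent

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("epitope sequence must be non-empty")
        if self.reference_start is not None and self.reference_start < 1:
            raise ValueError("reference_start is 1-based")


#: Linear epitopes of the five anti-ORF2p rabbit monoclonal antibodies,
#: on the L1RP ORF2p reference.  MT49/MT69 sit on the endonuclease surface,
#: MT9/MT11 between the endonuclease and reverse-transcriptase domains, and
#: MT5 (containing the L1Hs-diagnostic V990) near the C domain.
ORF2P_EPITOPES: dict[str, str] = {
    "MT5": "QDIGVGKD",
    "MT9": "KASRRQEITKIRAE",
    "MT11": "KELEKQEQT",
    "MT49": "DRSTRQ",
    "MT69": "LHQADLID",
}


@dataclass
class VariantReport:
    """Variant load of one locus relative to the reference."""

    locus_id: str
    n_variants: int
    percent_divergence: float


@dataclass
class PairwiseAlignment:
    """Gapped reference/locus strings from a global alignment."""

    locus_id: str
    aligned_reference: str
    aligned_locus: str
    reference_length: int


# ---------------------------------------------------------------------------
# Digestion


def digest(
    protein: str, max_missed_cleavages: int = 1
) -> list[tuple[str, int, int, str, str]]:
    """In-silico tryptic digestion: cleave after K/R unless followed by P.

    Returns ``(peptide, start, end, prev_aa, next_aa)`` tuples with 1-based
    inclusive coordinates, for 0..max_missed_cleavages missed sites, in
    (start, end) order.  '-' marks the protein terminus.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    cut_after = [
        i for i in range(len(protein) - 1)
        if protein[i] in "KR" and protein[i + 1] != "P"
    ]
    boundaries = [0] + [i + 1 for i in cut_after] + [len(protein)]
    out: list[tuple[str, int, int, str, str]] = []
    for bi in range(len(boundaries) - 1):
        for missed in range(max_missed_cleavages + 1):
            bj = bi + 1 + missed
            if bj >= len(boundaries):
                break
            start, end = boundaries[bi], boundaries[bj]
            prev_aa = protein[start - 1] if start > 0 else "-"
            next_aa = protein[end] if end < len(protein) else "-"
            out.append((protein[start:end], start + 1, end, prev_aa, next_aa))
    out.sort(key=lambda t: (t[1], t[2]))
    return out


# ---------------------------------------------------------------------------
# Alignment and variant counting


def _make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_to_reference(
    locus: LocusRecord,
    reference: str,
    **scores: float,
) -> PairwiseAlignment:
    """Needleman–Wunsch global alignment of a locus protein to the reference.

    Default scoring: match +1, mismatch −1, affine gaps (open −5,
    extend −1).  Ties are broken deterministically by taking the first
    optimal alignment in the aligner's enumeration order.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    aligner = _make_aligner(**scores)
    alignment = next(iter(aligner.align(reference, locus.protein)))
    ref_aln, loc_aln = str(alignment[0]), str(alignment[1])
    return PairwiseAlignment(
        locus_id=locus.locus_id,
        aligned_reference=ref_aln,
        aligned_locus=loc_aln,
        reference_length=len(reference),
    )


def variant_count(
    alignment: PairwiseAlignment, per_residue_indels: bool = False
) -> VariantReport:
    """Count amino-acid variants of a locus relative to the reference.

    Variants = substituted reference positions + deleted reference
    positions + insertion events (each contiguous insertion run counts
    once; set ``per_residue_indels`` to count every inserted residue).
    Percent divergence is 100 · n_variants / reference length.
    """
    subs = dels = ins_events = ins_residues = 0
    prev_ins = False
    for r, q in zip(alignment.aligned_reference, alignment.aligned_locus):
        if r == GAP and q == GAP:
            continue
        if r == GAP:
            ins_residues += 1
            if not prev_ins:
                ins_events += 1
            prev_ins = True
            continue
        prev_ins = False
        if q == GAP:
            dels += 1
        elif r != q:
            subs += 1
    n = subs + dels + (ins_residues if per_residue_indels else ins_events)
    return VariantReport(
        locus_id=alignment.locus_id,
        n_variants=n,
        percent_divergence=100.0 * n / alignment.reference_length,
    )


def _reference_column_residues(alignment: PairwiseAlignment) -> list[str]:
    """Locus residue (or gap) aligned to each reference position, in order."""
    out: list[str] = []
    for r, q in zip(alignment.aligned_reference, alignment.aligned_locus):
        if r != GAP:
            out.append(q)
    return out


def per_position_identity(
    loci: Sequence[LocusRecord], reference: str
) -> np.ndarray:
    """Percent of loci matching the reference residue, per reference position.

    Gaps count as non-identical.  Returns a vector of reals in [0, 100] of
    the reference length.
    """
    if not loci:
        raise ValueError("need at least one locus")
    counts = np.zeros(len(reference))
    for locus in loci:
        aln = align_to_reference(locus, reference)
        residues = _reference_column_residues(aln)
        counts += np.array([q == r for q, r in zip(residues, reference)], dtype=float)
    return 100.0 * counts / len(loci)


# ---------------------------------------------------------------------------
# Epitope conservation


def locate_epitope(epitope: Epitope, reference: str) -> int:
    """1-based start of the epitope on the reference protein."""
    if epitope.reference_start is not None:
        return epitope.reference_start
    pos = reference.find(epitope.sequence)
    if pos < 0:
        raise ValueError(
            f"epitope {epitope.name!r} not found on reference and no reference_start given"
        )
    return pos + 1


def epitope_scan(
    epitope: Epitope,
    loci: Sequence[LocusRecord],
    reference: str,
) -> tuple[dict[str, int], float]:
    """Mismatch count per locus in the epitope window, plus match fraction.

    The epitope is located on the reference; for each locus the aligned
    residues over that window are compared to the epitope sequence, with
    gapped positions scored as mismatches.  The family match fraction is
    the proportion of loci with zero mismatches.
    """
    start = locate_epitope(epitope, reference)  # 1-based
    window = range(start - 1, start - 1 + len(epitope.sequence))
    if window[-1] >= len(reference):
        raise ValueError(f"epitope {epitope.name!r} extends past the reference")
    mismatches: dict[str, int] = {}
    for locus in loci:
        aln = align_to_reference(locus, reference)
        residues = _reference_column_residues(aln)
        mm = sum(1 for i, j in enumerate(window) if residues[j] != epitope.sequence[i])
        mismatches[locus.locus_id] = mm
    n_match = sum(1 for v in mismatches.values() if v == 0)
    fraction = n_match / len(loci) if loci else 0.0
    return mismatches, fraction


# ---------------------------------------------------------------------------
# Coordinates


def aa_to_nt(aa_position: int) -> tuple[int, int]:
    """Map a 1-based amino-acid position to its 1-based codon interval.

    Position *k* occupies nucleotides (3·(k−1)+1, …, 3·(k−1)+3) of the ORF.
    """
    if aa_position < 1:
        raise ValueError("aa_position is 1-based and must be >= 1")
    first = 3 * (aa_position - 1) + 1
    return first, first + 2


# ---------------------------------------------------------------------------
# Orthogonalization


def orthogonalize_loci(
    observed_peptides: Sequence[tuple[str, Sequence[str]]],
    loci: Sequence[LocusRecord],
    consensus: str,
) -> tuple[list[str], dict[str, str]]:
    """Reduce a redundant locus database to a minimal peptide-explaining set.

    Two steps: (a) retain every locus supported by at least one peptide
    unique to it; (b) for each peptide whose supporting loci are all still
    unretained, add exactly one representative — the supporting locus most
    different from the consensus (highest variant count; ties broken by
    lexicographically smallest locus id).

    Returns the retained locus ids (input order, then representatives in
    peptide order) and a map from each step-(b) peptide to its
    representative.
    """
    by_id = {l.locus_id: l for l in loci}
    for peptide, support in observed_peptides:
        if not support:
            raise ValueError(f"peptide {peptide!r} has empty locus support")
        for lid in support:
            if lid not in by_id:
                raise ValueError(f"peptide {peptide!r} supported by unknown locus {lid!r}")

    unique_support = {
        support[0] for _, support in observed_peptides if len(set(support)) == 1
    }
    retained = [l.locus_id for l in loci if l.locus_id in unique_support]
    retained_set = set(retained)

    variant_cache: dict[str, int] = {}

    def variants(lid: str) -> int:
        if lid not in variant_cache:
            aln = align_to_reference(by_id[lid], consensus)
            variant_cache[lid] = variant_count(aln).n_variants
        return variant_cache[lid]

    representative: dict[str, str] = {}
    for peptide, support in observed_peptides:
        if any(lid in retained_set for lid in support):
            continue
        rep = min(sorted(set(support)), key=lambda lid: (-variants(lid), lid))
        representative[peptide] = rep
        if rep not in retained_set:
            retained.append(rep)
            retained_set.add(rep)
    return retained, representative
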