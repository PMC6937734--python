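"""Fragment-ion annotation and per-PSM quality metrics.

Given a peptide sequence and a fragmentation peak list, this module computes
the quantities the repeat-aware PSM filters consume:

* the **matched-intensity fraction** — the share of total peak intensity
  explained by theoretical b/y ions of the assigned peptide,
* the **maximum fragmentation gap** — the longest stretch of sequence, in
  residues, with no fragment-ion evidence for any internal cleavage site,
* the **tryptic status** of the peptide boundaries (full / semi / non).

A fragmentation *gap* is defined as a maximal run of consecutive backbone
cleavage sites covered by no matched b or y ion, reported in residues as
run length + 1; a peptide with no covered site at all has gap = its length.
Ion series are b and y at charges 1+ and 2+ by default (HCD-dominant), with
no neutral losses; monoisotopic masses throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from pyteomics import mass as _pmass

#: Monoisotopic residue masses for the 20 standard amino acids.
RESIDUE_MASS: dict[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}

PROTON = 1.007276
WATER = 18.010565

TERMINUS = "-"


class UnknownResidueError(ValueError):
    """Peptide contains a symbol outside the 20 standard residues."""


@dataclass
class Spectrum:
    """A fragmentation spectrum: peaks plus optional precursor info."""

    peaks: list[tuple[float, float]]
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None
    title: str = ""

    def __post_init__(self) -> None:
        mzs = [p[0] for p in self.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            self.peaks = sorted(self.peaks, key=lambda p: p[0])
        if any(p[1] < 0 for p in self.peaks):
            raise ValueError("negative peak intensity")


@dataclass
class PSMRecord:
    """One peptide-spectrum match with assignments, score and derived metrics.

    The quality metrics (``matched_intensity_fraction``,
    ``max_fragmentation_gap``, ``covered_cleavage_sites``) are unset until
    :func:`annotate` has been applied; ``tryptic_status`` is derived from the
    flanking residues on construction.
    """

    spectrum_id: str
    peptide: str
    modifications: list[tuple[int, float, str]] = field(default_factory=list)
    prev_aa: str = TERMINUS
    next_aa: str = TERMINUS
    assignments: list[str] = field(default_factory=list)
    evalue: float = 1.0
    sample: str = ""
    matched_intensity_fraction: Optional[float] = None
    max_fragmentation_gap: Optional[int] = None
    covered_cleavage_sites: Optional[list[bool]] = None

    def __post_init__(self) -> None:
        if len(self.peptide) < 1:
            raise ValueError("peptide must have length >= 1")
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")
        for pos, _, _ in self.modifications:
            if not 1 <= pos <= len(self.peptide):
                raise ValueError(
                    f"modification position {pos} outside peptide of length {len(self.peptide)}"
                )

    @property
    def annotated(self) -> bool:
        return self.matched_intensity_fraction is not None

    @property
    def tryptic_status(self) -> str:
        return tryptic_status(self.peptide, self.prev_aa, self.next_aa)


@dataclass
class FragmentAnnotation:
    """Result of matching a spectrum against a peptide's b/y ladder."""

    matched_peaks: list[tuple[int, str]]
    matched_intensity_fraction: float
    covered_cleavage_sites: list[bool]
    max_gap: int


def theoretical_ions(
    peptide: str,
    modifications: Sequence[tuple[int, float, str]] = (),
    charges: Iterable[int] = (1,),
) -> list[tuple[str, float]]:
    """Monoisotopic b- and y-ion m/z for all prefix/suffix lengths 1..L-1.

    b_k = (sum of first k residue masses + mods on prefix + z·proton)/z;
    y_k = (sum of last k residue masses + mods on suffix + water + z·proton)/z.
    A single-residue peptide has no internal cleavage site and yields an
    empty list.
    """
    for aa in peptide:
        if aa not in RESIDUE_MASS:
            raise UnknownResidueError(f"unknown residue symbol {aa!r}")
    L = len(peptide)
    mod_mass = np.zeros(L)
    for pos, shift, _ in modifications:
        mod_mass[pos - 1] += shift
    residue = np.array([RESIDUE_MASS[aa] for aa in peptide]) + mod_mass
    prefix = np.cumsum(residue)
    ions: list[tuple[str, float]] = []
    total = prefix[-1]
    for z in sorted(set(int(c) for c in charges)):
        if z < 1:
            raise ValueError("charges must be positive integers")
        for k in range(1, L):
            ions.append((f"b{k}^{z}", (prefix[k - 1] + z * PROTON) / z))
            ions.append((f"y{k}^{z}", (total - prefix[L - k - 1] + WATER + z * PROTON) / z))
    return ions


def annotate(
    psm: PSMRecord,
    spectrum: Spectrum,
    tolerance_ppm: float = 10.0,
    charges: Iterable[int] = (1, 2),
) -> FragmentAnnotation:
    """Match a spectrum against the peptide's theoretical b/y ladder.

    A peak is matched when within ``tolerance_ppm`` of any theoretical ion;
    each peak contributes once to the matched intensity even when it matches
    several ions.  Cleavage site *i* (0-based, between residues i+1 and i+2)
    counts as covered when any b(i+1) or y(L-1-i) ion matched.  The result
    is also written back onto the PSM (``matched_intensity_fraction``,
    ``max_fragmentation_gap``, ``covered_cleavage_sites``).
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    L = len(psm.peptide)
    ions = theoretical_ions(psm.peptide, psm.modifications, charges)
    covered = [False] * (L - 1)
    matched_peaks: list[tuple[int, str]] = []
    matched = np.zeros(len(spectrum.peaks), dtype=bool)
    mzs = np.array([p[0] for p in spectrum.peaks])
    intens = np.array([p[1] for p in spectrum.peaks])
    for label, mz in ions:
        tol = mz * tolerance_ppm * 1e-6
        if len(mzs):
            hits = np.nonzero(np.abs(mzs - mz) <= tol)[0]
        else:
            hits = []
        for idx in hits:
            matched_peaks.append((int(idx), label))
            matched[idx] = True
            series, rest = label[0], label[1:]
            k = int(rest.split("^")[0])
            site = k - 1 if series == "b" else L - k - 1
            if 0 <= site < L - 1:
                covered[site] = True
    total = float(intens.sum())
    fraction = float(intens[matched].sum() / total) if total > 0 else 0.0
    max_gap = _max_gap_from_coverage(covered, L)
    ann = FragmentAnnotation(
        matched_peaks=matched_peaks,
        matched_intensity_fraction=fraction,
        covered_cleavage_sites=covered,
        max_gap=max_gap,
    )
    psm.matched_intensity_fraction = fraction
    psm.max_fragmentation_gap = max_gap
    psm.covered_cleavage_sites = covered
    return ann


def _max_gap_from_coverage(covered: Sequence[bool], peptide_length: int) -> int:
    """Longest run of consecutive uncovered cleavage sites + 1.

    Equals the peptide length when no site is covered, and 1 for a complete
    ladder (or a single-residue peptide, which has no sites).
    """
    longest = run = 0
    for c in covered:
        run = 0 if c else run + 1
        longest = max(longest, run)
    if peptide_length > 1 and longest == peptide_length - 1:
        return peptide_length
    return longest + 1


def residue_gap_sizes(covered: Sequence[bool]) -> list[int]:
    """Per-residue size of the fragment-evidence block containing each residue.

    Covered cleavage sites partition the peptide into blocks; every residue
    in a block of *g* residues is assigned gap size *g*.  A fully covered
    ladder gives 1 everywhere.
    """
    L = len(covered) + 1
    sizes = [0] * L
    start = 0
    for i in range(L):
        end_of_block = i == L - 1 or covered[i]
        if end_of_block:
            g = i - start + 1
            for j in range(start, i + 1):
                sizes[j] = g
            start = i + 1
    return sizes


def tryptic_status(peptide: str, prev_aa: str = TERMINUS, next_aa: str = TERMINUS) -> str:
    """Classify peptide boundaries as ``full``, ``semi`` or ``non`` tryptic.

    Trypsin cleaves after K or R except when the next residue is P.  The
    N-terminal boundary is tryptic iff ``prev_aa`` ∈ {K, R} and the first
    peptide residue is not P, or ``prev_aa`` is the protein terminus '-';
    symmetrically for the C-terminal boundary.
    """
    n_ok = prev_aa == TERMINUS or (prev_aa in "KR" and peptide[0] != "P")
    c_ok = next_aa == TERMINUS or (peptide[-1] in "KR" and next_aa != "P")
    if n_ok and c_ok:
        return "full"
    if n_ok or c_ok:
        return "semi"
    return "non"
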