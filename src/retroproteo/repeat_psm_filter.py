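"""Repeat-aware PSM retention and ORF2p false-positive rejection.

Peptides from LINE-1 loci are shared among hundreds of near-identical
genomic copies, so PSM-level quality control must be stricter than for
ordinary proteins.  This module implements:

* :func:`filter_psms` — retention rules on matched-intensity fraction,
  fragmentation gap, peptide length, e-value and single-gene assignment;
* :func:`orf2_rejection_flags` — review flags for candidate ORF2p variant
  peptides that are more parsimoniously explained by the consensus
  sequence (semi-tryptic boundaries, deamidation artifacts, non-tryptic
  consensus substrings, poor fragmentation over variant positions);
* :func:`select_correlated_peptides` — the mutually rank-correlated
  peptide-set selection used to pick reliable quantifiable peptides;
* :func:`presence_matrix` — the peptide-by-sample detection matrix.

Rejection filters are reported as flags, not hard drops; they are review
criteria and the caller decides whether to discard flagged PSMs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .fragment_annotation import PSMRecord, residue_gap_sizes, tryptic_status
from .io_formats import SequenceEntry

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds for PSM retention.

    Defaults are the rules used for repeat-aware LINE-1 peptide searches:
    matched-intensity fraction > 0.40, fragmentation gap ≤ 3 residues,
    peptide length ≥ 7, e-value ≤ 0.01, and assignments confined to a
    single gene.
    """

    min_matched_fraction: float = 0.40
    max_gap_residues: int = 3
    min_peptide_length: int = 7
    max_evalue: float = 0.01
    require_unique_gene: bool = True
    spearman_threshold: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_matched_fraction <= 1.0:
            raise ValueError("min_matched_fraction must be in [0, 1]")
        for name in ("max_gap_residues", "min_peptide_length", "max_evalue", "spearman_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class PeptideQuantVector:
    """Per-sample quantities for one peptide; NaN marks missing."""

    peptide: str
    quantities: np.ndarray

    def __post_init__(self) -> None:
        self.quantities = np.asarray(self.quantities, dtype=float)
        if not np.isfinite(self.quantities).any():
            raise ValueError(f"peptide {self.peptide!r} has no non-missing quantity")


class NotAnnotatedError(RuntimeError):
    """A PSM reached the filter without fragment annotation."""


def filter_psms(
    psms: Sequence[PSMRecord],
    gene_map: Mapping[str, str],
    config: FilterConfig | None = None,
) -> tuple[list[PSMRecord], list[tuple[PSMRecord, str]]]:
    """Apply the retention rules; return (retained, rejection log).

    Each rejected PSM carries its first failing reason among ``fraction``,
    ``gap``, ``length``, ``evalue``, ``multi-gene`` (checked in that
    order).  Proteins absent from ``gene_map`` count as their own gene.
    """
    config = config or FilterConfig()
    retained: list[PSMRecord] = []
    rejected: list[tuple[PSMRecord, str]] = []
    for psm in psms:
        if not psm.annotated:
            raise NotAnnotatedError(
                f"PSM {psm.spectrum_id!r} is not annotated; run fragment annotation first"
            )
        reason = None
        if not psm.matched_intensity_fraction > config.min_matched_fraction:
            reason = "fraction"
        elif psm.max_fragmentation_gap > config.max_gap_residues:
            reason = "gap"
        elif len(psm.peptide) < config.min_peptide_length:
            reason = "length"
        elif psm.evalue > config.max_evalue:
            reason = "evalue"
        elif config.require_unique_gene:
            genes = {gene_map.get(p, p) for p in psm.assignments}
            if len(genes) > 1:
                reason = "multi-gene"
        if reason is None:
            retained.append(psm)
        else:
            rejected.append((psm, reason))
    return retained, rejected


# ---------------------------------------------------------------------------
# ORF2p rejection flags


def _is_tryptic_occurrence(consensus: str, start: int, length: int) -> bool:
    prev_aa = consensus[start - 1] if start > 0 else "-"
    end = start + length
    next_aa = consensus[end] if end < len(consensus) else "-"
    return tryptic_status(consensus[start:end], prev_aa, next_aa) == "full"


def _best_window(peptide: str, consensus: str) -> Optional[int]:
    """Start of the consensus window of equal length with fewest mismatches."""
    L = len(peptide)
    if L > len(consensus):
        return None
    best_start, best_mm = None, L + 1
    pep = np.frombuffer(peptide.encode(), dtype=np.uint8)
    cons = np.frombuffer(consensus.encode(), dtype=np.uint8)
    for s in range(len(consensus) - L + 1):
        mm = int((cons[s:s + L] != pep).sum())
        if mm < best_mm:
            best_start, best_mm = s, mm
    return best_start


def orf2_rejection_flags(
    psm: PSMRecord,
    consensus: str,
    locus_sequences: Sequence[SequenceEntry] = (),
) -> set[str]:
    """Review flags for a candidate ORF2p variant PSM.

    Returns a subset of ``{semi_tryptic, deamidation_explainable,
    nontryptic_consensus_explainable, poor_variant_fragmentation}``:

    * ``semi_tryptic`` — the peptide is not fully tryptic;
    * ``deamidation_explainable`` — replacing D→N and/or E→Q at the
      positions where the peptide differs from its best-aligned consensus
      window yields an exact consensus substring (deamidation converts
      N→D and Q→E, so such a "variant" needs no genomic explanation);
    * ``nontryptic_consensus_explainable`` — the peptide occurs verbatim
      in the consensus but only with non-tryptic boundaries there;
    * ``poor_variant_fragmentation`` — some position where the peptide
      differs from consensus lies inside a fragmentation gap > 1 residue
      (no direct fragment evidence for the variant residue).
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    flags: set[str] = set()
    peptide = psm.peptide
    if psm.tryptic_status != "full":
        flags.add("semi_tryptic")

    occurrences = [
        m for m in range(len(consensus) - len(peptide) + 1)
        if consensus[m:m + len(peptide)] == peptide
    ]
    if occurrences and not any(
        _is_tryptic_occurrence(consensus, s, len(peptide)) for s in occurrences
    ):
        flags.add("nontryptic_consensus_explainable")

    start = _best_window(peptide, consensus)
    if start is not None:
        window = consensus[start:start + len(peptide)]
        diffs = [i for i in range(len(peptide)) if peptide[i] != window[i]]
        if diffs and all(
            (peptide[i] == "D" and window[i] == "N") or (peptide[i] == "E" and window[i] == "Q")
            for i in diffs
        ):
            flags.add("deamidation_explainable")
        if diffs and psm.covered_cleavage_sites is not None:
            sizes = residue_gap_sizes(psm.covered_cleavage_sites)
            if any(sizes[i] > 1 for i in diffs):
                flags.add("poor_variant_fragmentation")
    return flags


# ---------------------------------------------------------------------------
# Correlated peptide-set selection

#: Above this many peptides, exact clique search switches to a greedy scheme.
EXACT_CLIQUE_LIMIT = 20


def _pairwise_spearman(
    vectors: Sequence[PeptideQuantVector], min_pairs: int = 3
) -> pd.DataFrame:
    names = [v.peptide for v in vectors]
    rho = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for a, b in itertools.combinations(range(len(vectors)), 2):
        x, y = vectors[a].quantities, vectors[b].quantities
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_pairs:
            logger.info(
                "peptides %r/%r share only %d samples; correlation undefined",
                names[a], names[b], int(ok.sum()),
            )
            continue
        r = spearmanr(x[ok], y[ok]).statistic
        rho.iloc[a, b] = rho.iloc[b, a] = r
    np.fill_diagonal(rho.values, 1.0)
    return rho


def _mean_pairwise(rho: pd.DataFrame, members: Sequence[str]) -> float:
    vals = [rho.loc[a, b] for a, b in itertools.combinations(members, 2)]
    return float(np.mean(vals)) if vals else 1.0


def select_correlated_peptides(
    vectors: Sequence[PeptideQuantVector],
    threshold: float = 0.6,
) -> list[str]:
    """Largest peptide set in which every pair has Spearman ρ ≥ threshold.

    The pairwise criterion defines a graph whose maximum clique (size ≥ 2)
    is returned; ties go to the clique with higher mean pairwise ρ, then
    to the lexicographically smallest member tuple.  Pairs with fewer than
    3 jointly observed samples have undefined ρ and are treated as below
    threshold.  Exact search is used up to ``EXACT_CLIQUE_LIMIT`` peptides,
    a greedy scheme (highest-degree seed, best-improvement growth) above.
    """
    if len(vectors) < 2:
        return []
    rho = _pairwise_spearman(vectors)
    names = list(rho.index)
    G = nx.Graph()
    G.add_nodes_from(names)
    for a, b in itertools.combinations(names, 2):
        if rho.loc[a, b] >= threshold:
            G.add_edge(a, b)
    if G.number_of_edges() == 0:
        return []
    if len(names) <= EXACT_CLIQUE_LIMIT:
        cliques = [sorted(c) for c in nx.find_cliques(G) if len(c) >= 2]
        if not cliques:
            return []
        return min(cliques, key=lambda c: (-len(c), -_mean_pairwise(rho, c), tuple(c)))
    return _greedy_clique(G, rho, names)


def _greedy_clique(G: nx.Graph, rho: pd.DataFrame, names: list[str]) -> list[str]:
    seed = max(names, key=lambda n: (G.degree(n), n))
    clique = {seed}
    while True:
        candidates = [
            n for n in G.nodes
            if n not in clique and all(G.has_edge(n, c) for c in clique)
        ]
        if not candidates:
            break
        clique.add(max(candidates, key=lambda n: _mean_pairwise(rho, sorted(clique | {n}))))
    return sorted(clique) if len(clique) >= 2 else []


# ---------------------------------------------------------------------------
# Presence matrix


def presence_matrix(
    retained: Sequence[PSMRecord],
    samples: Sequence[str],
    peptide_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Peptide-by-sample boolean detection matrix.

    Entry [p, s] is True iff at least one retained PSM of peptide *p*
    carries sample label *s*.  Rows follow ``peptide_order`` when given
    (e.g. by position on the reference protein), otherwise first-seen
    order; columns follow ``samples`` as given.
    """
    if peptide_order is None:
        seen: dict[str, None] = {}
        for psm in retained:
            seen.setdefault(psm.peptide, None)
        peptide_order = list(seen)
    matrix = pd.DataFrame(False, index=list(peptide_order), columns=list(samples), dtype=bool)
    for psm in retained:
        if psm.peptide in matrix.index and psm.sample in matrix.columns:
            matrix.loc[psm.peptide, psm.sample] = True
    return matrix


def write_rejection_log(
    rejected: Sequence[tuple[PSMRecord, str]], path: str
) -> None:
    """Write the rejection log as TSV (spectrum id, peptide, reason)."""
    with open(path, "w") as handle:
        handle.write("spectrum\tpeptide\treason\n")
        for psm, reason in rejected:
            handle.write(f"{psm.spectrum_id}\t{psm.peptide}\t{reason}\n")
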