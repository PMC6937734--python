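"""Seeded generators for every input the pipeline consumes.

Each generator returns, alongside the data, a :class:`TruthLedger`
recording every random decision made, so expected outputs at every stage
can be recomputed exactly without external downloads.

The defaults emulate the study conditions the pipeline targets:

* a family of 146 near-identical LINE-1 ORF2p-like locus proteins of
  1275 residues with a per-residue substitution rate of 1.25% relative to
  a common consensus (the observed average divergence of full-length
  genomic L1 copies),
* tryptic peptides with noisy singly charged b/y fragment ladders,
* replicate IP-vs-control intensity matrices, 3 vs 3, with 1000 null
  proteins, 50 spiked proteins enriched by 2 log2 units in the IPs,
  within-group standard deviation 0.5 on the log2 scale, and
  left-censored (abundance-dependent) missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .fragment_annotation import PROTON, RESIDUE_MASS, WATER, PSMRecord, Spectrum, theoretical_ions
from .io_formats import RawIntensityTable
from .locus_toolkit import LocusRecord, digest

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Synonymous codon choices per amino acid (standard code; no stops).
_CODONS: dict[str, list[str]] = {}
for _c in [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]:
    _aa = str(Seq(_c).translate())
    if _aa != "*":
        _CODONS.setdefault(_aa, []).append(_c)


@dataclass
class GeneratorConfig:
    """Knobs for all generators; the seed is mandatory.

    Defaults are the emulated study conditions (see the module docstring),
    not tuning parameters.
    """

    seed: int
    n_loci: int = 146
    protein_length: int = 1275
    mutation_rate: float = 0.0125
    indel_rate: float = 0.0
    n_samples: int = 6
    n_proteins: int = 1000
    n_spiked: int = 50
    effect_log2: float = 2.0
    within_group_sd: float = 0.5
    missing_rate_low_abundance: float = 0.3
    spectrum_noise_peaks: int = 10
    fragment_dropout: float = 0.1
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 3.0

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "indel_rate", "missing_rate_low_abundance", "fragment_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")


@dataclass
class TruthLedger:
    """Ground truth behind one generator run."""

    planted_variants: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    planted_indels: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    spiked_proteins: dict[str, float] = field(default_factory=dict)
    missing_cells: list[tuple[int, int, str]] = field(default_factory=list)
    spectrum_truth: list[dict] = field(default_factory=list)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(rng.choice(_CODONS[aa]) for aa in protein)


def generate_locus_family(
    config: GeneratorConfig,
) -> tuple[list[LocusRecord], str, TruthLedger]:
    """Generate a consensus protein and a family of mutated locus copies.

    The consensus is uniform over the 20 residues; each locus carries
    Bernoulli(``mutation_rate``) substitutions per position (recorded as
    (1-based position, from, to)) and, with per-locus probability
    ``indel_rate``, one short deletion of 1–3 residues.  Nucleotide
    sequences are random synonymous reverse-translations, so the
    translation invariant holds by construction.
    """
    if config.n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(config.seed)
    consensus = _random_protein(rng, config.protein_length)
    ledger = TruthLedger()
    loci: list[LocusRecord] = []
    for i in range(config.n_loci):
        locus_id = f"L1_locus_{i:04d}"
        residues = list(consensus)
        subs: list[tuple[int, str, str]] = []
        hit = np.nonzero(rng.random(len(residues)) < config.mutation_rate)[0]
        for pos in hit:
            old = residues[pos]
            new = rng.choice([a for a in AMINO_ACIDS if a != old])
            residues[pos] = new
            subs.append((int(pos) + 1, old, str(new)))
        indels: list[tuple[int, str, str]] = []
        if rng.random() < config.indel_rate and len(residues) > 10:
            size = int(rng.integers(1, 4))
            start = int(rng.integers(1, len(residues) - size))
            removed = "".join(residues[start:start + size])
            del residues[start:start + size]
            indels.append((start + 1, removed, ""))
        protein = "".join(residues)
        loci.append(
            LocusRecord(
                locus_id=locus_id,
                subfamily="L1Hs" if i % 4 else "L1PA2",
                orf_label="ORF2",
                protein=protein,
                nucleotide=_reverse_translate(rng, protein),
            )
        )
        ledger.planted_variants[locus_id] = subs
        ledger.planted_indels[locus_id] = indels
    return loci, consensus, ledger


def generate_spectra(
    peptides: Sequence[str],
    config: GeneratorConfig,
    tolerance_ppm: float = 10.0,
) -> tuple[list[tuple[Spectrum, PSMRecord]], TruthLedger]:
    """Noisy singly charged b/y ladders for a list of peptides.

    Each theoretical 1+ b/y ion is dropped independently with probability
    ``fragment_dropout``; ``spectrum_noise_peaks`` noise peaks are placed
    uniformly over the m/z range but outside the ppm windows of all
    theoretical ions, so the ledger's matched-intensity fraction and
    fragmentation gap are exact by construction.  Intensities are
    lognormal.
    """
    rng = np.random.default_rng(config.seed)
    ledger = TruthLedger()
    out: list[tuple[Spectrum, PSMRecord]] = []
    for si, peptide in enumerate(peptides):
        if len(peptide) < 2:
            raise ValueError("peptides must have length >= 2")
        ions = theoretical_ions(peptide, charges=(1,))
        kept = [ion for ion in ions if rng.random() >= config.fragment_dropout]
        peaks: list[tuple[float, float]] = []
        for label, mz in kept:
            peaks.append((mz, float(rng.lognormal(mean=10.0, sigma=1.0))))
        lo, hi = 100.0, max([mz for _, mz in ions]) + 200.0
        placed = 0
        while placed < config.spectrum_noise_peaks:
            mz = float(rng.uniform(lo, hi))
            if any(abs(mz - tmz) <= tmz * 2 * tolerance_ppm * 1e-6 for _, tmz in ions):
                continue
            peaks.append((mz, float(rng.lognormal(mean=9.0, sigma=1.0))))
            placed += 1
        total = sum(p[1] for p in peaks)
        matched = sum(p[1] for p in peaks[: len(kept)])
        # A site counts as covered when any emitted peak lies within the
        # matching tolerance of one of the site's ions — including rare m/z
        # coincidences with ions that were themselves dropped — so the
        # ledger agrees exactly with 1+ annotation at the same tolerance.
        covered = [False] * (len(peptide) - 1)
        kept_mzs = [mz for _, mz in kept]
        for label, tmz in ions:
            if not any(abs(pmz - tmz) <= tmz * tolerance_ppm * 1e-6 for pmz in kept_mzs):
                continue
            series, rest = label[0], label[1:]
            k = int(rest.split("^")[0])
            site = k - 1 if series == "b" else len(peptide) - k - 1
            covered[site] = True
        run = longest = 0
        for c in covered:
            run = 0 if c else run + 1
            longest = max(longest, run)
        true_gap = len(peptide) if longest == len(peptide) - 1 else longest + 1
        spectrum = Spectrum(
            peaks=sorted(peaks), title=f"synthetic_{si}",
            precursor_mz=(
                sum(RESIDUE_MASS[aa] for aa in peptide) + WATER + 2 * PROTON
            ) / 2,
            precursor_charge=2,
        )
        psm = PSMRecord(
            spectrum_id=f"synthetic_{si}", peptide=peptide,
            prev_aa="K", next_aa="A",
            assignments=["SYNTH"], evalue=1e-4,
        )
        ledger.spectrum_truth.append(
            {
                "spectrum_id": f"synthetic_{si}",
                "peptide": peptide,
                "true_matched_fraction": matched / total if total else 0.0,
                "true_max_gap": true_gap,
                "n_kept_ions": len(kept),
            }
        )
        out.append((spectrum, psm))
    return out, ledger


def peptides_from_family(
    loci: Sequence[LocusRecord], min_length: int = 7, max_length: int = 25
) -> list[str]:
    """Unique tryptic peptides (0 missed cleavages) across a locus family."""
    peptides: dict[str, None] = {}
    for locus in loci:
        for pep, _, _, _, _ in digest(locus.protein, max_missed_cleavages=0):
            if min_length <= len(pep) <= max_length:
                peptides.setdefault(pep, None)
    return list(peptides)


def generate_ipms_matrix(
    config: GeneratorConfig,
) -> tuple[RawIntensityTable, TruthLedger]:
    """Replicate IP-vs-control intensity matrix with spiked enrichment.

    Null proteins share a baseline log2 abundance across groups; the first
    ``n_spiked`` proteins are shifted up by ``effect_log2`` in the case
    group.  Gaussian within-group noise (sd ``within_group_sd``) is added
    on the log2 scale, then left-censored missingness is applied: the
    missingness probability is ``missing_rate_low_abundance`` ·
    Φ((c − value)/1.5) with c one baseline-sd below the baseline mean, so
    low-abundance measurements are preferentially lost.  Values are
    exported on the raw scale with 0 encoding missing.
    """
    if config.n_samples % 2 or config.n_samples < 6:
        raise ValueError("n_samples must be even and >= 6 (>= 3 per side)")
    rng = np.random.default_rng(config.seed)
    n_case = n_ctrl = config.n_samples // 2
    n_total = config.n_proteins + config.n_spiked
    ledger = TruthLedger()
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n_total)
    ids = [f"SPIKE_{i:04d}" if i < config.n_spiked else f"NULL_{i - config.n_spiked:04d}"
           for i in range(n_total)]
    for i in range(config.n_spiked):
        ledger.spiked_proteins[ids[i]] = config.effect_log2
    log2 = np.empty((n_total, config.n_samples))
    for i in range(n_total):
        case_mean = baseline[i] + (config.effect_log2 if i < config.n_spiked else 0.0)
        log2[i, :n_case] = rng.normal(case_mean, config.within_group_sd, size=n_case)
        log2[i, n_case:] = rng.normal(baseline[i], config.within_group_sd, size=n_ctrl)
    from scipy.stats import norm

    censor_mid = config.baseline_log2_mean - config.baseline_log2_sd
    p_miss = config.missing_rate_low_abundance * norm.cdf((censor_mid - log2) / 1.5)
    miss = rng.random(log2.shape) < p_miss
    for r, c in zip(*np.nonzero(miss)):
        ledger.missing_cells.append((int(r), int(c), "left_censored"))
    raw = np.where(miss, 0.0, np.exp2(log2))
    samples = [f"IP_{k + 1}" for k in range(n_case)] + [f"Ctrl_{k + 1}" for k in range(n_ctrl)]
    table = RawIntensityTable(
        protein_ids=ids,
        sample_columns=samples,
        values=raw,
        reverse_flags=np.zeros(n_total, dtype=bool),
        contaminant_flags=np.zeros(n_total, dtype=bool),
    )
    return table, ledger


def default_groups(config: GeneratorConfig) -> list[str]:
    """Group labels matching :func:`generate_ipms_matrix` column order."""
    half = config.n_samples // 2
    return ["case"] * half + ["control"] * half
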