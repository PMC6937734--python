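# Methods

This note documents the models and procedures `retroproteo` implements,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Fragment annotation

Theoretical fragment masses are monoisotopic b- and y-ions for all
prefix/suffix lengths 1..L−1:

    b_k = (Σ prefix residue masses + mods on prefix + z·m_p) / z
    y_k = (Σ suffix residue masses + mods on suffix + m_H2O + z·m_p) / z

with m_p = 1.007276 Da and m_H2O = 18.010565 Da. Residue masses come from
pyteomics' standard table. The default series is b/y at charges 1+ and 2+
with no neutral losses — HCD fragmentation on Orbitrap-class instruments
is dominated by these — and both the series and the matching tolerance
(default 10 ppm, matching typical high-resolution search settings) are
arguments.

**Matched-intensity fraction.** A peak is matched when it lies within
tolerance of any theoretical ion; each peak contributes once to the
matched intensity even if it matches several ions, so the fraction is
bounded by 1. The fraction over an empty spectrum is defined as 0. No
noise floor is applied: all peaks enter the denominator.

**Fragmentation gap.** "Gap" is not a standardized quantity; here a
cleavage site counts as covered when any b- or y-ion spanning it matched,
and a gap is a maximal run of consecutive uncovered sites, reported in
residues as run length + 1. A fully covered ladder has gap 1; a peptide
with no covered site has gap equal to its length. This makes the ≤ 3
residue filter threshold interpretable as "no stretch of more than three
residues lacks fragment evidence" and is validated against a brute-force
run scan in the tests.

**Tryptic status.** A boundary is tryptic when the preceding residue is
K/R not followed by P, or when it is a protein terminus. Full/semi/non
classification follows from the two boundaries independently.

## Repeat-aware PSM filtering

Retention thresholds (matched fraction > 0.40, gap ≤ 3, length ≥ 7,
e-value ≤ 0.01, single-gene assignment) are the package defaults and all
configurable. "Gene" is resolved through an explicit protein→gene map in
which all L1 loci of the same ORF collapse to one gene, so peptides
shared among loci survive while genuinely ambiguous peptides are dropped.
Rejections carry the first failing criterion, checked in the order
fraction, gap, length, e-value, gene.

**ORF2p rejection flags.** Four review criteria for candidate ORF2p
variant peptides are computed as flags rather than hard drops, since each
marks a *more parsimonious* explanation rather than a proof of error:

1. *poor_variant_fragmentation* — a position where the peptide differs
   from its best-matching consensus window lies in a fragment-evidence
   block larger than one residue (the variant residue itself is not
   bracketed by matched ions). This is the computational proxy for manual
   spectrum review, which does not scale.
2. *deamidation_explainable* — replacing D→N and/or E→Q at exactly the
   differing positions recovers a consensus substring; deamidation
   (N→D, Q→E) is a common artifact that mimics genomic variants.
3. *nontryptic_consensus_explainable* — the peptide occurs verbatim in
   the consensus, but at no occurrence with fully tryptic boundaries; an
   in-source or chymotryptic-like cleavage of the abundant consensus
   protein is then the simpler explanation. An occurrence *with* tryptic
   boundaries means the peptide is a legitimate consensus peptide and no
   flag is raised.
4. *semi_tryptic* — the peptide itself is not fully tryptic.

The consensus window used for flags 1–2 is the equal-length substring of
the consensus with the fewest mismatches; at the ≤ 2.5% divergence of L1
families an ungapped window scan is equivalent to alignment.

**Correlated peptide sets.** The quantifiable-peptide criterion — every
pair of selected peptides Spearman-correlated at ρ ≥ 0.6 over jointly
observed samples — is formalized as a maximum-clique problem on the
threshold graph, the strictest reading of "correlated with each other".
Pairs with fewer than 3 joint observations have undefined ρ and are
treated as below threshold. Search is exact (full clique enumeration) up
to 20 peptides and greedy (highest-degree seed, best-improvement growth)
above; ties between maximum cliques go to the higher mean pairwise ρ,
then to the lexicographically smallest member set. Spearman uses average
ranks for ties. The quantity vector is deliberately agnostic (spectral
counts or intensities both work).

## Locus toolkit

**Digestion** cleaves after K/R except before P, emitting peptides for
0..k missed cleavages with 1-based inclusive coordinates and flanking
residues.

**Alignment.** Each locus is aligned to the reference by global
Needleman–Wunsch with match +1 / mismatch −1 and affine gaps (open −5,
extend −1), via Biopython's `PairwiseAligner`; the first alignment in its
deterministic enumeration order is used, which fixes tie-breaking without
affecting scores. A star topology (every locus vs one reference) replaces
multiple alignment: at ≤ 2.5% divergence the per-locus variant counts are
the same and no external MSA engine is needed. Callers who must
reproduce an existing multiple alignment exactly can pass pre-aligned
sequences.

**Variant counting.** n_variants = substituted reference positions +
deleted reference positions + insertion events, where a contiguous
insertion run counts once (a `per_residue_indels` switch counts each
inserted residue instead; amino-acid "variant" counts in the literature
rarely state their indel convention, so both are available). Percent
divergence is 100·n_variants / reference length.

**Epitope scanning** locates an epitope on the reference (exact substring
or explicit 1-based anchor) and counts mismatching residues per locus in
the aligned window, scoring gapped positions as mismatches (the
conservative choice for predicting antibody recognition); the family
match fraction is the proportion of loci with zero mismatches. The five
anti-ORF2p monoclonal epitopes (MT5 QDIGVGKD, MT9 KASRRQEITKIRAE, MT11
KELEKQEQT, MT49 DRSTRQ, MT69 LHQADLID) ship as a constant.

**Coordinates** are 1-based and inclusive on both protein and ORF
nucleotide scales; residue k occupies nucleotides 3(k−1)+1..3(k−1)+3, so
the L1Hs-diagnostic residue 990 maps to 2968–2970.

**Orthogonalization** reduces a redundant locus database against observed
peptides in two steps: (a) retain every locus with at least one peptide
unique to it; (b) for each peptide still unexplained, add the single
supporting locus most different from the consensus (highest variant
count; ties to the lexicographically smallest id). Peptides are processed
in input order and a peptide already covered by an earlier representative
adds nothing; consequently every retained locus is justified by a unique
peptide or a representative designation, though a representative can in
principle become coverage-redundant by a later addition.

## LFQ enrichment

Preprocessing removes reverse/contaminant-flagged rows and configurable
id substrings (default IGHG1 — the IgG heavy chain of the mock-IP
antibody, which would otherwise dominate both arms), log2-transforms
non-zero intensities, converts zeros to an explicit missing mask (the
MaxQuant export convention), and drops all-missing rows. Downstream code
never tests for zero.

**Imputation** runs on the log2 scale, per group, in two stages, with the
replicate-difference model fitted *before* any imputed value exists:

- *All replicates of a group missing*: each cell is drawn uniformly from
  [μ_c − 3σ_c, μ_c − 2σ_c] with μ_c, σ_c from the replicate column's
  observed values — a left-censored assumption appropriate when absence
  reflects abundance below the detection limit.
- *Some replicates missing*: from proteins fully observed in the group, a
  distribution of relative replicate differences
  delta = (Int_rep1 − Int_rep2)/mean(Int_rep1, Int_rep2) is collected over
  all replicate pairs; then delta_new ~ Normal(μ_delta,
  sd_delta/(ρ̄·√2)) and I_new = mean(observed replicates)·|1 + delta_new|.
  ρ̄ is the mean pairwise Pearson correlation among the group's replicate
  columns on fully observed proteins; the √2 rescales a pairwise
  difference spread to a single-replicate spread, and the correlation
  divisor widens the draw when replicates agree poorly. ρ̄ ≤ 0 is an
  error, not a silent fallback — it signals replicates too discordant to
  support model-based imputation. "Which correlations" is not fixed by
  convention, so the function accepts a pluggable correlation estimator.

Both stages use seeded generators; runs are bit-reproducible.

**Testing.** Per-protein two-sample t-tests (Welch by default — the
safer choice under unequal variances; pooled-variance Student's via a
flag), Benjamini–Hochberg adjustment within each comparison, log2 fold
change as case mean − control mean. Zero variance in both groups with
equal means yields p = 1 by convention. A protein is *significant* when
p.adj ≤ 0.05, log2FC ≥ 1, and at least two case replicates are
non-imputed (applied to the case side; a switch extends it to both
groups). Integration counts, per protein, the comparisons passed and
reports ≥1/≥2/≥3 tiers.

**Power at the default design.** A 3-vs-3 comparison estimates each
protein's variance with ~4 degrees of freedom, and BH across ~1000 tests
demands raw p ≲ 0.002 of a true positive. A spiked effect of 2 log2
units with within-group sd 0.5 (Cohen's d = 4) reaches that level in only
~14% of cases, so the pipeline's sensitivity for such spikes is low by
construction — a property of small-replicate t-tests, not of the
implementation. High recovery occurs for proteins that are also absent
or censored in controls, where imputation places the control arm several
standard deviations low and fold changes are large; this is the regime
of genuinely enriched IP proteins. The null side is well calibrated
(raw p ≤ 0.05 fraction ≈ 5%) and observed false-discovery proportions in
spike-in simulations are ≤ 10%.

**Band ranking.** Gel-band identifications are sorted by log E-value
(ties: higher PSM count, then id); keratins, non-human entries, and
everything at or below trypsin's rank are dropped; then entries
homologous to a retained higher rank, or with fewer than half the top
retained entry's PSMs, are pruned. Homology is supplied as external group
labels since no sequence-level criterion is standard. The operation is
idempotent.

## Synthetic data

The generators emulate the study conditions, not arbitrary data:

- *Locus families*: a uniform-composition consensus of 1275 residues
  (the ORF2p length) and 146 copies with per-residue substitution
  probability 0.0125 — the observed mean divergence of full-length
  genomic L1 ORF2p (16 variants, 1.25%) — plus optional short deletions.
  Nucleotide sequences are random synonymous reverse-translations, so
  translation consistency holds by construction.
- *Spectra*: singly charged b/y ladders with independent per-ion dropout,
  lognormal intensities, and noise peaks placed uniformly in m/z but
  outside the ppm windows of all theoretical ions, so the ledger's
  matched fraction and gap are exact for 1+ annotation at the same
  tolerance.
- *IP matrices*: 3 IP vs 3 control replicates, 1000 null + 50 spiked
  proteins, spike effect 2 log2 units, within-group sd 0.5 on the log2
  scale, baseline abundances N(25, 3²) (typical MaxQuant LFQ log2 range).
  Missingness is left-censored: probability
  `missing_rate_low_abundance · Φ((c − value)/1.5)` with c one baseline
  sd below the baseline mean and a default ceiling of 0.3, a realistic
  LFQ missingness level; an MCAR-style null is obtained by setting the
  rate to 0.

What passing these tests shows: the arithmetic of each stage is correct
against independent oracles and the pipeline's statistical behaviour is
as analyzed above. What it does not show: robustness to features the
generators omit — chromatographic co-elution, isotope envelopes,
peptide-specific ionization efficiency, shared-peptide protein inference,
batch effects, and non-normal intensity noise.

## Known limitations

- Fragment annotation covers b/y with no neutral losses or immonium
  ions; spectra dominated by losses will under-report matched intensity.
- The greedy clique fallback above 20 peptides is not guaranteed maximal.
- Orthogonalization is order-dependent for rule-(b) representatives (see
  above); the retained set always explains every observed peptide.
- Reproducing cohort-scale results (tier counts across tumor
  comparisons, hot-locus epitope surveys) requires the corresponding
  public datasets and locus databases; the package operates on them
  through the same interfaces but does not download them.
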