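# Methods

This note records the models, conventions and numerical choices behind each
stage, what the simulators do and do not emulate, and the limits of what
passing tests demonstrate.

## Coordinates and annotation

All analysis runs in transcript space, 0-based half-open: 5′UTR
`[0, cds_start)`, CDS `[cds_start, cds_end)` (length ≡ 0 mod 3), 3′UTR
`[cds_end, length)`. Genome-space input (GTF, 1-based closed; BED12,
0-based) is projected onto transcripts at ingest, with minus-strand exons
reversed, so no downstream code is strand-aware. One transcript per gene is
assumed; duplicate gene ids are not merged.

## Ribosome profiling

**P-site offsets.** For each footprint length L, every read whose 5′ end
lies in `[cds_start − w, cds_start)` (default w = 30, capped at L − 1) votes
with the distance `cds_start − five_prime_end`; the mode is the offset.
Ties break toward the smaller offset (a deterministic rule; the tie itself
carries no information). Lengths with fewer than 50 in-window reads inherit
the mode of the pooled histogram. This is a metagene-mode estimator: it
needs an initiation peak to be identifiable, because under perfectly uniform
CDS coverage the in-window histogram is flat across `offset − 3k` and the
mode is undefined up to a codon. Accepted footprint lengths default to
25–35 nt; others are ignored with a log line.

**Periodicity and regions.** P-site = 5′ end + offset; frame =
(psite − cds_start) mod 3, computed over CDS-internal P-sites only. Region
occupancy percentages count P-sites over 5′UTR/CDS/3′UTR. RPKM =
count / (region kb × library millions); footprints are assigned to the
region containing their P-site, RNA fragments to the region of their 5′
end; zero-length regions yield NaN, never a division error.

**Codon occupancy.** The E/P/A-site codon is the codon containing
psite + {−3, 0, +3} nt; occupancy is the site count divided by the codon's
frequency across the analyzed CDSs, rescaled to mean 1 over observed codons
(codons absent from the CDSs are NA). Off-frame P-sites are assigned to the
codon containing them rather than discarded.

## Translational efficiency and differential calling

TE = RPKM(CDS, RPF) / RPKM(exons, RNA) on replicate-pooled (summed) counts;
per-replicate tables are retained for QC such as replicate Pearson r on
log₂(count + 1). When any of a transcript's four pooled counts falls below
10, a symmetric pseudocount of 0.5 is added to all four before RPKM, which
bounds fold changes without moving well-covered estimates. Transcripts
absent from a library, or with all-zero counts, are classed `low_coverage`.

Significance of the footprint change is a per-transcript two-sided Fisher
exact test of pooled CDS counts against library totals, BH-adjusted. The
class rules use strict inequalities exactly as stated: up-translated iff
log₂FC(TE) > 1 and |log₂FC(mRNA)| < 1 and FDR < 0.2; down symmetric;
|log₂FC(mRNA)| ≥ 1 is `excluded_transcriptional` regardless of TE. A
Wilcoxon signed-rank test on paired log₂ TE summarizes global shifts.

Because TE is a ratio of relative (depth-normalized) densities, planting an
effect on a subset shifts the apparent TE of the complement in the opposite
direction (compositionality). The recovery studies therefore score
sensitivity/FDR against the planted up set; the small compositional down
shift (≈ −0.5 log₂ units at 15% PES × 4×) stays inside the ±1 cutoff and
produces no systematic false calls at the tested depths.

## 5′ motif classification and enrichment

PES: a run of ≥ `min_run` (default 5) consecutive pyrimidines (C/U≡T)
beginning within the first `window` (default 10) nt of the 5′ UTR; TOP
additionally requires the run to start at +1 with a C. Both knobs are
configurable since the operational definition in the literature varies;
ambiguity codes other than C/T break runs (conservative). Enrichment is the
exact hypergeometric upper tail on the population of coverage-tested
transcripts (not the whole annotation), which conditions the test on
testability. Fold enrichment is (k/n)/(K/N).

## HDX-MS differential uptake

Uptake is the centroid-mass difference to the undeuterated measurement,
uncorrected for back exchange; normalization divides by max-exchangeable
amides (length − 2 − prolines at positions ≥ 3), the D₂O fraction, and an
80% recovery default. Ingest keeps high/medium-confidence rows, collapses
duplicate (peptide, charge, state, exposure) entries whose retention times
agree within ±0.5 min by centroid averaging, and keeps distinct-RT species
separate. Ligand-minus-apo differences are computed per timepoint and for
the maximum uptake across timepoints, each thresholded at ±0.5 Da
(protected/exposed/ns); both the per-peptide calls and the residue-level
map are exported, since tools differ in where they apply the criterion.

Residue aggregation assigns each exchange-competent residue (≥ start + 2 of
a covering peptide, non-proline) the **unweighted mean** of covering-peptide
ΔD in Da — equal evidence per peptide, no length weighting (a weighted mode
could be added, but the unweighted surface is what the per-peptide
significance calls already reflect). "Heavy smoothing" is quantified as a
centered 5-residue moving average along contiguous covered runs (window 1
disables; window must be odd). Prolines and uncovered residues stay NA.

Because peptide-level ΔD is a sum over the peptide's residues, a peptide
straddling a protection boundary carries part of the footprint's total
deficit onto residues it covers outside the footprint. The margin is
quantifiable: with competent length L_c and per-residue contrast δ (Da), the
mean at a residue d residues outside the boundary is bounded by roughly
δ·L_c/2 · (share of straddlers), decaying to zero at d ≈ L_c. Residue-level
calls are therefore identifiable only when coverage is dense (many
non-straddling peptides per residue) and δ·L_c sits near the call threshold.
The localization study uses exactly that regime: 8 ± 0.5-residue peptides at
redundancy 16 over a 200-residue protein, a domain-sized 51-residue planted
footprint, protection factor 0.55, and lognormal intrinsic rates with
median 10⁻³ s⁻¹ so the apo/ligand contrast peaks inside the 30–9000 s
grid (analytically at t* = ln(1/p)/(k(1−p)) ≈ 1.3×10³ s). Under these
conditions, across 40 seeds, no protected call falls outside the planted
interval dilated by the smoothing half-width, and sensitivity over
exchange-competent residues exceeds 0.93. Sensitivity excludes prolines,
which carry no exchangeable backbone amide and are uncoloured by design.

QC statistics (coverage %, mean peptides per covered residue, length
mean/sd) count every peptide row, so charge states raise redundancy as they
do in instrument exports.

## Equilibrium binding

One-site hyperbola f(C) = C/(K_d + C), ceiling fixed at 1 because an EMSA
fraction bound is already a ratio; a Hill exponent is available but defaults
to 1. The fit multi-starts over 7 log-spaced K_d values spanning
[C_min/10, C_max·10]; SE comes from the Jacobian at the optimum. A curve
must beat the best constant fit in an extra-sum-of-squares F test
(df (1, n−2), α = 0.05) to earn a numeric K_d; otherwise the verdict is
`no_binding` — the appropriate report for a flat or non-saturating control.
The constant (not zero) null matters: a small constant background would
otherwise be "explained" by a huge-K_d hyperbola and misread as binding.

## Simulators: what they emulate, and what they do not

All generators take explicit seeds; a single global seed is expanded into
per-stage substreams (`substreams`) so stages can be regenerated
independently. Outputs are deterministic for a fixed seed and numpy
Generator implementation (float draws included; bit-identical across runs
and platforms for the same numpy major version).

* **Transcriptome** — UTR/CDS lengths uniform in configurable ranges
  (defaults 20–150 nt 5′UTR, 100–400 codons, 30–200 nt 3′UTR), iid
  background nucleotides at a GC setpoint, CDS framed by ATG and a stop.
  Motifs are planted (or excluded) by constructive rejection so the truth
  table equals the classifier output by construction. Internal stop codons
  and codon-usage structure are not modeled; nothing downstream reads them.
* **Footprints/RNA** — transcript abundance and baseline TE are lognormal
  (log-sd 1.0 and 0.35); expected footprint counts ∝ abundance × TE × CDS
  length, RNA counts ∝ abundance × transcript length; multinomial depth
  allocation; P-sites over CDS codons with a 5× initiation-dwell boost at
  the start codon (the feature that makes metagene offset estimation
  well-posed) and frame0 probability 0.9; 5′ end = P-site − offset(L) with
  a 26–34 nt length distribution. RNA fragment 5′ ends are uniform — no
  positional bias model, since TE is a ratio and the total-RNA arm has no
  planted bias. No sequencing error, UMI structure, codon-level dwell
  variation, or biological replicate dispersion beyond counting noise: the
  recovery studies therefore demonstrate correctness of the estimators
  under the stated generative model, not robustness to real-library
  artifacts (dispersion would primarily widen the Fisher test's calibration).
* **HDX** — per-residue single-exponential kinetics with lognormal intrinsic
  rates (median 10⁻³ s⁻¹, log-sd 1.0), uptake summed over exchange-competent
  residues, scaled by D₂O fraction (default 0.83, a 5:25 labelling dilution)
  and recovery 0.8; ligand multiplies rates by the protection factor inside
  the planted interval; Gaussian centroid noise (default 0.05 Da) per
  (peptide, time, state). Timepoints default to 0/30/300/1000/3000/9000 s.
  Peptide maps are uniform-start with normal lengths (14.6 ± 7.9 default)
  at a target redundancy (6.9 default). EX1/bimodal exchange,
  isotope-envelope shapes and back-exchange variation are not simulated —
  centroids only.
* **Binding** — f = C/(K_d + C) + N(0, σ), clipped to [0, 1], over a
  12-point log grid spanning 0.5–60 µM, 3 replicates, σ = 0.02 default.

## Problem sizes in the self-validation studies

The TE recovery study runs 1,000 transcripts, 15% PES, 4× effect, duplicate
libraries at 2×10⁶ reads each, averaged over 10 seeds, with a 20-seed null
(effect 1×). The null uniformity check scores hypergeometric p on random
200-transcript samples of the tested population — the well-defined null,
since a null run calls essentially nothing up. QC recovery uses 300
transcripts at 5×10⁵ reads; HDX and binding studies are seconds each
(the K_d noise study spans 100 seeds). These sizes keep the full validation
in the minutes range on a single CPU while leaving Monte-Carlo error well
below the acceptance margins.

## Known limitations

* Fisher-exact significance on pooled counts treats replicates as one
  library; biological overdispersion would anti-conservatively narrow p.
  The spec'd design calls for this test; a GLM layer is out of scope.
* Residue-level HDX resolution is bounded by peptide overlap; raw-Da
  aggregation bleeds multi-residue deficits across footprint boundaries
  (quantified above). Interpret residue maps together with the per-peptide
  calls.
* The offset estimator assumes an initiation peak; libraries depleted of
  initiating ribosomes (e.g. harringtonine-free run-off protocols with
  aggressive start trimming) may need the offset table supplied externally.
* The no-binding F test compares two one-parameter models; its df
  convention (1, n−2) is a pragmatic choice validated by the flat-control
  behavior, not an exact likelihood-ratio calibration.
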