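# ribopes

Translatome, 5′ pyrimidine-motif, HDX-MS and binding-curve analysis for
studies of sequence-selective translation control — with seeded simulators
that plant known ground truth for every input, so the whole pipeline is
testable by parameter recovery.

## The problem

Small regulatory RNAs and RNA-binding proteins can steer ribosomes toward or
away from mRNA subsets that share 5′ UTR features — classically the 5′
terminal oligopyrimidine tract (TOP: a transcript starting with C followed
by an uninterrupted pyrimidine run) and the broader class of
pyrimidine-enriched sequences (PES) near the transcription start site.
Quantifying such a program takes three measurement layers, and this package
implements the computation behind each:

1. **Ribosome profiling → translational efficiency (TE).**
   For each transcript, TE = RPKM(CDS, footprints) / RPKM(exons, total RNA).
   Upstream of TE: P-site offsets per footprint length are estimated by the
   metagene mode of `cds_start − 5′end` over a window upstream of start
   codons; trinucleotide periodicity and P-site region occupancy serve as
   library QC; codon occupancy for the E/P/A sites is site counts divided by
   codon usage. Differentially translated transcripts satisfy (strictly)
   log₂FC(TE) > 1, |log₂FC(mRNA)| < 1 and a Benjamini–Hochberg FDR < 0.2 on
   the footprint-count change (two-sided Fisher exact test per transcript).

2. **5′ motif classification and enrichment.**
   PES: a run of ≥ 5 pyrimidines (C/U) beginning within the first 10 nt of
   the 5′ UTR; TOP: the C-initiated run at +1 (TOP ⊂ PES). Over-representation
   of PES among up-translated transcripts is scored with the exact upper-tail
   hypergeometric test, P(X ≥ k), X ~ Hypergeom(N, K, n), conditioning the
   population on coverage-tested transcripts.

3. **HDX-MS differential uptake and equilibrium binding.**
   Peptide deuterium uptake D(t) = centroid(t) − centroid(0), no
   back-exchange correction, normalized by max-exchangeable amides
   (length − 2 − prolines beyond position 2), D₂O fraction and recovery
   (80%). Ligand-minus-apo differences are thresholded at ±0.5 Da,
   aggregated to residues as unweighted means over covering peptides, and
   smoothed with a 5-residue moving average (prolines uncoloured). Binding
   curves f(C) = C/(K_d + C) are fit by least squares with a no-binding
   verdict when the fit does not beat a flat model (F test, α = 0.05).

Each analysis has a matching generator (`simulate_*`) that emits the same
file formats the readers consume plus a truth table, so sensitivity, false
discovery and localization are measurable quantities, not hopes.

## Worked example

`examples/01_translatome.py` simulates 300 transcripts (20% carrying a
planted PES), duplicate footprint and RNA libraries at 5×10⁵ reads with a
4× TE effect on PES transcripts in the perturbed condition, and runs the
full calling path:

```
P-site offsets by read length: {26: 10, 27: 10, 28: 11, 29: 12, 30: 12, 31: 13, 32: 13, 33: 13, 34: 14}
frame fractions (f0,f1,f2): (0.9, 0.05, 0.05)
translation_class
unchanged          220
up_translated       65
down_translated     15
planted up-translated recovered: 65/66 (65 called)
```

The offsets and frame bias are exactly the planted values; 65 of 66 planted
transcripts are recovered with zero false up-calls. (The down-calls are the
compositional echo of relative normalization — boosting one fifth of the
library depresses everyone else's apparent TE.) The other examples cover
motif enrichment (`02`), HDX footprint mapping (`03`: planted residues
60–110, called 49–116 under 5-residue smoothing and ~15-residue peptides)
and K_d fitting (`04`: 2.062 ± 0.033 µM against a true 2 µM, and a
`no_binding` verdict for a flat control).

A thin CLI wraps the same functions: `ribopes run --config cfg.yaml --seed 1
--outdir out/` executes simulate → riboqc → quantify → te → motif → enrich →
hdx → fit-binding with checksummed, rerun-skipping manifests; every stage is
also available as a subcommand.

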