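# Methods

This note records the statistical definitions, conventions and design
choices behind `cpcodon`, in the order the pipeline applies them.

## CDS screening

A record is kept iff it starts with ATG, ends with TAA/TAG/TGA, contains
no in-frame internal stop, and its length is a multiple of 3 and at
least `min_length` (default 300 bp — short ORFs give unstable per-gene
indices, and 100 codons is the conventional floor for ENC). Rejections
record the *first* failed rule in the fixed order AMBIGUOUS,
NOT_TRIPLET, NO_START, BAD_STOP, INTERNAL_STOP, TOO_SHORT, so rule
tallies are deterministic. Sequences containing N are rejected outright
(AMBIGUOUS): a codon with an ambiguous base has no defined identity,
and silently dropping codons would bias per-gene lengths. Counting
functions nevertheless skip (and log) N-containing codons so partially
ambiguous data can be analysed deliberately.

Chloroplast inverted repeats duplicate genes; whether to collapse exact
(name, sequence) duplicates is a reporting choice with no single right
answer, so deduplication is a separate opt-in step
(`dedupe_identical`, CLI `--dedupe-identical`) and reproduction of
published CDS counts is best-effort either way.

The plastid genetic code (NCBI table 11) is used throughout; its 61/3
sense/stop partition coincides with the standard code. Stop codons form
a single three-member family that participates in RSCU/RFSC, the
high-frequency screen and the optimal-codon rule (termination-codon
preference is a real, reportable signal) but is excluded — together
with the non-degenerate ATG and TGG — from GC3s, ENC, CAI, PR2 and the
CA codon set.

## Usage statistics

**RSCU** is observed count over family mean, `x_ij n_i / T_i`; **RFSC**
is the family share `x_ij / T_i`; the two satisfy `RSCU = n_i · RFSC`
and the family sums `Σ RSCU = n_i`, `Σ RFSC = 1`, which the tests
enforce to 1e−9 on random tables. Unobserved families carry value 0 and
an explicit flag rather than NaN, so matrices stay numeric.

**High-frequency codons**: `RFSC > 0.6` or `RFSC > 1.5/n_i`. The second
clause reads "exceeds the family-average frequency by half again"; it
is the binding rule for 4- and 6-fold families (thresholds 0.375 and
0.25), while 0.6 binds for 2- and 3-fold families. Both inequalities
are strict.

**ENC** follows Wright's estimator. Per family with total n ≥ 2,
`F̂ = (nΣp² − 1)/(n − 1)`; families at n = 1 are excluded (F̂ is
degenerate there). Class means over degeneracies 2/3/4/6 give
`ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, clamped to [20, 61] (the raw
estimator overshoots 61 by sampling noise). The single 3-fold class
(Ile) is imputed as `F̄₃ = (F̄₂ + F̄₄)/2` when absent *or* non-positive —
tiny samples can give F̂ = 0, which would otherwise blow up the
reciprocal; any other empty class drops its term and the result is
rescaled by 20 / (amino acids covered), keeping the [20, 61] scale
comparable. Six-fold families (Leu, Ser, Arg) are classed whole, per
Wright's original scheme; `split_sixfold=True` classes their 2- and
4-fold codon boxes separately for comparison with tools that split.
The mutation-only expectation is `ENC(s) = 2 + s + 29/(s² + (1−s)²)`
at synonymous GC3 = s.

**CAI** needs a high-expression reference the input data must supply;
lacking external expression data, the pipeline uses the pooled
lowest-ENC 10% library (strong bias as the expression proxy — the same
convention the optimal-codon split uses). Relative adaptiveness is
`w_j = RSCU_ref,j / max-in-family`, and CAI is the geometric mean of w
over the gene's codons excluding ATG, TGG and stops. Codons unused by
the reference are floored at w = 0.01 (logged) to keep the log-mean
finite; families entirely absent from the reference are uninformative
and weighted 1.

**CBI/Fop** are computed over codons of amino acids owning at least one
optimal codon: `Fop = N_opt/N_tot` and
`CBI = (N_opt − N_rand)/(N_tot − N_rand)` with
`N_rand = Σ T_i k_i/n_i`, so exactly-random usage scores CBI = 0 and
purely optimal usage 1.

## Optimal codons

Genes with defined ENC are ranked ascending (ties broken on gene id so
the split is reproducible); `k = max(1, round-half-up(0.10 N))` genes
from each end form the high- (low ENC) and low-expression libraries.
RSCU is computed on each library's *pooled* counts — pooling stabilises
rare families that per-gene averaging would leave empty — and a codon is
optimal iff `ΔRSCU > 0.08` (strict), `RSCU_high > 1` and
`RSCU_low < 1`. Synthetic recovery: with one designated codon per
degenerate family enriched (p = 0.85) in half of 60 genes and depleted
(p = 0.05) in the other half, the procedure recovers ≥ 90% of the
designated codons (seeded test).

## Mutation–selection diagnostics

The **PR2** coordinates `A3/(A3+T3)` and `G3/(G3+C3)` are tallied over
fourfold-degenerate codon boxes by default (Sueoka's convention: only
there are third-position substitutions guaranteed synonymous, so
deviations from 0.5 cleanly separate strand-asymmetric mutation from
selection); an `all_synonymous` option exists for comparison with
analyses that use every degenerate codon. The species-level value is
the unweighted mean over genes, so long genes do not dominate.

The **neutrality plot** regresses per-gene GC12 (mean of position-1 and
-2 GC over all codons) on GC3 computed after excluding ATG and TGG,
the three stops, and the three Ile codons. The conventions in the
literature disagree on the Ile exclusion and on whether stops belong in
GC3, so each exclusion is an independent toggle; the default is the
union of all three. OLS and the Pearson r/p come from
`scipy.stats.linregress`, and slope = r·sd(y)/sd(x) is asserted
internally as a cross-check.

## Correspondence analysis

CA is run on the gene × 59-codon RSCU matrix (not raw counts), so gene
length and amino-acid composition are already normalised out and axes
reflect synonymous choice only. Standard chi-square-metric CA: divide
by the grand total, form `S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}`, SVD, and
report principal coordinates; total inertia equals χ²/N, which an
independent oracle verifies in the tests. Because P is normalised,
singular values are ≤ 1 and an absolute cutoff of `max(shape)·ε`
separates rank from round-off. CA axes are sign-ambiguous: each axis is
flipped so its largest-magnitude codon loading is positive, which makes
coordinates reproducible but means correlations with external indices
can legitimately change sign relative to other software. The first 4
axes are reported by default. Axis-1 correlations use Pearson r with a
two-sided t-test, marked `*` for p < 0.05 and `**` for p < 0.01;
missing index values are dropped pairwise.

## Host comparison

Frequencies are expressed per 1000 codons over all 64 codons, stops
included. The Kazusa-layout parser accepts RNA or DNA alphabets and
requires all 64 codons. A codon is flagged when the query/host ratio is
≥ 2 or ≤ 0.5 (boundaries inclusive); the rule is symmetric under table
exchange, which is asserted as a property. A codon used by the query
but absent from the host is flagged (ratio ∞); absent from both, it is
not (ratio NaN).

## Synthetic data

`generate_genome` draws structurally valid CDS from per-family codon
probability vectors, a uniform sense-amino-acid composition, triplet
lengths uniform on a range (default 300–1602 bp, the span typical of
plastid genes), an optional per-gene GC3 target (families are tilted
toward G/C- or A/T-ending members so the expected synonymous GC3 equals
the target exactly for fully mixed families), and an optional symmetric
Dirichlet concentration — one knob running from uniform usage (ENC → 61)
to near-degenerate usage (ENC → 20). `generate_neutrality_set` plants a
GC12-on-GC3 line by mixing amino acids whose first two positions are
all-GC (Ala/Gly/Pro) or GC-free (Lys/Phe/Asn/Tyr) in proportion to the
per-gene GC12 target (defaults: 60 genes of 1200 bp, GC3 uniform on
0.15–0.60, a realistic plastid spread). All draws come from one seeded
`numpy` generator; output is byte-identical per seed.

What the generators do *not* emulate: real plastid gene content and
amino-acid composition, codon autocorrelation along genes, IR
duplication, or annotation errors. Passing the synthetic recovery tests
therefore demonstrates correctness of the statistics and sensitivity of
the procedures at the stated effect sizes — not that any particular
biological dataset will show those effects.

## Problem sizes and numerics

Tests run toy sets of ≤ 60 genes and ≤ 3000 bp per gene, and the
reference script uses 10,000 codons for the ENC ceiling — large enough
that the finite-sample correction, not noise, dominates (the estimator
is within 0.5 of 61 there). Identities (family sums, RSCU–RFSC link,
CA transition formulas, χ²/N) are asserted to 1e−9; recovery bands
(neutrality slope 0.2 within [0.15, 0.25] at 60 genes) reflect the
sampling noise of the stated design, with seeds fixed once.

## Known limitations

- CAI/CBI/Fop depend on the internally derived reference and optimal
  sets; numbers from tools with externally supplied references (e.g.
  ribosomal-protein sets) will differ systematically.
- ENC conventions vary across software in exactly the places documented
  above (n = 1 families, empty classes, six-fold splitting); agreement
  with other implementations is expected only under matching settings.
- The screening rules assume standard plastid gene models; genes using
  alternative start codons (e.g. rps19 GTG in some taxa) are rejected
  rather than special-cased.
- Published CDS counts for IR-bearing genomes depend on annotation and
  duplicate handling; the dedupe toggle makes both conventions
  available but cannot guarantee either matches a given annotation
  vintage.
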