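# Methods

## The statistic

For a coding sequence of length L over {A,C,G,T} (IUPAC ambiguity codes
tolerated), the normalized content of a dinucleotide XpY is

    O/E = (n_XY / n_windows) / ((n_X / n_bases) · (n_Y / n_bases))

with overlapping windows counted on the given strand only, left to
right. Windows containing a non-ACGT base are excluded from both n_XY
and n_windows, and non-ACGT bases from the mononucleotide counts. The
dinucleotide frequency is taken over valid windows (≈ L−1) and the base
frequencies over valid bases (L); the alternative all-over-L convention
is available (`denominator="bases"`) and differs by < 0.4% at the 300 nt
minimum length, below the 2-decimal resolution at which results are
reported. O/E is undefined (NaN, excluded downstream with a logged
count) when either base is absent or no valid window exists. CpG O/E is
strand-symmetric but TpG and CpA are not; no reverse-complement pooling
is done, since the deamination signature is read from each strand's own
excess.

## Sequence selection

Filters run in the order taxon → isogroup dedup → length (the order is a
documented convention; the source procedure does not state one).
Dedup keeps one uniform-random member per isogroup, drawn with a
per-group RNG seeded by (global seed, isogroup id) over members sorted
by gene id — so the choice is reproducible, independent of input order,
and idempotent. Genes without an isogroup are treated as their own
group and never dropped. The length cutoff is strict: < 300 nt is
discarded, 300 nt is kept. Taxon matching is exact string equality on a
caller-supplied label (taxonomic judgment happens upstream, e.g. by
BLAST top hit). Output is sorted by gene id.

The six-frame ORF extractor (plumbing for raw transcripts) returns the
longest ATG…stop ORF (stop included) over frames +1,+2,+3,−1,−2,−3 with
ties to the earlier frame, then leftmost; with no complete ORF it falls
back to the longest codon-aligned stop-free stretch. Ambiguity codes
reverse-complement to N.

## Mixture model and bimodality test

Let x₁…x_n be the defined per-gene CpG O/E values. The one-component
model is N(μ, σ²) with the closed-form MLE. The two-component model is

    f(x) = w·φ(x; μ₁, σ²) + (1−w)·φ(x; μ₂, σ²)

with a **common component variance** by default. Two observations force
this choice: classical mixture fits of CpG O/E distributions report
identical component SDs within a species, and the accompanying
likelihood-ratio statistic is referred to χ² with 2 degrees of freedom —
exactly the number of parameters (w, μ₂) the common-variance
two-component model adds over the single normal. A per-component-
variance fit remains available (`equal_var=False`).

EM details: initialization splits the sample at the median (component
means/weights from the halves, shared SD from the whole sample);
`restarts − 1` additional starts jitter the means by N(0, (0.25·s)²).
Convergence is relative log-likelihood change < 1e-8 or 1000 iterations;
the variance floor is 1e-6 (O/E² units) against collapse on duplicated
values; log-likelihood monotonicity is asserted every iteration. The
best converged restart wins; components are reported sorted by mean, and
the mixing proportion "of the former" component always refers to the
lower-mean (methylated) one. Because the single normal is a point of the
two-component parameter space (equal means), the k=2 fit is floored at
the k=1 MLE: if EM early-stops fractionally below it on unimodal data,
the degenerate equal-means representation is returned, which guarantees
ln L₂ ≥ ln L₁.

The bimodality statistic is G² = 2(ln L₂ − ln L₁), clipped at zero, with
p the upper tail of χ²(2). The 2-d.f. reference is kept deliberately —
it reproduces the classical procedure — although mixture LRTs violate
the regularity conditions (the weight sits on a boundary under H₀ and
μ₂ is unidentified), so the p-value is approximate; with G² in the
hundreds-to-thousands at realistic sample sizes the verdict does not
depend on the approximation. The likelihood is computed on the raw
values (not binned frequencies).

## Classification threshold

x* solves w₁φ(x; μ₁, σ₁) = w₂φ(x; μ₂, σ₂). With equal SDs the closed
form is x* = (μ₁+μ₂)/2 + σ²·ln(w₁/w₂)/(μ₂−μ₁); otherwise the equation
is quadratic in x and the root in the open interval (μ₁, μ₂) is taken
(there is at most one there). If no root lies between the means — e.g.
extreme weight imbalance — the midpoint is used and flagged
`midpoint-fallback`. Genes with O/E ≤ x* classify "low"; the tie at
exactly x* goes to "low" by convention (a measure-zero event).

## Enrichment

For each (GO id, category) pair present in ≥ 1 classified gene, the 2×2
table is (annotated, not annotated) × (low, high), where "not annotated"
includes genes with no terms at all in that category — the universe is
all classified genes (a annotated-only universe is a one-line change in
the caller, not a config flag). Fisher's exact test is two-sided by the
minimum-likelihood convention (sum of same-margin tables with
probability ≤ observed, 1e-12 float-tie slack); Benjamini–Hochberg runs
separately within BP, CC and MF; the enriched side compares a/(a+c)
against b/(b+d), with exact ties labelled "none" and never significant.
No GO-graph ancestor propagation is performed: terms are tested exactly
as annotated.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
at the study's scale: default n = 20,000 genes of 999 nt (a mid-size
transcriptome survey; sequence count chosen to match the order of
magnitude of assembled isotigs in such surveys), uniform base
composition, class and per-gene target CpG O/E drawn from the preset
two-component mixture, targets clipped to [0.05, 1.5].

Per-gene sequences come from a first-order Markov chain built on the
joint dinucleotide distribution J: seed J with the independence product
π·πᵀ, pin J[C,G] = oe·π_C·π_G, and (with deamination coupling, the
default) add half the removed CpG mass to each of J[C,A] and J[T,G] —
the two strands' deamination products; Sinkhorn scaling then restores
both marginals to π exactly, with an outer loop re-pinning the CpG cell
(converges to < 1e-13). The transition matrix T = J/π is row-stochastic,
has stationary distribution π, and satisfies P(G|C) = oe·π_G, so the
chain's long-run CpG O/E equals the target exactly and CpG-poor genes
carry elevated TpG/CpA. Matrices are cached on targets quantized to
1e-3 O/E units. Feasibility requires oe < 1/π_G.

At 999 nt the realized per-gene O/E is unbiased for its target (class-
mean bias < 0.01, tested) but carries counting noise that inflates the
realized class SD above the target-mixture SD; recovery checks therefore
target means and weights, not SDs. Annotations give every gene a unique
isogroup, taxon "insect" and GO terms: 50 background terms at rates
uniform in [0.01, 0.10] identical across classes, plus planted terms
(defaults: one BP term at 40%/5% low/high, one CC term at 5%/40%)
providing known enrichment ground truth. Options plant multi-member
isogroups and a "protist" contamination fraction to exercise the
filters. Everything derives from one integer seed; outputs are
byte-reproducible.

What the generator does **not** emulate: codon structure and ORF
grammar (sequences are consumed directly as CDS; enforcing start/stop
codons would distort the dinucleotide calibration), codon-usage and
amino-acid composition bias, expression-dependent sampling, assembly
artifacts, and GO-term correlation structure. Passing recovery tests
therefore demonstrate the statistical machinery under the assumed
mixture-plus-noise model, not robustness to every property of real
transcriptome data.

## Problem sizes and numerical choices

The test suite and the acceptance script use n = 20,000 values/genes for
recovery checks (matching the presets' intended scale) and smaller n for
orchestration tests; the full suite runs in well under a minute on one
CPU, the acceptance script in seconds. Component-mean estimates at
n = 20,000 have SE ≈ 0.003 or less, so recovery is asserted to ±0.01 —
one unit in the last reported decimal. Fixed seeds are used throughout;
the acceptance script derives all of its sub-seeds from the single
`--seed` argument.

## Known limitations

- The χ²(2) p-value for the mixture LRT is anti-conservative in theory
  (boundary non-regularity); no bootstrap calibration is provided.
- k is limited to 1 or 2 components, normal only.
- Fisher tests are two-sided only; one-sided variants are not exposed.
- The threshold classification ignores assignment uncertainty near x*;
  no posterior-probability soft classification is reported.
- GO enrichment treats terms independently (no DAG, no term slimming).
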