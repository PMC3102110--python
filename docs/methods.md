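# Methods

This note records the models, conventions and numerical choices behind
coralscreen, and what the synthetic tests do and do not establish.

## The codon model and its estimator

The core quantity is the per-gene ratio ω = dN/dS of nonsynonymous to
synonymous divergence between one pair of orthologous coding
sequences. We fit the Goldman–Yang M0 ("one-ratio") codon model: a
reversible continuous-time Markov chain on the 61 sense codons whose
rate from codon *i* to *j* is zero if they differ at more than one
position and otherwise proportional to π_j, multiplied by κ for
transitions and ω for nonsynonymous changes. Q is scaled so that one
time unit equals one expected substitution per codon; stationarity and
reversibility (π_i q_ij = π_j q_ji) let us compute P(t) = exp(Qt)
through a symmetric eigendecomposition, which is both faster and more
stable than a general matrix exponential.

The pairwise likelihood treats one sequence as a draw from the
stationary distribution and the other as its descendant at distance t;
by reversibility this equals the unrooted two-descendant
parameterization with total path length t, which is also exactly how
the simulator generates data (each descendant evolves t/2 from an
ancestor drawn from π). The likelihood is maximized over (t, κ, ω) in
log-parameter space with bounded L-BFGS-B, three starts at
t ∈ {0.01, 0.2, 1} (the pairwise surface can be flat at low
divergence), κ started at 2 and ω at the NG86 point estimate. Bounds:
t ∈ [10⁻⁶, 50], κ ∈ [10⁻³, 99], ω ∈ [10⁻⁴, 99]. An ω estimate pinned
at the upper bound — including the identical-sequence case where ω is
undefined — is reported as the sentinel value 99 with status
`omega_sentinel` rather than an unbounded ratio, and such pairs are
excluded by the downstream filters together with any pair with dN > 1
or dS > 1 (multiple hits per site make those estimates unreliable).

dS and dN are derived under the mutational-opportunity convention:
synonymous/nonsynonymous site fractions are computed from the fitted
model with ω set to 1, the fitted t is split into synonymous and
nonsynonymous substitutions per codon, and each is divided by its site
count. Under this convention dN/dS reproduces the fitted ω to machine
precision (asserted in tests). Other site-normalization conventions
(physical sites, equal-weighting) give different dS and dN but the
same ω; no exact agreement with any particular external program's dS
and dN is claimed.

Codon frequencies default to F3x4 (position-specific nucleotide
frequencies multiplied and renormalized over sense codons), estimated
from the two sequences with a +1 pseudocount per nucleotide per
position so no sense codon receives zero frequency (the rate matrix
requires strictly positive π). F1x4 and equal frequencies are
available; equal frequencies with κ = 1 make the NG86 cross-check
tightest, since those are NG86's implicit assumptions. The genetic
code is pinned to the standard nuclear code.

NG86 counting is kept as an independent, likelihood-free companion
estimate: per-codon synonymous site fractions averaged over the two
sequences, observed differences averaged over all minimal mutational
pathways (pathways through stop codons excluded; single-nucleotide
changes creating stops counted as nonsynonymous with the per-position
denominator kept at 3), and the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4 (reported as saturated).
NG86 carries a known downward bias in ω when κ > 1; the concordance
tests therefore compare medians at low divergence rather than single
draws.

## Orthology and frame validation

BLAST is deliberately not a dependency. The six-frame translated
search is an exact Smith–Waterman over all 36 frame pairs (BLOSUM62,
gap cost 11 + k), and bit scores use fixed Karlin–Altschul constants
(λ = 0.267, K = 0.041, the gapped-BLOSUM62 values). The 300-bit
reciprocal-best-hit default is the screen's published operating point,
but with an internal exact aligner it is a calibration analog, not a
BLAST-identical threshold; it is configurable, as is everything else,
in the single YAML config. E-values for annotation use
E = m·n·K·e^(−λS) with m the total residue count of the reference;
annotation requires strictly E < 10⁻⁵.

Frame validation recomputes the pair's alignment on the oriented
sequences and selects the frame pair by ORF content: among all 36
frame alignments, the one maximizing the combined length of the
longest stop-codon-free runs (query + subject), with raw score as the
tie-break. The raw-score maximum alone is not safe here — two nearly
identical transcripts align almost as well in a shared wrong frame,
because stop–stop columns still score +1 in BLOSUM62, and for
fast-evolving genes (ω well above 1) the true frame's amino-acid
mismatches can erase its advantage. The longest stop-free stretch is
exactly the signal that breaks this tie, which is why the cascade is
built around the LSCFPS in the first place. Remaining conventions:
LSCFPS length ties prefer the 5′-most run; accepted ORFs must be ≥ 30
codons; "the same reference hit" means the same best-hit identifier,
not the same score; when both the LSCFPS and the 2nd LSCFPS validate,
the longer wins; mitochondrial screening uses the full transcript
(contamination often sits in UTRs) with nucleotide scoring +1/−2,
gap 2.5 + 2.5k, λ = 1.28, K = 0.46, and a 50-bit removal threshold.
Every pair leaves the cascade either validated or carrying an explicit
rejection code — nothing is dropped silently.

## Rank statistics and the GO scan

Group contrasts use the Mann–Whitney U test: exact when the pooled
sample is ≤ 12 without ties, otherwise the normal approximation with
midranks, tie correction and continuity correction. The conserved-vs-
TRG comparison is two-sided; the GO scan is one-sided for members ranking high.
Exact and asymptotic P agree to about 0.02 at the switchover size —
the continuity correction alone moves mid-range P by ~0.014 — so no
tighter agreement is asserted.

GO annotations are propagated to all ancestors through is_a and (by
default, switchable) part_of. Categories with fewer than 5 members are
dropped, as are categories holding more than 25% of the orthologs that
carry at least one term in the namespace (both bounds strict in the
stated direction: exactly 5 stays, exactly 25% stays). Identical
member sets collapse to the deepest term (shortest-path depth from the
namespace root; ties to the smallest ID). Benjamini–Hochberg FDR is
applied separately per statistic and per namespace, mirroring the
separate biological-process and molecular-function analyses. Category
clustering is UPGMA on 1 − |shared|/min(size); the dendrogram is
exported as newick and fixes the row order of the exported scan matrix.

The expression analysis joins orthologs to six developmental
synexpression clusters (table join, or best nucleotide hit when
cluster sequences are given; score ties prefer the lower cluster
label). TRG overrepresentation uses Pearson χ² without continuity
correction on the 2×K table (Yates is a 2×2 device) with all six
clusters retained. The two-way ANOVA of log₁₀ ω on cluster ×
annotation uses Type II sums of squares for order invariance on
unbalanced data; ω = 0 records are excluded from the log transform and
counted in the run log. With sparse cells (clusters lacking TRG
members) the interaction term is rank-deficient and its F is reported
as NaN rather than imputed.

## The synthetic generator

The generator emulates the statistical structure the screen assumes,
with one master seed and per-gene streams derived by a counter-based
SeedSequence scheme (`[master, stream, crc32(gene_id)]`) so any subset
regenerates identically.

Per gene: ω follows a two-component lognormal mixture — 88% from a
"conserved" component with median 0.23 and 12% from a faster component
with median 0.50 (log-sd 0.6 and 0.8), a minority of which exceeds 1.
By default the faster component coincides with the TRG label
(P(TRG) = 0.12), so the lineage-specific class is genuinely faster —
the contrast the screen exists to detect; a switch decouples them for
null experiments. Divergence t is gamma-distributed with mean 0.12
substitutions per codon (shape 4), which puts synonymous divergence on
the ~0.04–0.1 scale appropriate for congeneric species pairs; κ is 2;
gene length is uniform on 200–500 codons so that true pairs clear the
300-bit pairing cutoff with margin. Codon frequencies are F3x4 built
from nucleotide frequencies (0.3, 0.2, 0.2, 0.3), exercising the
non-uniform-π code paths. Transcripts carry uniform 0–300 nt random
UTRs; species B's strand is random and unknown to the screen. The
protein reference contains translated ancestors of non-TRG genes only;
a 6 kb random mitochondrial sequence provides decoys by embedding a
200 nt segment in ~5% of species-A transcripts. GO assignments draw
Poisson(2) leaf terms per gene from a small synthetic two-namespace
ontology (written as OBO 1.2 and parsed back through the ordinary
reader); planted terms receive exactly their chosen member genes,
whose ω is redrawn from a lognormal with median = effect × 0.23, so a
planted effect of 3 triples the typical member ω. Expression clusters
are assigned independently of ω with the published cluster-size
proportions as weights.

What the generator does not emulate: indels within coding sequence
(alignment gaps still occur through UTR trimming and frame
extraction), sequencing error, chimeric or partially assembled
transcripts, paralogy, and real GO topology at scale. Passing the
round-trip tests therefore demonstrates the machinery is correct under
the model's own assumptions, not that the screen is robust to assembly
artifacts.

## Problem sizes and verification scale

The end-to-end suites run 24-gene bundles (one full screen ≈ 2 minutes
on one core; determinism is checked byte-for-byte on an 8-gene rerun).
Parameter recovery uses 50 replicate 3000-codon pairs at
(t, κ, ω) = (0.2, 2, 0.5) with the median ω̂ required inside ±10%; the
neutrality check (ω = 1) uses the same 3000-codon scale, where the ML
ratio estimator's finite-sample skew is negligible (at a few hundred
codons its mean exceeds 1 by several percent, a property of the
estimator, not a bug). Rank-scan calibration uses 200 replicate null
scans of 50 categories over 1000 genes; planted-category power uses 20
replicates of a 20-gene category with effect 3 among 1000 genes at 10%
FDR. `scripts/acceptance.py` reruns the synthetic screen and the
recovery suite from scratch and writes every quantity it computes.

## Known limitations

Pairwise, gene-wide M0 only: no site models, branch models or
likelihood-ratio tests — with two species those are out of reach, and
an ω below 1 gene-wide can hide positively selected sites. The
internal aligner is exact but O(nm); the package is sized for
desk-scale studies (thousands, not millions, of transcripts). ClustalW
itself is not embedded; the global aligner uses ClustalW-like defaults
(BLOSUM62, open 10, extend 0.1) and is declared an emulation. Exact
reproduction of any specific external program's dS/dN site counts is
not claimed, only of ω under the stated convention.
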