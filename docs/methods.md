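# Methods

This note records the models implemented in `mesoimmunity`, the parameter
choices that matter, the numerical conventions, and what the synthetic
generators do and do not emulate.

## Coordinate and orientation conventions

All genomic coordinates are 1-based, inclusive, on the top strand; internal
converters map to 0-based half-open slices.  The genome "center" is the
midpoint (rounded down) of the prophage-inheritance marker gene — integrase
for integrating phages, parA for extrachromosomal ones.  A repressor-binding
site is *syn*-oriented (with transcription) when it lies on the top strand
left of the center or on the bottom strand right of it; a site whose
midpoint falls exactly on the center classifies by strand ('+' → syn) and
is logged.  Site sequences are always stored sense-converted (reverse
complemented for bottom-strand sites), so motif models are built in a
single orientation.

## Stoperator discovery

The finder is a two-component mixture EM over all sequence windows of one
width (the "any number of repetitions" site model): a window is either a
motif instance (product-multinomial over positions) or 0-order background
estimated from genome composition.  Specifics:

* widths 12–16 are run independently; windows come from both strands.
* initialization: the most frequent exact w-mers (3 starts, ties broken
  lexicographically); motif columns start at 0.7 on the seed base.
* the site prior λ starts at (expected sites)/(windows) with expected
  sites = 30, and is clamped to [1/n, 0.05]; 30 iterations maximum with an
  early stop when no matrix entry moves by more than 1e-4.
* per width the best start is kept, scored by mean per-column information
  content × posterior site count (capped at 50); up to two candidates
  survive across widths.
* a candidate is noise unless its mean information content reaches 1.0
  bit/column *and* its posterior supports at least 10 sites; genomes where
  no candidate passes return a "not found" flag with no sites.  This floor
  separates planted-motif genomes from i.i.d. random sequence in the test
  battery.
* strand orientation of a discovered matrix is mathematically arbitrary;
  when a reference motif is supplied the candidate (and orientation)
  minimizing the motif distance to it is selected — mirroring selection
  against empirically determined reference sites — otherwise orientation is
  canonicalized to the lexicographically smaller consensus.
* final site calling is delegated to the scanner: the threshold is set so
  the site count equals the EM-supported count clamped into [10, 50], and
  the returned model is the count-based PWM rebuilt from the called site
  sequences.  Re-scanning with the returned model at the returned threshold
  reproduces the returned sites.

The scanner reports all non-overlapping hits on both strands at or above a
log-odds threshold, resolving overlaps greedily best-score-first with ties
to the leftmost start and then the '+' strand (palindromic hits are
therefore reported once).

## PWM construction and motif distance

Position probabilities use the log2 probability-ratio scheme with a
√N-scaled pseudocount, `P = (n + k·bg·√N)/(N + k·√N)`, defaulting to
k = 0.8 and uniform background — the conventional defaults of the standard
PWM toolchain, adopted because only "default settings" are specified
upstream.  Log-odds are `W = log2(P/bg)`; with k = 0 degenerate columns
produce −∞ weights, which the scanner treats as hard mismatches.

The motif distance is a per-column Euclidean distance on probability
matrices with a 1/√2 normalization so each column contributes at most 1:
`D = (1/w) Σ_j sqrt(Σ_b ΔP² / 2)`.  It is symmetric, zero iff the matrices
are identical, empirically satisfies the triangle inequality, and is
bounded in [0, 1] (two opposing point-mass columns score exactly 1).  The
exact normalization inside the upstream tooling is not published; this
concrete formula preserves the stated contract (0 iff identical, larger =
more dissimilar) and is the package's own choice.  Unequal widths are
compared by sliding the narrower matrix and taking the best full-overlap
offset.

## Whole-genome distances

`D_Nuc` is an anchor-based estimator engineered to the published endpoints
(0 = identical, 0.5 = no similarity): exact 13-mer seeds against both
strands of the partner genome are merged into maximal exact segments on
their diagonals, segments are tiled greedily longest-first without overlap
in either genome, and the aligned identical fraction
f = 2·matches/(lenA + lenB) gives `D_Nuc = (1 − f)/2`.  The 13-bp seed
matches the stoperator length scale.  Because both strands are seeded the
estimator is invariant under reverse-complementing one genome; a pair with
"no similarity" therefore means no shared 13-mer on *either* strand, and
the synthetic no-similarity construction verifies exactly that.

`D_GC = 1 − mean(|A∩B|/|A|, |A∩B|/|B|)` over pham (gene-phamily) sets
reproduces the published endpoints exactly: 0 when the sets coincide, 1
when they are disjoint.

Protein distances are uncorrected p-distances per 100 aligned residues
from pairwise global alignments (BLOSUM62, gap open 10, extend 0.5);
columns containing a gap carry no weight in either numerator or
denominator, so a clean insertion leaves the distance at 0.  The published
analysis aligned whole phamilies with an MSA; pairwise alignment is this
package's choice and agrees exactly with Hamming/length on gap-free pairs.
The repressor N-/C-terminal split position is configurable; the default of
residue 60 places the boundary just downstream of the 20-residue
helix-turn-helix DNA-binding domain (the published split cites coordinates
not reproduced in print).  The HTH distance is a plain Hamming count on
20-residue domains.

## Immunity scoring and statistics

The ordinal rubric maps plate observations to scores 0–6.  The published
wording leaves the efficiency-of-plating bin edges fuzzy ("less than
~10⁻³–10⁻⁴", "of 1"); the package fixes half-open bins — plaque-forming:
EOP < 1e-3 → 2, 1e-3 ≤ EOP < 0.5 → 3, EOP ≥ 0.5 ("order unity") → 4/5/6 by
plaque phenotype vs the control (weakened → 4, indistinguishable → 5,
strengthened → 6; if both weakening and strengthening marks are present the
weakening reading wins).  Plaque-free: lysis at 0 / 1–2 / 3 / ≥4 of the
highest spot dilutions → 0 / 1 / 2 / 3.  The edges are constructor
arguments (`ScoreBins`).

Replicates are aggregated by arithmetic mean with n/min/max bookkeeping.
ΔΙ is defined over lysogen defenders only (a cloned-repressor strain has no
challenging identity); one-directional pairs are excluded and counted.
Profile correlations default to Pearson (the published analysis names only
"correlation coefficient"); Spearman is available by flag; constant
profiles return an undefined correlation with a warning rather than a
number.  Regressions are ordinary least squares with an optional clade
membership filter reproducing "intra-clade comparisons only" scoping.
Assay-count summaries count unique (challenger, defender, kind) cells;
reciprocal pairs are unordered lysogen pairs tested in both directions;
lysogen–CRS paired comparisons count *comparisons* (two per complete pair
sharing a challenger).

Note on sign conventions: the infection score Ι measures infection
*success*, so Ι rises — immunity weakens — as genotype distances grow.
Profile correlations between two phages fall as their motif distance
grows.  Statements about "immunity" trends are statements about 5 − Ι.

## Mutation notation

The parser covers the compact genotype grammar: substitutions `G44351A`,
insertions `44333:44334 27-bp ins` / `43427:43428 G insertion` (coordinates
flank the insertion; length-only insertions edit as N-runs), deletions
`Δ45310:48001` (inclusive at both ends), recombinations
`rec Tx 44620:44630 and RR 44127:44137` (crossover windows, optionally
genome-tagged), and parenthesized protein annotations (`Rep Q138*`,
`Rep R52fs`, `Δrep`, `rep Δ5' end`, `gp59.2 sense`, `Rep-HA`).  Formatting
is the exact inverse of parsing.  Edits apply right-to-left so parent
coordinates stay valid; substitutions verify the reference base.
Recombinations are represented but never auto-applied — the windows do not
determine the junctions — a helper builds the hybrid from user-chosen
junction points inside the windows (defaulting to window midpoints).

Repressor impact classifies by the first affected codon: substitutions by
translating the parent and mutant codon (silent → sense, stop → nonsense,
else missense); insertions/deletions inside the gene by frame (out-of-frame
→ frameshift, in-frame → missense at the first touched codon); a deletion
covering the gene's 5′ end → 5′ truncation, covering the whole gene →
complete deletion, with those two taking precedence over codon-level calls.
Because real parent genomes are not distributable, the validation suite
reconstructs *synthetic* parents — a bottom-strand repressor ORF laid out
so the catalogued genomic coordinate falls in the annotated codon with the
annotated amino-acid change — and checks the classifier against every
annotated catalog entry; these genomes are stand-ins, not reconstructions.

Escape ("defense escape mutant") virulence breadth uses a configurable
escape threshold, default Ι ≥ 3 (the lowest plaque-forming rubric score): a
defender is a *gain* when the mutant reaches the threshold and its parent
does not.  Gains confined to the parent's own system → narrow homotypic;
gains excluding it across ≤ 2 systems → narrow mesotypic; anything broader
→ broad.  A missing homotypic defender flags the profile rather than
failing.

## Binding fits

Substrates are 30-bp duplexes: 8-bp upstream flank, 13-bp site, 9-bp
downstream flank, cut from the genome in the site's orientation.
Substitution series enumerate subsets of the differing positions between
two sites (all subsets, or the 2^(k−1) subsets containing an anchor
position), ordered by subset size then position, named by the substituted
positions (e.g. `C9G10C11A12`).

The one-site model `Y = Bmax·X/(K_D + X)` is fit by bounded least squares
(K_D > 0; 0 < Bmax ≤ 1.2 — a mild ceiling, since whether the published
fits constrained Bmax is not stated) with deterministic multi-start from
the minimum, median and maximum positive concentration; K_D standard errors
come from the fit covariance.  Percent-bound inputs are auto-normalized
(max > 1.5 ⇒ percent).  All-zero titrations report an above-range K_D
sentinel instead of a spurious estimate.  No cooperative (Hill) term is
offered: monomeric binding shows no cooperativity.  With 8-point titrations
the ±2·stderr interval is a Wald interval at 6 residual degrees of freedom,
so its empirical coverage sits near 90% rather than the asymptotic 95%.

## Synthetic generators

`simulate_clade` evolves four lineage states along a tree (default: a
balanced 16-taxon tree, branch length 0.5; any newick is accepted):
genome background (substitutions at 0.04/site/unit branch), stoperator
consensus (0.3/position/unit), repressor (N-terminal region
0.02/residue/unit, C-terminal 0.06 — the 3× ratio produces the faster
C-terminal drift; the 20-residue HTH window evolves 5× slower than the
N-terminal rate), and pham content (replacement at 0.08/pham/unit from 40
starting phams).  Leaves are assembled deterministically from their evolved
state: the inheritance marker gene (integrase or parA) sits at the genome
center, the repressor ORF is written onto the bottom strand at ~0.88 of the
genome length, one annotation-only gene carries each pham, and 20–30 site
copies of the consensus (5% per-base noise) are planted outside gene
intervals, syn-oriented with probability 0.95.  Because leaf assembly is
keyed to the evolved state, zero-length branches yield byte-identical
genomes.  Rates were chosen once so that pairwise motif distances span
roughly the homotypic-to-mesotypic range across the default tree.

`simulate_immunity` generates scores from distances, not mechanism:
Ι = clamp(round(5·g(β·D − α·promiscuity_defender)) ± ordinal noise, 0, 6)
with g a logistic-tail saturating link (g(x) = 0 for x ≤ 0), β = 8 so the
observed motif-distance range maps onto the full score range, α scaling a
per-defender latent promiscuity that produces reciprocal asymmetry
(α = 0 ⇒ perfectly symmetric scores), 15% ordinal jitter per replicate,
3 replicates per comparison, and heterotypic outgroup pairs forced to
complete superinfection.  This is a deliberate statistical stand-in for the
repressor–operator biophysics — sufficient to exercise every analysis
stage, but it encodes the monotone distance–phenotype link by construction.
Passing tests therefore demonstrate that the pipeline *recovers* planted
structure, not that real phenotypes obey it.

`simulate_plate_observations` samples uniformly inside the rubric cell of a
target score (round-trip identity with the scorer);
`simulate_unrelated_pair` draws two random sequences and re-randomizes rare
13-mer collisions (including reverse-complement collisions) until the k-mer
contents are verifiably disjoint; `simulate_binding` adds seeded Gaussian
noise to the one-site curve, clipped to [0, 1].

All generators take an integer seed and are pure functions of
(config, seed).

## Problem sizes in the test battery

The suite exercises discovery on 50-kb genomes with 20–30 planted sites
(the biological scale), statistic-level tests on 8-taxon 30-kb clades,
regression-sign recovery across 20 seeds of 8-taxon 20-kb clades, and K_D
recovery over 200 seeded titrations — sizes chosen to keep the full suite
around a minute while preserving the regimes the methods target.

## Known limitations

* The EM finder models a 0-order background; strongly biased or repetitive
  genomes may need a higher information-content floor.
* `D_Nuc` is an endpoint-calibrated estimator, not a reimplementation of
  any published alignment pipeline; between the endpoints it is monotone in
  shared exact 13-mer segment coverage, which understates similarity for
  highly diverged but alignable pairs.
* Protein distances are pairwise, not MSA-projected; on heavily gapped
  pairs the two approaches can differ.
* The phenotype simulator contains no repressor–operator biophysics, no
  secondary immunity loci, and no plaque-morphology mechanics; its ordinal
  noise is symmetric.
* Recombinant genotypes require user-supplied junctions; the catalog's
  crossover windows alone do not determine the hybrid sequence.
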