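# Methods

This note documents the models, statistics and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and
the limitations a user should know before applying the pipeline to real
genomes.

## Hit validation and the census

Domain-hit tables (protein, profile, e-value, probability, coverage) stand
in for the output of profile searches against a conserved-domain database.
A protein is retained as a NAP candidate iff at least one hit has e-value
< `validation_evalue` (default 10⁻⁵), probability (when present)
> `validation_probability` (default 90%), and coverage (when present)
≥ `bbh_coverage` (default 0.75; applying the pairwise-alignment coverage
cut-off to hit validation is the conservative reading). Each retained
protein gets exactly one family — the profile of its minimum-e-value
passing hit, ties resolved by higher probability then lexicographic profile
label — making validation idempotent and independent of input order.
Multi-family proteins are deliberately not modeled.

Census cells report, per lineage × family, the total copy count and the
per-genome dose range **over carrier genomes only** (the carrier
convention). Whether the published ranges span all genomes or only carriers
is not stated in the source tables; the carrier convention is assumed
throughout and is what the fixtures encode.

## Presence reconstruction and the core/flexible partition

A census cell (total, dose_min, dose_max) does not determine the underlying
per-genome presence matrix. The *maximum-spread* rule reconstructs
carriers(lineage, family) = min(n_lineage, ⌊total / dose_min⌋) — the
largest carrier count consistent with the cell. It is deterministic,
consistent with every cell of the packaged census, and reproduces the
six-family core under the occupancy rule.

Compartments: **core** iff class-wide occupancy strictly exceeds
`core_occupancy` (0.90 of all genomes; "more than 90%" is the operative
definition); otherwise **conserved flexible** in lineages whose frequency
index reaches `conserved_frequency` (≥ 0.90 by default — the boundary
comparator is configurable because the narrative uses both > and ≥);
otherwise **non-conserved flexible**. A lineage represented by one genome
can only be conserved via an explicit flag, since a frequency of 1/1 is
uninformative.

The paralogue index divides the mean dose over *carrier* genomes by the
number of distinct PFs of that family in that lineage ("average genetic
dose ... for every lineage that encodes" reads as conditional on carrying).
The denominator is per-family-per-lineage; when PF counts are not supplied
it defaults to 1, so the index reduces to the mean carrier dose.

## Clustering

Pairwise identity comes from global Needleman–Wunsch alignment under
BLOSUM62 with gap open 10 / extend 1 (the classic aligner defaults; the
source method states only identity thresholds). Identity is matches over
**all** alignment columns, gap columns included — the stricter,
reproducible denominator — so the 50% clustering threshold is
interpretable. Coverage is the aligned (residue-paired) span of the shorter
sequence over its length.

Greedy clustering processes sequences by decreasing length (ties by id) and
assigns each to the first centroid at ≥ threshold identity, so results do
not depend on file order. BBH triangle clustering filters pairwise hits at
coverage ≥ 0.75 and e-value ≤ 10⁻⁵, computes per-(protein, target-genome)
best hits (max score, tie → min e-value, then lexicographic subject), keeps
mutual pairs, finds triangles spanning three distinct genomes, and merges
triangles sharing an edge; proteins in no triangle stay singletons. BBH is
cross-genome by construction, so within-genome paralogs can only co-cluster
through the identity step — mirroring the two-tool layering of the original
workflow. The pipeline exposes both steps and lets the caller choose the
order, since their exact interplay upstream is underdetermined.

## Physicochemistry

Molecular weight is the sum of average residue masses plus one water
(18.0153 Da), via Biopython. The theoretical pI uses Henderson–Hasselbalch
terms with the pKa set of the classic EMBOSS-style calculator (N-terminus
8.6, C-terminus 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1).
Net charge is strictly decreasing in pH, so the bisection root on [0, 14]
(|charge| < 10⁻⁴) is unique. Structure-aware pKa shifts are out of scope,
and reproducing real-data medians (e.g. a specific Fis median pI) requires
the actual proteomes, which are not shipped. Acidophile/mild-acidophile
cut-points for the pI–growth-pH split are descriptive inputs, not fitted.

## Genomic context

The ±5 kb vicinity window is measured from gene boundaries; any CDS whose
span intersects [start − 5 kb, end + 5 kb] counts, with wraparound on
circular replicons. Strand is ignored for inclusion. The vicinity frequency
index is the percentage of a family's genes with ≥ 1 neighbor bearing a
given KEGG annotation, over genes with a *resolvable* vicinity (≥ 1
annotated neighbor); a repeated annotation within one neighborhood counts
once. The denominator is configurable to "all located family genes" because
the published table does not state it. Origin-relative positions are
(midpoint − ori) mod length, as a fraction of the replicon, quartered into
quadrants from the origin.

## MGE association and inverted repeats

A NAP belongs to an element iff its gene midpoint lies inside the region
(robust to boundary-straddling annotations; full containment is a config
choice away), plasmid replicons capture all their genes, and nested regions
resolve to the innermost. Classification is rule-based and total: plasmid
(whole replicon); ICE (T4SS and integrase); IME (relaxase and integrase,
no T4SS); island otherwise. Hallmark roles come from the input annotations;
a keyword mapper (virB/trb/tra → t4ss, mob/relaxase → relaxase,
xerD/integrase → integrase, ...) is provided for convenience only.

The inverted-repeat finder enumerates palindromic axes; for each axis and
admissible loop length the stem grows outward from the innermost base pair
while the mismatch budget holds. A repeat is reported only when neither a
one-pair outward nor inward extension stays within the budget (maximality),
so no reported repeat is a sub-stem of another on its axis; N never pairs.
This reporting rule is applied literally, which with a nonzero mismatch
budget can leave a mismatched pair at a reported stem's outer edge; the
brute-force oracle in the tests uses the identical rule. The packaged
oriT-like fixture is synthetic: 169 bp carrying two planted repeats with
the published stem/loop dimensions (8 + 10 nt stems, 4 nt loops), verified
to contain exactly those two at min_stem 6, max_loop 10, no mismatches.

## Expression

Depth tracks (bedGraph, 0-based half-open on disk, converted on read) are
binned as mean per-base depth per 10-bp bin — equivalent to reads-per-bin
up to the constant read length, which cancels in normalization. RPGC
divides by total signal / effective genome size (the genome-wide mean
depth), making the genome average exactly 1.0; normalization is idempotent
and invariant to rescaling the raw depth. The effective genome size
defaults to the track length and accepts an explicit constant. Fragment
extension of paired reads is not applicable to depth-track input.

## Phylogenetics

Distances are dissimilarities (100 − % identity) with pairwise deletion of
gapped columns, matching the quantity the analysis reports, rather than
model-corrected distances. Neighbor-joining is the canonical Saitou–Nei
algorithm; Q-criterion ties resolve to the lexicographically smallest pair
of cluster labels (a cluster is labeled by its smallest leaf), branch
lengths are clamped at zero, and additive inputs are recovered exactly.
Maximum-likelihood inference and bootstrapping are out of scope; NJ is the
single standardized tree builder. Robinson–Foulds is the unweighted
bipartition symmetric difference (via dendropy).

## Synthetic data: what it does and does not emulate

`generate_pangenome` draws, per lineage × family, carriers at the stated
presence fraction and doses uniformly on the dose range (the real
within-species dose distribution is unknown beyond ranges;
uniform-on-range is this package's choice). Genome sizes are normal around
the lineage mean. Mobile regions arrive as a Poisson count per genome with
log-uniform lengths on [10 kb, 300 kb] (the scale of the published
elements), each carrying relaxase + integrase (T4SS in half), optional NAP
cargo (`mge_nap_rate` — this, not mere placement, is what plants the
NAP–relaxase covariation), and hallmark genes planted within the 5-kb
window of MGE-resident NAPs at a configurable rate. A decoy fraction (10%)
of genes receives a non-NAP hit with e-value log-uniform on [10⁻⁴, 1] —
entirely above the validation cut-off — to exercise filtering.
`naps_scale_with_size` adds size-coupled extra copies of HU/IHF families to
plant the NAP-count–genome-size covariance. One integer seed drives a
single NumPy generator; identical spec + seed is byte-identical.

Marker sequences evolve by per-site replacement with probability
1 − exp(−rate · branch), uniform over the other 19 residues — the simplest
model with an analytic p-distance expectation (identity between two leaves
is a + (1 − a)/20 with a the product of per-branch 1 − 20p/19 factors).
No indels, no rate heterogeneity, no codon structure, no realistic
nucleotide composition; passing recovery tests therefore demonstrates the
pipeline's statistical machinery, not robustness to alignment error or
compositional bias in real data. Coverage tracks are per-base Poisson
draws — no read-level artifacts, duplicates or strandedness.

Study sizes used by the test suite: frequency-index recovery on one
500-genome lineage (3σ binomial tolerance); covariation sign recovery over
100 replicates of 50-genome pangenomes; marker recovery over 100 replicates
on a balanced 16-leaf tree with pendant/internal branch lengths 0.02/0.01
substitutions per site (pairwise divergences ≈ 4–12%, bracketing the
published core-NAP dissimilarity scale), comparing a 1,000-residue
SMC-like marker against an 80-residue Fis-like marker. These sizes keep the
whole suite under ten seconds while leaving the binomial tolerances
meaningful.

## Known limitations

- Profile searches, read alignment, KEGG annotation and MGE boundary
  detection are consumed as inputs, never recomputed.
- The maximum-spread reconstruction is one consistent completion of the
  census, not the (unpublished) true presence matrix.
- Greedy identity clustering is order-stabilized but still greedy; it is
  not a globally optimal partition.
- The pI model ignores folded-state pKa shifts; values are comparable
  across proteins, not absolute measurements.
- Published correlations that require the 93 downloaded genomes or SRA
  RNA-seq runs (e.g. r = 0.805 NAPs vs genome size, the ~9–12× expression
  peaks) are replaced by sign-recovery properties on synthetic data.
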