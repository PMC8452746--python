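# Methods

This note documents the models and algorithmic choices behind
`clonedeconv`, the assumptions they rest on, and what the bundled
simulator does and does not establish about real data.

## Input model

The unit of input is one patient's *segment file*: one row per detected
genetic alteration with chromosome, 1-based closed start/end
coordinates, alteration type (`gain`, `loss`, `cnni`, `amplification`,
`snv`, `sv`, `other`), data source, and one MCF column per biopsy. MCF
(mutated clone fraction) is the percentage of cells in a biopsy
carrying the alteration, in `[0, 100]`. The package does not estimate
MCFs from raw reads or array intensities except through the VAF
formulas below; upstream tools (or the `mcf` module) must supply them.
Missing MCF cells are preserved as missing and never coerced to a
number.

## Event unification

Copy-number calls for one underlying lesion differ slightly in
breakpoints across biopsies. Two detections are the same event when
they share chromosome and type, neither qualifies as a stem event, and
both breakpoint distances satisfy `|Δstart| ≤ co_ev` and
`|Δend| ≤ co_ev` (inclusive). Defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `co_ev` | 1,000,000 bp | breakpoint measurement uncertainty; 0.4–2 % of a chromosome length |
| `stem_threshold` | 90 % | MCF required in *every* biopsy for a stem event |
| `arm_tolerance` | 5 % | span shortfall allowed when calling whole-chromosome / arm scope |

Merging is the transitive closure (single linkage) of the pairwise
relation within each (chromosome, type) group: chained near-identical
breakpoints across many biopsies collapse into one event, and the
partition does not depend on row order. A first-match greedy mode is
available (`linkage="greedy"`). The unique event's coordinates are
those of its first-seen member; its per-biopsy MCF is the member value,
with the maximum taken (plus a warning) if two members from the same
biopsy merge, and 0 where no member exists.

Missing-MCF policy: an event the user declares stem on biological
grounds (e.g. an amplicon whose cellular fraction is hypervariable)
has missing values set to 100 %; any other event with a missing MCF is
removed with a warning, so intratumor variation is not overestimated.

Genomic scope (whole chromosome / chromosome arm / segmental / point)
is classified against a bundled table of GRCh38 chromosome lengths and
approximate centromere intervals; any genome can be substituted via a
four-column TSV. Scope only affects contradiction exemptions, so
approximate centromeres suffice.

## MCF from sequencing data

For a mutation with variant allele frequency `VAF`, allele-specific
copy numbers `CN_mut`, `CN_wt`, multiplicity `M` (mutated allele
copies, default 1) in a sample of tumor cell fraction `TCF`:

    MSF = VAF · ((CN_mut + CN_wt) · TCF + 2 · (1 − TCF)) / M
    MCF = 100 · MSF / TCF        [percent]

`TCF` is estimated per sample: a Gaussian kernel density estimate
(Silverman bandwidth) of the VAFs in (0, 1], the local maximum closest
to VAF 0.5, times two — the mode of clonal heterozygous diploid
mutations sits at `TCF/2`. At least 10 VAFs are required; otherwise
the user must supply `TCF`. Noise can push `MCF` past 100 %; it is
clipped into `[0, 100]`, with a warning when clipping exceeds 5
points. QC for external sequencing data follows read depth ≥ 10 and
total coverage ≥ 200 in all samples, restricted to mutations lying in
diploid segments in every sample.

## Pre-clustering

Alterations residing in the same cells have identical true MCFs in
every biopsy, so events are clustered as points in B-dimensional MCF
space with DBSCAN. Defaults: `ε = 0.5`, Euclidean distance on the raw
percentage scale, `minPts = 1`. The percent-scale metric makes the
default radius mean "profiles agreeing within about half a percentage
point", which matches the clustering's stated purpose — grouping
alterations that track each other exactly, to reduce search
complexity — rather than clonal inference; a `scale="unit"` option
rescales coordinates by 1/100 for data calibrated on fractions.
`minPts = 1` guarantees no alteration is discarded as noise: every
event must reach the event matrix. The `k`-distance profile (distance
to the k-th nearest neighbor, sorted) is exported for elbow-based `ε`
tuning. Clustering is an optimization only; `--no-precluster` replaces
it with singleton clusters and leaves results on clean data unchanged.
The interface is deliberately small so another grouping method can be
dropped in.

## Subclonal deconvolution

Each biopsy is 100 % of cellular space, partitioned as clusters are
nested (the space matrix, column sums fixed at 100). Placing a cluster
of size `z` inside a partition consumes `z` of the parent's remaining
space; a placement is feasible in a biopsy when remaining space is at
least `z − tol_overlap`. `tol_overlap` defaults to 10 MCF percentage
points — the magnitude of real-world MCF noise; on noise-free data any
small value gives identical results.

One parent per cluster must serve *all* biopsies. The search charges
clusters against their parents in a fixed global order (decreasing
total size, then more members, then id — deterministic) and explores
parent choices by branch-and-bound over the full space of rooted
forests, minimizing lexicographically:

1. number of (cluster, biopsy) capacity violations — each violation
   corresponds to clone sizes that cross between samples and will
   surface as a PLC/BMC in the phylogeny;
2. number of user-rule violations (a mother→daughter ban is enforced
   only when the data allow an alternative placement; if not, the
   placement stands and the user is advised to revise the input);
3. minus the number of biopsies whose single-sample allocation
   supports the placement;

with remaining ties broken by the largest-available-space rule
(earliest-created partition on exact ties). Candidate parents are
ordered greedily, so the first complete solution *is* the classical
decreasing-size / largest-available-space allocation; a search budget
(30,000 placements) guarantees termination on adversarial inputs, in
which case that greedy solution is kept and a warning is emitted. On
instances small enough to enumerate, the result is verified in the
test suite against brute-force enumeration of all forests
(contradiction minimality).

Subclone fractions are `z_self − Σ z_children` per biopsy, clipped at
zero (warning when the deficit exceeds the tolerance). The event
matrix assigns each subclone the union of its own and its ancestors'
cluster events; stem events are present in every subclone. When more
than one violation-minimal forest exists, the alternatives can be
enumerated and sampled (seeded), with a per-cluster certainty count
marking which placements are unique and which are not.

## Phylogenies

Taxa are the subclone genotype columns plus a pseudo-taxon with no
alterations, which becomes the root (the model below is time
reversible, so rooting does not change the likelihood).

**Maximum parsimony.** Fitch small parsimony on the binary characters;
search = NNI hill-climbing from a neighbor-joining start tree on
Hamming distances, wrapped in a ratchet-style loop (50 iterations,
25 % of characters double-weighted, seeded) to escape local optima.
Ancestral states come from per-character minimum-change dynamic
programming; ties are resolved toward changes nearer the root
(accelerated transformation), and integer branch lengths are the
per-edge change counts. The parsimony score is bounded below by the
number of distinct events, with equality exactly when the matrix is a
perfect phylogeny.

**Maximum likelihood.** A symmetric two-state Markov model — the
binary-character analog of an equal-rates, equal-frequencies
nucleotide model — with `P(no flip | t) = (1 + e^{−2t})/2` and
equilibrium (½, ½). Edge lengths of the NJ start tree are optimized by
L-BFGS-B on the Felsenstein pruning likelihood; reported lengths are
rescaled to expected alterations per edge. Topology search by NNI is
available (`nni_moves=True`) but off by default; edge-length
optimization on the NJ topology is the default mode. One caveat of the
two-state model: when half or more of the characters separate two
genotypes the ML distance saturates, so stem edges of very divergent
trees can be overestimated — topology comparisons are unaffected.

**Contradictions.** From the ancestral reconstruction (minimum-change
states for MP, maximum marginal states for ML): PLC = an event gained
on ≥ 2 distinct branches, BMC = an event lost below a gain. Whole-
chromosome and chromosome-arm events are marked exempt (such gains and
losses are biologically plausible); a BMC on a `cnni` event (copy-
neutral LOH) is never exempt, since heterozygosity cannot be regained.

**Statistics.** Stem length = summed length of the initial
non-branching path from the root; branch count = edges below that
path, excluding zero-length pendants (subclones identical to an
ancestral genotype); topology comparison = unordered rooted-tree
isomorphism on subclone labels after collapsing internal edges shorter
than 0.01 alterations.

## The lattice tumor simulator

Purpose: produce spatially structured mixtures of genotypes with known
truth, not realistic tumor growth. One founder cell with one
aberration (the stem event) sits at the origin of an integer lattice
with 26-neighbor adjacency. Per step, a random cell among those with
at least one free neighbor divides; the daughter occupies a uniformly
chosen free neighbor position; with probability `mut_prob` the
daughter acquires one extra aberration with uniformly random
chromosome, breakpoints and type (`gain`/`loss`/`cnni`). Growth stops
at `n_cells` (default 40,000). `mut_target = k` sets
`mut_prob = k/n_cells`, so about `k` subclonal alterations arise per
tumor; the study settings are k ∈ {15, 50, 100}.

Virtual biopsies are Euclidean balls of radius 2 lattice units
(≈ 30–35 cells). Centers are drawn uniformly in the bounding box and
accepted when their distance from the box center lies in
`[r_mean/2, r_mean]`, where `r_mean` is the mean of the six absolute
half-extents of the box — a mid-shell band that avoids both the
homogeneous core and the empty corners; empty draws are retried.
Biopsy MCFs are exact cell fractions, so they satisfy the
subclone-sum identity exactly and the deconvolution reproduces them
with zero residual.

**Accuracy scoring.** A detected alteration is *correctly allocated*
when the full genotype of the subclone it is assigned to equals the
set of mutations in the genotype where it arose (its true lineage),
both restricted to alterations detected in at least one biopsy. The
sweep (`fig4_experiment`) grows one tumor per mutation rate, draws
three independent biopsy sets for each biopsy count 1–10 (90
deconvolution runs), and reports the mean proportion correct — over
all alterations, and excluding alterations found in a single biopsy.

What the simulator does *not* model: MCF measurement noise, detection
limits, selection, cell death, overlapping aberrations on one
chromosome, and multi-allelic events. Passing the simulation suite
therefore shows that the allocation logic is correct when MCFs are
exact; it does not bound performance under real measurement error,
where the overlap tolerance and pre-clustering radius carry the load.
Under this neutral uniform-in-time mutation model, alterations large
enough to be detected in small mid-shell biopsies are uncommon
(an alteration reaching ≥ 1 % of cells must arise within roughly the
first hundred divisions), so a typical simulated segment file contains
only a few alterations; single-biopsy alterations dominate the
residual error, and excluding them yields essentially perfect
allocation — the same error structure the allocation rules predict
(misnesting by largest-available-space when only one biopsy
constrains the order, zero-distance cluster merges of same-fraction
single-cell detections, and absorption of locally fixed alterations
into the stem in single-biopsy runs).

## Cohort analytics

`evaluation.run_cohort` runs the pipeline over a batch of segment
files, recording per tumor: subclone count, MP/ML tree statistics,
whether the two topologies are identical, and PLC/BMC counts before
and after scope exemptions. Tumors whose cells all share one genomic
profile yield an event matrix but no tree and are excluded from tree
statistics. Group comparisons use the two-sided Mann–Whitney U test
(exact null for combined n ≤ 20 without ties, normal approximation
with tie and continuity corrections otherwise). Per-tumor failures
are logged and do not stop the cohort.

## Determinism

Every stochastic component (growth, biopsy placement, ratchet
perturbations, alternative-solution sampling) takes an explicit seed,
and derived seeds are spawned deterministically below 2^31; identical
seeds reproduce identical tumors, segment files, trees and accuracy
numbers bit for bit.

## Known limitations

- The allocation objective counts capacity violations in one fixed
  charging order; pathological crossing instances can admit equally
  minimal forests under a different order.
- The two-state ML model saturates at 50 % character difference (see
  above); branch lengths near saturation are unreliable though finite.
- TCF estimation assumes a visible clonal heterozygous diploid mode;
  heavily aneuploid samples should supply TCF externally.
- The simulator's detection sparsity (few alterations per segment
  file) means cohort-scale claims about dense real tumors rest on the
  patient-data pathway, not on simulation.
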