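# Methods

This note documents the models, algorithms, parameters and design choices
behind `phagescan`, and what its synthetic fixtures do and do not show
about real data.

## Scope and data model

The package operates at desk scale (thousands of sequences, hundreds of
structures) on five representations: protein records (uppercase one-letter
sequences, optional 1-based inclusive genomic coordinates), CA-trace
structure models (ordered Å coordinates, one per residue, optional
per-residue pLDDT read from the PDB B-factor column), domain-hit tables,
defense-system annotation tables, and screen reports. Structure prediction,
domain search and defense-system annotation are upstream of the package:
their outputs are consumed as files (PDB and TSV with a documented column
contract), so synthetic and real data share one code path.

PDB reading policy: first model, first chain, altloc blank or `A`,
residues ordered by sequence number, residues without a CA skipped with a
warning, minimum three residues. AlphaFold2-style monomer models satisfy
these trivially; the policy makes arbitrary PDBs deterministic. mmCIF,
multi-chain complexes and full-atom detail are out of scope — TM-scoring
needs only CA traces.

## Structural alignment

**Kabsch superposition.** Least-squares rigid superposition by SVD of the
cross-covariance of centered point sets, with the usual sign correction of
the smallest singular vector so reflections are never returned
(det R = +1). Rank-deficient (e.g. collinear) inputs still yield a valid
minimizer through the SVD.

**TM-score.** For an alignment with distances d_i under a superposition,
TM = (1/L_norm) Σ 1/(1 + (d_i/d0)²) with d0 = 1.24 (L_norm − 15)^{1/3} −
1.8 Å. d0 is floored at 0.5 Å (configurable) so chains shorter than ~22
residues remain scoreable. All three normalizations (query length, target
length, shorter chain) are always computed, each with its own d0; every
screen threshold applies to the shorter-chain normalization, with a config
switch (`tm_normalization`) since published screens are not always
explicit about the choice.

**Scoring a fixed correspondence** (`tm_from_pairs`) maximizes TM over
superpositions: Kabsch on all pairs, then iterated re-superposition on the
close subset (d_i < max(2 d0, 4.5 Å)), plus restarts from sliding windows
of 20 pairs; the running best is returned and is non-decreasing by
construction.

**Searching for the correspondence** (`structure_align`) is a
TM-align-style heuristic: seed transforms come from gapless threading of
one chain along the other at every offset and from Kabsch superpositions
of fragment pairs on a strided grid (fragment length 20, stride 4), each
seed scored by the TM of the diagonal correspondence it implies; the best
8 seeds are refined by iterative dynamic programming — score matrix
S(i,j) = 1/(1 + (d_ij/d0)²) under the current superposition, global DP
with a flat gap penalty of −0.6 (no extension term) and free terminal
gaps, then TM-optimal re-superposition of the new pairs — for up to 20
rounds or until the TM change falls below 1e-6 or the pair set repeats.
Alignments are sequential (strictly increasing in both indices);
non-sequential alignment is not supported. The search is deterministic for
a fixed configuration.

This heuristic approximates what US-align computes with default
parameters; it can differ on hard pairs (it has fewer seed families and no
secondary-structure stage). All screening claims are therefore validated
on constructed fixtures whose true similarity is known by design, not on
parity with another program. The DP inner loops are numba-compiled; a
~200×200 pair aligns in tens of milliseconds.

## Sequence layer

**Alignment.** Needleman–Wunsch (global) and Smith–Waterman (local) with
BLOSUM62 and affine gaps in BLAST semantics: a gap of length k costs
`open + k·extend`, default 11/1. Traceback is deterministic with ties
preferring diagonal, then up (gap in the second sequence), then left. For
*clustering*, identity = identical columns / all alignment columns
including terminal gaps — a strict, order-stable denominator. For the
*divergence filter*, identity is over the local alignment only (BLAST
`pident` semantics). Scores are verified against exhaustive enumeration at
tiny lengths and against Biopython's `PairwiseAligner` at moderate
lengths.

**E-values.** Karlin–Altschul, E = K·m·n·exp(−λS), with the standard
gapped-BLOSUM62 constants λ = 0.267, K = 0.041; n is the summed residue
count of the reference set. No finite-size edge correction is applied —
at the E-value thresholds used here (0.1, and 10 for hit reporting) the
correction does not change verdicts at these sequence lengths, and the
uncorrected form is exactly reproducible.

**Greedy clustering.** Records are seeded longest-first (ties broken by
id); each record joins the first existing centroid (in creation order)
with global identity at or above the threshold, else founds a new cluster.
This is the partition semantics of USEARCH-style centroid clustering with
the heuristics (k-mer sorting, acceptance windows) replaced by exact
alignment, which desk scale affords; the output is a deterministic
partition with every member within the threshold of its centroid.

**Divergence filter.** A candidate is excluded when any reference yields a
local alignment with identity > 30% or E < 0.1. The identity criterion
applies only to alignments that constitute homology evidence: the HSP must
be a reportable hit (E ≤ 10, the BLASTP reporting default) *and* span at
least 50% of the shorter sequence. The raw Smith–Waterman optimum between
two unrelated proteins is almost always a 3–12-column chance segment at
30–100% identity; without the span condition the identity rule would
discard unrelated and related candidates alike. With it, measured on
random 100–200-mers against three references, ~94% of unrelated candidates
are retained (the remainder excluded by genuine chance E < 0.1), while
copies diverged to 35–50% identity are always excluded. Both gates
(`hit_evalue`, `hsp_min_cover`) are parameters.

## Physico-chemical filter

Net charge is the Henderson–Hasselbalch ampholyte sum: +1/(1+10^(pH−pKa))
per basic group (N-terminus, K, R, H), −1/(1+10^(pKa−pH)) per acidic group
(C-terminus, D, E, C, Y); X contributes nothing. Charge is strictly
decreasing in pH, so the isoelectric point is the unique root, found by
bisection on [0, 14] to |charge| < 1e-4 (≤ 100 iterations; non-convergence
only signals a corrupt pKa table). The default pKa set is EMBOSS;
absolute pI values are table-dependent, but the ≤ 7 / > 7 partition the
screen relies on is robust for clearly acidic or basic sequences. The
boundary is inclusive: pI exactly 7.0 is retained. The filter is applied
to cluster centroids; members inherit the verdict through the report's
membership list.

## Island mining and prevalence

Within each contig, systems are sorted by start; every **adjacent** pair
whose edge-to-edge gap (right.start − left.end − 1) lies in [1000, 15000]
bp — both bounds inclusive — forms a region. Only adjacent pairs qualify:
a third system inside a wider gap would split it, and restricting to
adjacency prevents double-counting intervening genes. A gene counts as
intervening only when both ends lie strictly inside the open interval
between the system footprints; genes straddling a boundary likely belong
to the systems and are excluded. Distance is edge-to-edge (not
midpoint-based), matching the intent of collecting the proteins *between*
two systems; both the window and the containment rule are parameters.

Prevalence of a marker among genomes carrying a system: total = distinct
genomes with ≥ 1 annotation of the system, carriers = those also in the
marker-hit set; genomes with the marker but not the system count toward
neither. Percent is rounded half-up to two decimals (21/7308 → 0.29%).
The rate is undefined (an error) when no genome carries the system.

## Screening cascades

Stage orders follow the discovery workflows; per-candidate predicates
(length, divergence, pI, domain) commute and are verified to do so, while
clustering does not and is pinned in place.

* **Acr screen**: length ≤ 200 aa → cluster at 95% identity (centroids
  proceed) → divergence vs reference Acrs → pI ≤ 7 → no domain hit at
  E ≤ 0.01 → structure availability (a logged exclusion stage, not an
  error — real catalogs have models only for a subset) → TM ≥ 0.6 vs any
  reference. The best hit per reference is flagged, and the full hit list
  is kept.
* **Defense screen** (on island-mined intervening proteins): cluster at
  50% → no domain hit → length ≥ 200 aa (inclusive at 200) → structure
  availability → TM > 0.65 → divergence vs the references.
* **Counter-defense screen**: per candidate×reference pair, retain iff
  TM(shorter) > 0.6 AND shorter ≥ 70% of longer AND no detectable
  sequence similarity; all three criteria are reported per pair.
* **Fusion scan**: candidates with TM ≥ 0.6 hits to two distinct
  references; the candidate-side aligned residue sets of the two best
  hits are compared, and Jaccard < 0.25 flags a putative fusion. The 0.25
  segment-disjointness threshold is this package's operationalization of
  a qualitative idea and is exposed in the config.

Every screen emits a funnel log with per-stage (n_in, n_retained,
n_excluded); conservation and chaining are enforced at construction time,
so a funnel that drifts from its reports cannot be produced.

## Synthetic data: what it emulates, and what it does not

Generators are fully deterministic (one seed → byte-identical files).

* **Folds** are ideal geometries: helix (radius 2.3 Å, rise
  1.5 Å/residue, 100°/residue), strand (3.5 Å/residue with a 0.5 Å
  zig-zag), helix hairpin (two antiparallel helices, 4-residue turn),
  coil (self-avoiding 3.8 Å random walk). Same-archetype pairs score high
  TM, cross-archetype pairs score low — which is the property the screens
  consume — and the ideal geometry makes oracle TMs computable.
* **Structural homology** is Gaussian coordinate noise (σ per axis) plus
  a random proper rigid transform: a monotone, controllable TM
  degradation. σ = 0.8 Å on these folds keeps TM(shorter) ≈ 0.8–0.9.
* **Sequences** have controlled acid/base composition and controlled
  pairwise identity (iterative substitution to a target global identity;
  the random floor is ~5%). Planted homologs get sequences drawn to be
  invisible to the divergence filter and acidic (pI ≤ 6.5), emulating the
  remote-homolog regime where only the fold is conserved.
* **Genomes** are one contig each, a BREX system plus systems from a
  small pool, inter-system gaps drawn inside [1000, 15000] bp with
  probability 0.6 (else deliberately outside on either side), intervening
  genes fully inside in-window gaps, plus occasional boundary-straddling
  genes that must not be counted. Decoy intervening proteins come from a
  small redundant pool (mirroring catalog redundancy and keeping 50%
  clustering cheap); some carry domain hits, some are sub-200 aa, so
  every defense-screen stage is exercised. The marker is planted in
  exactly round(prevalence × genomes) genomes — count rounding, not
  Bernoulli — so prevalence recovery is exact rather than stochastic.

What passing these fixtures shows: the decision logic, thresholds,
bookkeeping and numerics behave exactly as specified at realistic signal
levels. What it does not show: performance on real evolutionary
divergence (ideal archetypes are cleaner than AlphaFold models; real
remote homologs have indels, domain rearrangements and low-confidence
regions), calibration of the TM heuristic against US-align on hard pairs,
or robustness to annotation noise in real PADLOC/CDD output.

## Default study conditions and problem sizes

End-to-end validation runs the Acr screen on 50 decoys + 3 plants
(references: hairpin 90 aa, helix 70 aa, strand 64 aa; plant noise 0.8 Å,
rigid transforms on) across 5 generator seeds, and the defense pipeline on
400 genomes at 5% marker prevalence — sizes chosen so a full validation
cycle completes in about a minute on one CPU while every filter stage and
failure mode stays populated. All thresholds sit in one dataclass
(`ScreenConfig`) and one YAML config per pipeline run; the run manifest
records the config snapshot, input checksums, seed, funnel counts and
per-stage wall clock, so identical inputs reproduce identical outputs.

## Known limitations

* The TM search is sequential-only and lighter-seeded than US-align;
  scores on genuinely hard pairs may be underestimates (never inflated —
  every reported TM is realized by an explicit superposition).
* Karlin–Altschul statistics use fixed gapped constants without
  composition- or length-adjustment; E-values near a threshold can differ
  from BLAST's.
* Greedy clustering is O(records × centroids) exact alignment — fine for
  thousands of sequences, not millions.
* The pI model ignores post-translational modification and local
  electrostatic environment, as any sequence-only model must.
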