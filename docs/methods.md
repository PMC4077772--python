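# Methods

This note records the models and procedures implemented in `rfamide`, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the package's numerical conventions. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Precursor annotation

**ORF scan.** Forward strand only — the input is oriented cDNA, not genomic
DNA. Every ATG opens a candidate ORF that runs to the first in-frame stop;
ORFs reaching the sequence end without a stop are kept but flagged
incomplete. A codon containing N is treated as untranslatable and the ORF is
dropped: a conservative, loud failure rather than a guessed translation. ORF
coordinates exclude the stop codon, so an n-residue precursor corresponds to
a 3n-bp ORF. Coordinates are 0-based half-open internally; report writers
print 1-based inclusive positions, the convention of the sequence-databank
literature.

**Signal peptide.** Secretory leaders are detected with a two-part
heuristic: (i) a hydrophobic core — maximum 7-residue mean Kyte–Doolittle
hydropathy ≥ 1.6 within the first 40 residues; (ii) the von Heijne (−3,−1)
rule applied downstream of the core: a cut at position p requires a small
neutral residue (A/G/S/C/T/Q) at p−1 and a small or aliphatic residue
(A/V/S/C/T/G/I/L) at p−3, searched over the eight positions after the core;
the candidate closest to the core is taken. Window, threshold and search
limit are keyword arguments. Proteins shorter than 15 residues cannot carry
a cleaved leader and return "absent". This is deliberately a transparent
weight-free heuristic, not a trained predictor (no weight matrices, no HMM):
its role in the pipeline is to set the mature-region origin, and every
decision it takes is reproducible by an exhaustive scan (the test oracle).

**Convertase cleavage.** Three motif classes, all cutting C-terminal to the
motif: dibasic pairs (KR/RR/KK/RK), furin-type tetrapeptides [K/R]-X-X-R,
and a single basic residue immediately preceded by Gly — the
amidation-competent monobasic site, where the Gly is the amide donor.
Overlapping motifs are all reported and excision uses the union of cut
points (maximal fragmentation), so a tetrapeptide flank such as RSGR and its
embedded Gly+R site simply coincide on the same cut. One restriction is
imposed on top of the raw motif grammar: **proline blocks processing** — the
X positions of [K/R]XXR may not be Pro, and no cut is reported immediately
before a Pro. Without this, the R-P-Q-R tetrad inside every PQRFamide
peptide (…W-R-P-Q-R-F-NH₂) would be scored as a cleavage site and the
pipeline would destroy exactly the peptides it is meant to find; proline's
rigid backbone adjacent to the scissile bond is a standard explanation for
uncleaved basic sites in prohormone processing. A known residual limitation:
a mature peptide that itself *begins* with Gly-basic (e.g. GR…) presents an
internal amide-donor signature that the scanner cannot distinguish from a
processing site; such peptides would be over-fragmented.

**Excision and amidation.** Segments between consecutive cuts (bounded by
the signal end and the protein end) are trimmed of trailing basic residues
(motif material), then a remaining C-terminal Gly followed by a basic
residue marks amidation: the Gly is removed and the peptide flagged
amidated. Length bounds 3–50 aa suppress fragments and spacer debris while
spanning the known RFamide size range. By default only amidated peptides are
reported — the C-terminal amide is constitutive for this family and
non-amidated segments are spacers or propeptide material; a flag keeps all
segments for exploratory use.

**Family classification** is a pure function of the amide flag and the
C-terminal five residues, tested in priority order LPXRFa (LP[L/Q]RF) before
PQRFa (PQRF) before generic RFa (RF); a non-amidated sequence is always
"other". The priority matters because LP**Q**RF also ends in PQRF.

## Mass spectrometry

Monoisotopic residue masses; neutral mass M = Σ residues + 18.010565 (water),
C-terminal amidation replaces OH by NH₂ (Δ = −0.984016 Da), protonation adds
1.007276 Da. Average masses are available behind a flag for display
purposes; all printed matches in the RFamide literature are monoisotopic.
Fragmentation is modelled as singly charged b/y series only — what MALDI
post-source decay produces — with b_i = Σ(first i residues) + proton and
y_i = Σ(last i residues) + water (+ amide Δ) + proton; a/x/c/z series,
multiple charges, isotope envelopes and modifications other than the
C-terminal amide are out of scope. The ladder satisfies the complementarity
identity b_i + y_{n−i} = [M+H]⁺ + proton, which the tests assert for random
peptides.

Matching assigns each theoretical ion its nearest observed peak within a
flat, symmetric tolerance (default ±0.5 Da — generous against the 0.1–0.3 Da
accuracy of reflectron MALDI-TOF instruments, chosen so the printed
observed-vs-calculated gaps of the amphioxus peptides fall well inside). A
peak may serve several theoretical ions only when those ions are themselves
closer than the tolerance (flagged ambiguous); otherwise only the nearest
claimant keeps it. Candidate ranking orders by precursor-matched,
then fragment coverage, then |precursor error|, with the sequence string as
a final deterministic tie-break. No calibration model is fitted: the peak
lists this pipeline consumes are externally calibrated, and the tolerance is
treated as flat across the mass range.

## Phylogenetics

Distances: p (mismatch fraction over comparable sites) or Poisson-corrected
d = −ln(1−p), with pairwise gap deletion by default (complete deletion
behind a flag). p = 1 or an empty comparable-site set raises an explicit
undefined-distance error naming the pair rather than producing infinities.

Neighbor joining follows Saitou–Nei: minimise
Q(i,j) = (m−2)d(i,j) − r_i − r_j, join, branch lengths from the standard
formulas, reduce the matrix with the usual average rule. Two determinism
choices: Q ties resolve to the lexicographically smallest pair of cluster
representative labels (the smallest leaf label in each cluster), so label
permutations yield identical trees; and negative branch-length estimates are
clamped to zero with an explicit warning, never silently. Bootstrap supports
resample alignment columns with replacement; replicate r uses substream r of
one seeded generator (`numpy` `SeedSequence.spawn`), so runs are reproducible
and trivially parallelisable. Supports are attached to leaf bipartitions —
each split canonicalised to the side excluding the alphabetically smallest
taxon — not to node order, so rooting and serialisation cannot corrupt them.
Replicates whose resampled matrix is undefined are redrawn and counted, with
a hard cap that raises advising a model or data change. Outgroup rooting
places the root at the midpoint of the outgroup's pendant edge on a clone of
the input tree. Newick IO preserves absent branch lengths as absent (None,
never 0) and internal-node support labels.

## Synteny

Neighborhoods are the k genes (default 10) on each side of the focal gene on
its scaffold, ordered by start coordinate — gene order, not bp distance,
because assemblies of unequal contiguity are being compared. Conservation
statistics: shared count (A-window genes with an ortholog in the B window;
set semantics so tandem duplicates count once), Jaccard index
shared/(|A|+|B|−shared), and the longest collinear run — an LCS over the
ortholog relation, maximised over B forward and reversed, so whole-scaffold
reflection leaves it invariant. With many-to-many ortholog maps the
count-once convention makes the shared count direction-dependent (one A gene
with three B partners contributes 1 forward but 3 in reverse); symmetry of
the Jaccard index under A/B swap is therefore guaranteed only for one-to-one
maps, and the map flags many-to-many-ness. The permutation null replaces the
B focal gene with a uniformly random B gene and recomputes the shared count;
p = (1 + #{null ≥ obs})/(1 + n_perm), the standard add-one empirical
estimator, which can never return 0.

## Synthetic data

All generators are pure functions of (seed, parameters).

**Precursors** are built from the same grammar the annotator decodes: a
Met + hydrophobic leader that satisfies the hydropathy/(−3,−1) rule, then per
peptide a spacer, an N-flank (dibasic or [K/R]XXR), a body over residues
chosen to be side-effect-free (no basics, Gly, Pro, or strongly hydrophobic
residues), the family suffix, the amide-donor Gly and a basic C-flank; a
spacer tail pads the protein past the default 50-codon ORF minimum. Reverse
translation draws synonymous codons uniformly (codon-usage bias is
irrelevant to every consumer); UTRs avoid ATG so the planted ORF stays the
longest. The generator re-annotates its own product and fails loudly if the
round trip is not exact, making the zero-noise contract structural. This
grammar emulates precursor *architecture*, not real sequence composition:
spacers are compositionally unnatural, and passing round trips demonstrate
rule consistency, not performance on real cDNA.

**Spectra**: every precursor [M+H]⁺ and full b/y ladder perturbed by
Gaussian(σ) m/z error (default σ = 0.1 Da, matching reflectron-MALDI-scale
accuracy), plus uniform noise peaks; intensities log-normal with noise an
order dimmer. No isotope structure, detector saturation or
retention-time dimension.

**Alignments** evolve down a tree under a 20-state Markov chain:
substitution events at rate 1 per site per unit branch length, the new
residue uniform over the other 19 — so branch lengths are expected
substitutions per site and
P(two states differ | path length t) = (19/20)(1 − e^(−20t/19)),
the closed form the statistical tests check against. The Poisson distance
−ln(1−p) is the infinite-alphabet limit of this model and slightly
underestimates long path lengths (at t = 1 the bias is ≈ 7%); the
transformation is monotone, so neighbor joining remains consistent, and
the 8-taxon recovery test (branch lengths 0.1–0.2, 500 columns, ≥ 95 of 100
seeds) quantifies the practical effect. No indels are simulated; gap
handling is exercised by hand-built fixtures instead.

**Synteny tables**: two single-scaffold tables with
round(shared_fraction · 2k) of the A focal gene's 2k neighbors given
ortholog partners among the B focal's neighbors, order-preserving (so the
planted collinear run equals the planted shared count), remaining genes
unrelated. No rearrangement process beyond the planting; inversions exist in
the statistics (order reversal) but not in the generator.

## Problem sizes

The shipped analyses and tests use desk-scale sizes chosen to exercise every
code path with comfortable statistical margins: 3-peptide precursors
(~90 aa), 8-taxon 500-column alignments with 100–1000 bootstrap replicates,
41–201-gene scaffolds with k = 10, and 999 permutations. All are parameters;
nothing in the implementation assumes these values.

## Known limitations

- The signal-peptide heuristic is rule-based; on real proteomes a trained
  predictor (out of scope here) is more accurate.
- The cleavage grammar cannot recognise a mature peptide that begins with
  Gly-basic (see above); convertase context beyond the motif (P1'
  preferences, secondary structure) is not modelled.
- Only singly charged b/y ions; spectra from ESI instruments (multiply
  charged) need a different ladder.
- The Poisson distance mismatches the 20-state generator at long branches;
  no rate heterogeneity or empirical exchange matrices (JTT etc.).
- Ortholog inference is consumed, never performed; many-to-many maps break
  Jaccard symmetry by design (count-once semantics).
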