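# Methods

## Matching model

The scanner is an exhaustive sliding-window matcher over unaligned
sequence, equivalent for full-length ungapped hits to what probe-matching
web tools and BLASTn-short report at a 0-mismatch tolerance. Gapped or
partial alignments are intentionally not modelled: a FISH probe or PCR
primer either anneals along its full length or it does not, at the
stringency this analysis assumes.

Per aligned position, the subject symbol matches the oligo symbol iff the
subject's IUPAC expansion set is a subset of the oligo's. This is
asymmetric on purpose: degeneracy in the oligo (e.g. 515F's `Y`/`M`)
broadens what it accepts, while ambiguity in the subject means the
deposited base is uncertain and cannot be claimed as a match. A subject
`N` is never a match; it is tallied against a separate N allowance
(`ScanPolicy.max_subject_n`, default 0) rather than the mismatch budget
(`max_mismatches`, default 0), mirroring the usual "0 N's" control.
Internally symbols are 4-bit expansion masks, so the subset test is
`subject_mask & ~oligo_mask == 0` and a window is scored with one
vectorized pass per oligo position.

Orientation: FISH probes are complementary to the rRNA, so the default
scans the probe's reverse complement against the deposited gene-sense
sequence (`probe_orientation="revcomp_of_probe"`). `as_is` and `both` are
available because public probe-matching services do not document their
convention; results in this package use the default. Primers are always
scanned as written (forward) or as their reverse complement on the sense
strand (reverse, inside the PCR simulation).

Coordinates are 0-based half-open throughout; a sequence with several
binding sites counts once in every statistic.

## In-silico PCR

A sequence is amplifiable by a primer pair iff some forward-primer site
lies upstream of, and does not overlap, some site matching the reverse
primer's reverse complement, and the spanned interval length is within the
pair's amplicon bounds. Default bounds are region-specific (e.g. 200-700 nt
for V4-V5) and exist to suppress spurious distant pairings; the generic
default is [50, 2500]. Amplifiability implies both single primers match,
so pair coverage never exceeds the smaller single-primer coverage.

### 5'-end (27F) evaluability

Many deposited 16S sequences are 5'-truncated or primer-clipped, and
counting them against a 27F-anchored primer set would understate its
coverage. The omission rule is operationalized as: a sequence is evaluable
iff a relaxed match to the 27F pattern (mismatch budget + 2) starts within
the first 25 nt. The widened budget detects the primer *region* even in
sequences the strict scan would legitimately fail; the 25 nt window and +2
relaxation are this package's choices, configurable at the call site.
Databases whose sequences are uniformly primer-clipped are better handled
with the per-database `skip_27f_sets` mode, which reports the 27F sets as
"not evaluated" instead.

## Coverage statistics

Coverage is `round_half_up(100 * n_target_hit / n_target, 1)`. Half-up
rounding at one decimal is fixed (via `decimal.Decimal`) so that published
one-decimal figures are bit-reproducible from integer counts. An empty
target group yields an *undefined* coverage (`None`, `NA` in reports),
never 0.0, to avoid fabricating coverage for absent taxa. Non-target hits
are aggregated by each out-group sequence's lowest available rank label
(genus where present), matching how such results are conventionally
narrated. Mix coverage is the set union of member hit sets; the Venn
partition is exact over binding signatures and is refused above 6 oligos
(2^n regions), where a pairwise co-coverage matrix is offered instead.

The packaged table of published per-probe evaluation counts records, for
each probe x database, the printed group size, targeted-hit count and
coverage percentage, plus a `consistent` flag. Five rows are flagged where
the printed percentage cannot be reproduced from its own printed counts
(for two of them the publication's own running text computes the
hits/group-size value). This package always follows the hits/group-size
definition and preserves the discrepancy in the table rather than matching
both figures.

Copy-number correction divides each relative abundance by the taxon's 16S
gene copy number and renormalizes. It preserves the simplex, is invariant
to uniform scaling of copy numbers, and fails hard on a missing copy
number. The shipped copy-number table uses genome/MAG-derived values
(2 for *Ca.* Accumulibacter and *Defluviicoccus*, 1 for the
Actinobacteria-affiliated PAOs and *Ca.* Competibacter, 4 for
*Dechloromonas*, whose reported range is 3-4).

## Taxonomy refinement

Pairwise identity is computed from a deterministic global alignment
(match +1, mismatch -1, linear gap -2; traceback ties resolved diagonal
first, then up, then left) as identical aligned positions divided by the
*shorter* sequence length — the CD-HIT convention, adopted so cluster
results are comparable to CD-HIT runs. Clustering is greedy-incremental:
sequences sorted by descending length (ties by id), the longest unassigned
sequence seeds a cluster and recruits everything at or above the cutoff.
Defaults follow the operational 16S boundaries: 98.7% (species) and 94.5%
(genus); both are parameters, not constants.

Tree-based manual taxonomy confirmation is deliberately replaced by
nearest-reference assignment: a query inherits the label of its
highest-identity confirmed reference if that identity clears the genus
cutoff, else it is "unassigned" (raising the cutoff can only abstain,
never relabel). This is sufficient to build refined explicit-id target
groups for coverage runs; it does not reproduce clade-level curation that
required externally curated reference sequences, which the API accepts as
an input but does not bundle.

## Synthetic databases

The generator emulates the features of a reference 16S database that the
pipeline is sensitive to: clade structure (per-taxon ancestors mutated
from a common root at 5-15% divergence, members within 1.3% of their
ancestor, i.e. inside the species boundary), sequence lengths of
1200-1500 nt by default, probe-binding sites planted as the reverse
complement of the probe with degenerate positions resolved uniformly at
random (so subject-side IUPAC handling is exercised), primer amplicons
planted as forward + sense-strand reverse-complement sites at an in-bounds
distance, a configurable fraction of `N` positions outside planted sites,
and an exact count of 5'-truncated records. Probe sites are planted at or
beyond a configurable offset (default 350 nt) chosen to exceed the maximum
truncation length, so truncation affects primer evaluability but never
probe truth; the generator rejects configurations where this cannot hold.

Truth is exact by construction: each background draw is rejection-resampled
until no unplanted oligo site exists at the configured stringency, and the
finished database is re-scanned in full against the truth object before it
is returned. Determinism: one `numpy` generator seeded from the single
config seed drives every draw in a fixed order, so identical (config,
seed) pairs reproduce the FASTA byte-for-byte.

What the generator does *not* model: 16S secondary structure and conserved
domain architecture, real primer-site sequence context, chimeras, and
database-specific annotation noise. Passing planted-truth tests therefore
demonstrates that the statistics are computed correctly, not that any
probe performs well on real data — real-database numbers require the real
release.

## Problem sizes used in the checks

The automated checks run at sizes chosen to exercise every code path while
staying cheap: scanner-vs-brute-force agreement over 10,000 random
(oligo 15-25 nt, subject 20-300 nt, budgets 0-2) cases; planted-truth
recovery over 50 seeded databases of 14 sequences x 500-600 nt; clustering
oracle comparison on 40 sequences of 160 nt at both cutoffs; label
recovery for 100 queries mutated at 2% from 5 references. Evaluating a
full non-redundant SILVA/MiDAS release uses the identical code paths via
the CLI and is a matter of supplying the downloaded FASTA.

## Known limitations

- No hybridization thermodynamics: formamide concentrations are carried as
  metadata only; a mismatch-bounded string model cannot rank probes by
  melting behaviour.
- No gapped matching; an oligo with an indel relative to the subject is
  simply a non-match.
- Nearest-reference assignment is a simplification of phylogenetic
  curation; clade-level (below genus) refinement needs curated clade
  references supplied by the user.
- The published-counts table reproduces printed figures only up to the
  five documented internal inconsistencies flagged within it.
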