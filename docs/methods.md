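# Methods

## The problem

Nanopore basecallers are trained on a limited set of DNA modifications (5mC,
5hmC, 6mA). A modification type absent from the training data perturbs the
pore current and produces a *systematic* mismatch: most reads carry the same
wrong base at the same genomic position. Read-consensus polishers (Racon,
Medaka) cannot remove such errors, because the consensus itself is wrong.
`modpolisher` corrects them after assembly by combining three orthogonal
signals at each draft position:

1. **allele discordancy** — the fraction of read bases differing from the
   major allele, `1 − max(counts)/Σcounts`. Modification-mediated errors are
   not perfectly systematic; a minority of reads still call the true base.
2. **mean basecall quality** — the arithmetic mean of the Phred scores of the
   read bases at the position. Basecallers emit depressed qualities where the
   signal does not fit their model.
3. **homolog conservation** — the fraction of closely related genomes,
   aligned to the draft, that share the majority allele at the position.
   Modified motifs are conserved within a lineage; a true base wrongly called
   in the draft is still present in the relatives.

A locus is a *candidate* when discordancy > 5% **and** mean quality < 15
(strict inequalities; both thresholds are exposed as parameters). A candidate
is *corrected* to the homolog consensus allele only when all aligned homologs
agree on it (100% conservation), the allele differs from the draft base, and
— by default — the allele is observed among the read bases at the locus
("the alternative allele concordant with the homologs"; `--allow-unseen-allele`
relaxes this). Everything else is logged as skipped with a reason. The rule
set is deliberately specificity-first: a genuine strain variant, where every
homolog disagrees with the draft but the reads support it confidently, fails
the quality/discordancy gates and is never touched.

**Motif-aware mode.** When the user names a modified motif (e.g. `CCGAC`,
IUPAC W/S accepted), the conservation bound at loci lying inside a motif
occurrence is relaxed from 100% to 80%. A placement is tested on both strands
and the candidate position itself is treated as a wildcard: the draft base at
a modified locus is often the error, and would otherwise break the very
occurrence that marks the locus.

Corrections are substitutions only; coordinates never shift, and polishing is
idempotent (the corrected base now equals the homolog consensus, so the locus
is skipped on a second pass).

## Homolog selection

Candidates come from a local directory of genomes (or a prebuilt sketch
database); there is no network retrieval. Selection is two-staged:

- **MinHash screen.** Each genome is reduced to the bottom-`s` (default 1000)
  64-bit hashes of its canonical k-mers (k = 21, Mash's defaults; canonical =
  lexicographic minimum of k-mer and reverse complement). The hash is a
  seeded murmur-style 64-bit finalizer applied to the 2-bit-packed k-mer, so
  sketches are bit-reproducible and k is limited to 31. The Jaccard
  similarity is estimated with the merged bottom-`s` convention (sample =
  bottom `s` of the union of the two sketches) and converted to identity via
  the Mash distance `d = −(1/k)·ln(2j/(1+j))`. The top `t` (default 20)
  genomes with identity strictly above 0.95 survive.
- **Fragment ANI/ASI.** Each survivor is chopped into non-overlapping 3 kb
  fragments (terminal remainder under 1.5 kb dropped — the candidate homolog
  is the fragmented query, aligned against the draft) and each fragment is
  aligned by edit distance (edlib, infix mode). A fragment is *aligned* when
  its identity `1 − edits/length` is at least 0.80 (configurable). ANI is the
  mean identity of aligned fragments; ASI is the percentage of fragments that
  aligned, penalizing structural variation that ANI ignores. Retention
  requires ANI > 99 and ASI > 90 (strict). When fewer than 3 genomes survive,
  the strict filters are waived and all Mash-screen survivors are used, with
  `fallback_used` flagged in the output.

Multi-record FASTA files are concatenated per file for sketching; fragments
never span record boundaries in spirit because the homolog is fragmented, not
the draft.

## Pileup statistics

Read and homolog alignments (SAM/BAM, read through pysam) are reduced to a
dense per-position table: four read allele counts, four homolog allele
counts, and the quality sum. Only aligned (M/=/X) bases count; insertion and
deletion gaps, soft/hard clips and N calls contribute nothing (the target
error class is the mismatch). Secondary, supplementary and unmapped records
are excluded; MAPQ is not filtered by default (`min_mapq` exists). Quality
averaging is done in Phred space (arithmetic mean of Q values). Homolog
evidence is count-only — a genome has no base qualities — and each homolog
genome (identified by query name) contributes at most one count per draft
position however many records it produced. Conservation is evaluated over
homologs actually aligned at the locus; uncovered homologs abstain, and a
minimum homolog depth of 3 (plus a minimum read depth of 5) guards against
meaningless conservation estimates. SAM's 1-based coordinates are converted
to 0-based half-open internally; contigs are processed independently.

## Motif recovery

The corrected loci should pile up on the modification motif. Each corrected
position contributes the width-11 window centered on it (windows overhanging
a contig end are dropped), taken from the *polished* sequence so the restored
base does not corrupt the signal. Windows are strand-canonicalized
(lexicographic minimum of window and reverse complement), making the report
invariant to the strand the genome was written on. The report contains a
4×width position frequency matrix; a consensus string (single base at column
frequency ≥ 0.75, two-base IUPAC code when the top two sum to ≥ 0.9, else N);
and a ranking of the strand-canonical k-mers (default k = 5, matching the
pentanucleotide motifs of interest) overlapping the center position, with the
fraction of windows containing each. Because canonicalization flips roughly
half the windows, a motif and its reverse complement (GCAGC/GCTGC) merge into
one canonical pentamer while the consensus shows the ambiguity code (GCWGC).
Where the modified base sits inside the motif is not assumed: windows are
centered on the corrected position and the k-mer scan covers all offsets.

## Synthetic truth sets

The generator emulates the observed error phenomenology, not the nanopore
signal. Defaults (the study conditions used throughout the tests):

| parameter | default | meaning |
|---|---|---|
| length | 50 kb | single contig |
| motif / sites | GCAGC × 60 | planted non-overlapping occurrences |
| modified loci | 40 | error at the motif's central base |
| decoy loci | 20 | strain variants: homologs ≠ draft, reads support draft |
| homologs | 10 at SNP rate 0.005 | ≈ 99.5% ANI, ASI 100 |
| depth | 30× (2 kb tiled reads) | substitution-only, exact CIGARs |
| modified pileup | 30% truth allele, Phred 6–12 | discordancy ≈ 0.3, mean Q ≈ 9 |
| background | 1% error, Phred 20–30 | discordancy ≈ 0.01, mean Q ≈ 25 |

The draft error allele follows a fixed truth→error transversion table; the
modified base is planted at the center of the pentamer. Homologs carry the
truth allele at every modified locus (a `modified_locus_conservation` dial
lowers this for motif-mode experiments, e.g. 0.9 → 9 of 10 homologs), carry
the decoy allele at every decoy locus, and never receive SNPs at planted
loci. Reads are emitted pre-aligned (SAM with exact CIGARs) so no external
aligner is needed; FASTQ is written for optional minimap2 integration. All
randomness flows from one seed; a fixed seed reproduces every file byte for
byte.

What the generator does **not** model: homopolymer indels, chimeric or
clipped reads, coverage fluctuations, multi-replicon genomes, or basecaller
quality-score miscalibration. Passing tests therefore demonstrate the logic
of the gates, not performance on real flowcell data.

## Quality evaluation

Assembly accuracy is summarized as `Q = −10·log10(errors / aligned bases)`
over a global (edit-distance) alignment of assembly against reference,
contigs paired by size rank. Mismatches and indel bases both count as errors;
indels are counted per base by default (per event behind a flag, where an
"event" is a gap run in the alignment — note that optimal alignments of
ambiguous contexts may split a long gap). A perfect assembly reports the cap,
default Q60, matching the ceiling convention of reported Q values.
`aligned_length` counts base-aligned columns (matches + mismatches).

## Numerical and design notes

- Threshold comparisons at candidate loci are made on integer counts
  (`alt_count > 0.05 · depth`) so a pileup sitting exactly on the boundary is
  excluded regardless of floating-point representation; 100% conservation is
  likewise exact because counts are integers.
- A tie for the homolog majority allele leaves the consensus undefined and
  the locus untouched; a candidate whose consensus equals the draft base is
  logged, not re-examined.
- The Mash estimator is exact when the sketches hold every canonical k-mer of
  the union; tests exploit this by using an oversized sketch as the
  brute-force comparison regime.
- Empty inputs degrade explicitly: zero read depth → discordancy undefined
  (locus skipped); zero homolog depth → conservation undefined; zero homolog
  SAMs → the run refuses with guidance, since conservation without homologs
  is meaningless.
- Problem sizes in the test-suite and the reproduction script (50 kb genomes,
  20 simulation replicates, 30 kb ANI pairs) were chosen as the smallest
  scales at which sketch sampling error, fragment counts and per-locus
  statistics are all well resolved.

## Known limitations

- Only substitution errors are corrected; homopolymer and other indel errors
  are upstream polishers' domain.
- The built-in whole-genome aligner fallback (used when minimap2 is absent)
  assumes collinear genomes; rearranged homologs should be aligned externally
  and passed as SAM.
- Sketching requires k ≤ 31 (2-bit packing); this covers all practical Mash
  settings.
- The selection stage holds one genome in memory at a time but sketches are
  kept for the whole database; for very large local collections build the
  sketch database once and reuse it.
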