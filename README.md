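# modpolisher

Reference-guided correction of **modification-mediated errors** in nanopore
draft genomes.

Bacterial DNA modifications that a basecaller was never trained on perturb
the pore signal and leave *systematic* mismatches in the assembly: most reads
carry the same wrong base at the same locus, so read-consensus polishers
(Racon, Medaka) cannot fix them, and the draft can sit at Q26 instead of Q60.
`modpolisher` removes these errors in silico — no demodification by
whole-genome amplification, no short reads — by exploiting three signals at
each position of the draft:

- **allele discordancy** `D = 1 − max(c)/Σc` over the read allele counts
  `c = (c_A, c_C, c_G, c_T)`: modification errors are discordant (`D > 0.05`);
- **mean basecall quality** `Q̄ < 15`: the basecaller flags its own confusion;
- **conservation across homologs**: closely related genomes, selected by a
  MinHash screen (Mash identity > 0.95, top 20) refined by fragment ANI
  (> 99) and ASI (> 90, the percentage of 3 kb fragments that align at all),
  must agree **100%** on the replacement allele.

Only a candidate locus (discordant *and* low-quality) whose homologs are
unanimous on an allele that differs from the draft and is seen among the
reads gets corrected. Strain variants — where homologs disagree with the
draft but reads support it at high quality — are deliberately left alone. A
motif-aware mode (`--motif GCWGC`) relaxes conservation to 80% at loci inside
occurrences of a known modified motif, and a motif-recovery tool reads the
modification motif back out of the corrected loci as a PFM, IUPAC consensus
and ranked center pentamers. Assembly accuracy before/after is reported as
`Q = −10·log10(errors/aligned bases)`, capped at Q60.

The package is aimed at people finishing bacterial genomes from ONT-only
data: it takes a draft FASTA, reads aligned to the draft (SAM/BAM), and a
local directory of candidate homolog genomes, and produces a polished FASTA
plus a full evidence trail.

## Worked example

Everything below runs from scratch in ~10 s using the bundled simulator,
which plants 40 modification errors inside GCAGC motif occurrences of a 50 kb
genome, 20 strain-variant decoys, 10 homologs at 99.5% ANI, and 30× reads
(discordant, Phred 6–12 at modified loci):

```bash
modpolisher simulate --length 50000 --n-modified 40 --n-decoys 20 \
    --homologs 10 --seed 7 -o fixtures/
modpolisher polish --draft fixtures/draft.fa --reads fixtures/reads.sam \
    $(for s in fixtures/homolog_*.sam; do echo --homologs $s; done) -o out/
# 40 corrections (40 candidates) -> out/polished.fasta
modpolisher motif --genome out/polished.fasta \
    --corrections out/corrections.bed -o out/motif.json
# consensus NNNGCWGCNNN; top k-mer GCAGC (1.00) -> out/motif.json
modpolisher evaluate --assembly fixtures/draft.fa --reference fixtures/truth.fa
# aligned=50000 mismatches=40 insertions=0 deletions=0 Q=30.97
modpolisher evaluate --assembly out/polished.fasta --reference fixtures/truth.fa
# aligned=50000 mismatches=0 insertions=0 deletions=0 Q=60.00
```

All 40 planted errors are corrected (the draft climbs from Q30.97 to the Q60
cap), none of the 20 decoys is touched, and the planted pentamer is recovered
from the corrected loci — the consensus shows GCWGC because GCAGC and its
reverse complement GCTGC are one strand-canonical motif. The same stages are
available as one command (`modpolisher run`) that also performs homolog
selection from a FASTA directory and writes a run manifest, and as plain
library calls (`modpolisher.polish`, `modpolisher.generate`, ...).

`out/` contains the polished FASTA, `corrections.tsv` (per-correction
evidence: discordancy, mean quality, conservation, read support, mode),
`corrections.bed`, and `polish_report.json` with per-contig counters of
candidates, corrections and skip reasons.

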