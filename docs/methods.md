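# Methods

## The discovery model

LTR retrotransposons under RNAi control leave a composite signature in
paired wild-type / RNAi-mutant sequencing data: dense populations of
22–24 nt, 5'U-biased, dual-strand siRNAs over the element in wild type;
loss of those siRNAs in the mutant (or, for families undergoing active
retrotransposition, replacement by sense-only species of broad length,
consistent with reverse-transcription RNase H cleavage products); and a
rise in element mRNA. `retroscout` operationalises discovery as a chain of
falsifiable steps, each with explicit thresholds where the original
analysis was done by eye:

1. **Candidate regions.** All four coverage tracks (sRNA/mRNA x wild
   type/mutant) must be RPKM-normalised (the caller is depth-agnostic by
   contract and rejects raw tracks). Sliding windows (500 bp window,
   100 bp step over 50 bp bins) are flagged when the small-RNA signal is
   *lost* (wild-type mean >= 5 RPKM and a >= 4-fold pseudocounted drop) or
   *changed* (>= 4-fold shift in either direction — depth normalisation
   makes a mutant-specific species population visible as a gain), AND
   mutant mRNA is up >= 2-fold (pseudocount 1 RPKM). Flagged windows are
   merged across gaps <= 500 bp; regions overlapping existing annotations
   are discarded. Regions are carried forward only if they exceed 1 kb and
   contain at least one retroelement protein motif — that acceptance rule
   is enforced between the signature and annotation stages.
2. **Domain scan.** Regions (padded by 600 bp) are translated in six
   frames and scored against ungapped log-odds PSSMs for gag, protease,
   reverse transcriptase (RT), RNase H, integrase and chromodomain.
   Windows containing a stop are rejected outright: an intact domain is an
   open reading frame. Score thresholds are the (1-1e-3) quantile of 1000
   random sequences drawn from the *translated-genome* amino-acid
   background (the residue distribution obtained by translating random DNA
   of the genome's GC content) — a uniform-residue null systematically
   underestimates scores of AT-rich translated windows. Genomically
   overlapping hits keep only the best-scoring model: one nucleotide
   window encodes one domain.
3. **Cassette segmentation.** A merged region in a dense element array can
   span several elements. Hits are split into per-element cassettes by
   domain order: within one cassette, ranks
   gag < protease < RT < RNase H < integrase < chromodomain increase
   strictly along the genome on '+' (decrease on '-'); a rank reversal,
   strand change or > 1.5 kb gap starts a new cassette. Only hits scoring
   at least 40% of the way from the null threshold to the model's
   consensus score define structure: genuine domains — even several
   percent diverged — sit above ~60%, while chimeric windows bridging two
   element fragments across a short junction score below ~30%. A cassette
   must contain at least one core domain; a lone chromodomain (an
   auxiliary feature of Ty3-type elements, common in unrelated chromatin
   proteins) is not treated as element evidence.
4. **Borders.** For each cassette, the up/downstream flanks (up to 5 kb,
   but never beyond the neighbouring cassettes' anchors, nor more than
   600 bp outside the candidate region) are searched for direct repeats:
   shared 12-mers chained by diagonal, chains extended by banded local
   alignment (match +1, mismatch -1, gap open -5, extend -1; the first gap
   base costs the open penalty). Pairs need >= 100 bp and >= 80% identity;
   the best pair maximises repeat length x identity, ties broken by the
   smaller enclosed span. If a region was flagged only over the cassette
   (a borderline signature) and no pair fits inside it, the search is
   retried with a 2 kb reach capped at the neighbouring cassettes —
   generous enough for a spacer plus LTR, short enough not to recruit
   repeat copies from deeper in the array. Classification: full-length
   requires a repeat pair plus RT and integrase hits and spans the outer
   repeat bounds; otherwise >= 1 domain makes a partial spanning the
   domain envelope. TG...CA repeat termini are recorded as an advisory
   flag, never required. Border coordinates are maximal-scoring local
   alignment ends and may include a few chance-matching bases beyond an
   exact repeat.
5. **Copies and solo-LTRs.** Each family representative is searched
   against the whole genome on both strands (word size 12 — at the ~75%
   nucleotide identity typical of same-lineage cross-family matches, exact
   15-mers are too sparse to seed short copies; chains need >= 2 seeds;
   banded extension as above; matches >= 200 bp and >= 70% identity).
   Novel matched loci are annotated like candidate regions, with border
   search reach derived from the representative's own cassette-to-border
   offsets. Solo-LTRs are found by searching each family's LTR consensus
   (>= 80% identity); matches within 1 kb of a domain-bearing call are
   its own borders and are removed. Finally, calls mostly contained in a
   stronger call (more domain evidence, then longer) are dropped.
6. **Families and lineages.** Elements are compared over their RT,
   RNase H and integrase nucleotide sequences: per shared domain, global
   alignment (match +1, mismatch -1, gap -2), identity = matches /
   aligned columns excluding terminal gaps, combined as a length-weighted
   mean; arguments are canonicalised so the result is symmetric under
   co-optimal alignments. Families are the single-linkage transitive
   closure of identity > 0.95 — "same family" is a transitive relation
   (complete linkage is an alternative reading; a per-domain criterion is
   available via configuration). Elements with none of the three domains
   are excluded from clustering. Family labels are deterministic,
   numbered by the leftmost coordinate of each family's representative
   (its longest member). Lineage assignment reduces phylogenetic
   placement to a neighbor-joining tree (scikit-bio) over family
   representatives plus bundled reference taxa from the two fission-yeast
   retroelement lineages, with distance = 1 - identity; each family takes
   the lineage of its nearest reference by patristic distance.
   Maximum-likelihood inference and bootstrap support are out of scope.
7. **Small-RNA profiles.** Reads are assigned to an element when they
   overlap it by >= 50% of their length (multimappers count at every
   element); lengths outside 15–35 nt are tallied and dropped. A profile
   is siRNA-like iff its modal length (ties to the smaller value) is in
   {22, 23, 24}, its antisense fraction >= 0.2 and its global 5'U
   fraction >= 0.5; sense-degradation-like iff the sense fraction is
   >= 0.95 and it is not siRNA-like; anything else — including profiles
   under 50 reads — is ambiguous. A per-length 5'-nucleotide table is
   also emitted (the global-vs-per-length reading of "5'U bias" is
   ambiguous in qualitative descriptions; the global fraction decides).
8. **Quantification.** Comparative Ct with amplification efficiency fixed
   at 2: per replicate dCt = Ct(target) - Ct(reference); fold =
   2^-(dCt - mean calibrator dCt), exponentiated per replicate and
   reported as mean +/- SD on the fold scale (matching how such panels are
   plotted; averaging ddCt before exponentiation is available via the
   arithmetic, and makes the calibrator's mean fold exactly 1 only when
   its replicate dCt values are equal). ChIP enrichment = target/control
   ratio in IP over input; histone-mark levels are normalised to total
   histone and optionally to a calibrator. Copy-number tables (genomic
   DNA) run through arithmetic identical to expression tables. All
   quantities are invariant to a global Ct shift.

## The synthetic study system

`synthio` generates the full data constellation with ground truth. Its
defaults are the study conditions every acceptance check runs under:

| parameter | default | notes |
|---|---|---|
| genome | 3 contigs, 2 Mb total, GC 0.40 | background i.i.d. |
| families | 5, alternating between 2 lineages | Ty3-like cassettes carry a chromodomain |
| copies per family | 2 full-length, 3 partial, 3 solo-LTR | partials always retain RT |
| element / LTR length | 5000 / 300 bp | internal layout shared within a lineage |
| divergence | 2% within family, 20% between | per-site substitutions, no indels |
| wild-type siRNAs | 2000 reads/element; 0.35+0.35 mass on 23/24 nt; antisense fraction 0.5; 5'U target 0.75 | |
| mutant reads | 2000/element, sense-only, uniform 18–30 nt, mobilizing family only | |
| mRNA | background 5 RPKM, 8x over elements in the mutant, Poisson bin noise | depth factor 4 counts/RPKM/bin |

Construction details that matter:

* Family cassettes encode the bundled reference proteins exactly, each
  family back-translating them with an independent uniform codon choice —
  that codon randomness *is* the between-family coding divergence (~75%
  nucleotide identity within a lineage), while LTRs diverge at the
  configured 20% rate from a deterministic lineage ancestor.
* Within-family substitutions avoid creating stop codons inside the
  cassette (purifying selection on functional copies); LTRs and spacers
  are non-coding and carry periodic "stop islands" (a 12-mer with stops in
  all six frames every ~90 bp) so non-coding sequence cannot masquerade as
  a protein domain.
* Elements sit in clustered "centromeric" windows. Within a cluster no
  family recurs within a window of three consecutive items, and solo-LTRs
  sit at the array margins with >= 1.3 kb of clear flank — otherwise a
  neighbour's near-identical repeats are formally indistinguishable from
  an element's own borders, and the 1 kb solo exclusion rule would erase
  planted solos. Tandem same-family copies, common in real centromeric
  arrays, are therefore outside the generator's guarantees (see
  Limitations).
* The 5'U bias is realised by biased start-site selection (a
  Bernoulli(target) choice between U-start and non-U-start positions of
  the actual sequence), never by overwriting bases, so reads stay
  consistent with the genome; the realised fraction is exact in
  expectation regardless of local composition.
* One random stream per artifact (genome seed+0, wild-type reads +1,
  mutant reads +2, coverage +3/+4, gene annotations +7): regenerating
  reads never perturbs the genome, and a fixed seed reproduces every
  output byte for byte.

What the generator does **not** emulate: sequencing error, PCR
duplicates, indels, nested or tandem same-family insertions, RNase H
sequence-context preferences (the mutant degradation species are uniform
sense-only stand-ins; no quantitative model exists for their lengths), and
mappability artifacts. Passing tests therefore demonstrate the pipeline's
logic under the study's effect sizes, not robustness to real-library
noise.

## Numerical and degenerate-case choices

* Coordinates are 0-based half-open everywhere; GFF3 converts at the
  boundary and round-trips byte-stably; bedGraph rasterisation is a
  length-weighted mean with absent intervals as zero, and overlapping
  input intervals are rejected as ambiguous densities.
* N bases never count as matches in any identity or PSSM computation; a
  minus-strand read's 5' nucleotide is the complement of the base at
  interval end-1.
* Alignment tie-breaks are fixed (diagonal, then gap-in-target, then
  gap-in-query), making every scan deterministic; the DP kernels are
  validated against independent oracles (a textbook pure-Python DP, an
  all-substring-pair maximum-subarray scan, all-window PSSM rescoring, and
  an unbanded Smith–Waterman from Biopython) in the test suite.
* Two triplets sharing no domain have an undefined identity (`None`),
  never a number; such pairs simply contribute no linkage edge.
* An element shorter than the longest read is skipped with a warning in
  read simulation; an empty read set yields an all-zero RPKM track.

## Known limitations

* At the planted divergence (2% per copy), two same-family copies are
  ~96% identical — only one point above the 95% family threshold. Pairs
  compared over a single shared domain (RT-only partials) have enough
  variance to fall below it occasionally; families with several members
  are protected by single linkage, but sparse families can split on
  unlucky seeds. This is a property of the threshold relative to the
  divergence, not of the implementation.
* The border search assumes interleaved arrays; immediately adjacent
  same-family copies share near-identical LTRs and their borders are
  genuinely ambiguous from repeat structure alone.
* The PSSM scanner is ungapped (no insert/delete states); strongly
  indel-diverged domains would need profile HMMs, for which the scanner's
  model interface is pluggable.
* The empirical-null alpha (1e-3) substitutes for an external
  significance convention; it, like every threshold above, is exposed in
  the pipeline configuration.
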