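# Methods

This note documents the models, conventions and numerical choices behind
`cdr3shm`, and what the simulation-based validation does and does not show.

## Coordinate and region conventions

All intervals are 0-based half-open internally. The CDR3 is delimited
IMGT-style: from the codon after the conserved FR3 cysteine (C104, the last
FR3 codon of the V segment) to the codon before the J-region conserved
tryptophan (W118). User-facing CDR3 amino-acid positions are 1-based from
the first codon after the cysteine, which makes a 13-aa CDR3 run 1–13 with
the QWL motif at 4–6.

Each CDR3 codon receives one region label from {V, N1, D, N2, J}: the
majority label of its three nucleotides' origins, ties resolved to the
5'-most contributing region. N regions are junction nucleotides not covered
by the V 3' end, the D match, or the J 5' end; P nucleotides are not
modelled separately. D reading frame *f* means translation of the D segment
starting at its nucleotide *f−1*.

## Germline database and archetypes

The packaged database (`data/synthetic_germline.*`) is fully synthetic: V
segments are stop-free random codon sequences with realistic FR/CDR interval
structure, ending in TGT (C104) plus a 6-nt junction tail encoding A-R; D and
J segments are short hand-designed sequences. The two archetypes are
constraint-driven stand-ins for the stereotyped receptors this analysis
targets, and every test relies only on the declared constraint sets
(positions, residues, encoding regions), never on the literal sequences:

- **subset1**: 13-aa CDR3 `ARQQWLGPSTFDY`; QWL at 4–6 encoded by the
  IGHD6-19-like D in frame 1; R at 2 V-encoded (codon AGA); D at 12
  J-encoded (codon GAC). The V gene carries a TGC (WRC) hotspot two
  nucleotides 5' of the position-2 adenine, the J gene a TAC (WRC) two
  nucleotides 3' of the position-12 adenine, and the N1–D boundary
  assembles an AGCA (WGCW) hotspot around the position-4 glutamine codon —
  the hotspot topology the analysis is designed to detect.
- **subset6**: 21-aa CDR3 `ARGPYYDYVWGSYTPRTAFDI`; the IGHD3-16-like D in
  frame 2 encodes YYDYVWGSY at 5–13, placing a valine (GTT) at position 9
  whose guanine is itself the deaminated site of a GYW hotspot (the context
  for the documented clonal V>I change); F at 19 is J-encoded (TTT).

Archetype assembly validates frame, productivity, declared CDR3 length, the
implied D reading frame and every constraint triple, and fails loudly
otherwise.

## Read simulator

Amplicons are full V(D)J rearrangements (270 and 294 nt for the two
archetypes); with the default 2×300 read length each mate covers the whole
amplicon, so every base is double-covered — the regime in which overlap
merging can correct most sequencing error, as in short-amplicon MiSeq
designs. Reads derive from the archetype or an injected variant by a
multinomial draw at the target frequencies; the truth ledger records the
realized counts (they sum to `n_reads` by construction).

The error model is substitution-only and uniform across positions:
aberrant-length molecules are excluded by the pipeline's length filters and
the same-CDR3-length variant definition, so indels would only consume
budget. Qualities are two-component: a Q37 baseline and a fraction of Q5
bases, each base erring with its Phred-implied probability
`10**(-Q/10)`. The low-quality fraction is derived so the aggregate
per-base error equals the configured `error_rate` (7.5% of bases at Q5
yields 2.4%); `error_rate=0` produces clean Q37 reads. Because errors
concentrate at low-quality bases, quality-aware merging reduces the
effective post-merge error to ≈0.2%/base, and the main clonotype ends up
holding ~60–65% of productive reads at 2.4% raw error — the realistic
dominant-clone regime. The per-sample/per-isotype seed is derived from the
master seed by CRC-keyed `SeedSequence` spawning, so cohorts are
reproducible file-for-file (gzip members are written with `mtime=0`).

What the simulator does **not** emulate: PCR amplification bias, chimeras,
UMIs, indel errors, position-dependent quality decay, and CLL-unrelated
background rearrangements. Passing tests therefore demonstrate correctness
of the analysis chain under calibrated substitution noise, not robustness
to every artefact of real libraries.

## QC

Pre-merge filters: per-mate mean quality (default ≥ 25; lengths are fixed
by the simulator). Merging scans candidate offsets of the
reverse-complemented mate, admits offsets with overlap ≥ 30 and mismatch
fraction ≤ 0.25, and picks minimum mismatches (ties: larger overlap, then
smaller offset); disagreeing bases resolve to the higher-quality call with
merged quality the maximum of the two. The scalar `merge_pair` is exact by
exhaustive scan; the batched path restricts to non-negative offsets
(reverse mate cannot overhang a full-length amplicon) and is tested against
the scalar path.

The CDR3-safety filter anchors on the FR4 W-G-x-G amino-acid motif (the
G-X-G being its last three residues), scanning all three frames and taking
the rightmost hit, and requires Phred ≥ 30 at every base in the *closed*
offset interval [−45, −30] from the first base of the motif's first G
codon. The phrase "the 30–45 nucleotide stretch ahead of the anchor" is
ambiguous between this literal interval and a variable-length upstream
stretch; the literal interval is the default and both bounds are
configurable. Window positions falling outside the read are ignored.

## Annotation

Gap-free semi-global alignment (+1 match, −2 mismatch, lexicographic
tie-break, unassigned below score 0 ≈ 67% identity) stands in for a full
annotator: the analysis concerns substitutions only. V identity is
computed over FR1–FR3 positions exclusively, so CDR3/junction mutations can
never reduce it — this is what makes "truly unmutated" (identity exactly
100.0) compatible with CDR3 variation. D genes are assigned by longest
exact substring match ≥ 5 nt (ties: longest, 5'-most, segment name), with
the reading frame derived from the match phase. A consequence worth noting:
a substitution near a D-match edge shortens the exact match, so a variant's
*own* region map can differ from the main clonotype's; all downstream
profiling therefore uses the main variant's region map and
germline-anchored reference, not each variant's.

The batched annotator used by the pipeline memoises junction-level work per
(placement, junction-window) signature and performs the full-read stop scan
per read; it is tested row-for-row against the scalar path on noisy reads.

## Clonotypes and variant roles

Clonotype = unique nucleotide rearrangement sequence over productive reads;
frequency denominator = the sample's productive reads. The read cutoff
(default 66, the coverage limit appropriate to ~2.4% error) is inclusive
(≥ 66). The germline-revertant exception retains a below-cutoff variant
that restores the germline residue at a position where the main clone is
clonally mutated — a revertant cannot arise as a sequencing artefact of
the mutated main sequence, so discarding it would bias against the most
informative variant class. Subclonal variants are defined against the main
variant only (same V gene, same CDR3 aa length, Hamming aa distance ≤ 2,
0 allowed for synonymous nucleotide variants), not transitively.

## Substitution profiling and statistics

At germline-encoded CDR3 positions, variants are compared against the
germline translation; at N positions — where no germline exists — against
the main variant, and such differences are reported but flagged
synonymous/non-SHM rather than entering positional statistics. The main
variant itself is diffed against germline, yielding *clonal* events (e.g. a
clonal V>I at position 9). Transition/transversion classification follows
chemistry (purine↔purine / pyrimidine↔pyrimidine = transition); a g>a
change is therefore always reported as a transition.

Positional targeting: per-sample per-position frequency = summed
frequencies of subclonal variants mutated at that position.
Kruskal–Wallis across positions gates one-sided Wilcoxon rank-sum tests of
each position against the pooled remaining positions, Holm-adjusted,
α = 0.05. One-sided is deliberate: "preferential targeting" asks whether a
position is *elevated*, and under a strong alternative the pooled reference
is inflated, which would otherwise flag untargeted positions as
significantly low. The all-identical input returns omnibus p = 1 with no
post-hocs. Subset-heterogeneity comparison uses the two-sided Mann–Whitney
U: exact enumeration when both groups have n ≤ 8 without ties, otherwise
the tie-corrected normal approximation without continuity correction (so
identical samples give p = 1 exactly). Holm adjustment is implemented
directly (step-down with monotonicity, capped at 1) and cross-checked
against an independent implementation in tests.

## Hotspot topology

WRC and GYW (its reverse-strand presentation) are scanned on the sense
strand, plus overlapping WGCW 4-mers; AGCT is flagged palindromic (the
overlapping motif present identically on both strands). Hotspots are
scanned on the *germline background* (the main sequence with its CDR3
templated positions reverted to germline), since that is the substrate SHM
acted on. A mutation at a deaminated site (the WRC C or GYW G) is
`canonical_AID`; an A/T change within 2 nt of a motif interval (the
default; configurable, as "adjacent" has no published numeric definition)
is `adjacent_AT_noncanonical`; anything else is `unassociated`.
Junction-created hotspots are motifs spanning ≥ 2 region labels that are
absent from a ±6 nt window of the pure germline concatenation (the
sequence with N nucleotides removed).

## Validation design and problem sizes

The validation suite runs entirely on simulated data at desk scale:
parameter recovery uses 20 seeds at depth 10⁵ with 0.1% injections and
`error_rate=0` — isolating sampling and pipeline fidelity from noise, since
with substitution error the exact-sequence clonotype count of *every* clone
(main and variants alike) is attenuated by the per-read error-free
probability, which biases absolute (though not relative) frequencies; error
control uses 50 seeds at depth 10⁴ with 2.4% error and no injections,
requiring zero spurious truly-unmutated subclonal variants above the
cutoff; statistical calibration uses 200 replicates for power (12 samples,
13 positions, 10-fold elevation at three positions) and 1000 for the
family-wise type-I rate. Oracle equivalence (hotspot scanner, subclonal
roles, merging, exact Mann–Whitney) is checked against independent
brute-force implementations living in the test suite.

## Known limitations

- The annotator is a deliberate simplification; on real, noisy, indel-
  containing data its identity values will not match a full gapped,
  allele-aware annotator. Equivalence is only claimed on simulator output
  and small fixtures.
- Exact-substring D assignment loses mutated D edges (see above).
- The germline database is synthetic; analyses of real repertoires must
  supply a real segment FASTA and boundary sidecar.
- Frequencies are reported against productive reads; under sequencing error
  absolute frequencies of exact-sequence clonotypes are attenuated
  (uniformly across clones). An alternative denominator (truly-unmutated
  reads only) is available via the clonotype table itself.
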