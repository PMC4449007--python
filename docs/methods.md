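# Methods

## Pattern engine

Patterns are parsed into ordered position elements (literal, class `[ ]`,
negated class `{ }`, wildcard `x`, each with an optional repeat `(n)` or
`(n,m)`, plus `<`/`>` terminal anchors). Matching is a backtracking scan
from every start position; all overlapping occurrences are reported, and a
variable repeat that admits several span lengths from one start reports
each distinct span. Coordinates are 1-based inclusive throughout.

Ambiguity is handled conservatively: an `X` in a sequence satisfies only
the wildcard or a class that explicitly lists `X`, and never a negated
class. This slightly under-counts motifs on low-quality sequences rather
than over-counting them, which is the right bias for a filter whose
positive calls are treated as strong evidence. The eight panel motifs use
only literals and classes; the extra grammar exists so users can supply
custom panels.

## Zones

The zone constraints are judged by the start position of each occurrence
("appears in" read as "begins in"). Halves split at floor(L/2) with the
boundary residue in the first half. The "middle part" for motifs 3–6 is
not precisely defined by the constraint's phrasing; we use the central
half of the chain, start ∈ [floor(L/4)+1, floor(3L/4)], exposed as
`middle_frac` (default 0.5). On the 335-residue human reference protein
this window is 84–251 and contains the reference positions of all four
middle motifs (160, 194, 227, 251), while the N/C-half rules contain the
reference positions of motifs 1–2 and 7–8, so the default panel is
self-consistent by construction (the `panel_refs_in_zone` quantity in the
acceptance output re-derives this at run time). Motif ordering along the
chain is *not* enforced — only the three zone rules are.

A motif found only outside its zone contributes nothing to the motif count
but stays in the scan output with `zone_ok = false`, so reports can show
near-misses.

## Classifier

The cascade is formalized as a four-label partition (CONFIRMED, CANDIDATE,
WEAK_HOMOLOG, REJECTED) over (domain E-value, best-hit family, motif
count); defaults are strict cutoff 1e-10, relaxed cutoff 1e-5, minimum
3 motifs. Two deliberate asymmetries:

- a protein with a strict-cutoff domain hit whose best database hit is
  *not* GT43 is REJECTED rather than WEAK_HOMOLOG — such hits behave as
  false positives from neighbouring GT-A families; `--lenient-besthit`
  relaxes this to CANDIDATE;
- consequently label monotonicity in the E-value holds within the GT43
  best-hit family but intentionally not across families.

The domain E-value defaults to the best per-domain independent E-value
(i-Evalue), since the evidence of interest is a domain hit; `--evalue-field
full` switches to the full-sequence value. When one protein has several
domain rows the minimum is kept. BLAST best hits are chosen by minimum
E-value, ties broken by maximum bit score, then input order (the behaviour
of the common tools). Report rows are ordered by descending motif count,
then ascending domain E-value, then id, so re-runs are byte-identical.

## Transcript mining

ORFs are maximal stop-to-stop stretches in each of the six frames, with no
start-codon requirement (assembled transcripts are often truncated at the
5' end). "Longer than 100 amino acids" is strict (≥ 101 residues kept).
Codons containing `N` always translate to `X`, even when every resolution
of the ambiguity encodes the same residue — the simple rule is easier to
reason about and errs toward fewer motif matches (`X` is conservative, see
above). Multiple qualifying ORFs per transcript are all retained, tagged
with frame and forward-strand coordinates. The dual homology filter keeps
a peptide only when both its best protein-database E-value and its domain
E-value are below the cutoff (default 1e-10); a missing evidence row
drops the peptide.

## Pairwise identity

Global alignment is Needleman–Wunsch/Gotoh with affine gaps, BLOSUM62,
gap open 10 / extend 0.5, end gaps penalized; local mode (Smith–Waterman)
is provided because published identity figures for fragmentary peptides
often derive from local alignments. Percent identity defaults to
identities over alignment columns after excluding terminal-gap columns —
for fragment-versus-full-length comparisons this measures the aligned core
rather than punishing the missing termini. `shorter_seq` and
`aligned_pairs` denominators are available. Traceback ties are resolved by
the aligner's deterministic first path, so identical inputs give identical
alignments.

## Synthetic data

The generator emulates the study conditions the pipeline is designed for:
catalytic-domain-sized proteins (lengths drawn uniformly from 200–500 aa
by default, within the 100–600 aa range of real GT43 candidates),
positives carrying 3–8 distinct in-zone motifs, and motif-free decoys.
Motif realizations are drawn uniformly from the pattern's finite language;
the background is i.i.d. uniform over the 20 standard residues (a
Swiss-Prot-like composition table is available). The whole sequence is
rejection-sampled (up to 1,000 attempts) until the only panel matches
anywhere are the planted ones, so truth records are exact rather than
probabilistic; decoys are certified motif-free by the same test.

Mock evidence mirrors the structure of real searches: positives draw
domain E-values log-uniformly from [1e-60, 1e-11] with a GT43-family best
hit; decoys either lack evidence or draw from the weak band [1e-9, 1e-6]
with a GT2-family best hit, reproducing the false-positive band that the
relaxed cutoff admits in real data. Transcripts are back-translated with
uniformly random synonymous codons and stop-bracketed flanks, so the
frame +1 maximal ORF is exactly the source peptide.

What the generator does **not** emulate: homologous-but-divergent true
positives (its positives contain literally planted motifs, not motifs
embedded in homologous context), sequencing/assembly errors, compositional
bias around motifs, and correlated evidence (domain E-value and best-hit
E-value are drawn independently). Passing the synthetic suite therefore
demonstrates that the machinery is exact on known ground truth — it does
not by itself establish sensitivity on real divergent homologs, which is
what the reproduction tests on public sequences cover.

## Problem sizes and numerics

The default test suite and the acceptance script use a 60-protein
classification study, 100 motif-recovery datasets, 1,000 random
pattern/sequence pairs against the regex oracle, 200 random transcripts
against the ORF oracle, and ≤ 8-residue pairs against the exhaustive
alignment oracle — sizes chosen so the full suite runs in seconds while
each randomized check still covers the grammar and edge cases well. Zone
arithmetic adds 1e-9 before flooring to guard against binary rounding of
fractions like 0.8. All randomness flows from explicit integer seeds;
derived seeds stay below 2^31.

## Known limitations

- The reproduction tests need public reference sequences (UniProt O94766,
  21 GenBank records, the transcriptome peptide workbook, the Arabidopsis
  IRX proteins); offline they fail with instructions for supplying local
  copies under `data/reference/` rather than skipping silently.
- The pipeline consumes precomputed HMMER domain tables and BLAST tabular
  files; it does not run those tools itself.
- Rounding conventions of published identity percentages are unknown; the
  reproduction test accepts a ±3-point window under either alignment mode.
- The family map is user-supplied; no CAZy snapshot ships with the
  package.
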