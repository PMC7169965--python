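# Methods

## The LLR composition model

A protein region is scored for prion-like composition by a two-state
model: each residue is emitted either by a *prion state* with
amino-acid frequencies `f_P` or by a *background state* with
frequencies `f_B`. The per-residue log-likelihood ratio is
`llr(aa) = log(f_P(aa) / f_B(aa))` (natural log by default; the base is
a parameter). The primary statistic, `map_parse_llr`, is the score of
the best single contiguous prion-state run of length ≥ c:

    score(run) = Σ llr(aa) + |run|·log(a_PP / a_BB) + K

where `a_PP`, `a_BB` are the self-transition probabilities implied by
geometric run-length priors and `K` is the constant cost of opening and
closing one run (`K = log a_BP + log a_PB − log a_PP − log a_BB`).
Because the transition terms reduce to one per-residue constant and one
per-run constant, the maximum over all runs of length ≥ c is found
exactly in O(n) with prefix sums; a second pass resolves score ties to
the leftmost, then shortest, interval so output is deterministic.
An auxiliary fixed-window score (`core_window_score`, best window of
exactly c residues, raw LLR sum) is also reported.

Assumptions: composition only — no sequence order, secondary structure
or disorder information enters the score; a single contiguous run is
scored per sequence/fragment (multi-domain proteins are handled by
fragment decomposition, below).

### Parameters

| parameter | default | meaning |
|---|---|---|
| `f_P` | shipped table | prion-state frequencies, modeled on the N/Q-rich, S/G/Y-enriched composition of known yeast prion-forming domains |
| `f_B` | shipped table | background frequencies (Swiss-Prot average composition) |
| `log_base` | e | base of all logarithms |
| `core_length` c | 60 residues | minimum run length for a prion-like call; sequences/fragments shorter than c get a "no domain" sentinel (both threshold flags false) |
| `prion_run` | 100 residues | expected prion-run length (geometric prior) |
| `background_run` | 500 residues | expected background-run length |

With the defaults the transition terms cost ≈ 11.3 LLR units for a
60-residue run — a weak prior that penalises spurious short runs
without overwhelming a genuine N/Q tract (a 60-mer at 70% Q+N scores
≈ +45). The run-length priors were fixed once at these round values;
they are deliberately weak because the decision thresholds (below)
carry the classification burden. All parameters load from a flat TSV
(`ScoreParams.from_file`), so replicating any external tool's tables is
a data question, not a code change.

Decision thresholds on the parse score: **> 0.0** (strict; any
predicted prion-like propensity) and **≥ 15.0** (inclusive; on the
order of the weakest score for a known fungal prion-forming domain).
Ambiguity codes X/B/Z/U score 0 and never terminate a run; input is
case-insensitive and `*` is stripped with a warning.

## Compositional-bias scan

`scan_lowest_p` finds, exhaustively over all windows whose length lies
in [15, 500] (clipped to the sequence; sequences shorter than 15 are
scanned at full length), the window minimising the binomial upper tail
P(X ≥ x | n, p) for the count x of target residues, computed in log
space via `scipy.stats.binom.logsf`. `best_of_qn` takes the minimum
over the target sets {Q}, {N} and pooled {Q,N}; the pooled expectation
is the sum of the per-residue expectations (0.05 + 0.05 = 0.10). Ties
prefer the pooled set, then Q, then the leftmost, shortest window. The
raw minimal log10 P is reported; no multiple-testing correction across
windows is applied, since the raw minimum is the quantity of interest
downstream. The exhaustive scan *is* the implementation — no greedy
accelerator is used.

## Domain architecture and fragments

Coordinates are 1-based inclusive throughout (Pfam/InterPro
convention). Homology hits with e-value ≤ 1e-4 become
`homology`-source intervals on their query coordinates and are merged
with curated annotations. Overlap reduction is greedy: sort by
decreasing length, keep an interval iff it shares no residue with an
already-kept interval on the same sequence. Length ties break by
earlier start, curated before homology, then input order — the rule is
otherwise underdetermined and determinism matters more than the choice.

Fragments are the inter-domain gaps plus one N-terminal and one
C-terminal piece, each extended by a 10-residue buffer *into* the
flanking domain(s) (domain edge annotations are frequently imprecise)
and clipped to the sequence; a zero-length gap between adjacent domains
still yields a 2×buffer fragment straddling the junction. A fragment is
*internal* iff kept domains flank it on both sides. Fragments shorter
than c are retained (fragment counts stay architecture-determined) but
carry the scoring sentinel. Per-protein prion-domain counts at both
thresholds, and the internal-only count at > 0.0, come from scoring
each fragment independently.

## Homology filters

RBH pairing: (a, b) iff b is a's unique best subject by bitscore and
vice versa; equal-bitscore ties disqualify the query. The paralog
sieve returns a proteome sequence iff it has ≥ 1 hit with e ≤ 1e-4 and
query coverage > 0.5 against the reference sets *and* its best such hit
(bitscore, then e-value; residual ties excluded) is to the Pub1/Tia1 or
Nam8/Ngr1 sets rather than Pab1. "Preference" by best bitscore was a
design choice: bitscore is database-size independent. Coverage is
computed on the candidate (query) sequence — the filter asks whether
the *majority of the candidate* matches a reference protein. Note the
sieve is monotone in its thresholds only when loosening them does not
admit a new higher-scoring Pab1 hit; on the fabricated test tables (no
near-threshold decoys) it is monotone.

## Summaries and trees

Threshold fractions, multi-prion fractions (count ≥ 2) and RRM
histograms are direct counts; display percentages round to integers
while machine-readable output keeps full precision. Pearson r uses the
t-transform two-tailed p (scipy), dropping incomplete pairs pairwise
and reporting the n actually used. Clade membership comes from an
explicit seq_id→clade mapping, not from tree topology. `prune_clade`
removes the subtree selected by an internal-node label or the MRCA of a
leaf set, then collapses unary nodes summing branch lengths, so
pairwise path lengths among survivors are preserved (dendropy backs the
tree operations).

## The synthetic generator

`generate_family` emulates a curated ortholog family: each sequence is
`linker (domain linker)*` where domains are copies of a fixed
80-residue RRM-like consensus mutated per site at `mutation_rate`
(default 0.1 — enough divergence to exercise homology extension while
keeping a recognisable core), linkers are i.i.d. draws from the
background table, and N/Q tracts (default one per sequence, 60
residues, 70% Q+N — a clearly prion-like but not saturated tract) are
planted into terminal or inter-domain linker slots, one slot per tract.
Defaults: 100 sequences, three 80-residue domains, linkers 40–90
residues. All randomness flows from the single spec seed through one
`numpy` generator; identical specs give byte-identical FASTA and truth
tables. Infeasible specs (e.g. internal placement with < 2 domains)
raise rather than silently truncating.

What the generator does **not** emulate: phylogenetic covariance
between sequences (no tree, no substitution model — linkers are
i.i.d.), real disorder profiles, length variation of domains, or
composition drift between clades. Passing tests therefore demonstrate
correctness of the *measurement machinery* under known ground truth,
not performance on real proteomes, where domain annotations are noisy
and tract composition varies continuously.

`generate_hit_table` fabricates similarity tables whose correct
downstream answer is known by construction: mutual-best-hit pairs for
the RBH filter, planted preferrers (~40% of candidates, the rest
failing exactly one condition each) for the paralog sieve, and
truth-coordinate hits with alternating qualifying/non-qualifying
e-values for homology extension.

## Numerical choices and degenerate inputs

- Frequency tables are floored at 1e-6 and renormalised on load, so
  log ratios are always finite.
- Binomial tails are computed entirely in log space; `x = 0` returns
  log10 P = 0 exactly.
- Score-tie resolution (leftmost, shortest) uses exact float equality
  between two passes that perform identical arithmetic, so it is safe.
- Empty filter selections raise explicit errors rather than returning
  NaN fractions; zero-variance correlation inputs raise.

## Problem sizes

The test suite and the acceptance script run desk-scale studies: oracle
equivalence on sequences ≤ 300 residues, 1,000-replicate interval and
architecture property checks, parameter recovery on families of
150–240 sequences (two 120-protein families in the acceptance study,
10% of them carrying two planted tracts). These sizes give binomial
sampling error well inside the stated tolerances (±2 points on the
multi-tract fraction at n = 200) while keeping the full suite under a
few minutes on one CPU.

## Known limitations

- The LLR tables are a literature-informed default, not a fit to any
  specific training corpus; absolute scores from other PrLD tools are
  comparable only after loading their tables.
- The parse scores one run per fragment; proteins with two prion-like
  tracts in the *same* inter-domain region count once.
- The bias scan is O(n·W) in sequence length and window range;
  proteome-scale scanning would want the window loop vectorised
  further, which has not been needed at family scale.
- Disorder percentages are consumed as input columns (two external
  predictors' per-protein totals); the package computes no disorder.
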