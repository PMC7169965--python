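# prionscope

Tools for quantifying how deeply **prion-like composition** and **RRM
domain architecture** are conserved across ortholog families of
RNA-binding proteins (the Pub1/Tia1 and Nam8/Ngr1 families and their
relatives).

Prion-like domains (PrLDs) are intrinsically disordered regions whose
amino-acid composition — typically rich in glutamine (Q) and asparagine
(N) — resembles that of known yeast prion-forming domains. `prionscope`
provides the full analysis chain for asking, family-wide, how conserved
that composition is:

- **LLR composition scoring** (`prionscope.prion`) — a table-driven
  log-likelihood-ratio scorer. Each residue contributes
  `log(f_P(aa) / f_B(aa))` where `f_P` and `f_B` are prion-state and
  background amino-acid frequencies; the primary score is the best
  single contiguous prion-state run of length ≥ c (default c = 60)
  under a two-state model with geometric run-length priors, found by an
  O(n) prefix-sum parse. Decision thresholds: LLR > 0.0 (any prion-like
  propensity) and LLR ≥ 15.0 (on the order of the weakest known fungal
  prion-forming domain).
- **Compositional-bias scanning** (`prionscope.bias`) — the most biased
  subsequence for Q, N, or pooled Q+N, scored by the binomial upper
  tail P(X ≥ x | n, p) with expected frequency p = 0.05 per residue
  (0.10 pooled), reported as log10 P.
- **Domain architecture** (`prionscope.domains`) — merge curated and
  homology-derived RRM annotations (e-value ≤ 1e-4), reduce overlaps
  greedily (longest first), split each protein into inter-domain
  fragments with a 10-residue buffer into flanking domains, and count
  prion-like domains per protein at both thresholds.
- **Homology filters** (`prionscope.homology`) — reciprocal-best-hit
  orthology from outfmt-6 tables, reference-proteome cross-referencing,
  and the comparative paralog sieve (best qualifying hit prefers
  Pub1/Nam8 over Pab1).
- **Family summaries** (`prionscope.summarize`) — threshold pass
  fractions, multi-prion-domain fractions, RRM-count histograms,
  Pearson correlations, Newick clade pruning, annotation-ring export.
- **Synthetic families** (`prionscope.synthetic`) — a seeded generator
  of ortholog families with planted RRM-like domains and N/Q tracts,
  plus fabricated similarity tables, so every stage is testable against
  known ground truth.

## Worked example

```python
from prionscope import *

spec = FamilySpec(n_sequences=50, seed=4)        # 3 RRMs + one N/Q tract each
records, truth = generate_family(spec)
params = ScoreParams.default()

anns = [DomainInterval(r.id, s, e)
        for r in records for (s, e) in truth.domains(r.id)]
table = annotate_proteins(records, anns, params=params)

tf = threshold_fractions(table)
print(f"LLR>0: {tf['n_gt0']}/{tf['n']} ({tf['pct_gt0']}%)  "
      f"LLR>=15: {tf['n_ge15']}/{tf['n']} ({tf['pct_ge15']}%)")
r, p, n = pearson_r(table.best_llr, -table.log10_flps_p)
print(f"Pearson LLR vs -log10 P(Q/N bias): r={r:.2f}, p={p:.2e}, n={n}")
```

prints

```
LLR>0: 50/50 (100%)  LLR>=15: 50/50 (100%)
Pearson LLR vs -log10 P(Q/N bias): r=0.95, p=7.97e-27, n=50
```

Every synthetic protein carries a planted 60-residue tract at 70% Q+N,
so all 50 pass both thresholds; the strong correlation between the LLR
and the Q/N binomial bias reflects that both statistics respond to the
same planted tracts. The first annotation rows:

```
 seq_id  best_llr  n_prion_domains_at_0  n_rrm  log10_flps_p
SYN0000 59.619173                     1      3    -36.054195
SYN0001 46.538105                     1      3    -30.738838
SYN0002 36.829231                     1      3    -23.219079
```

The same stages are available from the shell:

```sh
prionscope synth --n-sequences 50 --seed 4 --out-fasta fam.fasta --out-truth truth.tsv
prionscope prion-score --fasta fam.fasta --out scores.tsv
prionscope bias-scan --fasta fam.fasta --out bias.tsv
```

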