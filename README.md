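# varscape

Analyses of the fine-scale spatial and population structure of rare
variation in population-scale whole-genome sequencing callsets, for
statistical and population geneticists working with multi-sample VCFs:

* **Singleton clustering** — per-individual nearest-neighbour distances
  between singleton SNVs, modelled as a K-component exponential mixture
  f(d) = Σ_k λ_k θ_k⁻¹ e^(−d/θ_k) with θ_1 < … < θ_K, fit by EM; K chosen
  by an iterative likelihood-ratio rule (χ², 2 df, α = 0.01); singletons
  classified to components by posterior argmax.
* **Mutational spectra** — strand-collapsed six-class substitution spectra
  (with CpG stratification) of the singletons assigned to each component.
* **Hotspots & feature regression** — component counts in 1-Mb windows,
  hotspots above the genome-wide 95th percentile, and negative binomial
  regression log μ_w = β₀ + Σ_m β_m X_{m,w} on genomic feature tracks.
* **Rare-variant sharing** — the Jaccard index J = |A∩B|/|A∪B| over
  carrier sets of rare variants (2 ≤ full-sample carrier count ≤ 100),
  averaged within and between study × population-group splits.
* **pLOF depletion** — per-gene pLOF density L and singleton proportion S,
  tested for gene-set depletion/enrichment with a CDS-length-matched
  bootstrap (length-binned resampling, empirical one-sided P values).
* **Segment density** — common/rare × coding/noncoding variant counts per
  contiguous 1-Mb segment with regression adjustment for coding proportion
  C and accessibility A, plus CADD-tier concatenated segments.
* **Synthetic data** — generators for every input (mixture distances with
  known labels, coalescent singletons under encoded out-of-Africa
  demographic histories via msprime, structured genotype matrices, gene
  tables, feature-track windows), because the motivating callsets are
  access-controlled.

See `docs/methods.md` for the models, assumptions and design choices.

## Worked example

Run the full synthetic pipeline into a directory:

```sh
varscape run-all --seed 7 --out demo
```

This simulates a group-structured genotype matrix, writes it as VCF,
re-reads it, extracts per-individual singletons and their
nearest-neighbour distances, fits the mixture, and runs the sharing,
depletion and segment analyses. `demo/mixture_fit.json` from that run:

```json
{"K": 4,
 "lambda": [0.0146, 0.1842, 0.4644, 0.3367],
 "theta":  [5.2, 1908.0, 40727.1, 151011.4],
 "loglik": -237412.62, "n": 20000, "converged": true}
```

The selection rule recovered the four generating processes: ~1.5 % of
distances from a ~5 bp process (tightly clustered mutation events), ~18 %
from a ~2 kb process, and the remainder from the two diffuse background
processes at ~40 kb and ~150 kb. `demo/sharing.tsv` shows the planted
excess of within-group rare-variant sharing (means over all pairs):

```text
group_a  group_b  mean_J   n_pairs
S_A/A    S_A/A    0.5073   66
S_A/A    S_B/B    0.2853   144
S_B/B    S_B/B    0.4670   66
```

and `demo/depletion.json` recovers the planted half-rate gene set:
`fold_change_L = 0.453`, `p_low_L = 5.0e-04` — the set carries roughly half
the pLOF burden expected for its CDS lengths.

Library use mirrors the CLI:

```python
from varscape import mixture, simulate

d, labels = simulate.simulate_mixture_distances(n=50_000, seed=1)
fit = mixture.select_k(d, alpha=0.01, k_max=6, seed=1)
posterior = mixture.classify_singletons(fit, d)
```

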