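# hemescreen

A transcriptomic screen for **transcriptionally regulated heme transporters**
in *Aedes aegypti*. During blood digestion the mosquito midgut is exposed to
~10 mM heme — a nutrient, a signal, and a potent pro-oxidant — yet the
membrane transporters that move heme across the midgut epithelium are
unknown. If import/export is transcriptionally regulated, candidate
transporters should show a diagnostic signature: **up under heme deficiency
and down under heme excess** (import-like), or the mirror image
(export-like). This package implements the full computational screen over
gene × sample read-count matrices from heme-deficient / heme-excess /
normal-serum treatments of cultured cells and ex vivo midguts:

1. **Differential expression** — the negative-binomial exact test for
   two-group counts: TMM normalization, library equalization, a single
   common dispersion φ estimated by conditional maximum likelihood, the
   conditional exact test on group sums, and Benjamini–Hochberg FDR.
   For a gene with group sums *S_A*, *S_B* conditioned on *s = S_A + S_B*:

   `p = Σ { P(a)·P(s−a) : P(a)·P(s−a) ≤ P(S_A)·P(S_B) } / Σ_a P(a)·P(s−a)`

   with *S_A* ~ NB(n_A·μ̂, φ/n_A) and μ̂ = s/(n_A+n_B).
2. **Soft clustering** — fuzzy c-means (memberships
   `u_ik = 1/Σ_j (d_ik/d_ij)^{2/(m−1)}`) on per-gene z-standardized
   treatment profiles, with centroid shapes classified as import-like,
   export-like, serum-response or other.
3. **TM-domain enrichment** — are DEGs richer in transmembrane-segment
   genes than random same-size genome subsets? 30 resampled draws, a
   two-tailed z-test, and the exact hypergeometric moments reported
   alongside as an analytic cross-check.
4. **Candidate prioritization** — q-value, ≥ 2 TM segments (multipass
   proxy), ≥ 2-fold change, function-class and mitochondrial exclusions,
   cluster concordance, and overlap tallies across datasets.

A **synthetic-data generator** plants import-like/export-like/serum/
mitochondrial responders in NB counts with known effect sizes, providing
ground truth for recovery and calibration tests. The published midgut
candidate tables are bundled and can be replayed through the filter chain
(`hemescreen replay-tables`).

## Worked example

Numbered drivers under `analysis/` run the screen on synthetic data:

```bash
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_soft_clustering.py
python analysis/04_candidate_prioritization.py
python analysis/05_replay_published_tables.py
```

which prints, for two simulated 8,000-gene datasets (3 treatments × 3
replicates, φ0 = 0.1, 2-fold planted effects):

```
ds1: dispersion 0.101; 36/7960 genes significant at q < 1e-4; 36/200 planted responders recovered
ds1: c=8 clusters, ...; 82/100 planted importers in import-like clusters
ds1: 134 strict candidates (66 import-like, 68 export-like); DEG TM enrichment obs 36 vs exp 12 (z=10.0, p=2e-23)
midgut candidates: 40 total, 28 import-like / 12 export-like
2-fold subset: 6 down / 5 up / 11 total
shared with cultured cells: 11 importers + 4 exporters = 15; importer degree histogram {'1': 8, '2': 1, '3': 2, '4': 0}
```

Reading this: the common dispersion is recovered at its simulated value
(0.1); at the strict q < 10⁻⁴ cutoff every significant gene is a planted
responder (FDR control); most planted importers land in clusters labelled
import-like at > 50% membership; and the DEG set is strongly enriched for
TM-containing genes, as expected since planted transporters are multipass.
The last three lines re-derive the published midgut candidate splits
exactly from the bundled tables.

The same stages are available as a CLI (`hemescreen simulate/de/cluster/
enrich/candidates/run-all/replay-tables`) and as library functions.

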