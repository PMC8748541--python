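# dropdms

Analysis toolkit for droplet-microfluidic deep mutational scanning (DMS) of
enzymes. A DMS screen of this kind expresses an error-prone PCR mutant
library of an enzyme (the motivating system is the human executioner
caspases CASP3/CASP7) in *E. coli*, encapsulates single cells in picoliter
droplets with a fluorogenic substrate, incubates briefly, and sorts droplets
whose fluorescence exceeds a gate. Sequencing the sorted pool against the
presorted input pool reveals which amino-acid substitutions an active enzyme
tolerates.

`dropdms` implements the full computational side of such a screen:

* **Screen simulation** (`dropdms.synth`) — error-prone PCR libraries with
  Poisson-distributed nucleotide substitutions, latent per-variant activity,
  Poisson droplet loading, expression noise, autofluorescence, a hard
  fluorescence gate with co-encapsulation carryover, and FASTQ-serializable
  reads with per-base errors. Every stage is seeded and reproducible.
* **Mutation calling** (`dropdms.calling`) — mean-quality read filtering
  (Phred ≥ 30 by default), gapless codon-aware substitution calling in
  canonical residue numbering, and per-pool count tables with a
  minimum-observation threshold (≥ 10 by default).
* **Fitness estimation** (`dropdms.pu`) — per-substitution coefficients β
  from a case-control positive-unlabeled (PU) logistic regression. The
  sorted pool is treated as a sample of positives and the input pool as
  unlabeled with a known active fraction π (measured by a plate assay).
  With σ(x) = logistic(β₀ + xᵀβ), the probability that a read with
  substitution indicators x came from the sorted pool is

      q(x) = n_P σ(x) / (n_P σ(x) + n_U π),

  and (β₀, β) maximize the conditional likelihood of pool membership.
  Negative β are deleterious substitutions. The API follows the
  statsmodels convention: `PULogisticModel(features, prior_pi).fit()`
  returns a results object with `params`, `bse`, and `summary()`.
* **Profiles** (`dropdms.profiles`) — per-site mutational tolerance (mean
  |β| over all substitutions at a site, reported as a percentile rank),
  MSA-based conservation profiles (normalized column entropy), pairwise
  paralog alignment, coefficient-difference heatmaps, and moving-average
  smoothed divergence profiles with a permutation test per site.
* **Kinetics** (`dropdms.kinetics`) — Hill-equation fits
  v = V·Sⁿ/(Kⁿ+Sⁿ) by multi-start least squares, active-site titration
  for enzyme concentration, and derived k_cat and k_cat/K.
* **Screen statistics** (`dropdms.stats`) — Wilson binomial proportion
  confidence intervals, fold enrichment, and the >50%-of-wild-type
  functional classification rule.
* **Pipeline + CLI** (`dropdms.pipeline`, `dropdms.cli`) — a validated YAML
  config, an end-to-end `run` command (simulate/load → QC → call → count →
  threshold → PU fit → replicate concordance → profiles), and a JSON run
  manifest for byte-reproducible reruns.

## Worked example

```python
import numpy as np
from dropdms import *
from dropdms.calling import call_reads

# 60-codon toy gene, 8000-variant ePCR library, 25% active by construction
ref = random_coding_sequence(60, seed=999)   # or CodingSequence.from_fasta(...)
lib = simulate_epcr_library(ref, 8000, mean_nt_mutations=3.0, seed=1)
rng = np.random.default_rng(2)
subs = sorted({s for v in lib.variants for s in v.aa_substitutions})
truth = {s: float(rng.normal(0, 1.5)) for s in subs}
lib = assign_ground_truth(lib, truth, target_pi=0.25, seed=3)

inp, srt, summary = simulate_droplet_sort(lib, ScreenConfig(seed=4),
                                          n_droplets=1_000_000)
print(round(summary.occupied_fraction, 4), round(summary.sorted_purity, 3))
# 0.1003 0.695        <- 10% occupancy; 25%-active library sorts to ~70% active

ir = generate_reads(inp, 100_000, 0.001, seed=5)
sr = generate_reads(srt, 100_000, 0.001, seed=6)
tab = apply_count_threshold(build_count_table(ir, sr, ref), 10)
fm = FeatureMatrix.from_read_calls(call_reads(ir, ref), call_reads(sr, ref),
                                   tab.substitutions)
res = PULogisticModel(fm, prior_pi=0.25).fit()
print(len(tab), res.converged, round(res.intercept, 2))
# 507 True -1.17      <- 507 substitutions scored; intercept matches pi=0.25

profile = percentile_rank(site_tolerance(res.coefficient_table()))
```

On this run the fitted coefficients rank-correlate with the simulated truth
at Spearman ρ ≈ 0.55. Desk-scale recovery is bounded by the number of
variants carrying each substitution and by sorter impurity, not by read
depth; the estimator itself recovers truth at ρ ≥ 0.9 when observations
follow the PU sampling model directly (see `tests/test_acceptance.py`).

Quick arithmetic checks of the screen model:

```python
fold_enrichment(0.09, 0.95)        # 10.56 — a mock sort from 9% to 95% active
expected_throughput(1000, 0.10)    # (100.0, 360000.0) cells/s, variants/hour
```

The same pipeline runs from the shell:

```sh
dropdms run --config demo.yaml --out-dir out/   # writes TSVs + manifest.json
dropdms stats --k 19 --n 20                     # Wilson 95% CI
dropdms kinetics --data titration.tsv --enzyme-conc 0.1
```

## Limitations

The simulator models substitutions only (no indels), full-length reads (no
fragment tagmentation), and a uniform mutation spectrum. Gapless calling
assumes reads span the whole ORF; pre-aligned full-length sequences are
accepted in place of raw reads. See `docs/methods.md` for the model details
and numerical choices.
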