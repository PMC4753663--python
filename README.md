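# fermnet

Fermentation metabolic profiling pipeline: from batch-fermentation time
courses and GC-MS peak-area tables to specific rates, dual-response
PLS/VIP models, a nine-way metabolite classification, pathway
over-representation + topology impact analysis, and a bipartite
metabolite-pathway network.

## What it does

1. **Rates** — relative abundance `A_r = A_i / (DCW * A_s)` (internal-standard
   + biomass normalization), specific growth rate `mu = d ln(OD)/dt`, and
   specific butanol production rate `q = (dc/dt)/DCW`, by central finite
   differences (or smoothing spline).
2. **PLS/VIP** — one single-response NIPALS PLS model per phenotype
   (growth rate, butanol rate) on autoscaled data, with R²X/R²Y,
   7-fold cross-validated Q², autoscaled regression coefficients, and
   Wold's VIP.
3. **Typing** — each metabolite gets one of nine labels (A–I) from its
   (VIPb, Coeffb, VIPg, Coeffg) quadruple: VIP > 1 decides significance
   first, coefficient sign second. Two-character display codes (`**`,
   `+*`, `-*`, `+-`, `-+`, `*+`, `*-`, `++`, `--`) are emitted for the
   network.
4. **Pathway analysis** — per-type over-representation (one-sided Fisher
   exact / hypergeometric test) against the measured-metabolite
   background, out-degree-centrality pathway impact, and the
   `-log10(p) > 1` filter.
5. **Network** — a bipartite metabolite–pathway graph of the surviving
   incidences (GraphML + edge TSV), plus per-time ratio trajectories of
   metabolite pairs.
6. **Synthetic data** — a four-phase fermentation simulator, a metabolome
   generator with planted phenotype effects of controllable sign and
   size, and a pathway-library generator (GMT + SIF) with planted
   pathways — so every stage is testable without external data.

## CLI

```sh
# generate a synthetic input bundle (tables, pathway library, ground truth,
# and a ready-to-run config); omit --design for the built-in 4x5x97 design
fermnet simulate --design design.yaml --out sim/

# run the full pipeline
fermnet run --config sim/run_config.yaml --out results/
```

Exit codes: 0 success, 2 config error, 3 stage failure. The output
directory contains every intermediate table (phenotype, relative
abundance, PLS scores, typed metabolites, enrichment, network edges,
ratios), `network.graphml`, a `manifest.json` with input/output hashes
and thresholds, and a human-readable `summary.txt`. Reruns with the same
config and seed are byte-identical.

A minimal run config:

```yaml
inputs:
  time_course: sim/time_course.tsv
  metabolite_table: sim/metabolite_table.tsv
  internal_standard: IS_succinate_d4
  kegg_map: sim/kegg_map.tsv
  pathway_gmt: sim/pathways.gmt
  pathway_sif: sim/pathways.sif
seed: 0
vip_threshold: 1.0
neg_log_p_cutoff: 1.0
ratio_pairs: [[met_000, met_001]]
```

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (PLS oracle
equivalence against eigendecomposition and a reference implementation,
the VIP sum-of-squares identity, the exhaustive typing partition check,
a full rational-arithmetic sweep of the Fisher test for N ≤ 30, impact
monotonicity on random DAGs, rate-estimator oracles, a 100-seed planted
signal recovery experiment, and byte-level determinism).

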