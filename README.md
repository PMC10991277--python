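# ogtpred

Optimal-growth-temperature regression from protein sequence, with
ortholog-aware cross-validation and thermophilic-enzyme mining.

## What this is for

Thermostable enzymes are prized in industrial biocatalysis, but finding
them experimentally is slow.  Microbial proteomes carry a compositional
imprint of their host's optimal growth temperature (OGT): thermophile
proteins are enriched in E, L, V, Y and depleted in D, H, M, Q, S, T.
`ogtpred` turns that imprint into a screening tool for computational
biologists and enzyme engineers:

1. **Corpus building** — label every protein of a genome collection with
   the host's OGT (°C); genomes are classed psychrophilic (OGT < 20),
   mesophilic (30 < OGT < 40) or thermophilic (OGT > 50), with the
   boundary bands excluded from labelling.
2. **Homology-aware splitting** — ortholog clusters (OrthoFinder
   `Orthogroups.tsv`) are the unit of ten-fold cross-validation, so
   homologs never straddle a fold boundary and validation scores measure
   generalisation instead of family memorisation.
3. **Model** — a 1-D convolutional regressor on one-hot sequence
   matrices (two conv+maxpool stages, two dense+dropout stages, linear
   output), trained with Adam/AMSGRAD on MSE in °C with early stopping;
   kernel size and neuron count are tunable by grid search (full-scale
   optimum: kernel 18, 256 neurons).
4. **Evaluation** — Pearson r and MAE per fold, genome-level averages
   (`optTem_pre` vs `optTem_exp`), and per-residue frequency-vs-label
   correlations.
5. **Mining** — rank precomputed `hmmsearch --tblout` hits (e.g. Pfam
   chitinase domain PF00704 against a metagenome catalogue) by predicted
   temperature, bin them into the three classes, and export the top
   candidates for synthesis.

The model is

&nbsp;&nbsp;&nbsp;&nbsp;*t̂(s) = f<sub>θ</sub>(onehot(s)) ∈ ℝ (°C)*,&nbsp;&nbsp;
*θ\* = argmin<sub>θ</sub> Σ<sub>i</sub> (t̂(s<sub>i</sub>) − OGT(g(s<sub>i</sub>)))²*

with g(s) the source genome, evaluated by Pearson's r and MAE between
t̂ and OGT over cluster-disjoint validation folds.

## Worked example

Generate a synthetic study corpus (18 genomes in three temperature
classes, 200 proteins each, planted composition signal and ortholog
families), split it, train one fold, evaluate, and mine the bundled
domain-hit fixture:

```bash
ogtpred simulate --seed 1 --out-dir run/data
ogtpred split    --data-dir run/data --k 10 --seed 1 --out-dir run/split
ogtpred train    --data-dir run/data --split-json run/split/split.json \
                 --fold 0 --seed 1 --config examples/desk.yaml --out-dir run/model
ogtpred evaluate --data-dir run/data --split-json run/split/split.json \
                 --checkpoint run/model/model_fold0.npz --out-dir run/eval
ogtpred mine     --tblout run/data/mining/hits.tblout \
                 --fasta run/data/mining/mining_targets.faa \
                 --model run/model/model_fold0.npz --top-n 5 --out-dir run/mine
```

With `examples/desk.yaml` (kernel 18, 32 neurons — a desk-scale width),
`run/eval/report.json` from the commands above reads:

```
"validation": { "n": 135, "pearson_r": 0.847, "mae_celsius": 10.27, ... }
"test":       { "n": 2186, "pearson_r": 0.940, "mae_celsius": 6.94, ... }
```

meaning: on ortholog clusters never seen in training, predicted and true
OGT correlate at r ≈ 0.85 with a mean absolute error of ≈ 10 °C — the
per-protein label is intentionally noisy (not every thermophile protein
is thermostable), which is why genome-averaged predictions correlate far
more strongly (r ≈ 0.97 on the same run).  The mining step writes
`ranked.tsv` (one row per domain hit, hottest first):

```
rank  protein_id  predicted_temp  temp_bin      full_seq_evalue
1     mg_00005    62.80           thermophilic  1e-40
2     mg_00004    55.28           thermophilic  1e-35
3     mg_00003    49.79           mesophilic    1e-30
```

plus `bin_fractions.json` (the psychrophilic/mesophilic/thermophilic
shares of all hits) and a FASTA of the top candidates ready for
synthesis.

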