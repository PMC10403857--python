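# clipnet

Sequence-to-signal modelling of CLIP-seq crosslink profiles.

CLIP-seq experiments (eCLIP, iCLIP, miCLIP) read out protein-RNA contacts as
per-base crosslink counts, but those counts blend protein-specific signal
with protocol bias that also shows up in size-matched input controls.
clipnet trains a dilated-convolutional network that predicts, from RNA
sequence alone, the per-nucleotide *distribution* of crosslink counts in a
window, modelled as an additive multinomial mixture

    p_total = π · p_target + (1 − π) · p_control

where `p_control` is simultaneously fit to the control library and π, the
sequence-predicted mixing coefficient, measures the per-window
signal-to-noise. Training minimises the multinomial negative log-likelihood
−Σᵢ cᵢ log pᵢ on both tracks. Around the trained model the package provides:

* **Site selection** — a sliding-window Poisson enrichment filter
  (window 100 nt, p < 0.01, count ≥ 8, height ≥ 2, 50-nt jump after
  acceptance) with chromosome-wise train/validation/test splits;
* **Inference** — variable-length and whole-transcript prediction, and
  disentanglement of observed totals into expected target/control counts
  (E_target = π·p_target·N);
* **Attribution** — profile-level Integrated Gradients with the
  self-weighted functional F(x) = Σ pᵢ·stop_grad(pᵢ) and an exact
  target/control decomposition;
* **Motif discovery** — top-attribution 5-mer extraction, relevance ranking,
  gapless greedy consensus construction, Jensen-Shannon PWM similarity, and
  in-vitro (RBNS/RNAcompete-style) top-k recall;
* **Variant scoring** — KLD(p_REF ‖ p_ALT) impact scores and saturation
  mutagenesis;
* **Synthetic data** — a generator with exactly the model's generative
  structure and known ground truth (planted motifs, true π, true profiles),
  making every stage testable end to end.

The model is an sklearn-style estimator (`ProfileNet`, with
`fit`/`predict`/`get_params`); the network and its automatic
differentiation are implemented in NumPy within the package.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from clipnet import ProfileNet, SyntheticConfig, simulate_windows, profile_pcc

data = simulate_windows(SyntheticConfig(n_windows=2000, seed=11))
train, val, test = (data.subset(range(1600)), data.subset(range(1600, 1800)),
                    data.subset(range(1800, 2000)))

net = ProfileNet(filters=32, n_blocks=4, max_epochs=20, batch_size=64,
                 random_state=7)
net.fit(train.sequences, train.stacked_counts(),
        validation_data=(val.sequences, val.stacked_counts()))

pred = net.predict(test.sequences)          # (200, 300) p_total vectors
pcc = np.mean([profile_pcc(pred[i], test.p_mixture[i])
               for i in range(len(test))])
rho = spearmanr(net.predict_pi(test.sequences), test.pi)[0]
print(f"held-out PCC vs true mixture: {pcc:.3f}")
print(f"mixing-coefficient rank correlation: {rho:.3f}")
```

```
held-out PCC vs true mixture: 0.955
mixing-coefficient rank correlation: 0.916
```

The first number says the predicted count distributions track the true
per-window mixture closely on held-out windows; the second says the model
ranks windows by their true signal fraction π almost perfectly, i.e. it has
learned that windows with more planted motif copies carry more
protein-specific signal. Interrogating the same model recovers the planted
motif:

```python
from clipnet import IGConfig, integrated_gradients, extract_top_kmer, \
    aggregate_relevance, build_consensus

order = np.argsort(-test.signal_counts.sum(axis=1))[:80]
kmers = []
for i in order:
    amap = integrated_gradients(net, test.sequences_str[i],
                                IGConfig(steps=32, track="target"))
    kmers.append(extract_top_kmer(amap, test.sequences_str[i], k=5))
top = build_consensus(aggregate_relevance(kmers))[0]
print(top.matrix.consensus_string(), round(top.support_fraction, 2))
```

```
ACUAAC 1.0
```

— the planted ACUAAC motif, rebuilt from aligned high-attribution 5-mers.

## Command line

Each stage is also a subcommand (`clipnet simulate`, `make-sites`, `train`,
`predict`, `attribute`, `motifs`, `score-variants`, `mutagenesis`,
`evaluate`, `evaluate-transcripts`); every run writes a manifest (inputs,
digests, seed, version) next to its outputs.

```bash
clipnet simulate --n-windows 200 --seed 1 --out sim/
clipnet make-sites --annotations sim/windows.bed \
    --track-plus sim/signal.plus.bedGraph --out sites.bed
clipnet train --sites sites.bed --fasta sim/windows.fasta \
    --track-plus sim/signal.plus.bedGraph \
    --control-plus sim/control.plus.bedGraph --seed 1 --out model.npz
clipnet evaluate --model model.npz --fasta sim/windows.fasta \
    --sites sites.bed --track-plus sim/signal.plus.bedGraph --out eval.json
```

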