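# Methods

## The modelling problem

CLIP-seq protocols (eCLIP, iCLIP, miCLIP) map protein-RNA contacts at
single-nucleotide resolution: reverse-transcription truncations pile up
adjacent to the crosslinked base, so the 5′ read-start coverage forms a
per-base "crosslink count" track. These counts mix two sources — genuine
protein-specific contacts and protocol biases (e.g. uridine-tract
crosslinking propensity) that also appear in a size-matched input control
library. clipnet learns, from sequence alone, the *distribution* of
crosslink counts over a window, and separates the two sources explicitly.

## Count model

For a window of length L with observed counts c and total n = Σc, counts are
modelled as Multinomial(n, p) with a sequence-predicted probability vector p.
The loss for a track h is the multinomial negative log-likelihood

    L_h = − Σ_i c_i log p_i ,

dropping the multinomial coefficient log(n!/Π c_i!), which is constant in
the parameters; reported loss values are defined without it. Losses are
computed in log space (log-softmax plus a log-sum-exp mixture) so
probabilities never underflow.

In paired mode the CLIP track is an additive mixture

    p_total = π · p_target + (1 − π) · p_control ,

with a per-window mixing coefficient π ∈ (0,1) predicted from sequence. The
control head p_control is simultaneously fit to the control-library counts,
which pins the bias component; p_target is then the de-biased,
protein-specific signal. The additive (not multiplicative) combination lets
a window carry bias signal at positions where the target track has
essentially zero mass. The total training loss is
L_CLIP(p_total) + L_Ctrl(p_control). Expected counts disentangle as
E_target = π·p_target·N and E_control = (1−π)·p_control·N, which sum to N by
construction.

## Architecture

One-hot input (A,C,G,U/T → unit vectors, N → zero row) → 1-D convolution
(128 filters, width 12, ReLU) → 9 residual blocks. Block i applies a dilated
convolution (128 filters, width 6, dilation 2^i), batch normalisation, ReLU
and dropout 0.25, with an identity skip connection. All convolutions use
same padding, stride 1 and no pooling, so every layer output is
position-aligned with the input and the network applies unchanged to
sequences of any length ≥ the first convolution width. Each output head is a
transposed convolution with one width-20 filter producing per-position
scores, normalised by softmax over positions; π is a logistic unit on the
globally average-pooled bottleneck. At inference, batch normalisation uses
running statistics and dropout is off, which is what makes single-window
variable-length prediction deterministic and well defined.

Open choices resolved here: the first convolution carries ReLU only (no
batch normalisation); the dilation schedule starts at 2^1; probability
normalisation is exponentiate-and-renormalise, the parameterisation a
multinomial likelihood forces; the residual sum needs no projection because
channel counts match.

The network, its reverse-mode autodiff and the Adam optimiser are
implemented in NumPy inside the package (`clipnet.autodiff`, `clipnet.nn`):
convolutions are evaluated as sums of shifted BLAS matrix products with a
fused backward pass. Gradients are verified against central finite
differences in the test suite. Training tensors are float32; attribution
graphs run in float64 (see below).

## Training

Adam at initial learning rate 0.004, batches of 128 (configurable), at most
50 epochs. The learning rate halves when the validation loss has not
improved for 6 epochs; training stops after 10 epochs without improvement;
the best-validation weights are restored. Candidate training sites are
split by chromosome — chr2/9/16 validation, chr1/8/15 held-out test, other
autosomes train, non-autosomes excluded. One integer seed drives weight
initialisation, shuffling and dropout.

## Candidate-site selection

A 100-nt window slides at stride 1 over each annotated gene (counts taken
5′→3′, strand-specifically, summed over the full gene span including
introns). A window is accepted when its count total is enriched under
Poisson(λ = gene_count · 100 / gene_len) with upper-tail p < 0.01, total ≥ 8
(4 in iCLIP mode, reflecting shallower libraries) and maximum position-wise
count ≥ 2. After an acceptance the scan jumps 50 nt, suppressing redundant
overlapping candidates; accepted cores are extended symmetrically to 300 nt,
shifting inward at gene edges (genes shorter than 300 nt are skipped so
training tensors have fixed length). Sites from overlapping genes are
deduplicated on identical (interval, strand). The Poisson tail uses the
scipy survival function; the suite checks it against direct pmf summation
and the whole scanner against an independent brute-force enumeration.

## Attribution

Integrated Gradients is generalised from scalar outputs to profiles through
the functional F(x) = Σ_i p_i · stop_grad(p_i), numerically Σ p_i² with the
weighting excluded from differentiation, so high-probability positions
dominate without needing observed counts. The count-weighted alternative
F = Σ p_i c_i is available but not used downstream (it requires true counts
and can up-weight bias positions). The three track functionals decompose
additively: with shared weights w = stop_grad(p_total),
F_total = π Σ p_target,i w_i + (1−π) Σ p_control,i w_i exactly.

Two numerical decisions matter:

* The stop-gradient weights are frozen at the *observed input* for the whole
  integration path. F is then a genuine scalar functional with a
  conservative gradient field, and the completeness identity
  Σ IG = F(x) − F(x′) holds as the step count grows. (Re-freezing the
  weights at every interpolation point integrates a non-conservative field
  that converges to ½·Δ(Σp²) — a 50 % completeness residual by
  construction.)
* The path integral uses the midpoint rule, 50 steps by default, baseline
  x′ = 0 (the "absent sequence"; uniform 0.25 offered since completeness is
  baseline-relative), and the path graph runs in float64 so the quadrature
  error, not round-off, limits the residual. Because ReLU kinks make the
  integrand piecewise smooth, per-window residuals oscillate in sign as
  steps double; the residual shrinks monotonically in the mean over windows,
  and that is what the tests measure.

## Motif discovery

For each selected window (ranked by observed window count; the top-N
selection generalises narrow-peak ranking so it applies to synthetic data),
the 5-mer with the highest summed observed-base attribution (IG_sum) is
extracted, ties to the leftmost, windows containing N skipped. K-mers are
ranked by aggregate relevance (sum of IG_sum over occurrences) and greedily
aligned without gaps: each k-mer joins the earliest-created alignment
admitting ≥ 3 matches to the running column-majority consensus at its best
offset (most matches; ties to the smallest absolute, then most upstream
offset; column-majority ties resolve to the base that entered the column
first), otherwise it seeds a new alignment. Position-wise frequencies of
the aligned members give the consensus matrix; support is the member count.

Similarity of a k-mer to a reference PWM is 1 − mean position-wise base-2
Jensen-Shannon divergence, maximised over all sliding offsets with ≥ 3
overlapping columns and over all reference PWMs of the protein. The
inversion (1 − JSD) makes 1 mean identity, as a similarity should; one-hot
k-mer columns are used without pseudocounts since the JSD midpoint keeps the
divergence finite. In-vitro tables: R-scores standardise with the population
standard deviation; 7-mer scores convert to 5-mers by occurrence-weighted
means (a 7-mer containing a 5-mer twice contributes twice); agreement with a
model ranking is top-20 recall.

## Variant scoring

A single-nucleotide variant is scored on a model-native 300-nt window
centred on it (full-window divergence; a window this size avoids edge
effects, and the sub-window choice is configurable). Impact is
KLD(p_REF ‖ p_ALT) in nats — REF first, no symmetrisation — finite because
softmax probabilities are strictly positive, with the L2 profile difference
as a secondary score. The de-biased target track is the default in paired
mode, total otherwise. Saturation mutagenesis emits exactly 3·L scores (the
three alternative bases per position). A declared REF allele that
contradicts the fetched genome base is an error, not a warning. Inputs
shorter than the first convolution width are rejected, so the smallest
scorable window is 12 nt.

## Evaluation metrics

Window-level: Pearson correlation between the predicted probability vector
and observed counts (affine-invariant, so probabilities versus expected
counts is immaterial); constant-count windows are excluded and reported.
Site-level: within each transcript, called crosslink positions are
positives, all other positions negatives; auROC (rank statistic, ties at
half credit) and average precision are computed per transcript and averaged
across transcripts with at least `min_positives` sites (default 1; 10
reproduces stricter transcript selection). Scores are never pooled across
transcripts: a softmax profile sums to 1 per transcript, so positions are
only comparable within one.

A replicate baseline puts model accuracy in context: drawing pairs of
multinomial samples from a fixed truth p, the expected PCC between p and a
sample exceeds the expected PCC between two samples, because the truth
carries no sampling noise. A sequence model fit across windows can therefore
legitimately correlate better with an experiment than a biological replicate
does.

## Synthetic data

`clipnet.simulate` generates windows with exactly the generative structure
the model assumes, so every stage is testable with known truth. Defaults:
300-nt windows of uniform background; target motif ACUAAC planted at
random positions; U-rich bias motif (UUUUU) at 3 sites; p_target a Gaussian
bump (σ = 2 nt) centred 3 nt upstream of each motif start (truncations
accumulate immediately upstream of the bound motif); p_control is bias-site
bumps plus a 50 % uniform floor; window totals are negative binomial
(mean 50, dispersion 5) so depth varies across windows, with the control
library's depth drawn independently; signal counts are multinomial from the
π-mixture and control counts from p_control alone.

The mixing coefficient takes values {0.2, 0.5, 0.8} tied to 1/2/3 planted
motif copies. The coupling is deliberate: π is predicted from sequence
alone, so it is recoverable only if sequence carries it, and in real data
the signal fraction tracks motif strength. What the generator does not
emulate: PCR duplication, crosslink-induced mutations, transcript-abundance
variation, non-uniform background composition and genuinely unknown motifs —
so passing recovery tests demonstrates correctness of the machinery under
the model's own assumptions, not performance on real libraries.

`simulate_gene_track` produces Poisson background plus count spikes together
with the window starts an independent brute-force enumeration of the site
filter accepts, serving as the oracle for the production scanner.

## Test and acceptance problem sizes

The recovery suite trains a reduced model — 32 filters, 4 residual blocks,
batch 64, at most 20 epochs — on 1600 of 2000 simulated windows (200
validation, 200 held out). At these sizes training takes a few minutes on a
single CPU and the held-out checks are comfortably cleared (profile PCC
against the true mixture ≈ 0.95 versus the ≥ 0.5 requirement; π rank
correlation ≈ 0.92 versus > 0.5; consensus motif identical to the planted
ACUAAC). `scripts/acceptance.py` re-runs the same pipeline from scratch with
seeds derived from `--seed`.

## Known limitations

* No tiled inference: normalisation is global over the input, so stitching
  windows would change its semantics; sequences above `length_cap`
  (default 100 000 nt) are rejected with guidance.
* Replicates are merged by summation before training; no replicate
  weighting.
* The consensus aligner is greedy and order-dependent by design; it is a
  ranking summary, not an EM motif model.
* Single-base substitutions only in variant scoring; no indels.
* Training the full-size configuration (128 filters, 9 blocks) on real
  genome-scale site sets is substantially slower in this NumPy
  implementation than in a GPU framework; the architecture and losses are
  identical, only throughput differs.
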