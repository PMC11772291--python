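# Methods

`entner` implements an entity-aware domain-adaptation pipeline for clinical
named-entity recognition (NER), built around three ideas: masking *entities
rather than random tokens* during continued pre-training, anchoring the masked
representations to a frozen teacher with a contrastive objective, and a
fine-tuning stack (consistency regularization, section-information fusion,
up-sampling, pseudo-labeling) aimed at low-resource clinical corpora. The
target domain is inflammatory bowel disease (IBD) consultation notes: nine
entity types (diagnosis, diagnosis date, disease location/behavior/extent in
Montreal-classification vocabulary, peri-anal disease, previous surgery,
height, weight) annotated as flat character-offset spans in BRAT standoff
format and modeled as token-level BIO sequence labeling.

## Sequence labeling model

A sentence `X = [x1..xn]` is tokenized by a whitespace/punctuation tokenizer
that preserves exact character offsets (subword tokenization is deliberately
out of scope; the pipeline's bookkeeping is defined at the word-token level).
A transformer encoder produces hidden states that feed a linear classifier
over the BIO label space `C` (|C| = 2·9 + 1 = 19). Training minimizes the
token-level cross-entropy

    L_CE = -(1/N) Σ_i Σ_j y_ij log ŷ_ij

with label smoothing ε = 0.1 (ε = 0 recovers plain cross-entropy exactly).
Label dependencies are modeled by an additional transition-score layer over
label bigrams consumed by Viterbi decoding — a simulated CRF. By default the
transition scores are a fixed structural matrix (I-x may only follow B-x/I-x;
violations carry a −10⁴ penalty) and training stays per-token; with
`crf_nll=True` the transitions become learnable parameters trained by the
linear-chain sequence negative log-likelihood (forward algorithm in log
space). Decoding ties break toward the lowest label index.

### Encoder

The encoder is a small transformer trained from scratch (default 2 post-LN
layers, hidden size 64, 4 heads, GELU feed-forward of 4×, learned positional
embeddings, dropout 0.1). It replaces the large pre-trained language model a
production system would start from; any checkpoint exposing the same
interface can be substituted. All tensor math runs on a compact reverse-mode
autodiff layer over numpy (float64), adequate at this scale and verified
against central differences to ~1e-7.

Because the encoder is trained from scratch rather than adapted from a
pre-trained LM, the default learning rates are scratch-scale: 1e-3 for both
continued pre-training and fine-tuning (Adam, linear warmup over the first
10% of steps). A pre-trained encoder would want the conventional 1e-4 / 5e-5;
both are plain config fields.

## Continued pre-training

Three variants share one loop (default 200 steps, batch 32):

* **MLM** — each ordinary token is masked with probability p = 0.15 under the
  standard 80/10/10 corruption split (mask token / random token / keep).
  Special tokens and label tokens are never candidates.
* **EMLM (entity MLM)** — a label token encoding each entity token's BIO tag
  (`<B-diagnosis>` …) is inserted immediately before and after it; these label
  tokens act as ordinary context and are never masked. Only entity tokens are
  candidates, each masked independently with probability η = 0.7 (a per-token
  Bernoulli rate; an exact-fraction alternative exists but was not chosen —
  Bernoulli keeps the draw i.i.d. and the expected-rate tests exact). Masks
  are re-drawn every epoch (dynamic masking). The loss is the masked-token
  negative log-likelihood, L_E-MLM = −Σ_i m_i · log P(x_i | X^m). Label-token
  embeddings are initialized as the mean of the embeddings of the words in the
  entity-type name, so inserted labels start semantically close to related
  vocabulary.
* **EMLM + CL** — EMLM plus a masked-entity contrastive objective against a
  frozen teacher. Student and teacher are initialized from the identical
  checkpoint; only the student trains. The student encodes the masked sequence
  (h^m), the teacher the original (h), and for every masked entity position i

      L_CL = -Σ_i 1[i masked entity] · log  exp(cos(h_i^m, h_i)/τ)
                                            ─────────────────────────
                                            Σ_j exp(cos(h_i^m, h_j)/τ)

  with temperature τ = 0.01 and the denominator over all positions j of the
  same sentence (per-sentence, not cross-batch; inserted label tokens count as
  ordinary positions). The total objective is the plain sum
  L_pretrain = L_CL + L_E-MLM; the bundle maintains this identity exactly.

Convergence is operationalized as a fixed step budget rather than a loss-curve
criterion; the logged `l_per_masked` (loss per masked token) is the meaningful
progress metric because raw sums scale with how many tokens a batch happens to
mask.

## Fine-tuning stack

* **R-drop consistency** — the same batch is passed through the encoder twice
  under independent dropout draws, giving token distributions P1 and P2; the
  penalty is the per-token mean of ½[KL(P1‖P2) + KL(P2‖P1)], and the combined
  objective is L_finetune = L_CE + α·L_rdrop with α = 1 by default (applied to
  token distributions only, not the sentence head). With dropout 0 the two
  passes coincide and the penalty is exactly 0.
* **Section fusion** — the note's section title enters the model at one of
  three injection points: `embed` (a learned section embedding concatenated to
  every token embedding and projected back; the projection initializes to
  [I; 0], making the mode an exact identity at initialization), `text` (title
  tokens prepended with a separator), or `bias` (a per-section offset added
  uniformly to every token's label scores). Unknown titles map to a learned
  UNK attribute. Default for fusion variants: `embed`.
* **Up-sampling** — sentences mentioning under-represented entity classes are
  duplicated until each class's sentence count reaches (max class count)/r,
  r = 2 by default; originals are always retained.
* **Pseudo-labeling** — a trained model predicts on unlabeled notes; the
  Viterbi output is BIO-repaired (stray I- promoted to B-) and kept as silver
  data, flagged distinct from gold, in a single generation pass (re-invoke for
  iteration). No confidence filter by default; an optional mean-max-probability
  threshold is available.
* **Multi-task head (optional)** — a sentence-level binary head (peri-anal
  disease mention, the rarest class) reads only the first-position state;
  token classification reads the remaining positions. Joint loss is CE + BCE
  at 1:1.

Model selection is early stopping on dev strict micro-F1 with patience 10
epochs (30-epoch budget per training phase).

## Evaluation

Matching is span-level. *Strict*: exact (start, end, label). *Entity-type*:
label match with ≥ 1 character of overlap (no IoU threshold), each gold and
prediction matched at most once. Matched pairs are chosen in order of
decreasing overlap (ties leftmost) with augmenting paths guaranteeing a
maximum-cardinality matching — a plain greedy pass can strand a matchable pair
when spans interleave, which would break both the dominance property
(type TP ≥ strict TP) and agreement with the exhaustive assignment oracle.
Headline scores are micro-averaged; a token-level tagging accuracy is exposed
as a secondary diagnostic. Errors are assigned deterministically to a
five-way taxonomy (per prediction, in precedence order): conjunction merge
(one prediction covering ≥ 2 same-type golds with a conjunction in the gap),
extra information (gold strictly inside prediction), missing information
(prediction strictly inside gold), different entity type (overlap, other type
only), missing gold annotation (no overlap); untouched golds are reported
uncategorized.

## Synthetic corpus

The generator emits template-based pseudo-Dutch notes — section header lines
(`Anamnese:`, `Endoscopie:`, `Familiaal:`, …) followed by slot-filled
sentences — with exact 0-based half-open offsets and byte-identical output for
a fixed spec. It emulates the structural features that drive the method:

* nine entity types with heavy class imbalance (default relative weights put
  diagnosis ~30× peri-anal disease, the rarest class; the defaults are
  order-of-magnitude choices, not reproductions of any real corpus's counts);
* section-dependent validity: each section admits only certain entity types,
  and family-history sections contain diagnosis surface forms with *no* gold
  span — half of them rendered from the same templates as genuine diagnosis
  sentences, so the sentence text alone cannot decide entityhood and only the
  section can (without this lexical overlap the "ambiguity" would be trivially
  separable and section fusion untestable);
* abbreviation ambiguity: CD/UC appear both as diagnosis surfaces and inside
  lab-section measurement sentences;
* multi-token spans occasionally joined by a conjunction ("en"/"of") as two
  separate gold spans, feeding the conjunction-merge error category;
* an unlabeled fraction drawn from the same templates, so pseudo-labeling
  operates on in-distribution text.

What it does **not** emulate: real Dutch grammar and spelling variation,
annotator disagreement, discontinuous or nested entities, cross-sentence
entities, and realistic vocabulary size (a few hundred types). Passing tests
therefore demonstrate that the machinery is correct and that the directional
effects (pre-training helps initialization; section fusion buys precision
under section ambiguity) materialize under controlled conditions — not that
any particular score would transfer to real clinical text.

## Experiment matrix and problem sizes

`run_matrix` executes named variants (FT, FT-FS, FT-FS-PL, MLM-FT-FS-PL,
EMLM-FT, EMLM-FT-FS-PL, EMLM-CL-FT-FS-PL) over a seed list on shared
document-level splits (70/15/15 by note; test notes never enter pre-training,
fine-tuning, pseudo-labeling or up-sampling pools). The bundled experiments
use desk-scale sizes chosen as the package's defaults: 60-note corpora
(~900 sentences), a 2-layer/64-dim encoder, 200 pre-training steps, 30-epoch
fine-tuning budgets, and medians over 3 seeds for the directional
comparisons. Pseudo-label variants train a second phase on gold + silver.

## Numerical choices and degenerate inputs

* Float64 throughout; probabilities are clamped at 1e-12 before logs where a
  zero could face positive mass (R-drop, Viterbi emissions).
* Cosine similarity on a zero-norm vector raises rather than silently
  normalizing.
* A sentence with no entity tokens yields an empty entity mask (logged), not
  an error; a whole corpus without entities is a configuration error for the
  entity-masking variants.
* Invalid BIO output (I- after O or after a different type) is repaired to B-
  with a logged count, never rejected — model output must stay consumable.
* Viterbi and argmax ties resolve to the lowest label index; numpy's argmax
  ordering makes this deterministic.

## Known limitations

* The word-level tokenizer sidesteps subword/label alignment entirely; models
  requiring subword vocabularies would need tag propagation to first
  subpieces.
* The contrastive temperature τ = 0.01 is sharp; with random small-model
  representations the objective saturates quickly, and most of its measurable
  effect at this scale is on representation alignment rather than end-task F1.
* One pseudo-labeling pass, document-level random splits (no temporal/phase
  structure), flat entities only, no relation or attribute annotations.
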