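# Methods

## The model

`seqlda` treats nucleotide sequences as documents and k-mers as words and
fits a latent Dirichlet allocation (LDA) mixture model to k-mer count
matrices.  Each sample d carries topic proportions
θ_d ~ Dirichlet(α); each token in the sample draws a topic
z ~ Categorical(θ_d) and a feature w ~ Categorical(φ_z), where the K
topic–feature distributions φ_k have a Dirichlet(η) prior.  Topics are
interpreted as sequence signals: a splice-site motif, a base-composition
class, or a reading frame, depending on how the counts were built.

Three featurizations produce the count matrices:

1. **Positions as samples.** Sequences are aligned at an anchor (for a 3′
   splice site the intron-terminal AG occupies positions −2/−1).  Each
   alignment position is one sample; its counts are the k-mers starting in
   a sliding window of `window` adjacent positions, pooled over all
   sequences.  Rows are labeled by the window *start* position.  This view
   localizes motifs: a topic's membership curve across positions peaks
   where its k-mers concentrate.
2. **Positional k-mers as features.** Whole sequences (or packs of them)
   are samples; each feature couples a k-mer with its start position
   (`CCAG_at_-4`).  This distinguishes subtypes of aligned sequences.
3. **Bulk / frame-tagged k-mers.** Unaligned sequences are samples over
   the plain 4^k vocabulary.  For coding sequences the counts are split
   into three vectors by reading frame, where the k-mer at 0-based offset
   i belongs to frame (i mod 3) + 1 of the annotated frame-1 sequence.

Any k-mer window containing a non-ACGT base is skipped entirely — counted
in neither numerator nor denominator of any quantity.  The treatment of
ambiguous bases is this package's convention; only A/C/G/T are modeled.

## Inference

Fitting is batch variational Bayes with the standard fixed-point updates:
a per-document E-step refining variational Dirichlet parameters γ_d
(initialized at α + n_d/K, iterated to a mean membership change < 1e-3,
at most 100 inner iterations), and an M-step updating the variational
topic–feature parameters λ = η + sufficient statistics.  All updates touch
only the nonzero entries of the count matrix, so large sparse positional
vocabularies are cheap.  The evidence lower bound (ELBO) is computed every
iteration and recorded in `fit_info["bound_history"]`.

Numerical choices:

* **Priors** default to symmetric α = η = 1/K, the common default of batch
  variational LDA implementations; both are overridable.
* **Convergence.** The fit stops when the relative ELBO change stays below
  `tol` (default 1e-6) for 3 consecutive iterations, or at `max_iter`
  (default 100).  The patience matters: on position-as-samples corpora the
  bound can plateau for an iteration or two before topics separate, and a
  single small step is not convergence.  A looser tolerance (1e-3..1e-4
  relative) reliably under-fits because the bound magnitude scales with
  corpus token count.
* **Restarts.** `fit_lda(..., n_init=r)` runs r fits from seed-derived
  initializations (seed + 100003·i) and keeps the run with the highest
  final ELBO.  Like any mixture model, LDA has local optima — e.g. two
  topics splitting one reading frame while a third absorbs the other two
  frames; such collapsed solutions show clearly lower bounds, so
  bound-based selection discards them without reference to any labels.
  The pipelines in the test-suite and acceptance script use `n_init=3`.
* **Topic identifiability.** Topics are exchangeable, so after fitting
  they are re-ordered by descending total corpus usage (expected token
  mass); identical seeds then reproduce serialized models bit-for-bit.
* **Transform.** New samples are folded in by running the E-step with the
  point-estimate topics log φ held fixed.  The memberships returned by
  `fit_lda` are computed the same way, so `transform(model, training)`
  reproduces them exactly.  An all-zero row receives the prior mean
  (uniform 1/K).  Features absent from a query matrix are treated as zero
  counts; features unknown to the model are an error, because silently
  dropping misaligned positional vocabularies is the likeliest user bug.
* **Degenerate inputs.** An all-zero matrix is an error; K greater than
  the sample count warns and proceeds; K = 1 reduces to the
  prior-smoothed corpus frequency vector.

## Interpretation

Driving k-mers: the observation of k-mer w under topic t is a
Bernoulli(φ_t[w]) variable; the distinctiveness of w in t is
min_{t′≠t} KL(Bern(φ_t[w]) ‖ Bern(φ_t′[w])), in nats.  Each k-mer is
assigned to its argmax topic and each topic ranks its assigned k-mers by
distinctiveness (ties broken lexicographically).  The min-over-others
aggregation is the conservative reading of "distinct from all other
topics"; probabilities are clamped at 1e-12 to guard round-off in
serialized models.  Raw per-topic probabilities are deliberately not used
for ranking: abundant k-mers top several topics at once.

Likelihood scores: the fit of a sequence to a single topic is
Σ_windows ln φ_t[w], reported in log space only (the exponentiated product
underflows at realistic lengths).  All length−k+1 windows enter the sum.
For position-as-samples matrices the same multinomial form
Σ_w n[w]·ln φ_t[w] gives per-position likelihood curves; the count-only
combinatorial constant is topic-independent and omitted.

Subtype classification: Score(t | label) = log2 of (mean membership of t
within the label / mean membership of t overall).  A sample's predicted
label is the argmax over labels of membership · score column, ties going
to the alphabetically first label.  Reading-frame classification applies
this with labels {frame1, frame2, frame3} to the three frame-tagged count
vectors of a sequence; a prediction triple (1,2,3) is correct, and the
cyclic triples (2,3,1) and (3,1,2) flag potential frame shifts.

smORFs: an ATG paired with the next in-frame stop (TAA/TAG/TGA) with at
least 25 codons strictly between them, scanned in the three sense-strand
frames only (inputs are transcripts).  By default each stop is paired with
the most upstream ATG after the previous in-frame stop (longest-ORF rule);
`longest_only=False` emits every qualifying ATG.  Both policies are exact
against brute-force enumeration in the tests.  A smORF is called
coding-like when, treated as frame 1, all three of its reading frames are
classified correctly by a CDS-trained model.

Signal curves: at each window of positions, the fraction of k-mers
containing an IUPAC pattern (containment as substring, e.g. TNAC for the
human branch-site core, YYYYYY for a pyrimidine run).  The convention of
dividing this fraction by (window × k) to express a per-single-position
value is reported as `values`; the raw fraction is returned alongside,
since the division changes units without changing shape.  The branch-site
pattern is a mandatory parameter (documented default TNAC) because the
consensus is written several ways in the literature (TNAC, TAAC, CTNA,
CTRAY) and the package does not adjudicate.

## Synthetic data

The generators define the study conditions for every test:

* `simulate_topic_corpus` draws directly from the generative model
  (φ* rows Dirichlet(0.1), θ* rows Dirichlet(0.3), multinomial tokens),
  giving a ground truth for parameter recovery.  The reference condition
  is K=3, V=256, 200 samples × 2000 tokens.
* `simulate_anchored_introns` plants an IUPAC-instantiated branch motif at
  a fixed anchored offset (default scenario: TNAC at −30 with probability
  0.7) and an elevated-C/T tract (−20..−6, C+T probability 0.85) on a
  uniform background, anchor at the 3′ end.  Codes in the motif are
  resolved uniformly per sequence.
* `simulate_cds` draws internal codons i.i.d. from a 64-entry weight
  table with zero stop-codon mass, between an ATG and a uniform stop.  The
  default table is Zipf(s=1.5) over the 61 sense codons in seed-shuffled
  order — a strong, known codon bias so that reading-frame signal exists
  at desk scale (3000 training / 500 held-out sequences of 100–300
  codons).

What these emulate — and what they do not: real introns carry correlated
composition, length variation, and degenerate branch sites; real codon
bias is milder and gene-dependent; real UTRs are not uniform random
nucleotides.  Passing tests therefore demonstrate the correctness of the
machinery (counting, inference, scoring, enumeration) and its behavior
under known signal, not genome-scale performance figures, which depend on
annotation-derived data outside this package's scope.

## Problem sizes

The test-suite and the acceptance script run the pipelines at the sizes
stated above (200×2000-token corpora; 3000/500 CDS with packs 1–50; 2000
introns of 80 nt; 50 random 600-nt smORF fixtures), the package's chosen
desk-scale study conditions.  The pooling sweep repeats the CDS pipeline
over pack sizes {1, 5, 25} and three seeds.

## Known limitations

* Inference is batch-only; there is no online/streaming update and no
  automatic selection of the topic count.
* The likelihood treats overlapping k-mer windows as independent tokens;
  it is a scoring device, not a normalized sequence probability.
* Driving-k-mer tables list individual k-mers; assembling them into
  consensus motifs or information-content logos is left to the user (a
  position frequency matrix export is provided).
* smORF scanning is sense-strand only and uses ATG starts exclusively; no
  Kozak-context or start-codon-variant scoring.
* Classification is an uncalibrated score argmax; scores are relative
  enrichments, not posterior probabilities.
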