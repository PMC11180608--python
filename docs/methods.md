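# Methods

This note documents the models implemented in `alnvec`, the choices made
where the design was genuinely open, and what the synthetic studies do and
do not demonstrate.

## The problem

Remote homologs — proteins that share structure but have drifted below
~25% sequence identity — are invisible to classical sequence alignment.
Structure comparison (TM-score, a length-normalized similarity in (0,1]
where < 0.2 means unrelated and > 0.5 means same fold) detects them, but
needs structures. `alnvec` implements a two-stage, sequence-only stack:

1. **Retrieval.** A twin (Siamese) encoder φ maps each protein's
   per-residue embeddings to a single vector whose cosine similarity to
   another protein's vector is trained to equal the pair's TM-score. A
   database of such vectors is indexed and searched by cosine.
2. **Alignment.** A differentiable Needleman–Wunsch (NW) layer, scored by
   learned match/gap heads over the same residue embeddings, produces
   residue-level alignments of the query against each retrieved hit.

## Differentiable Needleman–Wunsch

The recursion on the p×q grid of a pair (X, Y) is

    v[i,j] = mu[i,j] + max( v[i-1,j-1],             (match, M)
                            g[i,j] + v[i-1,j],      (insert, X)
                            g[i,j] + v[i,j-1] )     (delete, Y)

with μ the match log-odds and g < 0 the gap log-odds. Note μ is added on
all three branches; `mu_on_gaps=False` selects the textbook variant (μ on
the match branch only) and all derivative bookkeeping follows the selected
mode. Replacing max by τ·log∑exp(·/τ) and argmax by softmax(·/τ) makes
v[p,q] smooth. The gradient of v[p,q] with respect to μ is the **expected
alignment** e: e[i,j] is the probability, under the Gibbs distribution over
monotone lattice paths, that the path visits cell (i,j). It is computed by
an adjoint sweep over the softmax weights ω, and a second
forward/backward sweep propagates a perturbation Z = [z_μ, z_g], giving
the directional derivative ⟨∇v, Z⟩ and the Hessian–vector product ∇²v·Z.
The ω̇ rule is the derivative of softmax, ω̇ = (diag(ω) − ωωᵀ)·ȧ/τ; it is
validated against central finite differences (the suite holds both sweeps
to relative error < 1e−4, and in practice they agree to ~1e−10).

Two boundary conventions are supported and recorded in every result:

* `as_printed` (default): v[0,0] = 1, other boundary cells 0. All finite;
  paths effectively enter anywhere along the top/left border.
* `path_strict`: v[0,0] = 0, other boundary cells −∞. Every path then runs
  from cell (1,1) to (p,q) and v[p,q] is exactly τ·log∑ over complete path
  scores — the semantics the exhaustive enumeration oracle checks (all
  grids ≤ 36 cells, agreement to 1e−8 in both modes).

**Reverse mode through e.** Training needs ∇_θ L for a loss L(e). By
symmetry of second derivatives, the vector–Jacobian product with adjoint
u = ∂L/∂e equals a forward-mode sweep along Z = (u, 0):
∇_μ L = ė(Z) and, since ∂v/∂g = E∘(ω^x+ω^y),
∇_g L = ė(Z)∘(ω^x+ω^y) + e∘(ω̇^x(Z)+ω̇^y(Z)).
This is verified elementwise against finite differences.

**Numerics.** Kernels are numba-compiled over float64; −∞ boundaries use
IEEE infinities with max-shifted log-sum-exp; probabilities are clamped to
[1e−12, 1−1e−12] before any logarithm; temperature defaults to 1
(exactly the printed operators) and is exposed mainly for the
zero-temperature-limit tests, where the smoothed value decreases to the
hard score within τ·log(3pq). Hard decoding is the classical max/argmax
under `path_strict` borders with fixed tie precedence match > insert >
delete, so decoding is deterministic and always yields a valid monotone
path. Batched evaluation slices each instance to its true (p,q) before the
kernel runs, so padded cells are never read and batch results are bitwise
identical to solo evaluation.

## Scoring heads

Match and gap scores come from two independent convolutional stacks M, G
(1-D convolutions, kernel size 5, same-padding, ReLU between layers;
reference scale eight layers of width 1024 on d = 1024, desk scale two
layers of width 32 on d = 16):

    mu = softplus(M(H_X) M(H_Y)ᵀ),   g = logsigmoid(G(H_X) G(H_Y)ᵀ).

The activations guarantee μ > 0 and g < 0 for arbitrary parameters, which
rewards matches, penalizes gaps and keeps the model identifiable.
Pre-activations are clipped to ±30 log-odds so the strict signs survive
floating-point underflow; scores beyond ±30 carry no usable information,
and gradients vanish only where the score is already saturated.

## Twin encoder and similarity regression

φ = transformer encoder layers (post-norm; 4 attention heads and
feed-forward width 2048 at reference scale) → masked average pooling →
dropout (0.1, inference-disabled) → one hidden fully connected layer with
tanh → linear projection (512-dim output at reference scale). The FC head
depth/width after pooling is not pinned down at reference scale; one
hidden layer of the output width was chosen, so parameter counts are not
comparable to any published model. tanh rather than a rectifier keeps the
hidden representation sign-symmetric, which suits a cosine-similarity
output. Both residual branches of each transformer block start with
zero-initialized output projections, so every block is the identity at
initialization — a standard stabilization when training transformers from
scratch on small corpora, and the identity map is exactly the right prior
here because the pooled input features already carry the similarity
signal.

Training minimizes mean |cos(φ(a), φ(b)) − label| with Adam (reference
initial learning rate 1e−4, batch size 32; the desk-scale study uses
2e−3). Both proteins share one φ. The best-validation snapshot is
restored. Sequences are encoded individually at their true length, so
"batching" is a loop, pooling never sees padding, and batch composition
cannot change a vector.

## Vector database

Vectors are L2-normalized at build time; cosine is an inner product; ties
break lexicographically by id, making search a pure function of (database,
queries, k). The exact backend is a brute-force scan and serves as ground
truth. The approximate backend is an inverted-file (IVF) index: k-means
into ~√n cells, query scans the `n_probe` best cells. The default probes
3/4 of the cells because that is what keeps recall@10 ≥ 0.95 on fully
unstructured Gaussian corpora — the worst case for an IVF index; clustered
real corpora tolerate far fewer probes, and `n_probe` is configurable. The
on-disk format (16-byte header + float32 rows, id list, key=value
manifest) is rebuildable bit-identically from the same inputs and seed;
the manifest's model hash is checked at query time.

## Training-data filter

Alignment training records are excluded when the alignment contains a run
of **more than 10** consecutive identical gap states (a run of exactly 10
is retained; a run mixing X and Y states counts as two separate runs —
the mixed case is not specified anywhere and this is the documented
choice) or when the structural-similarity label is **below 0.6** (exactly
0.6 is retained). The cross-entropy loss over e (Eq. form: sum of
e*·log e + (1−e*)·log(1−e)) is negated and averaged over cells by default
so learning rates are length-independent; a sum reduction is available.

## Synthetic studies: what they emulate and what they show

The generator plants every signal the real pipeline consumes: families
evolved from random ancestors by per-site substitution and geometric
indels (mean length 2); exact ground-truth alignments composed through
shared ancestor positions; labels exp(−λ·divergence) + N(0, σ²) clamped
to [0,1] with λ = 2, σ = 0.02 — a stand-in for TM-scores chosen because
recovery experiments only need a monotone, bounded, noisy label; and
cross-family pairs labeled uniformly in [0.02, 0.2] (unrelated regime).
Ancestors are 100–200 residues, matching typical protein chains and the
length-filtered corpora this emulates (≤ 300 residues); substitution-only
divergence up to 0.35 per member. The toy embedder provides the
residue-level signal: windowed-mean channels (identity vectors averaged
over ±2 neighbors) that degrade gracefully under substitution, plus
optional k-mer-hash channels (a position's vector is seeded by a CRC of
its local 3-mer) that are identical for conserved windows and independent
otherwise, so pooled inner products count shared k-mers. The regression
study uses 64 channels (48 of them hash); the alignment study uses 16
windowed-mean channels.

The studies are deliberately small: ~500 labeled pairs / 15 epochs for the
similarity regression (held-out median |pred − label| ≈ 0.074, Spearman
vs planted divergence ≈ −0.84); 300 filtered alignments / ≤ 35 epochs for
the aligner (held-out median edge precision ≈ 0.98, recall ≈ 0.82);
retrieval on a fold-structured corpus — member divergence ≤ 0.17, so
within-family pairs sit in the "same fold" similarity regime ≥ 0.5 — with
the encoder transferred unchanged from the regression study (top-1 family
sensitivity ≈ 94%). These sizes keep the whole suite within minutes on
one CPU; they are the package's reference desk-scale protocols
(`alnvec.protocols`), not attempts to reproduce any published benchmark.

What passing them shows: the differentiable kernel is exact against
enumeration; its derivatives are exact against finite differences; the
training signal flows end-to-end and recovers planted structure under
honest noise. What they do not show: performance on real proteins. The
generator has uniform substitution (no BLOSUM-like exchangeability, no
conservation heterogeneity), geometric indels only, a one-parameter label
model instead of TM-align, and a toy embedder instead of a pretrained
protein language model. Numbers from these studies say nothing about
CATH/SWISS-MODEL-scale accuracy.

## Known limitations

* Linear gap costs only; no affine gaps and no local (Smith–Waterman)
  variant, so long insertions are penalized per-residue.
* The reverse-mode pullback of the expected alignment is implemented for
  the default μ-on-all-branches recursion only.
* CPU only; the batching contract is honored by a loop, not a kernel.
* The approximate index targets recall, not sublinear-time guarantees; on
  unstructured data it scans ~75% of the database.
* Checkpoints store parameters as float32; reloaded models agree with
  in-memory ones only to that precision.
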