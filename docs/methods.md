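# Methods

## Model

The encoder operates on a residue graph built from a backbone structure.
Nodes are residues; each node i gets directed edges i→j to its k nearest
other residues by CA–CA distance (defaults k = 20, supported 10/20/30),
restricted to 30 Å. Ties in distance are resolved to the lower residue
index after rounding distances to 1e-6 Å, which makes the edge list
deterministic and stable under rigid motions (exact ties, common in
idealized geometry, would otherwise be reordered by floating-point
jitter). Edges are directed and not symmetrized: i→j exists iff j is
among i's k nearest, and messages aggregate over in-edges. Topology is
computed once from the input coordinates and never rebuilt from the
network-updated coordinates, which exist only as hidden state.

Each edge carries a 93-d attribute vector: 25 inter-residue atom-pair
distances over {N, CA, C, O, CB} (Å, clipped at the 30 Å cutoff), 12
coordinates of the N and C atoms of both residues in the orthonormal
frame anchored at the source residue's CA (e1 along CA→C, e2 the
orthogonalized CA→N direction, e3 their cross product), and a 56-d
transformer-style interleaved sin/cos encoding of the signed sequence
offset with geometrically spaced frequencies. The 25/12/56 split is this
package's reconstruction of a stated 93-d total from those three
ingredient families; the positional-encoding width is configurable, so
other splits are available. Glycine (and any residue without a CB atom)
receives a virtual CB from the standard ideal-tetrahedral linear
combination of N, CA, C, so every residue participates in the full
distance block. All edge features are functions of internal geometry and
sequence offsets only, hence invariant under rigid motions — this is what
makes the network's equivariance exact rather than approximate.

Message passing is the equivariant graph update: per-edge messages
`m_ij = φ_e(w_i, w_j, ‖x_i−x_j‖², w_eij)`, a coordinate update
`x_i ← x_i + C Σ_j (x_i−x_j) φ_x(m_ij)` and a node update
`w_i ← φ_v(w_i, Σ_j m_ij)`, stacked L = 6 times. φ_e, φ_x, φ_v are
two-layer perceptrons with SiLU; φ_x ends in a linear scalar gate. The
normalizer C is 1/n (node count) by default, with an in-degree
alternative behind a flag for very large graphs. An input projection maps
the node-attribute width d to the hidden width h before layer 1 (the
printed update rule is silent on this; consuming d directly in layer 1
would force h = d). Residual connections and normalization layers are off
by default and flag-gated. After the last layer the updated coordinates
are discarded; a linear readout maps node features to 33 token classes
(20 canonical residues plus ambiguity and special tokens, in the
published ESM-style order so external embedding tables align; sequence
characters outside the canonical 20 absorb into the 'X' token).

Numerical choices: the squared-distance input to φ_e is scaled by
1/cutoff² and the edge attributes by 1/cutoff before entering the MLP.
Raw squared CA–CA distances reach ~900 Å² and would dominate the O(1)
feature inputs, compounding over six layers; the scaling is a fixed
constant, so it changes neither expressiveness nor the invariance
argument. The φ_x output layer is initialized at 1e-2 of the usual Xavier
scale to keep early-training coordinate drift mild. Weights are Gaussian
Xavier; gradients come from the package's own reverse-mode autodiff over
numpy arrays, whose correctness is pinned by a finite-difference check
(numeric vs analytic agreement through two full layers at 1e-4 relative).

## Pre-training

Each epoch every sequence is independently re-perturbed and re-encoded
("mutate-then-recode"). The default perturbation is per-site multinomial:
with probability p (default 0.15) a site is redrawn from a replacement
distribution Θ over the 20 residues, possibly redrawing itself. p is
documented as tunable without a stated value; 0.15 mirrors the masking
convention's selection rate. Θ defaults to the residue frequencies of the
training corpus, recomputed at corpus load (tests use uniform Θ, under
which the expected changed-site fraction has the closed form p·19/20).
Alternative strategies: BERT-style masking (select 15% of sites; 80% →
`<mask>`, 10% → a different random residue, 10% unchanged — the mask
token is carried in perturbed sequences by the reserved character `#`);
additive Gaussian noise on embedding rows (variance 0.5); global-average
recoding (a perturbed site's row becomes the mean of same-residue rows,
grouped by the perturbed identity); and sliding-window recoding (mean of
the size-3 centred window, truncated at boundaries). Non-canonical ('X')
sites are never perturbed.

The objective is cross-entropy of the readout against the wild-type
residues at **all** positions (the printed loss sums over the whole
sequence); a flag restricts it to perturbed sites for experimentation.
Optimization is Adam at lr 1e-4 (conventional betas/eps), one step per
batch, no schedule or early stopping. Batches are filled greedily after a
seeded shuffle up to 8192 residues; proteins longer than 2000 residues
are removed from the corpus. Every epoch re-shuffles. Training aborts
with a diagnostic on a non-finite loss. All randomness (shuffling,
perturbation draws, initialization) descends from the single configured
seed, so identical configurations give identical loss traces.

Static embedding tables cannot re-encode a mutated sequence, so the
token-level strategies (multinomial, mask) require a sequence-encoding
provider (one-hot here); with precomputed tables the attribute-level
strategies apply. This is an interface constraint, not a modeling choice.

## Scoring and evaluation

One forward pass on the unmutated wild type produces the n×33
log-probability table; a mutant's fitness is the summed per-site log-odds
of mutant vs wild-type residue. Scores are therefore exactly additive
over disjoint sites given that single pass, and invariant to per-row
logit shifts. Ensembles average final scores arithmetically (averaging
log-probabilities before the odds is the untested alternative; the mean
of final scores was chosen because it commutes with the per-site
decomposition); a rank-average combiner is available for scale-free
pooling.

Curation groups mutant records by protein × condition. ΔTm-style ("dtm")
curation drops multi-site records; ΔΔG-style ("ddg") curation drops
records whose stated wild-type letter mismatches the reference sequence
extracted from the structure; both then drop groups with fewer than 10
surviving mutants and de-duplicate mutant strings. Assay names render pH
to one decimal and temperature as integer Celsius (`P1-7.0`,
`1A7V-6.5-25`).

Per-assay agreement is Spearman's ρ (average ranks for ties; constant
vectors are an error, not ρ = 0). The summary statistic resamples 50% of
the *assays* per run, without replacement, for 10 runs, and reports the
mean and standard deviation (ddof = 1) of the run-level averages. Whether
the resampling unit is assays or mutants, and whether sampling is with
replacement, were open readings; assay-level without replacement was
chosen because the reported deviation describes assay-aggregate spread,
and both per-mutant and with-replacement modes are exposed as flags. The
bootstrap mean converges to the unweighted macro mean as runs grow.

## Structure I/O

PDB parsing is delegated to biotite: model 1 only (the method consumes
single static structures), altlocs resolved by highest occupancy,
HETATM ligands/waters, ANISOU and header records ignored (non-standard
*amino acids* such as MSE are kept and mapped to their canonical parent,
else to 'X', preserving graph topology). Residues missing N, CA or C are
skipped; a missing carbonyl O is reconstructed from ideal peptide
internal coordinates (C–O 1.231 Å, CA–C–O 120.5°, N–CA–C–O dihedral
135°, an α-helical value — without the next residue's N the true
ψ-dependent dihedral is unknowable) and flagged. Positions are 1-based
everywhere, matching the "A24G" mutation convention; chains are
renumbered sequentially in file order, so insertion-coded residues keep
their place. No crystal-structure chain/altloc policy was stated for the
benchmarks this mirrors; these are this package's choices.

## Synthetic data

The fixture generator builds ideal α-helices from internal coordinates
(φ = −57°, ψ = −47°, ω = 180°, standard bond lengths/angles), giving the
3.8 Å consecutive CA spacing and the i→i+3/i+4 spatial contacts that make
the kNN graph's local-environment pathway nontrivial — a random coil
would leave mostly sequence-adjacent edges. Optional isotropic Gaussian
jitter models coordinate noise. Sequences are uniform-random over the 20
residues; CB is always virtual.

Synthetic assays plant a monotone signal: mutant "experimental" scores
are log-odds under a random planted per-position table plus Gaussian
noise, so a scorer holding the planted table achieves ρ = 1 at zero noise
and degrades monotonically as noise grows. This validates the scoring and
evaluation machinery end to end, independent of training quality.

What passing on fixtures does **not** show: helices are not real folds
(no tertiary contacts beyond the helix, no side chains, no residue-
dependent geometry), sequences carry no evolutionary statistics, and
planted assay scores share none of the label noise structure of real
ΔTm/ΔΔG measurements. Results on fixtures certify the machinery —
equivariance, optimization, score identities, evaluation plumbing — not
predictive performance on real proteins, which requires full-scale
pre-training on an experimental-structure corpus with a frozen
language-model embedding provider.

## Problem sizes used in the checks

The test suite and end-to-end runs use desk-scale settings chosen as the
smallest sizes at which each property is meaningfully exercised:
hidden width 16–64, message width equal to hidden, k = 5–10, corpora of
2–5 helices of 8–30 residues, 60–700 epochs at lr 1e-3 (the reference
lr 1e-4 is the default for full-scale corpora; the higher rate is
appropriate for memorization-scale corpora), and 30–200 mutants per
synthetic assay. Statistical constants are estimated on 10^5-site
sequences and 10^6-entry noise matrices. Full-scale values (h ∈
{512, 768, 1280}, 8192-token batches, 2000-residue cap) remain the
configuration defaults.

## Known limitations

- Inference cost is O(n·k) message computations per layer in pure numpy;
  proteins near the 2000-residue cap are slow compared to a GPU
  implementation of the same architecture.
- The 93-d edge featurization is a reconstruction; if the original
  feature split differs, learned models are not weight-compatible
  (the dimensions, but not semantics, are configurable).
- Whether "closest" in the kNN rule is CA–CA distance was not stated;
  CA–CA is assumed.
- Multi-chain proteins are concatenated in file order; the sequence
  offset feature treats the chain break as an ordinary offset.
- No insertions/deletions: scoring covers substitutions only.
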