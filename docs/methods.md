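# Methods

## Fragmentation model

Molecules are heavy-atom graphs: nodes carry an element code (fixed
vocabulary C, N, O, S, P, F, Cl, Br, I, Si, B, Se plus an "other" bucket),
an implicit-hydrogen count and a ring code; edges carry a bond-order code
(single/double/triple/aromatic) and a ring code. The ring code combines
in-ring membership, aromaticity and a smallest-ring-size bucket
{3, 4, 5, 6, ≥7}; this granularity is a design choice — any encoding that
separates aromatic six-rings from small strained rings would serve.
Stereochemistry is ignored throughout, and input SMILES with a net formal
charge or several components (salts) are rejected: the model operates on
neutral, connected structures and attaches the charge only at the ion stage.

Fragmentation is restricted to single edge removals, and only bridges are
breakable: cleaving a ring bond leaves the graph connected, so no fragment
pair exists. Each fragment enters the ion space at hydrogen shifts
{+1, 0, −1, −2, −3} relative to the homolytic fragment; shifts that would
require more hydrogens than the fragment carries are dropped (not clipped),
so the ion count per bond is at most 10 with equality only when both
fragments carry at least three hydrogens. Charge bookkeeping: a shift moves
neutral hydrogen atoms (1.00782503207 Da each) and the charge itself is an
electron removed (positive mode) or added (negative mode,
0.00054857990907 Da). The alternative proton-transfer bookkeeping differs by
under 1.1 mDa; the electron convention keeps shift arithmetic and charge
strictly orthogonal. Negative mode mirrors the positive shift set — a
symmetric treatment chosen here, since deprotonated chemistry gives no
reason to bias the shift set differently at this level of abstraction.

## Network

Integer features are embedded by one lookup table per feature (tables carry
a reserved trailing "unknown" row, so out-of-vocabulary codes degrade to a
learned default rather than failing) and summed per node/bond. Node states
pass through `depth` graph layers with ELU activations. The relational GCN
layer computes `h_i' = ELU(W_self h_i + Σ_r mean_{j∈N_r(i)} W_r h_j + b)`
with one relation per bond order; the plain GCN variant uses the
symmetric-normalized adjacency with self-loops. Mean (rather than sum)
neighbor aggregation keeps activations size-stable across molecules.

The edge head concatenates, for both endpoint orderings of a breakable bond,
the two endpoint states, the bond embedding and the covariate vector, and
maps them through one shared two-layer MLP to five logits — the shifts of
the fragment containing the first endpoint. The precursor head mean-pools
all node states, concatenates the same covariates, and produces a single
logit. All feasible ion logits plus the precursor logit go through one
softmax, so the output is a proper distribution by construction; a molecule
with no breakable bond (benzene, methane) yields precursor probability
exactly 1 without a forward pass through the edge head.

Covariates: molecular weight scaled by 1/1000, ion mode ±1, collision energy
in eV scaled by 1/100, instrument one-hot with an unknown bucket. The
scalings keep covariates O(1) alongside the embeddings. Covariates enter
only the heads, never the graph layers. The RT/CCS property heads receive
the same pooled-embedding-plus-covariates input as the precursor head but
with their own dense weights; with mean pooling the embedding alone loses
molecule size, and the covariates restore it.

Defaults: RGCN, depth 6, embedding 300, head hidden 512, ADAM lr 1e-3,
plateau factor 0.5 / patience 10, batch 32, 200 epochs. Depth/type/width
follow the configuration that performs best on validation data in this
family of models; the optimizer settings are ordinary declared defaults.
Tests and the acceptance run use a scaled configuration (depth 2, embedding
32, hidden 64, 25–40 epochs, libraries of 80–500 compounds), chosen so a
single-CPU run stays in the minutes range while the planted task remains
fully learnable. Seeding covers parameter initialization and batch order;
there is no dropout.

The compute core is a small reverse-mode autodiff over numpy arrays
(`bondbreak.nn.autodiff`) implementing exactly the operations the model
needs; gradients are verified against finite differences in the test suite
indirectly through the training behavior and directly during development.

## Targets, curation and metrics

Training targets: peaks are matched to the ion space at 50 ppm (10 ppm
appropriate for high-accuracy libraries, configurable); each matched peak
contributes its square-root intensity, split equally among all ions that
explain it; the peak nearest the declared precursor m/z within tolerance is
the precursor peak (precursor assignment wins over fragment matches);
contributions are normalized to sum 1. Unmatched intensity is dropped before
normalization — the alternative, keeping it as an "other" mass, would teach
the model to hedge toward unexplainable signal. Coverage is computed on raw
intensities (precursor included), while targets use square-root intensities:
coverage answers "how much measured signal is explainable", the sqrt enters
only the learning objective.

Curation filters: hard — weight ≤ 1000 Da, collision energy ≤ 100 eV, ≥ 2
fragment-matched peaks, coverage ≥ 50%, precursor raw-intensity share
≤ 90%; soft (at least one) — ≥ 50% of peaks matched, ≥ 5 peaks matched, or
coverage ≥ 0.8. NCE→eV conversion uses
`eV = NCE · (precursor m/z / 500) · charge factor` with charge factors
{1: 1.0, 2: 0.9, 3: 0.85, ≥4: 0.8} (the vendor convention for normalized
collision energies); spectra with missing or unparseable collision energies
are excluded as data, not raised as errors.

Similarity: tolerance-matched cosine on square-root intensities, intensity
products summed inside the tolerance window (exact cosine only for unique
matchings), default tolerance 0.01 Da with a ppm option. Coverage is the
experimental-intensity fraction on peaks with a predicted peak within
tolerance, and cosine ≤ √coverage for any prediction — the bound is attained
when all covered intensity sits on a single predicted peak. A bias value
(largest single matched product over the dot product) is reported for
monitoring only. Stepped-energy merging averages peak intensities over the
input spectra and renormalizes to maximum 1; since cosine is
scale-invariant, the sum-vs-mean choice only fixes the output scale.
Consensus merging of replicates clusters peaks at a ppm tolerance with
intensity-weighted cluster m/z and means across replicates (absent = 0).

## Synthetic data

The generator emulates clean centroided spectra whose intensities follow a
*planted rule*: an ion's logit is linear in the broken bond's order, the
fragment-side endpoint element, the elements adjacent to that endpoint
inside the fragment, and the hydrogen shift; precursor stability decreases
linearly with collision energy. The neighbor term makes the rule depend on
structure one hop beyond the bond itself, so a model without message passing
cannot represent it — depth must pay off, and it does (validation-loss
ordering is asserted in the tests). The planted softmax is defined in the
square-root intensity domain, matching how training targets are
constructed, so raw simulated intensities are the squared softmax
probabilities; sqrt-normalizing a noiseless simulated spectrum returns the
planted distribution exactly, which closes the
generator→annotation→training loop without approximation. Optional noise is
multiplicative Gaussian (truncated at −1) with renormalization.

Molecules come from an embedded list of 120 small drug-like/metabolite-like
structures plus random acyclic alkyl/ether/amine chains of 4–15 heavy atoms
(valence-respecting random trees over C/O/N). Defaults for the recovery
benchmark: 500 compounds, 3 collision energies on a 10–60 eV grid, noise
0.02. What passing these tests does **not** show about real data: no ring
openings or multi-step fragmentation, no adducts beyond [M+H]⁺/[M−H]⁻, no
isotope envelopes, chimeric peaks or electronic noise, and real
fragmentation chemistry is not linear in local features.

## Numerical choices and limitations

Predicted peaks are deduplicated at 1e-6 Da (exact-m/z arithmetic);
experimental merging uses ppm tolerances. Probability vectors are softmax
outputs, so normalization holds to machine precision; coverage is clamped to
[0, 1] against summation roundoff. Ion ordering is fixed (edge, side,
descending shift) so logit positions are reproducible across runs and
checkpoints. Checkpoints are JSON (config + parameters), portable and
text-only. CCS is regressed on a log scale (predictions strictly positive);
RT in seconds, with z-scored targets in both cases — a constant target
degenerates to predicting the mean exactly.

Known limitations: single-step fragmentation bounds achievable cosine by
√coverage on spectra dominated by multi-step or ring-opening fragments; the
numpy compute core is single-threaded and intended for desk-scale libraries
(thousands of spectra), not full public-library training; GAT/Transformer
graph layers are not implemented (the relational GCN is the selected
default); [M]⁺/[M]⁻ radical precursors and other adducts are out of scope.
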