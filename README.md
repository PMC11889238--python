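# bondbreak

Prediction of small-molecule tandem mass spectra (MS/MS) from molecular
structure, by modeling fragmentation as **single bond dissociation on the
molecular graph**.

Non-targeted metabolomics identifies compounds by matching measured MS/MS
spectra against reference libraries, but those libraries cover only a small
fraction of chemical space. In-silico fragmentation fills the gap: given a
structure (SMILES), simulate the spectrum a mass spectrometer would produce.
`bondbreak` is aimed at computational metabolomics and cheminformatics users
who need simulated reference spectra, spectrum annotation against a
theoretical fragment space, or spectral-library curation.

## The model

A molecule is a graph *G* with atoms as nodes and bonds as edges. Removing a
bridge bond *e* splits *G* into two fragments; every fragment is considered
as an ion at hydrogen rearrangements of {+1, 0, −1, −2, −3} hydrogen atoms,
giving the fragment ion space

  F(G) = ∪_{e∈E(G)} ∪_{F∈G₋ₑ} { [F+H]⁺, [F]⁺, [F−H]⁺, [F−2H]⁺, [F−3H]⁺ }

(negative mode analogously, with the charge carried by an electron added
rather than removed). Ring bonds are never cleaved: removing them does not
disconnect the graph, so no fragment pair exists.

A message-passing graph network (relational GCN by default, one relation per
bond order, ELU activations) embeds integer-coded atom features (element,
hydrogen count, ring type) and bond features (bond order, ring type). For
each breakable bond, a shared two-layer head maps the two endpoint states,
the bond embedding and acquisition covariates (molecular weight, ion mode,
collision energy, instrument type) to abundance logits θ_f for all ten ions
of that bond; a precursor head mean-pools the node states into a
precursor-stability logit σ. Probabilities follow a softmax over the whole
ion space plus the precursor:

  p(f) = exp θ_f / (exp σ + Σ_{f′} exp θ_f′)

Training minimizes a mean squared error against target distributions derived
from library spectra (square-root intensities, matched at 50 ppm, ambiguous
matches split equally), weighted by 1/(spectra per compound), with ADAM and
a reduce-on-plateau schedule; the best-validation checkpoint is kept. The
spectrum is reconstructed at exact fragment m/z, summing probabilities of
ions that land on the same peak. Retention time and collision cross section
are regressed from the pooled graph embedding with separate frozen-backbone
heads.

Evaluation uses tolerance-matched cosine similarity on square-root
intensities (with and without the precursor peak) and intensity coverage;
for any prediction, cosine ≤ √coverage.

## Worked example

`examples/03_train_and_predict.py` simulates an 80-compound library from the
planted ground-truth rule, trains a depth-2 relational network, and scores
held-out compounds:

```
240 curated spectra -> 192 train / 24 val / 24 test (compound-level split)
best validation loss 1.67e-05 at epoch 24
held-out spectra: median cosine 0.925 over 24 spectra

example held-out compound NC(CO)C(=O)O at 10 eV:
  m/z    44.9971  intensity 0.109
  m/z    17.0022  intensity 0.086
  m/z    88.0393  intensity 0.083
  m/z    46.0049  intensity 0.077
  m/z    89.0471  intensity 0.070
```

The median cosine of 0.925 says held-out spectra are reproduced nearly
peak-for-peak; the listed peaks are fragment probabilities at exact m/z
(serine shown: immonium-type and water-loss fragments dominate). The other
examples cover fragment enumeration, spectrum annotation, `.msp` library
curation, and RT/CCS heads — each runs in seconds to a minute.

A thin CLI wraps the same API: `bondbreak simulate | fragments | annotate |
filter | train | predict | evaluate`.

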