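# Methods

## The restricted SELFIES grammar

`latentmol.selfies_lang` implements a SELFIES-style string grammar for the
neutral organic subset (C, N, O, S, P, B, F, Cl, Br, I, Se, Sn; no formal
charges, isotopes or radicals). Tokens are atoms with an optional bond
prefix (`[C]`, `[=O]`, `[#C]`), branches (`[Branch1]`, `[=Branch2]`, …)
and ring closures (`[Ring1]`, `[=Ring2]`, …). After a branch or ring
token, the next one or two tokens are reinterpreted as an index (a fixed
16-token index alphabet encodes 0–15; two tokens encode 0–255) giving the
branch length in tokens or the ring-closure span in derivation positions.

Decoding is a valence-constrained derivation with three rules that jointly
guarantee a valid molecule for *any* token stream:

* bond orders are capped by the remaining valence of both endpoints
  (valence caps: C 4, N 3, O 2, S 6, P 5, halogens 1, B 3, Se 6, Sn 4;
  implicit hydrogens fill the remainder);
* a token that cannot apply at the current derivation state (branch or
  ring at the start, ring onto an existing bond, zero-capacity endpoints)
  is skipped, along with a skipped branch's body;
* the derivation ends when the chain atom is saturated or tokens run out.

Encoding walks a kekulized, stereochemistry-stripped RDKit molecule
depth-first. One DFS fixes both the spanning tree and the ring bonds, and
the emitter replays exactly that traversal, so decoder derivation order
equals DFS pre-order and ring spans are consistent. Branch blocks wrap
every non-final child; the connecting bond order lives on the branch token
and the branch's first atom token is emitted bare. The round trip
`decode(encode(s)) == canonical_generic(s)` is exercised over hand-picked
drug-like molecules and whole fixture corpora; decode robustness is
exercised on thousands of random token streams.

Aromaticity is handled by kekulizing on encode and re-aromatizing on
decode (RDKit sanitization), so aromatic systems survive the round trip as
their canonical forms. Multi-fragment species and charged species are
outside the grammar and raise an explicit error; the corpus-preparation
stage skips such inputs and counts them as lost before the filter cascade.

## Corpus preparation

Raw SMILES are canonicalized to generic (stereo-free) form, translated to
SELFIES, and filtered: token length inside an inclusive window (default
[30, 50] — the window counts tokens, a deliberate reading since character
counts would depend on the mono-character assignment), element whitelist
(default H/C/N/O/S/F/Cl/Br/I, so rare heteroatoms such as Sn, Se, B, P are
dropped; configurable), and deduplication on canonical generic SMILES
(distinct SELFIES strings can encode one molecule, so SELFIES text is the
wrong dedup key). Stage counts (input → after length → after elements →
after dedup) are reported for auditability. The train/validation split is
a seeded uniform shuffle with |validation| = round(fraction · n), default
fraction 0.10, no stratification.

## Sequence coding

Every SELFIES token maps to one printable character ("molecular
sequence"); `!` starts a sequence and `E` both ends and pads it, so a
vectorized molecule reads `!<sequence>EEE…` up to the fixed `embed`
length. Characters are assigned in sorted-token order from a fixed pool,
making the alphabet a pure function of the corpus token set. Default
`embed` is the longest training sequence + 2 markers, capped at 65 total
padded characters — the cap is interpreted as including the markers. The
full chain SELFIES → sequence → one-hot → sequence → SELFIES is the
identity for all corpus molecules, and alphabets serialize to JSON
bit-exactly.

## The encoder–decoder

A single-layer LSTM encoder reads the padded one-hot sequence; its final
hidden/cell pair is the molecule's latent state. A second LSTM of the
same width, initialized with that state, is trained with teacher forcing
(decoder input is the sequence shifted right by the `!` marker) under mean
categorical cross-entropy over all positions, padding included — the
model learns to emit the `E` padding itself, which is what makes greedy
decoding terminate. Prediction is deterministic: start from `!`, append
the argmax character, stop at `E` or after `embed − 2` characters.
Diversity comes from latent perturbation only.

Everything is NumPy: fused-gate LSTM forward, exact analytic BPTT
(validated against central finite differences in the test suite), Adam
with global-norm gradient clipping at 5, forget-gate bias initialized
at 1. Defaults — 128 units, batch 16, learning rate 10⁻², 200 epochs —
were chosen so the model reliably memorizes a 100-molecule corpus within
the epoch budget; on that benchmark it reconstructs 100/100 training
molecules exactly. Unit count, layer depth (one), optimizer and learning
rate are implementation choices exposed in `ModelConfig`.

## Generation by latent perturbation

For each seed active, the latent state is perturbed with independent
zero-mean noise applied to both the hidden and cell vectors and decoded
greedily. "Amplitude" is the per-component standard deviation: Gaussian
noise draws N(0, a²); the uniform option draws from [−a√3, a√3] so its
standard deviation is also a. Amplitude 0 returns the state unchanged,
giving the seed's own reconstruction. Defaults: amplitudes (0.1, 0.2), 20
samples per seed. Deduplication runs per amplitude first, then across
amplitudes when merging, so per-amplitude unique counts remain reportable.
Every decoded string is a valid molecule by the grammar's construction —
the property that motivates SELFIES over SMILES for generative use.
PubChem CID annotation is a network-gated convenience: offline it warns
and annotates nothing, and it never filters.

## Discriminators and ranking

QED, molecular weight, logP and the Lipinski N+O donor/acceptor counts
come from RDKit's descriptor engine; QED's desirability functions are
consumed, not re-derived. Rule-of-5 uses ≤ semantics at every boundary
and is strict (zero violations) by default, with the classic
one-violation variant available. The synthesizability score is a
Bernoulli naive-Bayes fragment sum: for Morgan fragments (default radius
2), a table trained on an easy set and a hard set assigns each fragment
ln[(n_easy+p)/(N_easy+2p)] − ln[(n_hard+p)/(N_hard+2p)] with pseudocount
p = 1; a molecule scores the sum over its distinct fragments, unseen
fragments contributing the smoothed unseen value. Thresholds: QED ≥ 0.5,
synthesizability ≥ 0 (exactly 0 is retained). The three filters are
independent predicates, so the surviving set is provably order-invariant;
per-stage and conjunction counts are reported, with pass rates printed to
two decimals.

Min-max normalization of QED and synthesizability runs over an *explicit*
reference set (default: the candidate pool before the synthesizability
filter) because the composite score is only comparable within a stated
reference; every report records which set was used. A single candidate
with a degenerate reference normalizes to 0 by convention; otherwise
constant reference values are an error. My score = 100 · (QEDnorm +
SYNnorm)/2 exactly, and rankings sort it descending.

## Similarity

RDKit path fingerprints (daylight-like; default paths up to 7 bonds, 2048
bits, both explicit in the configuration) are compared with the Tanimoto
coefficient |A∩B|/|A∪B|, 1.0 by convention
when both bitsets are empty. Single-atom molecules have no bond paths and
would hash to nothing, so they receive one deterministic identity bit
derived from their canonical SMILES — distinct atoms stay distinguishable
and self-similarity stays 1. Report summaries (min/max/mean) run over all
ordered pairs of the two sets, matching the every-candidate ×
every-training-molecule convention, with histogram bins emitted for
plotting.

## Docking orchestration

Candidates are embedded in 3D with ETKDG (fixed seed, hydrogens added,
MMFF relaxation) and written as SDF; embedding failures go to a skip
report rather than aborting the batch. The `mock` backend maps a SHA-256
hash of (canonical SMILES, receptor id) into [−12, −4] kcal/mol — a
deterministic stand-in that lets the whole pipeline and its tests run
with no external binary. The `vina` backend shells out to AutoDock Vina
and parses the best-pose affinity from its results table; receptor
preparation (PDBQT, box center/size) is deliberately upstream input,
since docking results depend strongly on the search box. Per-ligand mean
energies use exactly-rounded summation so they are receptor-order
invariant; rankings sort ascending by mean with ligand-id tie-breaks.
Per-pair energies are reported to 0.1 kcal/mol, means to 0.01.

The combinatorics utility computes the systematic-search conformation
count (box_volume^⅓/grid_step)³ · (360/angle_step)^(3+n_torsions); for the
10³ Å³ / 0.5 Å / 10° / 4-torsion example this is 6.27 × 10¹⁴, reported to
one significant figure as 6 × 10¹⁴. Enumeration time divides by the rate
and truncates to whole years — 19,025 years at 1000 conformations/s from
the one-significant-figure count, which is the arithmetic convention the
reported figure follows.

## Synthetic fixtures

Fixture corpora are sampled as uniform random token strings over a
restricted alphabet ([C], [N], [O], [S], [F], [=C], [=N], [=O],
[Branch1], [Ring1], [Ring2]) — small and organic so fixture molecules
stay loosely drug-like. A draw is rejected unless the decoded molecule
realizes at least half its token count as heavy atoms
(`min_atom_fraction = 0.5`), keeping SELFIES length roughly proportional
to molecule size as in real corpora; the fast variant
(`min_atom_fraction = 0`) is used where only record counts matter, such
as the 121,000-record split-arithmetic check. Seed actives are chosen
from a My-score-ranked corpus as two from the top, the two central ranks
(the "middle"), and the last — with "middle" defined as the two central
ranks of the descending ordering. The
synthesizability training pair is built programmatically: easy = short
C/N/O chains, hard = dense ring-heavy random-SELFIES molecules, disjoint
by canonical SMILES.

What the fixtures do *not* emulate: real screening-library chemistry.
Random-SELFIES molecules are structurally odd (peroxide chains, fused
small rings), so their QED is almost always below 0.5 and a fixture run
of the cascade typically passes nobody on the QED stage — the end-to-end
test therefore docks the top-ranked candidates when the cascade empties.
Passing tests show the machinery (round trips, training convergence,
accounting, invariances) is correct, not that fixture chemistry resembles
ZINC-scale corpora.

## Problem sizes and numerical choices

Training demonstrations and the acceptance run use a 100-molecule corpus
of 8–16-token fixtures (alphabet ≈ 17 characters, embed ≈ 16), where 200
epochs take well under a minute; the split-arithmetic check uses the fast
fixture variant at 121,000 records. Tolerances: gradient check at 10⁻³
relative; geometry checks at ±0.05 Å; noise-scale Monte Carlo at 5%
relative over 10⁴ draws. All randomness flows through explicit integer
seeds (Python `random.Random` for token sampling, NumPy `default_rng` for
weights, shuffling and noise), and checkpoints (JSON config/alphabet +
npz weights) restore decoding bit-exactly.

## Known limitations

* The grammar excludes charged, isotopic, radical and multi-fragment
  species; corpus preparation skips them rather than encoding them.
* Greedy decoding cannot produce diversity at amplitude 0; all diversity
  is latent-driven by design.
* The mock docking backend is a hash, not a physics model — it validates
  orchestration, aggregation and ranking, never binding chemistry.
* The synthesizability table trained on the bundled fixture sets is a
  toy; for real triage, train it on catalogue-scale easy/hard corpora.
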