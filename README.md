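# gestnet

Gesture-sequence coding and permutation-based network inference for dyadic
communication data in fission–fusion primate groups.

## The problem

Field studies of great-ape gestural communication ask whether *how* animals
gesture — single gestures, rapid bursts, or persistent series interleaved
with response-waiting pauses — tracks *who they are socially bonded to*.
The data are two interlocking streams from focal follows: instantaneous
scan samples (who is in the focal's party, who is within 10 m) and a
continuously recorded, time-stamped gesture log.  Both reduce to directed
weighted matrices over the same individuals, and relationships between the
matrices must be tested with permutation methods because dyads sharing a
node are not independent observations.

`gestnet` implements that pipeline for researchers in animal social network
analysis:

1. **Sequence coding** — segment the gesture log into sequences (same
   signaller, recipient and context, gaps ≤ 30 s) and classify each by its
   gap vector: *single* (one gesture), *rapid* (all gaps < 1 s), or
   *persistence* (at least one response-waiting gap ≥ 1 s).
2. **Network construction** — per ordered dyad (A, B):
   communication rate CA_AB = (C_AB × 60) / (P10_AB × 2), events per hour
   of co-proximity; proximity PROX_AB = 60 × P10_AB / party_AB, minutes
   within 10 m per party-hour; plus binary sex / age (≤ 5 y) / reproductive
   (male × cycling female) / maternal-kin similarity matrices.
3. **MRQAP with Double-Dekker semi-partialling** — multiple regression of
   one dyadic matrix on others; each predictor's null comes from node
   relabelings of its dyad-wise residual matrix, robust to network
   autocorrelation.  Exhaustive enumeration over all n! relabelings when
   n ≤ 7 (the engine's built-in exactness oracle).
4. **Node-level permutation regression** — weighted out-/in-degree
   centralities regressed on node covariates, null by permuting the
   outcome across nodes.
5. **Cohen's kappa** — two-coder reliability per response category.
6. **Synthetic generator** — a 12-animal fission–fusion community with a
   latent dyadic sociality that raises both proximity and the persistence
   rate by a planted, recoverable amount, so the whole pipeline is testable
   without field data.

## Worked example

```bash
cat > demo.yaml <<EOF
synthetic:
  seed: 1
n_perm: 2000
seed: 1
out_dir: demo_out
EOF
gestnet pipeline --config demo.yaml
```

prints, among the six dyadic models and the node-level model:

```
gestnet 0.1.0  seed=1 perms=2000 nodes=12 dyads=132
sequences: 499 {'single': 346, 'rapid': 107, 'persistence': 46} (excluded: 0)

== H1_proximity_by_sequence_type: proximity ~ ... (R^2 = 0.182, 2000 perms)
                       age_similarity  beta_std = -0.056  p = 0.644
                       sex_similarity  beta_std = +0.013  p = 0.923
                       kin_similarity  beta_std = +0.045  p = 0.716
                  oestrous_similarity  beta_std = +0.010  p = 0.943
                                rapid  beta_std = -0.124  p = 0.124
                               single  beta_std = -0.019  p = 0.824
                          persistence  beta_std = +0.404  p = 0.000 *
```

Read: across 132 ordered dyads, the coded gesture log yields 499 sequences;
controlling for demography and the other sequence types, only the planted
persistence→proximity association is detected (standardized coefficient
+0.40, permutation p < 0.001) — dyads that spend more time within 10 m per
party-hour exchange persistence sequences at a higher rate, which is
exactly the effect the generator planted.  The same stages are available
individually (`gestnet simulate/code/build/mrqap/nodereg/kappa`) and as
library functions.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full analysis from scratch: it simulates a community at
field-scale effort (12 focals, 25 nine-scan follows each), codes the
gesture log, builds all matrices, and runs every dyadic and node-level
permutation model at 2000 permutations, writing the target JSON to `--out`
and the complete model report beside it.

## Layout

```
src/gestnet/
  coding.py       segmentation + timing-rule classification, responses
  networks.py     dyad tallies, rate and similarity matrices
  mrqap.py        QAP correlation, Double-Dekker semi-partialling MRQAP
  nodereg.py      degree centralities, node permutation regression
  reliability.py  Cohen's kappa per response type
  synthetic.py    fission–fusion generator with planted effects
  matrices.py     the DyadMatrix container and dyad vectorization
  io.py, pipeline.py, cli.py
  data/           packaged 12-subject attribute table
```

See `docs/methods.md` for the statistical model, parameter defaults, and
known limitations.
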