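# revlearn

Simulation and computational modeling of a serial probabilistic
reversal-learning task: an adaptive-feedback task generator, six candidate
learning models (Rescorla–Wagner stimulus–action, double-update, and a
two-state hidden-Markov belief model, each with equal or separate
reward/punishment sensitivities), hierarchical empirical-Bayes fitting,
integrated-BIC model comparison, better-than-chance subject classification,
and belief-based subjective trial labeling with regressor export for
downstream GLM software.

## Layout

| module | contents |
|---|---|
| `revlearn.task` | block scheduler (reversal after 16 trials, or ≥70% correct from 10 trials) and the per-block tally controller enforcing 80/20 (neutral 50/50) outcome rates |
| `revlearn.models` | `SA`, `SA-RP`, `DSA`, `DSA-RP`, `HMM`, `HMM-RP`: likelihoods, belief trajectories, generative agents |
| `revlearn.fitting` | per-subject MAP under a group prior, Laplace-EM random-effects group fitting, binomial chance-fit test |
| `revlearn.comparison` | Monte-Carlo integrated BIC (`BIC_int`) with MC error, group-level model ranking |
| `revlearn.classification` | informative/probabilistic reward/punishment trial labels, PE and event regressor tables, pre-event reward-rate control |
| `revlearn.cohort` | seeded synthetic cohorts for three behavioral phenotypes; learning curves, percent correct, reversal counts |
| `revlearn.io` | TSV event tables, YAML configs and group priors |

## Command line

```sh
revlearn simulate --agent HMM --param gamma=0.9 --param c=2 --seed 1 --out events.tsv
revlearn make-cohort --seed 0 --out cohort/
revlearn fit --model HMM-RP --events cohort/events.tsv --out fits/
revlearn compare --models SA,SA-RP,DSA,DSA-RP,HMM,HMM-RP --events cohort/events.tsv --out comparison.tsv
revlearn classify --events cohort/events.tsv --fits fits/fits_HMM-RP.tsv --out regressors/
```

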