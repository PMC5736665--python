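# advicegame

Simulation, model fitting and analysis of **strategic confidence in
advice-giving**: how an adviser competing with a rival for a client's
attention inflates or deflates the confidence of their advice.

## The problem

Two advisers watch probabilistic evidence — a grid of 100 black/white
squares whose colour ratio gives the probability that a coin is hidden in
the black urn — and advise a client on a 10-level signed confidence scale
(5B "certainly black" … 5W "certainly white"). On each trial the client
first picks the adviser to follow (the other is ignored), both advisers
then commit their advice, and the urn named by the selected adviser is
opened. An adviser who only communicated the evidence would report the
confidence the grid warrants; real advisers deviate, and the *advice
deviance* (expressed minus warranted confidence, in confidence-scale units)
is the behaviour this package models.

The core trial-by-trial model couples two ingredients:

**Relative merit** — a delta-rule comparison of the two advisers'
prognostic values (confidence × accuracy, accuracy ±1):

```
ΔPV(t)  = Conf_P(t)·Acc_P(t) − Conf_R(t)·Acc_R(t)
PE(t)   = ΔPV(t) − RM(t)
RM(t+1) = RM(t) + γ·PE(t)
```

**The deviance model family** — six nested linear models of advice
deviance in the client's selection S(t) ∈ {+1 selected, −1 ignored} and the
sign of relative merit, up to the full interaction model

```
Deviance(t) = Bias + β_sel·S(t) + β_mer·sign(RM(t)) + β_int·S(t)·sign(RM(t))
```

(reductions: bias, client, merit, mixed; plus an *amplitude* variant using
RM itself instead of its sign). Models are fitted per participant by
adaptive random-walk Metropolis–Hastings on the robust cost
`L = Σ_t log(1 + |pred(t) − obs(t)|)` treated as a negative log-likelihood,
and compared by the Deviance Information Criterion. β_sel < 0 is the
*competitive* strategy (shout when ignored); β_sel > 0 is *defensive*.

The package also contains the full game simulator — a noisy rival adviser,
a client that updates multiplicative influence weights from squared
prognostic strengths (w_P + w_O = 10), evidence-degradation windows that
force selection switches, and generative participants driven by any of the
six models — so every downstream stage is testable on synthetic cohorts
with known ground truth.

## Worked example

Generate the synthetic cohorts, fit, compare and analyse (from
`analysis/`):

```sh
python 01_simulate_cohorts.py      # 30 advisers × 240 trials (+ controls)
python 02_fit_and_recover.py       # interaction-model fits + recovery
python 03_model_comparison.py      # six-model DIC comparison
python 04_behavioural_analysis.py  # 2×2 selection-by-merit analysis
```

`02_fit_and_recover.py` prints the parameter-recovery table (generating vs
estimated group means and per-participant recovery correlations):

```
       parameter  true_mean  est_mean  est_sem  correlation
            bias      0.628     0.542    0.067        0.988
  beta_selection     -0.157    -0.146    0.027        0.934
      beta_merit      0.022     0.002    0.023        0.932
beta_interaction     -0.294    -0.226    0.028        0.845
           gamma      0.304     0.366    0.025        0.362
```

so an individual adviser's bias and selection weight can be read back out
of 240 trials. `03_model_comparison.py` shows the generating model winning
the cohort-mean DIC (interaction 145.7 vs mixed 152.8, …; on a bias-only
control cohort the bias model wins). `04_behavioural_analysis.py` prints
the behavioural signature:

```
overall deviance: mean 0.52, t = 6.10, p = 1.2e-06, d = 1.11
cell means:
selected  positive   0.132
          negative   0.631
ignored   positive   0.945
          negative   0.405
highest cell: ('ignored', 'positive')   interaction F = 85.6, p < 0.0001
strategy: 26/30 competitive; beta_selection mean -0.146 ± 0.027
FNE ~ beta_selection: r = 0.36, p = 0.049 (n = 30)
```

— advice deviance peaks when the adviser is *ignored despite positive
relative merit*, and a higher (emulated) fear-of-negative-evaluation score
goes with the defensive strategy.

There is also a CLI over the same library
(`advicegame simulate|fit|compare|analyze|recover`), e.g.

```sh
advicegame --seed 7 recover --preset lab --model interaction \
    --n-participants 10 --out-dir scratch/recovery
```

## Layout

```
src/advicegame/     task_core, agents, learning, fitting, synthetic,
                    analysis, io, cli
analysis/           numbered narrative drivers (write to results/)
tests/              pytest suite incl. acceptance checks
docs/methods.md     modelling and numerical details
```
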