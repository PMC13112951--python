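# seqgnped

Nonparametric cognitive diagnosis for **polytomously scored** tests in
**small samples**.

Cognitive diagnostic assessment maps each examinee to a binary
attribute-mastery profile α ∈ {0,1}^K — which of K fine-grained skills they
have mastered — from their item responses and a Q-matrix linking items to
skills. Parametric diagnostic models (G-DINA and relatives) need hundreds
of examinees for stable estimation; classroom-sized groups (N ≈ 30–50)
break them. Nonparametric classifiers are robust at such sizes but have
historically required dichotomous (0/1) scoring, discarding the extra
information in partial-credit items.

`seqgnped` implements a sequential generalized nonparametric classifier
(seq-GNPED) that works directly on polytomous scores. A polytomous item
with maximum score S_j is treated as S_j sequential steps; a category-level
Q-matrix (Q_c) lists the attributes each step requires, and a score of h
means steps 1..h were completed.

## The classifier

Observed scores are dichotomized per step, y_ijh = 1{X_ij ≥ h}, and each
candidate profile α_m gets an ideal response at every (item j, step h):

- conjunctive (DINA-type): η⁽ᶜ⁾_mjh = ∏_{b≤h} ∏_k α_mk^{q_jbk} — all
  required attributes of steps 1..h mastered;
- disjunctive (DINO-type): η⁽ᵈ⁾_mjh = ∏_{b≤h} [1 − ∏_k (1−α_mk)^{q_jbk}] —
  at least one required attribute per step;
- weighted: η⁽ʷ⁾_mjh = w_ljh η⁽ᶜ⁾_mjh + (1 − w_ljh) η⁽ᵈ⁾_mjh.

The weight w_ljh ∈ [0,1] is estimated per *collapsed attribute class* l —
profiles agreeing on the attributes relevant to steps 1..h are
indistinguishable there and share one weight — by least squares,
ŵ_ljh = Σ_{i∈C_l}(y_ijh − η⁽ᵈ⁾) / (|C_l|(η⁽ᶜ⁾ − η⁽ᵈ⁾)), which in the only
non-degenerate case (η⁽ᶜ⁾, η⁽ᵈ⁾) = (0, 1) is 1 minus the class mean
response. Each examinee is assigned the profile minimizing the squared
Euclidean distance Σ_{j,h}(y_ijh − η⁽ʷ⁾_mjh)², and weight estimation and
reclassification alternate until fewer than a fraction ε (default 0.001)
of examinees change profile.

The package also ships the forward simulators (sequential DINA and mixed
DINA/G-DINA link generators, uniform and higher-order profile
distributions, Q-matrix misspecification, polytomous-proportion
reduction), the accuracy metrics PAR/AAR/AMR, and a config-driven
Monte-Carlo study runner.

## Worked example

```python
from seqgnped import (SeqGNPED, sim_qc, sample_profiles_uniform,
                      generate_seq_gdina, evaluate)

qc = sim_qc()                                   # 21 items, K = 5 attributes
alpha = sample_profiles_uniform(30, qc.n_attributes, seed=7)
X = generate_seq_gdina(alpha, qc, s=0.05, seed=8)

res = SeqGNPED(X, qc).fit()
print(res.summary())

report = evaluate(res.alpha_hat, alpha)
print(f"PAR = {report.par:.3f}, AAR = {report.aar:.3f}")
```

prints

```
seq-GNPED classification results
========================================
Examinees:            30
Items:                21
Category cells:       40
Attributes (K):       5
Candidate patterns:   32
Iterations:           2
Converged:            True
Final change rate:    0.0000
----------------------------------------
Attribute mastery rates:
  A1: 0.500
  A2: 0.667
  A3: 0.433
  A4: 0.467
  A5: 0.467
----------------------------------------
Weight entries estimated: 65, degenerate: 1202
PAR = 0.967, AAR = 0.993
```

A class of 30 simulated examinees answered 21 items (40 sequential steps)
generated at high item quality (slip 0.05). The classifier converged after
two passes; 29 of 30 examinees were assigned exactly their true 5-attribute
profile (PAR 0.967) and 99.3% of the 150 individual attribute judgements
were correct (AAR 0.993). The per-attribute mastery rates are the fractions
of the class classified as masters — the quantity a teacher would read off
to target instruction.

Command-line equivalents: `seqgnped simulate`, `seqgnped fit`,
`seqgnped evaluate`, `seqgnped replicate-study` (see `--help`).

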