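# cdmhier — statistical validation of attribute hierarchies in cognitive diagnosis models

Cognitive diagnosis models (CDMs) are restricted latent class models that
infer which of K binary skills ("attributes") each examinee has mastered
from binary item responses, guided by a J×K Q-matrix saying which attributes
each item requires. Attributes are often assumed to form a **hierarchy** —
prerequisite relations such as *linear* (1→2→3), *pyramid*, *inverted
pyramid* or *diamond* — under which some of the `L = 2^K` mastery patterns
are impermissible and their structural probabilities `π_l` are zero.
`cdmhier` provides the statistical machinery to test such an a-priori
hierarchy against data:

* **Saturated and hierarchy-restricted model estimation.** The saturated
  G-DINA model (identity link; the log-linear LCDM logit view is available
  as a reparameterization) and its hierarchical reduction — impermissible
  `π_l` fixed at zero, item effects not identifiable from permissible
  patterns removed — are fitted by marginal maximum likelihood EM.
* **Wald tests on the structural parameters.** With `R` the selector matrix
  of the impermissible positions among the free structural parameters
  `π_1 … π_{L−1}`, the statistic

  `W = (Rπ̂)ᵀ (R Σ̂ππ Rᵀ)⁻¹ (Rπ̂)  ~  χ²(rows of R)`

  tests whether the impermissible probabilities are jointly zero. The
  covariance `Σ̂ππ` is the structural block of the inverted information
  matrix, estimated either as the empirical cross-product of per-examinee
  scores (**Wald-XPD**) or as the observed information, the negative Hessian
  of the marginal log-likelihood (**Wald-Obs**).
* **Likelihood-ratio test.** `LR = 2(ℓ_s − ℓ_r)` between the saturated and
  restricted fits, with degrees of freedom equal to the difference in free
  parameter counts.
* **A simulation harness** reproducing the supporting Type I error and power
  studies: factorial designs over sample size, attribute count, item
  quality `(P0, P1) ∈ {(0.1,0.9), (0.2,0.8), (0.3,0.7)}`, hierarchy shape
  and attribute distribution (uniform over permissible patterns, or a
  dichotomized multivariate normal with correlations drawn from U(0.5, 0.8)).

Failing to reject supports the hierarchy; rejecting indicates the data
populate patterns the hierarchy forbids.

## Worked example

`examples/validate_hierarchy_simulated.py` generates 500 examinees from a
linear-hierarchy model over three attributes (high-quality items), fits the
saturated and restricted models and runs all three tests:

```
saturated fit:  loglik -6417.3, 111 free parameters
restricted fit: loglik -6421.6, 81 free parameters
structural estimates pi: [0.238 0.234 0.    0.002 0.254 0.    0.    0.272]
Wald-XPD: statistic=0.002, df=4, p=1.000 (retain H0 at alpha=0.05)
Wald-Obs: statistic=0.994, df=4, p=0.911 (retain H0 at alpha=0.05)
LR: statistic=8.636, df=30, p=1.000 (retain H0 at alpha=0.05)
```

The four permissible patterns (000, 100, 110, 111) absorb essentially all
structural mass, the impermissible estimates sit at or near zero, and every
test retains the hierarchy — the correct call, since the generating model
honoured it. `examples/type_i_error_and_power.py` runs the same design as a
small replication study (Type I error ≈ 0–0.02 per method, power 1.0,
MAP classification accuracy 0.99), and `examples/ecpe_analysis.py` applies
the workflow to the ECPE grammar data (see below).

A thin CLI mirrors the library:

```bash
cdmhier simulate --n 500 --k 3 --quality high --hierarchy linear --seed 1 --out-prefix demo
cdmhier test-hierarchy --responses demo_responses.csv --qmatrix demo_qmatrix.csv \
        --hierarchy linear --method all
cdmhier study --config study.yaml --out rates.csv
```

## The ECPE example

The standard real-data illustration is the grammar section of the
Examination for the Certificate of Proficiency in English: 28 items, three
attributes (morphosyntactic / cohesive / lexical rules), 2,922 examinees,
and a putative linear hierarchy lexical → cohesive → morphosyntactic. The
published Q-matrix is embedded (`cdmhier.datasets.ecpe_qmatrix`); the
response data ship with the CDM R package and are **not** redistributed
here. Export them to `data/ecpe_responses.csv` as described in
`examples/ecpe_analysis.py` to run the analysis and the corresponding
acceptance test.

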