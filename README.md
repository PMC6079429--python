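# dvclust

Model-based detection of **differentially variable (DV) genomic probes** —
probes (e.g. miRNAs, methylation marks) whose expression *variance* differs
between two groups of subjects, such as cases and controls. Variance
differences carry disease signal that mean-based differential-expression
analysis misses, and probe-wise equal-variance tests (F, Levene,
Brown–Forsythe) throw away the information shared across probes. `dvclust`
pools that information with a constrained finite mixture model.

## The model

Each probe's whole expression vector across all m = m_c + m_n subjects is
one observation from a three-component mixture. Component k has density
f_k(x) = N(μ_kc·1, Σ_kc) ⊗ N(μ_kn·1, Σ_kn) — the case and control blocks
are independent multivariate normals with **exchangeable (compound-symmetry)
covariance** Σ = σ²[(1−ρ)I + ρJ]: one mean, one variance, one
between-subject correlation per group. The components are

* **OV** (over-variable): σ²_1c > σ²_1n,
* **EV** (equal variance): σ²_2c = σ²_2n (means and correlations free),
* **UV** (under-variable): σ²_3c < σ²_3n.

Parameters (π, μ, σ², ρ) are estimated by EM; probe g is assigned to the
cluster with the largest posterior probability
p_gk = π_k f_k(x_g) / Σ_j π_j f_j(x_g). Probes landing in OV or UV are the
DV calls; the direction is the sign of s²_c − s²_n. The package also ships
the probe-wise baselines (F, Levene, Brown–Forsythe, trimmed Levene, with
Benjamini–Hochberg FDR control), four simulation scenarios with ground
truth (normal / multivariate-t, with and without correlation), pair-counting
Jaccard / FPR / FNR evaluation, Box-Cox + center/scale preprocessing, and a
discovery-to-validation bootstrap workflow.

## Worked example

```bash
python examples/01_detect_dv_mixture.py
```

```
EM converged after 5 iterations, log-likelihood -133261.5
estimated mixing proportions pi = [0.308 0.582 0.11 ]  (truth: 0.31 0.58 0.11)
  OV: case sigma^2 = 1.48, control sigma^2 = 0.42, rho = (0.08, 0.30)
  EV: case sigma^2 = 1.01, control sigma^2 = 1.01, rho = (0.04, 0.11)
  UV: case sigma^2 = 0.27, control sigma^2 = 1.69, rho = (0.03, -0.01)
detected  308 OV probes
detected  582 EV probes
detected  110 UV probes
pair-counting Jaccard index vs truth: 0.984
```

A 1000-probe, 50-case/50-control dataset is simulated from the packaged
generating model (310 OV / 580 EV / 110 UV probes), the mixture is fitted by
EM, and probes are assigned by maximum posterior probability. The estimated
mixing proportions and cluster variances match the generating values, and
the detected partition agrees with the truth almost perfectly (Jaccard
0.984; 1.0 is identical clusterings). The other examples compare against
the probe-wise tests (`02`), replicate calls across a discovery/validation
cohort pair with a subject-level bootstrap (`03`), and show how
heavy-tailed (multivariate t, df=3) data break the normality assumption and
collapse the agreement to a median Jaccard of about 0.29 (`04`).

The same workflow is scriptable from the shell:

```bash
dvclust simulate --scenario SimI -g 1000 --seed 1 --out expr.tsv --truth-out truth.tsv
dvclust detect expr.tsv --seed 1 --out call.tsv
dvclust baseline expr.tsv --test F --out f_call.tsv
```

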