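# popcode

How pairwise noise correlations shape the fidelity of a neural population
code, with everything else (tuning, noise variances) held fixed.

The package computes three information measures as functions of the pairwise
noise correlations — linear Fisher information `f'ᵀ(Cⁿ)⁻¹f'`, optimal-linear-
estimator (OLE) information `Lᵀ(Cⁿ+Cμ)⁻¹L`, and Gaussian mutual information —
and provides:

- **measures** — the three measures, signal correlations built from
  per-measure sensitivity vectors, analytic gradients with respect to the
  correlations, the noise-free upper bound on OLE information, correlation
  strength, and the rescaling weights linking signal correlations to the
  gradient (`G = −w∘ξ`, `w > 0`): the *sign rule* — noise correlations whose
  signs oppose the signal correlations never hurt, and are locally optimal.
- **spectrahedron** — geometry of the admissible set (correlation matrices
  with unit diagonal): classification, maximal feasible step along a ray
  (eigenvalue computation, bisection-verified), rank-controlled sampling.
- **optimize** — multi-start projected gradient ascent for maximizing a
  (convex) measure over the spectrahedron, with optional Euclidean norm caps;
  penalty sweeps `info − λ·Σρ²` tracing the (strength, information) frontier;
  the sign-rule curve. Optima above the independent-noise baseline land on a
  boundary (PSD or cap), as convexity demands.
- **cancel** — noise cancellation: a noise covariance attains the noise-free
  bound iff it annihilates the noise-free readout `A = (Cμ)⁻¹L`; with
  `qᵢ = σᵢ|Aᵢ|` this is possible iff `2·max(q) ≤ Σq`. Includes the
  closing-polygon construction, the dimension/basis of the canceling set
  (`N(N−1)/2 − N` generically), a numeric feasibility oracle via alternating
  projections, and the Monte-Carlo feasibility probability (→ 1 for large N).
- **sensitivity** — condition-number bounds (`λmax/λmin`, `2√K·λmax/λmin`)
  and empirical condition ratios for perturbations of the noise covariance
  and tuning.
- **synth** — heterogeneous von Mises populations with Poisson count
  variability (amplitudes χ²₃ scaled to mean 19 spikes/s, log-normal widths,
  equally spaced preferred directions, 100 ms count window) and packaged
  3-neuron fixtures with a checksum manifest.

## CLI

```sh
popcode simulate-population --n-neurons 10 --seed 0 --out-dir pop/
popcode info      --stats pop/ --measure ole
popcode optimize  --stats pop/ --measure ole --seed 0 --out opt.json
popcode sweep     --stats pop/ --measure ole --seed 0 --out sweep.csv
popcode scan      --n-neurons 4 --samples 500 --seed 0 --out scan.csv
popcode cancel    --stats pop/ --out-corr corr.csv --out-report report.json
popcode sensitivity --stats pop/ --measure fisher --seed 0 --out sens.json
popcode verify
```

Statistics directories hold comma-separated matrices (`sensitivities.csv`,
`cross_cov.csv`, `mean_resp_cov.csv`, `noise_vars.csv`, `stim_cov.csv`);
matrices round-trip losslessly at 17 significant digits. Results are JSON
records carrying the seed, an input hash, and the package version. Pairwise
quantities are ordered lexicographically over pairs (i < j), 0-based.

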