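# dcctree

Time-varying brain-network analysis for small region sets, built around the
default mode network (DMN) in autism research: **dynamic conditional
correlation (DCC-GARCH)** connectivity at every time point, a **minimum
spanning tree (MST)** per time point, twelve tree parameters with their
per-subject **temporal mean and variance**, and **confound-adjusted group
and symptom-severity statistics** — plus a synthetic DCC-GARCH cohort
generator with full ground truth, so every stage can be validated against a
known process.

## Who it is for

Researchers analysing resting-state ROI time series (e.g. ABIDE-style
cohorts) who want threshold-free, time-resolved network topology instead of
static or sliding-window connectivity, and methodologists who need a tested
reference implementation with simulation-based calibration.

## The model

For each demeaned ROI pair y_t (2×T), conditional variances follow
GARCH(1,1),

    σ²_{i,t} = ω_i + α_i y²_{i,t−1} + β_i σ²_{i,t−1},

and the standardized residuals ε_t = D_t⁻¹ y_t drive the DCC recursion

    Q_t = (1 − θ₁ − θ₂) Q̄ + θ₁ ε_{t−1} ε′_{t−1} + θ₂ Q_{t−1},
    R_t = diag(Q_t)^{−1/2} Q_t diag(Q_t)^{−1/2},

with Q̄ = (1/T) Σ ε_t ε_t′ and θ₁, θ₂ ≥ 0, θ₁+θ₂ < 1, estimated by
two-stage Gaussian quasi-maximum likelihood.  The N×N×T correlation tensor
C_t is converted per time point to edge costs 1/|c| and reduced by
Kruskal's algorithm to the MST — N−1 strongest connections, no threshold.
Per tree: degree k_i, betweenness BC_i (star hub = 1), eccentricity ecc_i,
maximum degree K, leaf fraction L_f, assortativity R, diameter D, maximum
betweenness BC, global efficiency E, characteristic path length L, degree
divergence κ = ⟨k²⟩/⟨k⟩, tree hierarchy T_h = leaf/(2·M·BC).  Group
inference controls age, IQ, two motion summaries, sex and site in a linear
model with BH-FDR over node-level families; ADOS associations are partial
Pearson correlations with t-based significance.

See `docs/methods.md` for estimation details, the generator's design and
the calibration studies.

## Worked example

```
python analysis/01_simulate_cohort.py --seed 1   # 10+10 subjects, N=6, T=300
python analysis/02_estimate_networks.py          # DCC -> MST -> summaries
python analysis/03_group_differences.py          # adjusted group tests
python analysis/04_symptom_correlations.py       # ADOS partial correlations
```

The simulated patient-like group has long-run correlations shrunk ×0.5 and
θ₁ raised 0.04→0.09 (lower-mean, more volatile connectivity).  Step 02
prints the fitted dynamics:

```
Fitted 20 subjects x 15 node pairs.
theta1: median 0.071, theta2: median 0.879; 0 pair(s) fell back to constant correlation.
Wrote results/summaries.csv (20 rows x 54 summary columns).
```

Step 03 recovers the injected topology effects — e.g. mean global efficiency
0.5996 ± 0.0028 (patient-like) vs 0.6218 ± 0.0069 (control), t = −7.20,
p = 1.1e-5: weaker, more volatile connectivity makes the time-resolved
trees less hub-centred (lower efficiency, higher diameter and path length).
Step 04 lists the summaries whose partial correlation with the generated
ADOS scales is significant at p < 0.05 in the 10 patients.

The same stages are available as a CLI (`dcctree simulate|dcc|mst|metrics|
stats|run`) and as one reproducible YAML-configured pipeline
(`dcctree run --config configs/demo.yaml`) that writes a manifest with checksums,
timings and stage caching.

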