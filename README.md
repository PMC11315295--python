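# phagequant

Quantitation of temperate-phage infection outcomes in bacterial
populations, built around the Q-induction assay for the plasmid-like
*Vibrio parahaemolyticus* phage φVP882.

After a phage infects a culture, each cell either lyses or becomes a
lysogen. Because inserting a selectable marker into φVP882 cripples its
infectivity, lysogens cannot be counted on plates. The Q-induction assay
counts them by killing them: every cell carries an arabinose-inducible copy
of the phage lytic regulator *q*, so inducing *q* after the infection
period lyses exactly the lysogenized cells, and the resulting dip in the
culture's OD600 measures the lysogen fraction. This package implements the
analysis side of that assay, plus the companion qPCR quantitation, for
microbiologists running plate-reader infection experiments:

- **Percent lysogens from growth curves.** From the phage-treated curve it
  reads the pre-lysis peak OD_P (maximum OD at or before a boundary: 4 h
  planktonic, 5 h surface) and the post-lysis valley OD_V (minimum after
  the boundary), and computes

      %L = (OD_P − OD_V / E) / OD_P × 100

  where the expansion factor E corrects OD_V for continued growth of the
  non-lysogens. With N_tP, N_tV the buffer-treated control's fitted
  logistic N(t) = K / (1 + ((K−N₀)/N₀) e^(−rt)) evaluated at the peak and
  valley times, E = N_tV/N_tP when the infected culture kept pace with the
  control (no net lysis; %L ≤ 0), and otherwise
  E = N_tV/N_tP + (N_tV/OD_V − 1), which additionally credits survivors
  with faster regrowth on nutrients released by lysis. Reported %L is
  clamped to [0, 100]; the raw value is kept for diagnostics.
- **qPCR absolute quantitation.** Standard curves Cq vs log10(copies),
  Cq→copies conversion, amplification efficiency, phage titering (*gp69*),
  lysogen counts (*cos* per *ompW*, normalized to a stable lysogen),
  percent adsorption, and fold particle production, with explicit handling
  of below-LOD measurements.
- **Validation.** Known-mixture calibration: regress estimated %L on the
  known mixture percent (OLS, induced samples only) and judge the
  estimator by slope and R².
- **Simulation.** A generative model of the whole experiment — logistic
  growth, Q-driven lysis of the lysogen fraction after induction, survivor
  regrowth, multiplicative plate-reader noise, synthetic Cq values — so
  every stage is testable without instrument data.

## Worked example

Simulate a 40% lysogen mixture and quantify it:

```python
from phagequant import SimulationConfig, simulate_mixture, quantify_lysogeny

cfg = SimulationConfig(lysogen_fraction=0.4, seed=7)
wells = simulate_mixture(cfg)
est = quantify_lysogeny(wells["induced_phagelike"], wells["buffer_control"])
print(f"%L = {est.percent_lysogens:.1f} ({est.branch}, E = {est.expansion_factor:.3f})")
print(f"peak {est.peakvalley.od_p:.3f} @ {est.peakvalley.t_p:.2f} h, "
      f"valley {est.peakvalley.od_v:.3f} @ {est.peakvalley.t_v:.2f} h")
```

prints

```
%L = 42.2 (scaled, E = 1.501)
peak 0.570 @ 4.00 h, valley 0.494 @ 4.50 h
```

The culture peaked at OD 0.570 at the 4 h boundary, lysis of the lysogens
dropped it to 0.494 half an hour later, and after expansion-factor
correction the estimator reads 42.2% lysogens against the true 40%. The same estimate
comes from the command line: write the curves with `phagequant simulate
--config sim.toml --out run/` and quantify with `phagequant quantify
--growth run/growth_long.csv --condition planktonic --out out/`, which
emits a TSV of per-strain means ± sd and a full-precision JSON report.

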