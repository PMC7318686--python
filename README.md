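# methyldyn

Fast (ps–ns) side-chain dynamics analysis for membrane proteins studied by
solution NMR: from relaxation observables to methyl symmetry-axis order
parameters, motional-class decomposition, and residual conformational
entropy.

## The problem

Methyl-bearing side chains (Ile, Leu, Val, Met) report on the internal
motion of a protein through the squared generalized order parameter of the
methyl three-fold symmetry axis, O²_axis ∈ [0, 1]: 1 means the axis is
rigid in the molecular frame, 0 means isotropic sub-nanosecond disorder.
For membrane proteins in micelles or bicelles the analysis chain is:

1. **Tumbling time.** Backbone ¹⁵N R1/R2 ratios are inverted against the
   Lipari–Szabo spectral density

       J(ω) = (2/5)·[S²τ_m/(1+(ωτ_m)²) + (1−S²)τ/(1+(ωτ)²)],
       1/τ = 1/τ_m + 1/τ_e,

   with the standard dipolar+CSA rate expressions, to give the global
   reorientation time τ_m. Residues with µs–ms exchange are screened out
   by their elevated R1·R2 product.
2. **η extraction.** Intra-methyl ¹H–¹H cross-correlated relaxation rates
   η are fit from intensity-ratio build-up curves,
   ratio(T) = (3/4)·η·tanh(√(η²+δ²)T)/(√(η²+δ²) − δ·tanh(√(η²+δ²)T)).
3. **Conversion.** O²_axis = (10/9)·η·r⁶_HH /
   ([P₂(cos θ_axis,HH)]²·(μ₀/4π)²·γ_H⁴·ħ²·τ_m).
4. **Motional classes.** The O²_axis distribution decomposes into bands —
   ω (rigid), α, J, and the membrane-protein J′ band near O² ≈ 0.21 that
   reflects extensive multi-torsion rotamer sampling. Band count is scored
   by BIC over 1-D Gaussian mixtures; centers and boundaries come from
   1-D k-means on error-filtered (≤ 0.1) values.
5. **Entropy.** The diffusion-in-a-cone mapping
   S/k_B = ln[π(3 − √(1+8·√O²_axis))] converts order parameters into a
   residual conformational entropy per methyl axis.

The package also computes MD-style order parameters from bond-vector time
series (ensemble formula and P₂-autocorrelation plateau), and spatial
statistics (O² vs distance-to-lipid, permutation tests for spatial
clustering of motional classes). Synthetic-data generators produce every
input with known ground truth, emulating the statistical structure of
published membrane-protein methyl datasets.

## Worked example

Generate a study-like synthetic dataset (90 methyl probes, micelle +
bicelle, three-band class structure), fit η for every probe, convert to
O²_axis at the micelle tumbling time, and summarize:

```
$ methyldyn simulate methyl --seed 7 --out-dir demo
$ methyldyn o2 demo/buildup_micelle.tsv --tau-m-ns 21.9 --environment micelle \
      --n-mc 200 --seed 7 --out demo/o2_micelle.tsv
INFO wrote 90 probes, <O2>=0.353 <err>=0.019
$ methyldyn report demo/o2_micelle.tsv --k 3
== table1:demo/o2_micelle.tsv ==
  n=90  <O2_axis>=0.353  <err>=0.019  T=323.1 K
  classes (k=3): J'/J/alpha centered at 0.180, 0.346, 0.537 (n_filtered=90)
  entropy: total 56.7 kB over 90 probes (mean 0.630 kB)
```

The mean O²_axis of ~0.35 is far below the ~0.5–0.6 typical of soluble
proteins — the membrane-protein signature the generator encodes — and the
three k-means centers recover the planted J′/J/α band structure
(0.21/0.36/0.55) to within sampling error. The per-probe precision
(±0.019) comes from seeded Monte-Carlo resampling of the build-up ratios.
Comparing the two membrane mimetics,

```
$ methyldyn compare-env demo/true_o2_micelle.tsv demo/true_o2_bicelle.tsv
{ "r_squared": 0.86, "slope": 1.06, ... "n_paired": 90 }
```

shows the strong micelle/bicelle correlation built into the generator:
fast side-chain dynamics are largely insensitive to the membrane mimetic.

The same operations are available as a library (`methyldyn.modelfree`,
`.classify`, `.entropy`, `.mdorder`, `.spatial`, `.synth`), returning
result objects (`TumblingEstimate`, `EtaFit`, `ClassModel`,
`EntropyEstimate`) rather than JSON.

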