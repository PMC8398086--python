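# specbind

Inference of ligand–protein binding from fluorescence-quenching titrations,
with the structural post-analytics usually reported alongside it.

When a small ligand (e.g. a polyphenol such as curcumin) binds a protein
(e.g. β-casein), it quenches the protein's intrinsic tryptophan/tyrosine
fluorescence. Titrating the quencher and reading the emission peak yields,
through three classical linear models, the full binding picture:

1. **Stern–Volmer quenching**: F₀/F = 1 + K_sv[Q]. The slope K_sv and the
   rate K_q = K_sv/τ₀ (τ₀ = 10⁻⁸ s) diagnose the mechanism: K_q above the
   diffusion limit (2×10¹⁰ L mol⁻¹ s⁻¹) means static quenching — a
   ground-state complex.
2. **Double-log binding plot**: log₁₀((F₀−F)/F) = log₁₀K_b + n·log₁₀[Q],
   giving the binding constant K_b and apparent site number n.
3. **Van't Hoff analysis**: ln K_b = −ΔH/(RT) + ΔS/R across temperatures,
   giving ΔH, ΔS, then ΔG = ΔH − TΔS per temperature, and the driving-force
   class from the signs (ΔH<0, ΔS>0 ⇒ electrostatic; both >0 ⇒ hydrophobic;
   both <0 ⇒ H-bond/van der Waals).

Around this chain the package provides docking-score conversion
(K_d = exp(E_b/R′T)), and desk-scale structural metrics: Kabsch
superposition RMSD over multi-model PDB trajectories, geometric
hydrogen-bond detection, a simplified Kabsch–Sander secondary-structure
assigner (H/E/T/C fractions), and four-level Ramachandran accounting. A
synthetic-data module generates every input — quenched Gaussian emission
titrations, exact van't Hoff series, ideal poly-alanine chains, rigid
motions, H-bond and β-sheet fixtures — with known ground truth, so the whole
pipeline is testable without any deposited data.

## Worked example

```python
import specbind as sb

# a casein-like titration: quencher 0-10 uM, emission peak 334 nm (pH 2.0)
truth = sb.QuenchTruth(Kb=6.48e4, n=1.13, lambda_center=334.0)
series = sb.generate_emission_titration(truth, T=298.0, pH=2.0)
quench, binding = sb.analyze_titration(series)
print(binding.Kb, binding.n, quench.mechanism.value)
```

prints `64800.0000000033 1.1300000000000041 static`: the double-log fit
recovers the generating K_b = 6.48×10⁴ L/mol and n = 1.13 exactly (the model
is log-linear and the data noiseless), and K_q exceeds the diffusion limit,
so the quenching is static. Feeding measured K_b values at three
temperatures into the thermodynamic stage:

```python
res = sb.fit_vant_hoff([(298, 6.48e4), (305, 6.17e4), (312, 5.73e4)])
print(res.dH, res.dS, res.driving_force.value)
```

prints `-6.779919383091315 69.39751496462148 electrostatic`: binding is
exothermic (ΔH ≈ −6.8 kJ/mol) and entropy-favoured (ΔS ≈ +69 J mol⁻¹ K⁻¹),
the signature of electrostatically driven association, with
ΔG ≈ −27.5 kJ/mol at 298 K (spontaneous).

The `examples/` directory holds one short script per capability
(quenching fits, van't Hoff, docking K_d, structural metrics, full
pipeline); each prints its numbers with a line on what they mean. A thin
CLI mirrors the library: `specbind fit-quenching`, `specbind vant-hoff`,
`specbind dock-kd`, `specbind struct rmsd|hbonds|ss|rama`, `specbind run`,
`specbind fixtures`.

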