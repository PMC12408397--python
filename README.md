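# ppmoens

Solution-structure ensemble analysis for peptide-conjugated morpholino
oligonucleotides (PPMOs).

Phosphorodiamidate morpholino oligonucleotides (PMOs) are uncharged
antisense therapeutics; conjugating a cell-penetrating peptide (here
-GlyArg₆ at the 3′ end) improves their uptake. In solution these
molecules do not fold into one canonical structure — they populate an
ensemble of partially folded conformers with a handful of base pairs and
base stacks. `ppmoens` implements the analysis chain that resolves such
an ensemble from experiment-facing observables:

* **Structural metrics** on multi-model conformer ensembles: end-to-end
  distance X, radius of gyration R_g, Shrake–Rupley SASA, base-stack and
  base-pair counts from base-fixed frames (rise z, slide ρ, inter-normal
  angle θ), geometric hydrogen bonds (d_DA < 3.3 Å, ∠D–H–A > 140°), and
  residue-contact time-fraction maps (COM distance < 7.5 Å) with 3′-end
  residue numbering.
* **CD deconvolution**: the observed ellipticity is modelled as
  Θ_th(λ) = Σᵢ wᵢ θᵢ(λ) over per-conformer basis spectra; the
  simplex-constrained weights wᵢ (softmax-parameterised) are fitted by
  Adam over 10,000 iterations from 20 restarts, minimising
  MSE = (1/m) Σⱼ [Θ(λⱼ) − Θ_th(λⱼ)]², with a thermodynamic tie-break
  selecting the near-equivalent fit with the most negative
  ⟨ΔG⟩ = Σ wᵢ ΔGᵢ, and a w ≥ 0.05 cut defining the reported conformers.
* **Viscosity**: ensemble-averaged intrinsic viscosity
  [η]_th = Σ wᵢ ηᵢ / Σ wᵢ, the Einstein/Huggins relation
  η(C) = η_s (1 + [η]c + k_H[η]²c²), and closed-form least-squares
  fitting of the Huggins constant k_H and of [η] from the dilute law.
* **Thermodynamics**: folding ΔH, ΔS, ΔG = ΔH − TΔS against an unfolded
  reference at T = 300 K, weighted means, and histogram distributions.
* **Synthetic data**: seeded generators for every input with known ground
  truth (planted stacks/pairs, Bernoulli contact schedules, Gaussian-band
  basis spectra, Einstein viscosity curves, broad energy distributions),
  so the full pipeline is testable end to end.

See `docs/methods.md` for the model details and numerical conventions.

## Worked example

Deconvolve a synthetic CD spectrum and reconstruct the viscosity curve:

```python
import numpy as np
from ppmoens.synthetic_data import (GeneratorConfig, gen_basis_spectra,
    gen_observed_spectrum, gen_viscosity_dataset, gen_energy_table)
from ppmoens.cd_deconvolution import (FitConfig, fit_weights,
    select_by_free_energy, top_conformers)
from ppmoens.thermodynamics import folding_deltas
from ppmoens.viscosity_model import (HydroParams, mean_intrinsic_viscosity,
    fit_huggins)

cfg = GeneratorConfig(seed=42, n_conformers=8)
basis = gen_basis_spectra(cfg)                      # 8 spectra on 200-330 nm
w_true = cfg.rng(7).dirichlet(np.ones(8))           # hidden populations
target = gen_observed_spectrum(basis, w_true, noise_sd=0.0)

fit = fit_weights(basis, target, FitConfig(seed=42, restarts=20))
deltas = folding_deltas(gen_energy_table(cfg))
fit = select_by_free_energy(fit.restarts, deltas.dG)
selected, coverage = top_conformers(fit)
print("MSE:", round(fit.mse, 8))
print("selected:", [(i + 1, round(w, 3)) for i, w in selected])
print("coverage:", round(coverage, 3))
print("<dG>:", round(fit.mean_dG, 1), "kcal/mol")

eta_i = cfg.rng(8).uniform(4.2, 6.3, 8)             # per-conformer [eta]_i
iv = mean_intrinsic_viscosity(eta_i[[i for i, _ in selected]],
                              [w for _, w in selected])
print("[eta]_th:", round(iv, 2), "cm3/g")
data = gen_viscosity_dataset(HydroParams(0.909, iv, 5.0),
                             np.arange(0., 101., 10.), noise_sd=0.02, seed=42)
k_h, sse = fit_huggins(data, 0.909, iv)
print("k_H:", round(k_h, 2))
```

Output:

```
MSE: 0.0
selected: [(1, 0.281), (5, 0.263), (2, 0.123), (7, 0.097), (3, 0.096), (4, 0.089)]
coverage: 0.95
<dG>: -77.8 kcal/mol
[eta]_th: 5.98 cm3/g
k_H: 5.07
```

The six conformers with w ≥ 0.05 carry 95% of the population, and the
fitted weights match the hidden truth (e.g. conformer 1 generated at
0.281, recovered at 0.281; the noiseless fit is exact to the printed
precision). Their weighted intrinsic viscosity feeds the Einstein
relation, and the Huggins constant refitted from the noisy curve (5.07)
recovers the generating value (5.0) within the noise.

The same analysis is scriptable from the shell:

```sh
ppmoens gen --seed 3 --n-conformers 8 --out fixture/   # inputs + truth.json
ppmoens run --config cfg.yaml --seed 7 --out results/  # full pipeline
```

`run` executes pre-screening → weight fitting → free-energy selection →
top-conformer truncation → viscosity averaging and Huggins fitting →
thermodynamic summaries, and writes `cd_fit.csv`, `fitted_spectrum.csv`,
`viscosity_fit.json`, `predicted_profile.csv`, `thermo.csv`,
`thermo_hist.csv`, `interaction_map.tsv`, `metrics.csv` and a
checksummed `manifest.json`. Reruns with the same seed are byte-identical.

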