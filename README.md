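# bh3forge

A tested, reusable implementation of the computational pipeline behind
designed protein binders that engage the BH3-binding groove of the
proapoptotic effectors BAK and BAX. It covers the full analysis arc of such
a project:

1. **Motif grafting** — transplant a BH3-like helix (with the conserved
   hotspots h1, h2, h3, h3+1, h3+2 = Ile, Leu, Ile, Gly, Asp at motif
   positions 1, 5, 8, 9, 10) onto every geometrically compatible window of a
   helix-bundle scaffold, under full-backbone RMSD ≤ 3.0 Å, endpoint RMSD
   ≤ 2.0 Å and a zero-clash gate with side chains reduced to glycine.
2. **Interface sequence design** — Monte Carlo simulated annealing over
   discrete rotamers at binder surface positions (side-chain SASA ≥ 30 Å² at
   probe 2.2 Å) within 8 Å, then 12 Å, of the target, hotspots fixed and
   Pro/Cys/Trp/Gly never introduced, under a declared simplified pairwise
   energy model.
3. **Design filters** — predicted binding energy ΔG<sub>bind</sub> =
   E(complex) − E(partners alone), Lawrence–Colman-style shape
   complementarity Sc ∈ [−1, 1], buried unsatisfied polar atoms at the
   interface, and a peptide-bond ω geometry check (|ω| ≥ 150°).
4. **Directed-evolution analytics** — per-mutation log2 enrichment of sorted
   vs naive SSM pools, the dual-criterion rule (a mutation must enrich
   independently under BOTH the affinity sort and the specificity sort), and
   degenerate-codon combinatorial library design with protein diversity
   capped below 4×10⁷ variants.
5. **Quantitative assay models** — global 1:1 biosensor kinetics
   (R(t) = R_eq(1 − e^(−(k_on·C + k_off)t)) in association, exponential
   k_off decay in dissociation; K_d = k_off/k_on), liposome release percent
   (100·(F − F_min)/(F_max − F_min)), variable-slope 4PL dose–response
   fitting, and an equilibrium model of the concentration-threshold
   mechanism by which a groove binder *activates* its target at
   substoichiometric doses and *inhibits* dimerization at saturating doses,
   including the α9 intramolecular competition that raises the apparent
   K_d of full-length BAX: K_d,app = K_d·(1 + K9).

Everything runs on synthetic inputs with known ground truth (the
`synthetic_data` module), so the whole pipeline is testable offline.

## Worked example

Fit a simulated four-concentration titration in the high-affinity regime and
summarize the pore-formation threshold mechanism at assay conditions
(38 nM target, 0.4 nM binder K_d, 15 nM activator):

```python
import numpy as np
from bh3forge.binding_kinetics import simulate_1to1, fit_1to1
from bh3forge.pore_model import MechanismParams, threshold_summary

times = np.linspace(0, 3000, 150)
traces = simulate_1to1(1e6, 4e-4, 1.0, [1e-10, 4e-10, 1.6e-9, 6.4e-9],
                       times, noise_sd=0.01, seed=0)
print(fit_1to1(traces).summary())
print(threshold_summary(MechanismParams(t_total=38e-9, kd_bind=0.4e-9,
                                        activator=15e-9)).summary())
```

prints

```
1:1 binding kinetics (global fit)
  traces:   4
  kon:      9.953e+05 M^-1 s^-1 +/- 6.6e+03
  koff:     0.0003999 s^-1 +/- 2.3e-06
  Rmax:     1.002 RU
  Kd:       4.018e-10 M (0.402 nM)
  residual: 0.2432
concentration-threshold summary
  activation peak: 3.1 nM (99.0 % release)
  inhibition IC50: 50.23 nM
  fold excess over target: 1.32x
```

The kinetic fit recovers the planted 400 pM dissociation constant from 1%
noise. The mechanism summary shows the signature of stoichiometric
inhibition: a tight binder's inhibition IC50 (≈50 nM) tracks the total
target concentration (38 nM), not its K_d, while the activation branch
peaks at a few nM — far below target saturation.

A shell interface wraps the same stages (`bh3forge graft`, `bh3forge
enrich`, `bh3forge fitbli`, `bh3forge fitdr`, `bh3forge simulate-mech`,
`bh3forge make-fixtures`, ...); run `bh3forge --help` for the full list.

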