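# allokin

Allosteric-network and binding-cooperativity analysis of multi-state protein
NMR titrations, with companion ITC and steady-state kinetics fitting.

## The problem

Protein kinase A's catalytic subunit (PKA-C) is a K-type cooperative enzyme:
nucleotide binding raises the affinity for (pseudo-)substrate, and this
positive binding cooperativity is carried by an internal allosteric network
of residues that respond to ligation in a coordinated way.  Oncogenic
variants — notably the DNAJB1–PKA-C fusion kinase that drives fibrolamellar
hepatocellular carcinoma — can leave structure and turnover essentially
intact while degrading that network and, with it, the cooperativity.

`allokin` implements the quantitative toolchain used to characterize such
defects from solution data:

- **CSP** — combined amide chemical-shift perturbations between two ligation
  states, Δδ = √((ΔδH)² + (0.154·ΔδN)²), with responder flagging at
  mean + 1 SD.
- **CHESCA** (chemical-shift covariance analysis) — residues whose shifts
  move collinearly across ≥ 4 ligation states (apo, ADP, ATPγN, ATPγN+PKI)
  belong to one allosteric network.  The package applies the
  linewidth-based inclusion filter Δδ > ½Δν_A + ½Δν_B, projects each
  residue's per-state (δH, 0.154·δN) points on their first singular vector,
  builds the |Pearson| matrix R_ij (cutoff 0.98), per-residue correlation
  scores, agglomerative clusters, and the community-level matrix
  R_X,Y = #(R_ij > 0.8)/(n_X·n_Y) over the nine functional communities of
  the kinase core.
- **CONCISE** — per-residue PCA places every ligation state on a 1-D
  open↔closed equilibrium coordinate; per-state Gaussian densities give the
  mean position ⟨PC⟩ and its width.  ⟨PC⟩ maps linearly to % closed and to
  ΔΔG via the anchors (0 % closed, 0 kcal/mol) and (100 % closed,
  −15 kcal/mol), the latter being RT·ln Kd summed over the wild-type's two
  binding steps at 300 K.
- **Thermodynamics** — the analytic 1:1 Wiseman isotherm derivative,
  least-squares (Kd, ΔH°) fitting, ΔG = RT·ln Kd, TΔS = ΔH − ΔG, and the
  cooperativity constant σ = Kd(apo)/Kd(nucleotide-bound).
- **Kinetics** — Michaelis–Menten fits and kcat/KM with quadrature error
  propagation.
- **Synthetic data** — a ground-truth generator for multi-state shift
  tables (latent closure coordinate λ per state, networked vs. independent
  residues), Wiseman isotherms and velocity curves, so the whole chain is
  testable end to end.

## Worked example

Cooperativity from the published dissociation constants (μM) of the
wild-type kinase (PKI binding: 17 apo, 0.16 nucleotide-saturated) and the
J-domain chimera (9 apo, 1.1 nucleotide-saturated):

```python
>>> from allokin import cooperativity_sigma, fold_change
>>> s_wt = cooperativity_sigma(17, 0.16).sigma      # 106.25
>>> s_chim = cooperativity_sigma(9, 1.1).sigma      # 8.18
>>> fold_change(s_wt, s_chim)
(12.98611111111111, 13)
```

The chimera loses 13-fold in nucleotide/pseudo-substrate binding
cooperativity.  The same loss shows up structurally — run the full chain on
synthetic data:

```python
>>> from allokin import (SyntheticShiftConfig, generate_shift_dataset,
...                      concise_scores, free_energy_map)
>>> cfg = SyntheticShiftConfig(n_residues=100, noise_sd_H=0.015,
...                            noise_sd_N=0.1, seed=42)
>>> table, communities, truth = generate_shift_dataset(cfg)
>>> res = concise_scores(table)
>>> {s: round(res.mean_pc[s], 2) for s in res.states}
{'apo': -1.18, 'ADP': -0.11, 'ATPgN': 0.13, 'ATPgN+PKI': 1.16}
>>> fm = free_energy_map(res)
>>> {s: round(fm.ddg[s], 1) for s in res.states}
{'apo': 0.0, 'ADP': -6.8, 'ATPgN': -8.4, 'ATPgN+PKI': -15.0}
```

The apo state sits at ⟨PC⟩ ≈ −1.2 (open), the two binary complexes near 0
(intermediate) and the ternary complex at ≈ +1.2 (closed); the ΔΔG column is
the free-energy progression implied by the extent of closure.  The same
pipeline is available from the shell:

```bash
allokin run --seed 7 --out results/      # simulate → CSP → CHESCA → CONCISE → ITC/MM
allokin itc sigma --kd-apo 17 --kd-nuc 0.16
allokin chesca --table shifts.csv --communities communities.csv --out chesca/
```

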