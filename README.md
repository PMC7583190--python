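# synpd

Multi-scale pharmacodynamic modeling of the synergy between paclitaxel
(PTX) and the SMAC-mimetic birinapant (BRP) in PANC-1 pancreatic cancer
cells. The package implements, as a tested and reusable library with a
CLI, four linked analysis stages:

1. **Cell growth / kill model.** Normalized cell density follows
   `dN/dt = (k_G − S_B − S_P)·N`, where each drug contributes a Hill
   cytotoxic signal `S = K_max·C/(Ψ·KC50 + C)` delayed through a chain
   of `n` transit compartments with mean transit time τ. The
   dimensionless interaction term Ψ multiplies both drugs' `KC50` in
   combination arms: Ψ < 1 means synergy (each drug potentiates the
   other), Ψ = 1 additivity, Ψ > 1 antagonism.
2. **Protein signaling network.** Ten drug-responsive proteins (cIAP1,
   p-NF-κB/p-p65, BAX, Bcl2, IRAK4, pJNK, pSTAT3, VDAC1, ELYS, ASPP2)
   follow indirect-response turnover
   `dP/dt = k_deg·(1+Sti)·(1−Inh)·Π P_j^γ − k_deg·P` with fold-change
   baseline 1, so `k_syn = k_deg`. BRP shuts off cIAP1 synthesis, PTX
   drives ELYS, any drug induces IRAK4, and only the combination blocks
   pJNK degradation.
3. **Cell-cycle / apoptosis compartments.** G0/G1 → S → G2/M → division
   with Gompertz contact inhibition `I0 = ln(N_max·live0) − ln(live)`,
   spontaneous apoptosis modulated by cIAP1 (`k_ap·cIAP^γ`), ELYS-gated
   mitotic arrest (`k_ma = k_ma0·ELYS^γ·(ELYS>1)`), arrested-cell
   apoptosis `k_apm = k_apm0·ASPP2_delayed·cIAP^γ₁·BAX^γ₂/Bcl2`, and
   mitotic slippage into an apoptosis-resistant polyploid pool.
   Michaelis–Menten conversion extrapolates the fitted drug effects to
   other concentrations; a plate-context switch transfers the model
   between 6-well and 96-well formats.
4. **Temporal proteomics.** Quantile normalization across batches,
   control-matched log2 fold-changes, and seeded k-means clustering of
   temporal profiles with a parsimony-aware cluster-count rule.

All stages are fitted by maximum likelihood with the study's variance
models (`Var = (δ+σ·Y)²` for densities/counts, constant error for
percentages and log2 fold-changes), AIC model selection for the transit
depth, and a sequential fix-upstream / fit-downstream strategy. A
synthetic-data module regenerates every input kind from the models plus
the stated noise structure, so the entire pipeline runs without any
external data.

## Worked example

```python
from synpd.growth import fit_growth
from synpd.synthetic import SyntheticSpec, generate_growth_data

spec = SyntheticSpec(seed=11)            # ground truth: psi = 0.69
data = generate_growth_data(spec)        # 35 arms x 5 times x 3 reps
fit = fit_growth(data, n_transit=3, seed=1)
print(f"psi = {fit.psi:.3f}, 95% CI {fit.psi_ci[0]:.3f}-{fit.psi_ci[1]:.3f}")
print(f"k_G = {fit.params.k_G:.4f} /h")
```

prints

```
psi = 0.660, 95% CI 0.639-0.681
k_G = 0.0224 /h
```

The recovered interaction term sits near the generating value 0.69 and
its confidence interval excludes 1, i.e. the synthetic combination data
carry a detectable supra-additive (synergistic) kill effect; `k_G` of
0.0224/h corresponds to a ~31 h doubling time for untreated cells.

The same analysis from the shell:

```sh
synpd generate growth --seed 11 --out run/
synpd fit-growth --data run/growth.csv --transit 3 --seed 1 --out run/
synpd run --out fullrun/ --seed 1       # entire pipeline end to end
```

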