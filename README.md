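# aggkin

Aggregation-kinetics modelling for antibody fragments from molecular-dynamics
descriptors.

## The problem

Protein aggregation is a central liability in the development of antibody
therapeutics, and its rate depends strongly on the formulation — the
combination of temperature, pH and ionic strength the protein sits in.  For
a Fab fragment whose aggregation is rate-limited by partial unfolding of the
native state, the molecular fluctuations visible in MD simulations carry
predictive information about the experimentally measured aggregation rate
ln(*v*) (*v* in % monomer lost per day).

`aggkin` implements the full workflow for turning per-condition MD
trajectories into aggregation-rate predictions:

1. **Descriptor extraction** (`aggkin.descriptors`) — 17 molecular features
   per formulation condition: total and nonpolar (carbon) solvent-accessible
   surface area by the Shrake–Rupley construction; the late-window SASA
   change ΔSASA of seven aggregation-prone regions (APRs) and their sum;
   the fraction of native Cα contacts *Q* (8 Å cutoff); mean RMSF, RMSD
   and radius of gyration over the final half of each trajectory;
   geometric hydrogen-bond counts; salt-bridge occurrence (acidic-O to
   basic-N within 3.2 Å); and the Henderson–Hasselbalch net charge
   Z = Σ_base 1/(1+10^(pH−pKa)) − Σ_acid 1/(1+10^(pKa−pH)) from supplied
   per-site pKa tables.  Values are averaged over replicate runs.
2. **Correlation analysis and feature selection** (`aggkin.statsel`) —
   Pearson/Spearman correlation matrices; a redundancy filter that drops,
   from every feature pair with |r| > 0.8, the member less correlated with
   ln(*v*); a three-band aggregation-risk classifier (high: ln(*v*) > 4,
   low: ln(*v*) < 0) scored by a single-descriptor threshold; and
   per-residue RMSF-vs-rate R² maps written into the B-factor column of a
   PDB for structure colouring.
3. **Model building** (`aggkin.regress`) — multiple linear regression and
   NIPALS partial least squares behind a statsmodels-style Model/Results
   interface, with seeded k-fold/LOOCV cross-validation (standardization
   learned on training folds only), fold-number sensitivity analysis
   against the LOOCV baseline, and a stability-aware model-selection rule.
4. **Attribution** (`aggkin.shapley`) — model-agnostic Shapley values
   (exact enumeration for small feature sets, permutation sampling with
   standard errors otherwise) and a mean-|φ| global importance ranking.
5. **Synthetic data** (`aggkin.synthgen`) — the packaged 49-condition
   formulation table, toy trajectories with planted temperature-dependent
   fluctuation amplitudes, and feature tables with planted low-rank linear
   structure for recovery tests.

The packaged 49-condition table (4 temperatures × 6 pH levels × 9 ionic
strengths, with measured melting temperature and aggregation rate) drives
the desk-computable statistics; trajectory descriptors accept multi-model
PDB or extended-XYZ input.

## Worked example

```python
from aggkin import regress, statsel, synthgen

# statistics on the packaged 49-condition formulation table
df = synthgen.condition_table_fixture().to_frame()
cm = statsel.correlation_matrix(df)
print(round(cm[("temperature", "ln_v")], 2))   # 0.84
print(round(cm[("pH", "tm")], 2))              # 0.65

# PLS on a synthetic feature table with planted low-rank structure
spec = synthgen.FeatureTableSpec(
    n_rows=49, feature_names=tuple("abcdefghi"), latent_rank=2,
    noise_sd=0.2, response_noise_frac=0.1, seed=1)
X, y, truth = synthgen.synth_feature_table(spec)
res = regress.PLSModel(y, X).fit()     # components chosen by inner 5-fold CV
print(res.summary())
rep = regress.cross_validate(regress.ModelSpec("pls"), X, y, k=10, seed=1)
print(f"mean MSE {rep.mean_mse:.3f}, out-of-fold R2 {rep.evaluation_r2:.3f}")
```

The summary prints the fitted coefficients on the original feature scale
(here 6 components, training R² 0.990), and the 10-fold cross-validation
reports `mean MSE 0.053, out-of-fold R2 0.982`: with only 10% response
noise the planted linear structure is recovered almost perfectly, which is
the calibration check the synthetic generator exists for.

The temperature correlation (0.84) says most of the variance in aggregation
rate across the 49 conditions is thermal; the pH–Tm correlation (0.65)
reflects the strong pH dependence of conformational stability.

A command-line surface wraps the same stages:

```bash
aggkin synth --kind conditions --out conditions.csv
aggkin stats --table conditions.csv --out correlations.csv
aggkin run --config pipeline.yaml        # full orchestrated bundle
```

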