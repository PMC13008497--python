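"""The full gated workflow plus bridging validation with a plug-in predictor.

Runs log2 → concordance screen → pairing/contamination/generalizability QC
gates → factor fitting → scaling → bridging QC on clean synthetic cohorts,
then demonstrates the biased-batch signature on predictions: fitted-line r²
survives an intercept bias while unity-line R² collapses.
"""

from plasmabridge import (BridgeConfig, ScalingFactorSet, SynthConfig,
                          apply_scaling, fit_scaling_factors,
                          generate_cohorts, prediction_agreement,
                          protein_concordance, run_pipeline, select_proteins,
                          surrogate_predictor)

data = generate_cohorts(SynthConfig(seed=31, n_cohorts=2, pairs_per_cohort=30,
                                    n_proteins=250, patient_effect_sd=1.5,
                                    noise_sd=0.2))
result = run_pipeline(data.paired(), config=BridgeConfig(seed=0),
                      reference_serum=data.reference_serum,
                      reference_plasma=data.reference_plasma,
                      panels=[data.contamination_panel])
print("pipeline gates:")
for gate, outcome in result.gates.items():
    print(f"  {gate:22s} {outcome}")
print(f"scaled serum matrix: {result.scaled_serum.values.shape}; "
      f"pair mutual-nearest-neighbour fraction "
      f"{result.coclustering.mnn_fraction:.2f} "
      "(≈1 means each scaled serum sample sits next to its own plasma mate).")

# bridging QC with a surrogate predictor: clean vs biased factors
pairs = data.paired()
a, b = pairs.subset_cohort("A"), pairs.subset_cohort("B")
selected = sorted(select_proteins(protein_concordance(a)))
factors = fit_scaling_factors(a.subset_proteins(selected))
panel = selected[:40]
pred = surrogate_predictor(5, panel, reference=a.plasma.subset_proteins(selected),
                           weight_loc=0.38)
p_plasma = pred.predict(b.plasma.subset_proteins(selected))
clean = prediction_agreement(
    p_plasma, pred.predict(apply_scaling(b.serum.subset_proteins(selected),
                                         factors, policy="drop")))
biased_set = ScalingFactorSet(factors.table.assign(
    intercept=factors.table["intercept"] + 0.5), provenance="biased")
biased = prediction_agreement(
    p_plasma, pred.predict(apply_scaling(b.serum.subset_proteins(selected),
                                         biased_set, policy="drop")))
print(f"\nprediction agreement, clean factors:  R²(unity) = "
      f"{clean.r2_unity:.2f}, r²(fitted) = {clean.r2_fitted:.2f}")
print(f"prediction agreement, +0.5 intercept: R²(unity) = "
      f"{biased.r2_unity:.2f}, r²(fitted) = {biased.r2_fitted:.2f}")
print("a systematic scaling bias shifts every prediction the same way: "
      "ranking survives (r² high) but absolute agreement collapses (R² low) "
      "— recoverable by a linear re-calibration, unlike genuine signal loss.")
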