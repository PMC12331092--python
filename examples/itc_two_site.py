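"""Fit a biphasic titration with the two-independent-site isotherm model.

Simulates a titration of 1 mM phosphopeptide into 200 μM arrestin
(2.5 μL injections, 298 K) with the mutant-isolated dissociation constants
K_D1 = 1.1 μM (site I) and K_D2 = 16.4 μM (site II), adds 2% heat noise,
refits both models and runs the extra-sum-of-squares F test.
"""

from argswitch import BindingParams, ITCExperiment, compare_models
from argswitch.synth import gen_itc_isotherm

experiment = ITCExperiment()  # 40 x 2.5 uL of 1 mM into 200 uM, 298 K
truth = BindingParams(kd1=1.1, kd2=16.4, dh1=-8.0, dh2=-4.0)
isotherm, _ = gen_itc_isotherm(experiment, truth, noise_sigma=0.02, seed=21)

comparison = compare_models(isotherm, experiment)
fit = comparison.two_site
print(f"injections: {len(isotherm)}, final molar ratio {isotherm.molar_ratio[-1]:.2f}")
print(f"F = {comparison.f_statistic:.1f}, p = {comparison.p_value:.2g} "
      f"-> preferred model: {comparison.preferred}")
print(f"site I : K_D1 = {fit.params.kd1:.2f} uM, dH1 = {fit.params.dh1:.2f} kcal/mol")
print(f"site II: K_D2 = {fit.params.kd2:.1f} uM, dH2 = {fit.params.dh2:.2f} kcal/mol")
print()
print("The biphasic curve needs both site classes: the F test rejects the")
print("one-site model and the fitted constants bracket the high-affinity")
print("(site I) and low-affinity (site II) binding events.  At 2% heat")
print("noise the individual K_Ds carry substantial scatter (see the")
print("methods note on identifiability at these concentrations).")
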