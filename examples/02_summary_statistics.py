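"""Compute the 42-statistic summary vector of one simulated dataset.

The vector condenses a genotype dataset (admixed sample + both source
samples) into the statistics used for ABC inference: within-population
diversity, the distribution of MDS-projected individual admixture
fractions and angles, and between-population differentiation.
"""

from admixhist import synthdata as sd
from admixhist.sumstats import SUMMARY_NAMES

spec = sd.SourcePairSpec(L=2_000, divergence=0.15)
params = sd.exemplar_parameters("Afr2Pulses-Eur2Pulses")
ps = sd.generate_pseudo_observed(params, spec, n=30, seed=2,
                                 with_summary=True)

vec = dict(zip(SUMMARY_NAMES, ps.summary))
print(f"summary vector has {len(vec)} named statistics\n")
for name in ("asd_mean_H", "het_mean_H", "F_mean_H",
             "alpha_mean", "alpha_var", "alpha_min", "alpha_max",
             "theta_mean", "fst_afr_H", "fst_eur_H", "f3_H_eur_afr"):
    print(f"  {name:15s} {vec[name]: .4f}")

print(
    "\nalpha_mean is the MDS-projection estimate of the sample's African"
    "\nadmixture proportion; f3 < 0 is the classic signal that the sampled"
    "\npopulation is admixed between the two sources; Fst values measure"
    "\nits differentiation from either source."
)
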