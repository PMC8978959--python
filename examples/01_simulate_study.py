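"""Generate a synthetic two-sample GWAS study with known ground truth.

The generator emulates a polygenic exposure (BMI-like), a biomarker
mediator instrumented by cis variants near its receptor gene (IL-6
signaling proxied by CRP), and a binary outcome (MS-like case/control
log-odds), under the structural model outcome = b2*exposure + b1*mediator.
"""

from mrmediate import TruthRecord, generate_study

truth = TruthRecord(alpha_true=0.37, beta1_true=0.31, beta2_true=0.15,
                    n_instruments=200, seed=1)
study = generate_study(truth)
study.write("scratch_example_study")

print(f"exposure dataset: {len(study.exposure)} variants "
      f"({len(study.exposure_instruments)} designated instruments)")
print(f"mediator dataset: {len(study.mediator)} variants "
      f"({len(study.cis_instruments)} cis instruments in {study.cis_region.name})")
print(f"outcome dataset:  {len(study.outcome)} variants")
print(f"true total effect: {truth.true_effect_xy:.4f} "
      f"(proportion mediated {truth.true_proportion_mediated:.3f})")
# The written TSVs round-trip through mrmediate.read_sumstats; truth.json
# records the generating parameters for recovery checks.
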