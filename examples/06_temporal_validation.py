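"""Blind temporal validation of a frozen cascade.

A development cohort (985 subjects) and a later-enrolment validation
cohort (685 subjects) are drawn from one generative law; the cascade is
fitted once on the development table and evaluated untouched on the
validation table — the validation rows influence nothing.
"""

from adcascade import (
    ADNI_LIKE_COUNTS,
    ADNI_LIKE_DEV_COUNTS,
    CohortSpec,
    PipelineSpec,
    adni_like_profile,
    generate_dev_and_validation,
    temporal_validate,
)

dev, val = generate_dev_and_validation(
    CohortSpec(n_per_class=ADNI_LIKE_DEV_COUNTS, d=40, s=8, seed=4,
               clinical_profile=adni_like_profile("dev")),
    CohortSpec(n_per_class=ADNI_LIKE_COUNTS, d=40, s=8, seed=5),
)
imaging = dev.feature_ids[:8]
pipeline = PipelineSpec(variant="clinical+imaging", learner="adaboost",
                        imaging_columns=imaging)

result = temporal_validate(dev.modelling_table(imaging), val.modelling_table(imaging),
                           pipeline, seed=6)

print(f"development n={dev.n}, validation n={val.n} (disjoint subjects)")
print(f"blind overall accuracy on the validation cohort: {result.overall_accuracy:.3f}\n")
for name, m in result.task_metrics.items():
    r = m.rounded()
    print(f"{name:28s} SEN={r['sensitivity']} SPE={r['specificity']} "
          f"ACC={r['accuracy']} F1={r['f1']} AUC={r['auc']}")
print("\nper-task rows use the survivor convention: each classifier is scored")
print("on the subjects that reach it after the earlier peels.")
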