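"""Train the fusion classifier on a small synthetic cohort.

Builds six phantoms, runs the full pipeline (standardization, label
transfer, feature extraction over the (W, G) grid, ANOVA screening,
per-image FCM), optimizes the weighted-majority fusion for one MRI
subset, and prints training and leave-one-out errors.

Uses a reduced phantom size so the script runs in about a minute; the
default study-scale suite is what scripts/acceptance.py evaluates.
"""

import numpy as np

import necromap as nm
from necromap import train_eval as te
from necromap.param_maps import derive_parametric_maps
from necromap.phantom import PhantomConfig, generate_phantom

fractions = (25.0, 45.0, 65.0, 85.0, 93.0, 97.0)
cases, truths = [], {}
for i, f in enumerate(fractions):
    cfg = PhantomConfig(shape=(48, 48, 8), spacing=(3.0, 3.0, 5.0),
                        tumor_center=(24.0, 24.0, 4.0),
                        tumor_axes=(14.0, 11.0, 3.0),
                        necrosis_blob_scale=5.0,
                        necrosis_fraction=f, seed=100 + i)
    case, truth = generate_phantom(cfg)
    derive_parametric_maps(case)
    cases.append(case)
    truths[case.case_id] = truth

subset = nm.SUBSETS["CONV+DW+DCE-q"]
case_data, case_fuzzy, sig = te.prepare_cohort(cases, subset.members,
                                               seed=0)
model = te.train_model(case_data, case_fuzzy, sig.selected, subset,
                       objective="min_avg", t=0.1)
print(f"chosen (W, G)        : {model.wg}")
print(f"fusion weights       : "
      + " ".join(f"{m}={w:.1f}" for m, w in
                 zip(model.members, model.weights.weights) if w > 0))
print(f"training f_avg       : {model.training_objective:.2f} pp\n")

loo = te.loo_predictions(case_data, case_fuzzy, sig.selected, subset,
                         objective="min_avg", t=0.1)
print(f"{'true %':>7s} {'LOO est %':>10s} {'error pp':>9s}  responder")
for cid in case_data:
    tr = truths[cid].aoi_fraction
    n = loo[cid]["n_aoi"]
    call = te.classify_responder(n)
    print(f"{tr:7.1f} {n:10.1f} {abs(n - tr):9.2f}  {call}")
# training f_avg is the optimized in-sample mean absolute error; the
# leave-one-out column is the honest estimate for unseen subjects.
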