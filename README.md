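# necromap

Estimating histologic tumor necrosis in osteosarcoma from multi-modal MRI.

After neoadjuvant chemotherapy, response in osteosarcoma is graded by the
fraction of the resected tumor that is necrotic: patients with ≥ 90%
necrosis are *good responders*, below 90% *poor responders*. The grading
is destructive, late, and based on a single histologic section. `necromap`
implements a classification model that estimates the necrosis fraction
before surgery, directly from MR images:

1. **Inputs per subject** — three conventional sequences (post-contrast
   T1 "PC", T1, STIR), a multi-b diffusion series, and a dynamic
   contrast-enhanced (DCE) series, plus the tumor volume of interest
   (VOI), the MRI plane matching the primary histologic section (POI),
   and — for training — a co-registered histologic viability map.
2. **Derived maps** — the apparent diffusion coefficient
   (`S(b) = S₀ e^(−b·ADC)`), DCE subtraction frames at 0/50/100 s after
   contrast arrival, the steepest slope
   `(SIₑ − SIₚ)·100 / (SI_base·T)` and the 100-s area under the
   time–intensity curve, and the Tofts pharmacokinetic parameters
   `Kᵗʳᵃⁿˢ` and `vₑ` from
   `C_t(t) = Kᵗʳᵃⁿˢ ∫₀ᵗ C_p(τ) e^{−(Kᵗʳᵃⁿˢ/vₑ)(t−τ)} dτ` —
   eleven co-aligned images in total.
3. **Features** — for every tumor pixel, a W×W window yields the original
   value, four sample moments, and 19 Haralick statistics from a
   direction-invariant gray-level co-occurrence matrix at G gray levels,
   over the grid W ∈ {3, 9, 15}, G ∈ {50, 100, 200}. One-way ANOVA
   against histology-transferred labels keeps the significant features.
4. **Classification** — each image is segmented by two-cluster fuzzy
   c-means (c = 2, m = 2, ε = 10⁻⁵) on its selected features; the
   per-image necrosis memberships u_i are fused by a weighted majority
   rule (`Σ w_k u_i^k > 1/2`, `Σ w_k = 1`), with the weights found by
   brute force over the discrete simplex minimizing the mean (*min-avg*)
   or maximum (*min-max*) absolute error against histology necrosis
   across the cohort. The (W, G) pair with the lowest optimized
   objective wins.
5. **Outputs** — percent necrosis on the plane of interest (N_AOI) or
   over the whole tumor (N_VOI), a binary viability map, Dice /
   Szymkiewicz–Simpson overlap against histology, and the responder call.

Because patient data of this kind is not publicly available, the package
ships a first-class phantom module that generates synthetic paired
MR/histology cases with known necrosis fraction, so the entire pipeline
is testable end to end (see `docs/methods.md` for what the phantom does
and does not emulate).

## Worked example

```python
import necromap as nm
from necromap.param_maps import derive_parametric_maps
from necromap.phantom import make_default_suite
from necromap import train_eval as te

# ten synthetic subjects with 20..99% true necrosis
suite = make_default_suite(seed=1)
cases = [c for c, _ in suite]
for c in cases:
    derive_parametric_maps(c)          # ADC + 7 DCE-derived maps

subset = nm.SUBSETS["CONV+DW+DCE-q"]   # 8 of the 11 images
case_data, case_fuzzy, sig = te.prepare_cohort(cases, subset.members,
                                               seed=1)
model = te.train_model(case_data, case_fuzzy, sig.selected, subset,
                       objective="min_avg", t=0.1)
print(model.wg, round(model.training_objective, 2))
# (9, 200) 2.96
```

The printed pair is the window size / gray-level count that minimized the
optimized objective, and `2.96` is the cohort mean absolute error (in
percentage points of necrosis) between the MRI estimate and histology at
the optimal fusion weights (the cohort's leave-one-out mean error is
larger, around 4-5 points — see `docs/methods.md` on why in-sample
optimization is optimistic). Leave-one-out estimates for unseen cases come
from `te.loo_predictions(...)`, whole-tumor estimates from
`te.estimate_voi_necrosis(model, case)`, and a per-case report (absolute
errors, Dice/overlap, responder calls) from `te.evaluate_cases(...)`.

Short narrative scripts for each capability live under `examples/`;
`necromap --help` exposes the same workflows as a command-line tool
(phantom generation, training, evaluation on case-bundle directories).

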