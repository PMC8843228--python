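"""Derive the advanced-MRI parametric maps and inspect class contrast.

ADC is fitted from the multi-b DWI stack; the DCE series yields
subtraction snapshots, the steepest slope, the 100-s AUC, and the Tofts
parameters Ktrans and ve. Necrosis should show higher ADC and weaker
enhancement than viable tumor — the contrast the classifier relies on.
"""

import numpy as np

from necromap.core_io import NECROTIC, VIABLE
from necromap.param_maps import derive_parametric_maps
from necromap.phantom import PhantomConfig, generate_phantom

case, truth = generate_phantom(PhantomConfig(necrosis_fraction=60.0,
                                             seed=7))
derive_parametric_maps(case)

poi = case.poi_index
labels = truth.labels[:, :, poi]
print(f"{'map':12s} {'necrotic':>12s} {'viable':>12s}")
for name, grid in case.images.items():
    plane = grid.values[:, :, poi]
    nec = plane[labels == NECROTIC].mean()
    via = plane[labels == VIABLE].mean()
    print(f"{name:12s} {nec:12.4g} {via:12.4g}")
# Each row shows the class-conditional mean on the plane of interest:
# ADC higher in necrosis; slope/AUC/Ktrans/subtractions higher in
# viable tumor (early, rapid enhancement of perfused tissue).
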