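"""Generate the study inputs: fractal fixtures, vascular phantoms, a cohort.

Writes phantom intensity images and ground-truth masks as PNG, the synthetic
663-person roster as CSV, and a small summary of what was generated.  All
downstream analysis scripts read from results/simulated/.
"""

from pathlib import Path

import pandas as pd

from retfractal import io as rio
from retfractal.cohort_gen import CohortSpec, generate_cohort
from retfractal.fixtures import FIXTURE_KINDS, generate_fixture
from retfractal.phantom import PhantomParams, generate_phantom

OUT = Path("results/simulated")
SEED = 20150327
N_PHANTOMS = 20

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    specs = {
        "filled_square": dict(size=256, depth=1),
        "straight_line": dict(size=512, depth=1),
        "uniform_disk": dict(size=1024, depth=1),
        "sierpinski_gasket": dict(size=1024, depth=7),
        "koch_curve": dict(size=729, depth=5),
        "branching_tree": dict(size=512, depth=13),
    }
    rows = []
    for kind in FIXTURE_KINDS:
        f = generate_fixture(kind, **specs[kind], seed=SEED)
        rio.write_mask(OUT / f"fixture_{kind}.png", f.image)
        rows.append({"kind": kind, "true_dimension": f.true_dimension,
                     "object_pixels": int(f.image.sum())})
    pd.DataFrame(rows).to_csv(OUT / "fixtures.csv", index=False)

    for i in range(N_PHANTOMS):
        ph = generate_phantom(PhantomParams(noise_level=0.03), seed=SEED + i)
        rio.write_image(OUT / f"phantom_{i:02d}_intensity.png", ph.intensity_image)
        rio.write_mask(OUT / f"phantom_{i:02d}_truth.png", ph.truth_mask)

    cohort = generate_cohort(CohortSpec(n=663, seed=SEED))
    rio.write_cohort(OUT / "cohort.csv", cohort)

    print(f"fixtures: {len(rows)} kinds -> {OUT}/fixture_*.png")
    print(f"phantoms: {N_PHANTOMS} -> {OUT}/phantom_*.png")
    print(f"cohort:   {len(cohort)} participants -> {OUT}/cohort.csv")


if __name__ == "__main__":
    main()
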