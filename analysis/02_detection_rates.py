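#!/usr/bin/env python
"""Detection-rate comparison across the four threshold rules.

Two inputs are pushed through the same detection-rate operation:

1. the published per-site lesion tallies of the 221-patient cohort
   (576 lesions; per-method failures 198/114/164/55), reproducing the
   reported rates 65.6 / 80.2 / 71.5 / 90.4%;
2. a simulated multi-lesion phantom mixing hot and faint lesions,
   showing the same qualitative result emerge from the segmentation
   code itself: the background-relative rule segments every lesion,
   while the absolute rule cannot see peaks below 2.5 and the 20%/40%
   rules leak into background on low-contrast lesions.

Writes results/detection_rates_published.csv and
results/detection_rates_phantom.csv with the per-method rates and the
chi-square / Fisher comparisons.
"""

from pathlib import Path

import pandas as pd

from petquant.cohort_stats import detection_rate_table
from petquant.phantom import LesionSpec, PhantomSpec, generate_phantom
from petquant.pipeline import segment_all
from petquant.reference import reference_lesion_statuses

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20260925


def phantom_statuses() -> pd.DataFrame:
    # lesions spanning contrast regimes: hot (detectable by all), faint
    # (peak < 2.5, invisible to the absolute rule), and very low
    # contrast (relative thresholds fall below the background, so the
    # grown region leaks)
    specs = [
        (10.0, "nasopharynx"), (15.0, "lymph_node"), (8.0, "bone"),
        (2.2, "lung"), (2.0, "liver"), (1.6, "skull_base"),
    ]
    lesions = []
    for i, (peak, site) in enumerate(specs):
        x = 20 + 40 * (i % 3)
        y = 20 + 40 * (i // 3)
        lesions.append(LesionSpec(center=(float(x), float(y), 30.0),
                                  radius=6.0, peak_suv=peak, site=site))
    spec = PhantomSpec(shape=(120, 100, 60), spacing=(1.5, 1.5, 1.5),
                       background_suv=1.0, noise_sd=0.08, blur_fwhm=6.0,
                       lesions=tuple(lesions), rng_seed=SEED)
    image, annotations, _ = generate_phantom(spec)
    per_lesion = segment_all(image, annotations, rng_seed=SEED)
    return per_lesion[["lesion_id", "site", "method", "detected"]]


def report(name: str, statuses: pd.DataFrame) -> None:
    table = detection_rate_table(statuses)
    out = table.per_method.copy()
    out["detection_rate_pct"] = (100 * out["detection_rate"]).round(2)
    out.to_csv(RESULTS / f"detection_rates_{name}.csv", index=False)
    table.pairwise.to_csv(RESULTS / f"detection_pairwise_{name}.csv", index=False)
    print(f"[{name}] global chi2 = {table.global_chi2:.1f}, "
          f"p = {table.global_p:.2g}")
    for row in out.itertuples():
        print(f"  {row.method:6s} {row.n_detected}/{row.n_lesions} "
              f"= {row.detection_rate_pct:.2f}%")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    report("published", reference_lesion_statuses())
    report("phantom", phantom_statuses())


if __name__ == "__main__":
    main()
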