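"""Compare model-derived and expert vulnerability ranks.

SensWeight (mean of fall and spring) is percentile-ranked into four
sensitivity bins; season-averaged percent change is thresholded at +/-25%
into directional bins; both are matched against the expert overall ranks.
When at least 20 species with sufficiently certain votes are available, a
random forest probes which sensitivity attributes drive match/mismatch.
Writes comparison.csv and the confusion matrices.
"""

import pandas as pd

from _shared import run_config
from sdmfuse.pipeline import stage_compare


def main():
    cfg = run_config(__doc__)
    stage_compare(cfg)
    comp = pd.read_csv(f"{cfg.outdir}/comparison.csv")
    n = len(comp)
    print(f"sensitivity ranks match for {int(comp['match_sensitivity'].sum())}/{n} "
          f"species; directional effects match for "
          f"{int(comp['match_direction'].sum())}/{n}")
    conf = pd.read_csv(f"{cfg.outdir}/confusion_direction.csv", index_col=0)
    print("directional confusion (SDM rows x expert columns):")
    print(conf)


if __name__ == "__main__":
    main()
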