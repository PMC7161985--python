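"""Validate fits on held-out survey years: AUC and Taylor statistics.

Species need AUC >= 0.7 in both seasons to stay in the analysis.
Writes validation.csv and a normalized Taylor diagram per season under
figures/.
"""

from pathlib import Path

import pandas as pd

from _shared import run_config
from sdmfuse.pipeline import stage_validate
from sdmfuse.validation import TaylorStats, taylor_diagram


def main():
    cfg = run_config(__doc__)
    stage_validate(cfg)
    val = pd.read_csv(f"{cfg.outdir}/validation.csv")
    figdir = Path(cfg.outdir, "figures")
    figdir.mkdir(exist_ok=True)
    for season, grp in val.groupby("season"):
        stats = {
            row.species: TaylorStats(row.r, row.crmse, row.crmse_norm,
                                     1.0, row.sd_ratio, row.sd_ratio)
            for row in grp.itertuples()
        }
        taylor_diagram(stats, figdir / f"taylor_{season}.png")
    included = val.loc[val["included"], "species"].nunique()
    print(f"{included}/{val['species'].nunique()} species pass the AUC >= "
          f"{cfg.auc_threshold} filter in both seasons")
    print(f"mean AUC {val['auc'].mean():.3f}; mean correlation "
          f"{val['r'].mean():.3f}; mean SD ratio {val['sd_ratio'].mean():.3f} "
          "(predictions smoother than observations)")


if __name__ == "__main__":
    main()
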