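"""Synthesize the study system: environment, trawl surveys, expert votes.

Writes survey.csv (tow-level catches for the 8-species panel),
votes.csv / neva_ranks.csv (expert elicitation analogue), and the depth
and monthly-SST NetCDF fields under the run directory.
"""

import pandas as pd

from _shared import run_config
from sdmfuse.pipeline import stage_generate


def main():
    cfg = run_config(__doc__)
    stage_generate(cfg)
    survey = pd.read_csv(f"{cfg.outdir}/survey.csv")
    print(f"surveys: {survey['tow_id'].nunique()} tows over "
          f"{survey['year'].nunique()} years x {survey['season'].nunique()} seasons")
    print(f"species: {survey['species'].nunique()}; "
          f"overall presence frequency {survey['presence'].mean():.2f}")


if __name__ == "__main__":
    main()
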