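"""Delta-downscale the 27-member SST ensemble to the observed grid.

Each member's future-year anomalies (relative to its own 1982-2011
climatology, coastal gaps filled) are regridded and added to the observed
climatology; the ensemble is summarised as the mean, second-coldest (p5)
and second-warmest (p95) member fields, then averaged into spring (MAM)
and fall (SON) seasonal projections. Writes sst_scenarios.nc.
"""

from _shared import run_config
from sdmfuse.climate import load_field
from sdmfuse.pipeline import stage_downscale


def main():
    cfg = run_config(__doc__)
    stage_downscale(cfg)
    ds = load_field(f"{cfg.outdir}/sst_scenarios.nc", None)
    for season in cfg.synthetic.seasons:
        base = float(ds[f"baseline_{season}"].mean())
        mean = float(ds[f"mean_{season}"].mean())
        p5 = float(ds[f"p5_{season}"].mean())
        p95 = float(ds[f"p95_{season}"].mean())
        print(f"{season}: baseline {base:.2f} degC -> future "
              f"{mean:.2f} (p5 {p5:.2f}, p95 {p95:.2f}) degC")


if __name__ == "__main__":
    main()
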