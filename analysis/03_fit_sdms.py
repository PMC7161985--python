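"""Fit the two-stage delta GAMs per species and season.

Stage 1: binomial-logit GAM of presence/absence on s(SST) + s(depth);
stage 2: Gaussian GAM of log positive biomass on the same smooths over
positive tows only. Penalized cubic splines (k = 10) with shrinkage;
smoothing parameters by REML; training years up to the split year.
Serialized fits land in fits/.
"""

from pathlib import Path

from _shared import run_config
from sdmfuse.delta import DeltaGAMFit
from sdmfuse.pipeline import stage_fit


def main():
    cfg = run_config(__doc__)
    stage_fit(cfg)
    for path in sorted(Path(cfg.outdir, "fits").glob("*.json")):
        fit = DeltaGAMFit.load(path)
        edf1, edf2 = fit.stage1.edf, fit.stage2.edf
        print(f"{fit.species}/{fit.season}: {fit.n_tows} tows, "
              f"{fit.n_presences} presences; stage-1 edf "
              f"(sst {edf1['sst']:.1f}, depth {edf1['depth']:.1f}); stage-2 edf "
              f"(sst {edf2['sst']:.1f}, depth {edf2['depth']:.1f})")


if __name__ == "__main__":
    main()
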