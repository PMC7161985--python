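"""Fuse the fitted SDMs with the expert votes via Bayes' theorem.

Per species: 1000 candidate stage-2 coefficient vectors are drawn from
MVN(beta, V), scored by the multinomial likelihood of the sensitivity and
directional votes under the candidate's bin probabilities plus the MVN
log prior, and the MAP candidate becomes the "combined" model, evaluated
against the SDM on held-out tows. Writes candidate_scores.csv,
fused_comparison.csv, fused_by_certainty.csv, a smooth-overlay figure for
one example species, and the run digest.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from _shared import run_config
from sdmfuse.delta import DeltaGAMFit, smooth_curve
from sdmfuse.pipeline import stage_fuse, summarize_run


def overlay_figure(cfg, outdir: Path) -> None:
    """Stage-2 SST smooths: fitted model, candidate spread, MAP candidate."""
    import json

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from sdmfuse.fusion import sample_candidates

    fused = pd.read_csv(outdir / "fused_comparison.csv")
    row = fused.iloc[0]
    fit = DeltaGAMFit.load(outdir / "fits" / f"{row.species}_{row.season}.json")
    map_info = json.loads(
        (outdir / "map_models" / f"{row.species}_{row.season}.json").read_text())
    term = fit.stage2.smooths[0]
    grid = np.linspace(term.x_min, term.x_max, 80)
    fig, ax = plt.subplots(figsize=(6, 4))
    draws = sample_candidates(fit, 100, np.random.default_rng(0))
    for theta in draws:
        ax.plot(grid, smooth_curve(fit, "sst", grid, beta=theta),
                color="0.8", lw=0.5, zorder=1)
    ax.plot(grid, smooth_curve(fit, "sst", grid), "k-", lw=2, label="SDM fit")
    ax.plot(grid, smooth_curve(fit, "sst", grid, beta=np.array(map_info["theta"])),
            "r--", lw=2, label=f"MAP candidate #{map_info['candidate']}")
    ax.set_xlabel("seasonal SST (degC)")
    ax.set_ylabel("stage-2 log biomass (depth at mean)")
    ax.set_title(f"{row.species} / {row.season}")
    ax.legend()
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    fig.savefig(figdir / "smooth_overlay.png", dpi=120, bbox_inches="tight")
    plt.close(fig)


def main():
    cfg = run_config(__doc__)
    stage_fuse(cfg)
    outdir = Path(cfg.outdir)
    overlay_figure(cfg, outdir)
    digest = summarize_run(cfg)
    (outdir / "digest.txt").write_text(digest)
    print(digest)


if __name__ == "__main__":
    main()
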