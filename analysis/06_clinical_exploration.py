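"""Exploratory clinical-arm analyses.

In the 80-subject clinical-like sample: plain-regression association of
stress with depressive severity, its moderation by the connectome score,
the stress-depression association within balanced low/medium/high score
subgroups, and the covariate-adjusted (ANCOVA) comparison of scores
between the clinical and community cohorts.
"""

import runpy
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
common = runpy.run_path(Path(__file__).parent / "00_common.py")

import pandas as pd

from pcskit.pipeline import run_pipeline


def main() -> None:
    args = common["study_args"](__doc__)
    cfg = common["study_config"](args.seed)
    run_pipeline(cfg, stages=("exploratory",), out_dir=args.out_dir)

    out = Path(args.out_dir)
    df = pd.read_csv(out / "exploratory_models.tsv", sep="\t")
    for _, r in df.iterrows():
        what = f"{r['outcome']} ~ {r['predictor']}"
        if isinstance(r["moderator"], str) and r["moderator"]:
            what += f" x {r['moderator']}"
        print(f"  [{r['block']}] {what}: beta = {r['beta']:+.3f}, p = {r['p']:.3g}")

    anc = pd.read_csv(out / "ancova.tsv", sep="\t").iloc[0]
    print(f"  ANCOVA cohort effect on score: F = {anc['f_stat']:.2f}, "
          f"p = {anc['p']:.3g} (n = {int(anc['n_obs'])})")


if __name__ == "__main__":
    main()
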