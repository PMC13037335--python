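"""Longitudinal change-score models and the moderation headline.

Computes follow-up-minus-baseline change scores, fits the clustered
models of stress change against symptom and cognition change, tests
whether the baseline connectome score moderates those couplings, and
checks whether the baseline score predicts follow-up symptoms.
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
    run_pipeline(cfg, stages=("longitudinal",), out_dir=args.out_dir)

    out = Path(args.out_dir)
    ch = pd.read_csv(out / "change_scores.csv")
    df = pd.read_csv(out / "longitudinal_models.tsv", sep="\t")
    print(f"{len(ch)} subjects with both waves; fitted {len(df)} models")

    mod = df[(df["block"] == "change_moderation") & df["moderator"].notna()]
    emo = mod[mod["outcome"].isin(["delta_anxiety", "delta_depression"])]
    for _, r in emo.iterrows():
        flag = "significant" if r["significant"] else "n.s. after correction"
        print(f"  moderation {r['outcome']} ~ delta_stress x score: "
              f"beta = {r['beta']:.3f}, dR2 = {r['delta_r2']:.4f}, "
              f"p = {r['p']:.2g} ({flag}); "
              f"simple slopes {r['slope_low']:.3f} -> {r['slope_high']:.3f}")


if __name__ == "__main__":
    main()
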