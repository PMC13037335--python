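"""Baseline (cross-sectional) association and moderation models.

Fits the family-clustered mixed models at the first wave: perceived
stress against emotional symptoms and cognition, the connectome score
against the same outcomes, and the stress x score moderation — with
Bonferroni correction within each outcome family.
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
    run_pipeline(cfg, stages=("baseline",), out_dir=args.out_dir)

    df = pd.read_csv(Path(args.out_dir) / "baseline_models.tsv", sep="\t")
    print(f"fitted {len(df)} baseline models "
          f"({int(df['significant'].sum())} significant after correction)")
    for _, r in df[df["significant"]].iterrows():
        print(f"  [{r['block']}] {r['outcome']} ~ {r['predictor']}: "
              f"beta = {r['beta']:.3f} (95% CI {r['ci_low']:.3f}, {r['ci_high']:.3f}), "
              f"p = {r['p']:.2g}")


if __name__ == "__main__":
    main()
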