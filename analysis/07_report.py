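"""Assemble the run summary and manifest for the whole study directory."""

import runpy
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
common = runpy.run_path(Path(__file__).parent / "00_common.py")

from pcskit.pipeline import run_pipeline


def main() -> None:
    args = common["study_args"](__doc__)
    cfg = common["study_config"](args.seed)
    run_pipeline(cfg, stages=("report",), out_dir=args.out_dir)
    print((Path(args.out_dir) / "summary.md").read_text())


if __name__ == "__main__":
    main()
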