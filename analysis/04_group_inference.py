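"""Per-coefficient group inference on the diarized conversation features.

Reads the feature table written by 03_conversation_task.py, runs the
unpaired t-test per cepstral coefficient (Student and Holm-corrected
variants side by side), writes results/ttest_panel_full.csv and a
cumulative-distribution figure with star annotations.

Run:  python analysis/04_group_inference.py
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from pdvoice import features, stats  # noqa: E402


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--features", type=Path,
                        default=Path("results/conversation/features.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    if not args.features.exists():
        sys.exit(f"{args.features} not found - run 03_conversation_task.py first")

    feats = features.read_feature_csv(args.features)
    hc = feats[feats["label"] == "HC"]
    pd_ = feats[feats["label"] == "PD"]
    panel = stats.coefficient_panel(hc, pd_, variant="student", correction="none")
    holm = stats.coefficient_panel(hc, pd_, variant="student", correction="holm")
    panel["p_holm"] = holm["p_corrected"]
    panel["stars_holm"] = holm["stars"]
    out_csv = args.out / "ttest_panel_full.csv"
    panel.to_csv(out_csv, index=False, float_format="%.6g")
    stats.plot_panel(hc, pd_, panel, args.out / "ttest_panel.png")

    shown = panel[["coefficient", "t", "p", "stars", "p_holm", "stars_holm"]]
    print(shown.round(4).to_string(index=False))
    print(f"\nuncorrected: {(panel['p'] < 0.05).sum()} / 26 at p < 0.05; "
          f"Holm: {(panel['p_holm'] < 0.05).sum()} / 26")
    print(f"wrote {out_csv} and {args.out / 'ttest_panel.png'}")


if __name__ == "__main__":
    main()
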