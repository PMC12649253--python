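"""Score the CES-D panel and classify each subject's five-state sequence.

Reads panel.csv (item-level or total-score dialect), applies the scoring
rules (reverse-scored items, person-mean imputation for up to two missing
items, the >= 12 episode cutoff) and the episode / persistence / remission /
relapse classification.  Writes states.csv and events.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from depmsm.cesd import classify_panel, events_to_frame, sequences_to_frame, tabulate_events


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/states"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    panel = pd.read_csv(args.in_dir / "panel.csv")
    sequences = classify_panel(panel)
    sequences_to_frame(sequences).to_csv(args.out_dir / "states.csv", index=False)
    events_to_frame(sequences).to_csv(args.out_dir / "events.csv", index=False)

    counts = tabulate_events(sequences)
    n_waves = panel.groupby("subject_id").size().iloc[0]
    print(f"classified {len(sequences)} subjects over {n_waves} waves")
    print("event counts per transition path:")
    labels = {
        "12": "no symptom -> new episode", "23": "episode -> persistence",
        "24": "episode -> remission", "34": "persistence -> remission",
        "45": "remission -> relapse",
    }
    for path, n in counts.items():
        print(f"  {path} ({labels[path]}): {n}")


if __name__ == "__main__":
    main()
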