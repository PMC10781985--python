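"""Rule-based chromatin-state annotation and mark/dip intersection.

Classifies every assessment anchor (ATAC or H3K27me3 peak) from the mark
combinations it overlaps (active promoter / predicted enhancer /
repressed / unclassified), compares against the planted states, filters
ATAC peaks to those over TI methylation dips, and tallies the upset-style
intersection of ATAC peaks with the four histone marks and dips. Writes
states.tsv and upset_counts.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from epichrom import io as eio
from epichrom.chromatin import filter_peaks_by_dips, upset_counts
from epichrom.config import PipelineConfig
from epichrom.pipeline import call_all_dips, chromatin_states
from epichrom.simulate import simulate_all


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed)
    ds = simulate_all(cfg.simulation)
    dips = call_all_dips(ds, cfg)
    calls = chromatin_states(ds, dips, cfg)
    args.out.mkdir(parents=True, exist_ok=True)

    df = pd.DataFrame(
        {
            "chrom": [c.peak.chrom for c in calls],
            "start": [c.peak.start for c in calls],
            "end": [c.peak.end for c in calls],
            "marks": ["+".join(sorted(c.marks_present)) for c in calls],
            "state": [c.state for c in calls],
            "has_dip": [c.has_dip for c in calls],
        }
    )
    eio.write_table(df, args.out / "states.tsv")
    print("state counts:")
    print(df["state"].value_counts())
    ok = sum(
        c.state == ds.truth.region_states.get(c.peak)
        for c in calls
        if c.peak in ds.truth.region_states
    )
    n = sum(c.peak in ds.truth.region_states for c in calls)
    print(f"planted-state agreement: {ok}/{n}")

    atac = ds.mark_peaks["ATAC"]
    in_dips = filter_peaks_by_dips(atac, dips)
    print(f"{len(in_dips)}/{len(atac)} ATAC peaks overlap a TI methylation dip")
    counts = upset_counts(atac, {
        **{m: ds.mark_peaks[m].peaks for m in ("H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3")},
        "DNAm_dip": dips,
    })
    rows = [
        {"combination": "+".join(sorted(k)) or "(none)", "count": v}
        for k, v in sorted(counts.items(), key=lambda kv: -kv[1])
    ]
    eio.write_table(pd.DataFrame(rows).set_index("combination"), args.out / "upset_counts.tsv")
    print("top intersections:", rows[:3])


if __name__ == "__main__":
    main()
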