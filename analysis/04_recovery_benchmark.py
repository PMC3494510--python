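#!/usr/bin/env python
"""Transfer-recovery benchmark across replicate seeds, plus null runs.

For seeds 1-5 simulates the standard dataset (10 implanted transfers among
50 families), runs the full pipeline, and scores algal_phylogenetic calls
against the truth table; two additional runs with transfer_fraction = 0
estimate the spurious call count on purely vertical proteomes.  Writes
results/benchmark.tsv.  Takes a few minutes.
"""

import tempfile
from pathlib import Path

import pandas as pd

from xenoscreen.hgt_calls import PipelineConfig, run_pipeline
from xenoscreen.synthetic_data import SimulationConfig, emit_dataset, read_truth_table

ROOT = Path(__file__).resolve().parent.parent


def one_run(seed, transfer_fraction, workdir):
    cfg = SimulationConfig(transfer_fraction=transfer_fraction, seed=seed)
    paths = emit_dataset(cfg, workdir / f"d{seed}_{transfer_fraction}")
    result = run_pipeline(
        paths["query"], paths["subjects"], paths["taxonomy"],
        workdir / f"o{seed}_{transfer_fraction}", PipelineConfig(seed=seed),
    )
    truth = {t.family_id: t for t in read_truth_table(paths["truth"])}
    tp = fn = fp = tn = 0
    for call in result.calls:
        transferred = truth[call.query_id.split("_")[1]].transferred
        algal = call.category == "algal_phylogenetic"
        tp += transferred and algal
        fn += transferred and not algal
        fp += (not transferred) and algal
        tn += (not transferred) and not algal
    return {"seed": seed, "transfer_fraction": transfer_fraction,
            "tp": tp, "fn": fn, "fp": fp, "tn": tn}


def main():
    rows = []
    with tempfile.TemporaryDirectory() as tmp:
        workdir = Path(tmp)
        for seed in (1, 2, 3, 4, 5):
            rows.append(one_run(seed, 0.2, workdir))
            print(f"seed {seed}: tp={rows[-1]['tp']} fn={rows[-1]['fn']} "
                  f"fp={rows[-1]['fp']}")
        for seed in (1, 2):
            rows.append(one_run(seed, 0.0, workdir))
            print(f"null seed {seed}: spurious algal calls = {rows[-1]['fp']}")
    df = pd.DataFrame(rows)
    out = ROOT / "results" / "benchmark.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, sep="\t", index=False)

    bench = df[df.transfer_fraction > 0]
    sens = bench.tp.sum() / (bench.tp.sum() + bench.fn.sum())
    fpr = bench.fp.sum() / (bench.fp.sum() + bench.tn.sum())
    print(f"\npooled sensitivity: {sens:.3f}")
    print(f"pooled false-positive rate: {fpr:.4f}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
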