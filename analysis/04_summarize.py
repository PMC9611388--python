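#!/usr/bin/env python
"""Summarize the pipeline run: connection peaks, ERD/ERS, ERP lateralization.

Reads the tables written by ``03_run_pipeline.py`` under ``results/run`` and
condenses them into ``results/summary.json``: per-band peak-connection times
and counts, the mu-rhythm ERD minimum and ERS maximum per condition with the
between-condition permutation test at the ERS window, and the PO7−PO8
window-mean lateralization per condition with its ANOVA.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    rundir = args.outdir / "run"
    if not (rundir / "manifest.json").exists():
        raise SystemExit(f"no pipeline run found under {rundir}; "
                         "run analysis/03_run_pipeline.py first")

    manifest = json.loads((rundir / "manifest.json").read_text())
    summary: dict = {"config_hash": manifest["config_hash"],
                     "seed": manifest["seed"]}

    conn = pd.read_csv(rundir / "connection_summary.tsv", sep="\t")
    summary["connections"] = {
        r.band: {"peak_time_ms": round(r.peak_time * 1000),
                 "peak_count": int(r.peak_count),
                 "total_significant_cells": int(r.total_significant)}
        for r in conn.itertuples()}
    for band, s in summary["connections"].items():
        print(f"[summary] {band}: {s['peak_count']} connections peak "
              f"at {s['peak_time_ms']} ms")

    mu = pd.read_csv(rundir / "ersp_mu_timecourse.tsv", sep="\t")
    summary["mu_rhythm"] = {}
    for cond, grp in mu.groupby("condition"):
        post = grp[grp.time >= 0]
        erd = post.loc[post.ersp_mean.idxmin()]
        ers = post.loc[post.ersp_mean.idxmax()]
        summary["mu_rhythm"][cond] = {
            "erd_db": round(float(erd.ersp_mean), 3),
            "erd_time_ms": round(float(erd.time) * 1000),
            "ers_db": round(float(ers.ersp_mean), 3),
            "ers_time_ms": round(float(ers.time) * 1000)}
        print(f"[summary] mu condition {cond}: ERD {erd.ersp_mean:+.2f} dB at "
              f"{erd.time * 1000:.0f} ms, ERS {ers.ersp_mean:+.2f} dB at "
              f"{ers.time * 1000:.0f} ms")
    summary["ers_permutation_test"] = manifest["ers_test"]
    print(f"[summary] ERS window permutation p = {manifest['ers_test']['p']:.4f}")

    erp = pd.read_csv(rundir / "erp_lateralization.tsv", sep="\t")
    summary["erp_lateralization"] = {
        str(row["condition"]): {"window_mean_uv": round(float(row["mean"]), 3),
                                "sem_uv": round(float(row["sem"]), 3)}
        for _, row in erp.iterrows()}
    summary["erp_anova"] = manifest["erp_anova"]
    if manifest["erp_anova"]:
        print(f"[summary] PO7-PO8 ANOVA: F = {manifest['erp_anova']['F']:.2f}, "
              f"p = {manifest['erp_anova']['p']:.4f}")

    out = args.outdir / "summary.json"
    out.write_text(json.dumps(summary, indent=2))
    print(f"[summary] -> {out}")


if __name__ == "__main__":
    main()
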