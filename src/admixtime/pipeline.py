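"""End-to-end demo pipeline: simulate -> degrade -> date -> IBD -> bounds.

Each stage writes its artifacts under the configured output directory and
contributes headline statistics to a final JSON report.  Any stage's
synthetic inputs can be replaced by real-data files read through
:mod:`admixtime.io`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io as aio
from .dating import ProportionDataset, PulseDatingMLE, mean_tract_time
from .ibd import IBDAncestryDeconvolution
from .maps import DEFAULT_AUTOSOME_CM, GeneticMap
from .models import PulseModel
from .sim import degrade_ancestry_calls, simulate_pulse_tracks, synth_ibd_cohort
from .tracks import mean_run_length
from .twowave import BoundSpec, early_time_bounds


def run_pipeline(config: aio.RunConfig) -> dict:
    """Run the declared stage sequence and return (and write) the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    stage = "simulate"
    try:
        n_chrom = int(config.simulate.get("chromosomes", 4))
        chroms = list(DEFAULT_AUTOSOME_CM)[:n_chrom]
        gmap = GeneticMap.uniform(
            {c: DEFAULT_AUTOSOME_CM[c] for c in chroms}, snps_per_cm=2.0)
        model = PulseModel(proportions=dict(config.simulate["proportions"]),
                           t=float(config.simulate["t"]))
        tracks = simulate_pulse_tracks(gmap, model,
                                       int(config.simulate["n_haploid"]),
                                       config.derived_seed("simulate"))
        aio.write_tracks(tracks, out / "tracks.tsv")
        labels = model.labels
        report["simulate"] = {
            "n_haploid": len(tracks), "t_true": model.t,
            "mean_minor_run_cm": mean_run_length(tracks, labels[1]),
        }

        stage = "degrade"
        calls, stats = degrade_ancestry_calls(
            tracks, gmap, float(config.degrade["target_accuracy"]),
            config.derived_seed("degrade"),
            float(config.degrade.get("error_block_mean_snps", 30)))
        aio.write_ancestry_calls(calls, out / "calls.tsv")
        report["degrade"] = stats

        stage = "date"
        data = ProportionDataset.from_call_table(calls, labels[0],
                                                 diploid=True)
        t_grid = np.arange(int(config.dating.get("t_min", 2)),
                           int(config.dating.get("t_max", 80)) + 1)
        mle = PulseDatingMLE(t_grid=t_grid,
                             fix_q=config.dating.get("fix_q", "mean")).fit(data)
        tract_t = mean_tract_time(
            report["simulate"]["mean_minor_run_cm"] / 100.0, model.q)
        report["date"] = {"q_hat": mle.q_, "t_hat_mle": mle.t_,
                          "t_hat_tracts": tract_t, "loglik": mle.loglik_}

        stage = "ibd"
        seg, truth = synth_ibd_cohort(
            int(config.ibd["n_segments"]), float(config.ibd["f_eu"]),
            float(config.ibd["p_eu"]), float(config.ibd["lambda"]),
            config.derived_seed("ibd"))
        fit = IBDAncestryDeconvolution(
            p_eu=float(config.ibd["p_eu"]),
            trim_cm=float(config.ibd.get("trim_cm", 0.25))).fit(seg)
        report["ibd"] = {"lambda_hat": fit.lambda_, "f_eu_hat": fit.f_eu_,
                         "mu_eu_hat": fit.mu_eu_, "truth": truth,
                         "p_eu": float(config.ibd["p_eu"])}

        stage = "bounds"
        b = config.bounds
        bounds = early_time_bounds(BoundSpec(
            T=tuple(b["T"]), q=tuple(b["q"]), mu=tuple(b["mu"]),
            t2=tuple(b["t2"])))
        report["bounds"] = {
            "t1_min": round(bounds.t1_min), "t1_max": round(bounds.t1_max),
            "argmin": bounds.argmin, "argmax": bounds.argmax}
    except Exception as exc:
        (out / "report.partial.json").write_text(
            json.dumps(report, indent=2, default=float))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                default=float))
    return report
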