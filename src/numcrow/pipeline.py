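"""End-to-end pipeline: simulate -> behavior -> selectivity -> pev ->
decode -> statespace -> report.

One master seed deterministically spawns a per-stage random stream, so a
stage can be re-run in isolation and two runs with the same configuration
and seed produce identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from numcrow import behavior, decoding, io as nio, pev, selectivity, statespace, stimgen
from numcrow.synthdata import Dataset, SimConfig, build_dataset

log = logging.getLogger("numcrow.pipeline")

STAGES = ("simulate", "behavior", "selectivity", "pev", "decode", "statespace", "report")

# Stage names map to fixed substream indices so that re-running a subset of
# stages reproduces the full-run results.
_STAGE_STREAM = {name: i for i, name in enumerate(STAGES)}


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    pev_shuffles: int = 1000
    decode_iterations: int = 100
    error_decode_outer: int = 100
    error_decode_inner: int = 32
    make_plots: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _stage_rng(config: PipelineConfig, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed)
    return np.random.default_rng(ss.spawn(len(STAGES))[_STAGE_STREAM[stage]])


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    stages: list[str] | None = None,
    dataset: Dataset | None = None,
) -> Path:
    """Run the requested stages, writing every artifact under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    requested = list(stages) if stages else list(STAGES)
    for s in requested:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")

    summary: dict = {"seed": config.seed, "stages": requested}

    if dataset is None:
        if "simulate" in requested or not (out / "bundle" / "manifest.json").exists():
            log.info("stage simulate: building dataset (seed=%d)", config.seed)
            dataset = build_dataset(config.sim, seed=config.seed)
            nio.write_bundle(dataset, out / "bundle")
        else:
            dataset = nio.read_bundle(out / "bundle")

    sel_table = None

    def selectivity_table() -> pd.DataFrame:
        nonlocal sel_table
        if sel_table is None:
            cached = out / "selectivity.csv"
            if "selectivity" not in requested and cached.exists():
                sel_table = pd.read_csv(cached)
            else:
                sel_table = selectivity.classify_all(dataset)
        return sel_table

    if "behavior" in requested:
        log.info("stage behavior")
        curves = behavior.performance_curves(dataset.trials)
        behavior.curves_to_frame(curves).to_csv(out / "behavior_curves.csv", index=False)
        behavior.percent_correct(dataset.trials).to_csv(
            out / "behavior_percent_correct.csv", index=False
        )
        behavior.distance_size_summary(curves).to_csv(
            out / "behavior_curve_fits.csv", index=False
        )
        overall = behavior.percent_correct(dataset.trials, grouping=["format"])
        summary["percent_correct_by_format"] = {
            str(r["format"]): float(r["percent_correct"]) for _, r in overall.iterrows()
        }

    if "selectivity" in requested:
        log.info("stage selectivity")
        table = selectivity_table()
        table.to_csv(out / "selectivity.csv", index=False)
        n_total = len(dataset.neurons)
        counts = {
            epoch.value: int(
                table[(table["epoch"] == epoch.value) & table["selective"]].shape[0]
            )
            for epoch in selectivity.Epoch
        }
        n_seq = counts[selectivity.Epoch.SAMPLE_SEQ.value]
        n_sim = counts[selectivity.Epoch.SAMPLE_SIM.value]
        piv = table.pivot(index="neuron_id", columns="epoch", values="selective")
        overlap = int(
            (
                piv[selectivity.Epoch.SAMPLE_SEQ.value].astype(bool)
                & piv[selectivity.Epoch.SAMPLE_SIM.value].astype(bool)
            ).sum()
        )
        p0 = selectivity.chance_overlap_percent(n_seq, n_sim, n_total) / 100.0
        summary["selectivity"] = {
            "n_neurons": n_total,
            "counts": counts,
            "sample_overlap": overlap,
            "chance_overlap_percent": 100.0 * p0,
            "overlap_binomial_p": (
                selectivity.overlap_binomial_test(overlap, n_total, p0) if 0 < p0 < 1 else None
            ),
        }

    if "pev" in requested:
        log.info("stage pev (%d shuffles)", config.pev_shuffles)
        ids = selectivity.delay_selective_ids(selectivity_table())
        if ids:
            series = pev.pev_analysis(
                dataset, ids, n_shuffle=config.pev_shuffles, rng=_stage_rng(config, "pev")
            )
            pev.series_to_frame(series).to_csv(out / "pev_series.csv", index=False)
            summary["pev"] = {
                "n_neurons": len(ids),
                "crossover_time_ms": pev.crossover_time_ms(series),
            }
            if config.make_plots:
                _plot_pev(series, out / "pev_timecourse.png")
        else:
            summary["pev"] = {"n_neurons": 0, "crossover_time_ms": None}

    if "decode" in requested:
        log.info("stage decode (%d iterations)", config.decode_iterations)
        ids = selectivity.delay_selective_ids(selectivity_table())
        ids = decoding.included_neurons(dataset, ids)
        if ids:
            rng = _stage_rng(config, "decode")
            table = decoding.delay_rate_table(dataset, ids)
            results = {}
            for fmt in ("seq", "sim"):
                r = decoding.decode_within_format(
                    dataset, ids, fmt, config.decode_iterations, rng, table
                )
                results[f"cv_{fmt}"] = r
                t = decoding.decode_cross_format(
                    dataset, ids, fmt, config.decode_iterations, rng, table
                )
                results[f"transfer_{fmt}_to_{t.test_format}"] = t
            cor, err = decoding.error_trial_decode(
                dataset,
                ids,
                config.error_decode_outer,
                config.error_decode_inner,
                rng,
                table,
            )
            for name, r in results.items():
                np.savetxt(out / f"confusion_{name}.csv", r.confusion, delimiter=",")
            summary["decoding"] = {
                "n_neurons": len(ids),
                **{name: r.accuracy for name, r in results.items()},
                "error_trials_correct_accuracy": float(cor.mean()),
                "error_trials_error_accuracy": float(err.mean()),
                "correct_vs_error_auc": decoding.auc_separation(cor, err),
            }
        else:
            summary["decoding"] = {"n_neurons": 0}

    if "statespace" in requested:
        log.info("stage statespace")
        ids = selectivity.delay_selective_ids(selectivity_table())
        if len(ids) >= 3:
            ts = statespace.condition_averaged_states(dataset, ids)
            proj, evr = statespace.pca_project(ts)
            fmt_d = statespace.format_distance(ts)
            num_d = statespace.numerosity_distance(ts)
            fmt_d.to_csv(out / "statespace_format_distance.csv")
            num_d.to_csv(out / "statespace_numerosity_distance.csv")
            summary["statespace"] = {
                "n_neurons": len(ts.neuron_ids),
                "pc_variance_explained": [float(v) for v in evr],
            }
            if config.make_plots:
                _plot_trajectories(ts, proj, out / "statespace_trajectories.png")
        else:
            summary["statespace"] = {"n_neurons": len(ids)}

    if "report" in requested:
        log.info("stage report")
        # Stimulus-constraint spot check on freshly generated standard timings.
        rng = _stage_rng(config, "report")
        sums, mins = [], []
        for n in stimgen.NUMEROSITIES:
            for _ in range(250):
                t = stimgen.gen_sequential_standard(n, rng)
                sums.append(t.total_ms)
                mins.append(float(t.interleaved().min()))
        summary["stimulus_check"] = {
            "n_timings": len(sums),
            "total_ms_min": min(sums),
            "total_ms_max": max(sums),
            "interval_min_ms": min(mins),
        }
        with open(out / "report.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

    return out


def _plot_pev(series, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, s in series.items():
        (line,) = ax.plot(s.time_centers_ms, 100 * s.mean_omega2, label=name)
        if s.null_q95 is not None:
            ax.plot(s.time_centers_ms, 100 * s.null_q95, "--", color=line.get_color(), lw=0.8)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("time from delay onset (ms)")
    ax.set_ylabel("explained variance $\\omega^2$ (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_trajectories(ts, proj, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    colors = {1: "C0", 2: "C1", 3: "C2", 4: "C3"}
    for (num, fmt), traj in zip(ts.conditions, proj):
        style = "-" if fmt == "seq" else ":"
        ax.plot(*traj.T, style, color=colors[num], label=f"n={num} {fmt}")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_zlabel("PC3")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
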