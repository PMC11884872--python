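"""End-to-end pipeline: simulate -> closed loop -> analysis -> stats report.

One master seed fans out deterministically to per-session seeds
(``SeedSequence(master, spawn_key=(group, mouse, day))``), each simulated
session is replayed through the closed-loop engine under a simulated clock
(feedback group with tones, control group without), and the resulting
session records feed the offline analysis. Outputs are tidy text artifacts:
per-session logs, a per-mouse per-day ratio CSV, cluster assignments, a
stats JSON, and the echoed effective config. Identical seeds produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import analysis
from .config import RunConfig, dump_config
from .engine import SessionRecord, run_stream
from .simulate import cohort_keys, session_seed, simulate_session

__all__ = ["PipelineReport", "pipeline_end_to_end", "analyze_sessions"]


@dataclass
class PipelineReport:
    out_dir: Path | None
    n_sessions: int
    groups: tuple[str, ...]
    n_days: int
    excluded_mice: list[str]
    cluster_k: int | None
    group_day_means: dict
    per_day: list
    anova: list
    summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n_sessions": self.n_sessions,
            "groups": list(self.groups),
            "n_days": self.n_days,
            "excluded_mice": self.excluded_mice,
            "cluster_k": self.cluster_k,
            "group_day_means": self.group_day_means,
            "per_day": self.per_day,
            "anova": self.anova,
        }
        d.update(self.summary)
        return d


def _analysis_outputs(
    records: Sequence[SessionRecord],
    cfg: RunConfig,
    out_dir: Path | None,
    trajectory_samples: int,
    k_range: Sequence[int],
    tsne: bool,
) -> PipelineReport:
    counts = analysis.count_table(records, cfg.trial)
    cohort = analysis.reach_ratio(counts)
    stats_res = analysis.group_stats(cohort) if _stats_possible(cohort.table) else None

    segments = []
    for rec in records:
        segments.extend(analysis.segments_from_record(rec, cfg.trial, paw="left"))
    traj = analysis.align_and_resample(segments, T=trajectory_samples)

    cluster = None
    features = None
    if traj.matrix.shape[0] >= max(k_range):
        n_comp = analysis.choose_n_components(traj.matrix, threshold=0.9)
        features = analysis.pca_embed(traj.matrix, n_comp).scores
        usable = [k for k in k_range if k <= traj.matrix.shape[0]]
        cluster = analysis.gmm_cluster(features, usable, seed=cfg.seed)

    embedding = None
    if tsne and features is not None:
        perplexity = min(30.0, (features.shape[0] - 1) / 3.0)
        if perplexity >= 5:
            embedding = analysis.tsne_embed(features, perplexity=perplexity, seed=cfg.seed)

    means = (
        cohort.table.groupby(["group", "day"])["normalized"].mean()
        if not cohort.table.empty
        else pd.Series(dtype=float)
    )
    group_day_means = {
        f"{g}_day{d}": float(v) for (g, d), v in means.items()
    }

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort.table.to_csv(out_dir / "ratios.csv", index=False)
        cluster_df = traj.meta.copy()
        if cluster is not None:
            cluster_df["cluster"] = cluster.labels
        if embedding is not None:
            cluster_df["tsne_1"] = embedding[:, 0]
            cluster_df["tsne_2"] = embedding[:, 1]
        cluster_df.to_csv(out_dir / "clusters.csv", index=False)
        if stats_res is not None:
            stats_res.to_json(out_dir / "stats.json")

    report = PipelineReport(
        out_dir=out_dir,
        n_sessions=len(records),
        groups=tuple(cfg.design.groups),
        n_days=cfg.design.n_days,
        excluded_mice=cohort.excluded,
        cluster_k=None if cluster is None else int(cluster.k),
        group_day_means=group_day_means,
        per_day=[] if stats_res is None else stats_res.per_day.to_dict(orient="records"),
        anova=[] if stats_res is None else json.loads(stats_res.anova.to_json(orient="records")),
    )
    if out_dir is not None:
        with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
    return report


def _stats_possible(table: pd.DataFrame) -> bool:
    if table.empty or table["group"].nunique() != 2:
        return False
    return all(
        table[table["group"] == g]["mouse"].nunique() >= 2 for g in table["group"].unique()
    )


def pipeline_end_to_end(
    seed: int | None = None,
    out_dir: str | Path | None = None,
    config: RunConfig | None = None,
    trajectory_samples: int = 100,
    k_range: Sequence[int] = tuple(range(1, 7)),
    save_sessions: bool = True,
    tsne: bool = False,
) -> PipelineReport:
    """Simulate a cohort, run every session closed-loop, analyze, report.

    Feedback-group sessions run with tone commands, control-group sessions
    without; everything is deterministic given the master seed.
    """
    cfg = config or RunConfig()
    if seed is not None:
        cfg = RunConfig(cfg.trial, cfg.sonification, cfg.design, cfg.learning,
                        cfg.calibration, int(seed))
    out = Path(out_dir) if out_dir is not None else None
    records: list[SessionRecord] = []
    for group, mouse, day in cohort_keys(cfg.design):
        ss = session_seed(cfg.seed, cfg.design, group, mouse, day)
        stream, truth = simulate_session(
            mouse, day, group, cfg.learning, cfg.design, ss, cfg.calibration
        )
        rec = run_stream(
            stream, cfg.calibration, cfg.trial, cfg.sonification,
            mode=group, mouse=mouse, day=day, group=group,
        )
        records.append(rec)
        if out is not None and save_sessions:
            sess_dir = out / "sessions" / f"{group}_{mouse}_day{day}"
            rec.save(sess_dir)
            truth.to_jsonl(sess_dir / "ground_truth.jsonl")
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        dump_config(cfg, out / "effective_config.yaml")
        (out / "seed.txt").write_text(f"{cfg.seed}\n", encoding="utf-8")
    return _analysis_outputs(records, cfg, out, trajectory_samples, k_range, tsne)


def analyze_sessions(
    sessions_dir: str | Path,
    out_dir: str | Path | None = None,
    config: RunConfig | None = None,
    trajectory_samples: int = 100,
    k_range: Sequence[int] = tuple(range(1, 7)),
    tsne: bool = False,
) -> PipelineReport:
    """Run the offline analysis over a directory of saved session records."""
    cfg = config or RunConfig()
    sessions_dir = Path(sessions_dir)
    dirs = sorted(d for d in sessions_dir.iterdir() if (d / "meta.json").exists())
    if not dirs:
        raise FileNotFoundError(f"no session records under {sessions_dir}")
    records = [SessionRecord.load(d) for d in dirs]
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        dump_config(cfg, out / "effective_config.yaml")
        (out / "seed.txt").write_text(f"{cfg.seed}\n", encoding="utf-8")
    return _analysis_outputs(records, cfg, out, trajectory_samples, k_range, tsne)
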