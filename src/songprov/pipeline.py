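"""End-to-end orchestration: data -> song measures -> feeding -> model -> report.

A run is driven by a :class:`RunConfig` holding either paths to real input
files (sequences, RFID log, metadata) or a simulation block.  The report
contains only recomputable numbers plus provenance (config hash, seed,
package version); no wall-clock timestamps, so identical config + seed
yields byte-identical report JSON.  A single top-level seed governs every
stochastic stage through a documented derivation scheme (CRC-32 of the
stage name mixed into a SeedSequence).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
import zlib
from dataclasses import dataclass, field
from datetime import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, SongprovError
from .feature_model import (
    RESPONSE,
    SONG_MEASURES,
    SvmParams,
    loo_predict,
    select_features,
    spearman,
    standardize,
)
from .feeding import (
    events_to_visits,
    feeding_anova,
    group_rates,
    parse_rfid_log,
    rates_to_frame,
    session_rates,
    summarize_male,
)
from .song_corpus import (
    compute_repertoire,
    describe_measures,
    read_sequences,
)
from .song_network import build_network, network_metrics, write_graphml
from .synthetic_data import SimulationConfig, simulate_study

logger = logging.getLogger("songprov")


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a per-stage seed: SeedSequence([seed, crc32(stage_name)])."""
    return np.random.SeedSequence([seed, zlib.crc32(stage.encode("utf-8"))])


@dataclass(frozen=True)
class RunConfig:
    # exactly one of (simulation) or (sequences+rfid+metadata paths)
    simulation: SimulationConfig | None = None
    sequences_path: str | None = None
    rfid_path: str | None = None
    metadata_path: str | None = None

    window: int = 533
    drop_self_loops: bool = True
    min_gap: float = 60.0
    morning_end: time = time(10, 0)
    evening_start: time = time(18, 0)

    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-4
    cv_folds: int = 5
    cv_rule: str = "min"  # or "1se"

    svm: SvmParams = field(default_factory=SvmParams)
    loo_mode: str = "refit"  # "refit": re-select inside each round; "fixed": reuse

    seed: int = 0

    def __post_init__(self) -> None:
        real = all(
            p is not None
            for p in (self.sequences_path, self.rfid_path, self.metadata_path)
        )
        if self.simulation is None and not real:
            raise ConfigError(
                "config must provide either a simulation block or all three "
                "input paths (sequences, rfid, metadata)"
            )
        if self.simulation is not None and real:
            raise ConfigError("provide simulation or input paths, not both")
        if self.loo_mode not in ("refit", "fixed"):
            raise ConfigError(f"unknown loo_mode {self.loo_mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        d["morning_end"] = self.morning_end.isoformat()
        d["evening_start"] = self.evening_start.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            sim = dict(d["simulation"])
            if "start_date" in sim:
                from datetime import date

                sim["start_date"] = date.fromisoformat(sim["start_date"])
            for key in ("morning_start", "morning_end", "evening_start", "evening_end"):
                if key in sim:
                    sim[key] = time.fromisoformat(sim[key])
            if "hatchling_range" in sim:
                sim["hatchling_range"] = tuple(sim["hatchling_range"])
            if "years" in sim:
                sim["years"] = tuple(sim["years"])
            d["simulation"] = SimulationConfig(**sim)
        for key in ("morning_end", "evening_start"):
            if key in d and isinstance(d[key], str):
                d[key] = time.fromisoformat(d[key])
        if "svm" in d and isinstance(d["svm"], dict):
            d["svm"] = SvmParams(**d["svm"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:16]


class _Stage:
    """Context manager logging stage timing to stderr (never to the report)."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = _time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = _time.perf_counter() - self.t0
        if exc is not None:
            logger.error("stage %s: failed after %.2fs", self.name, dt)
            if isinstance(exc, SongprovError):
                raise SongprovError(f"[stage {self.name}] {exc}") from exc
            return False
        logger.info("stage %s: done in %.2fs", self.name, dt)
        return False


def build_feature_table(
    sequences,
    summaries_by_male: dict[str, dict],
    feeding_by_male: dict[str, float],
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    meta = metadata.set_index("male_id")
    rows = []
    for male_id, meas in sorted(summaries_by_male.items()):
        if male_id not in feeding_by_male:
            raise ConfigError(f"male {male_id!r} has song data but no feeding data")
        if male_id not in meta.index:
            raise ConfigError(f"male {male_id!r} missing from metadata")
        row = {"male_id": male_id, **meas}
        row["n_hatchlings"] = float(meta.loc[male_id, "n_hatchlings"])
        row["year"] = meta.loc[male_id, "year"]
        row[RESPONSE] = feeding_by_male[male_id]
        rows.append(row)
    return pd.DataFrame(rows).set_index("male_id")


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis and return the report as a plain dict.

    If ``outdir`` is given, the report JSON, per-male tables and GraphML
    networks are written there as a side effect.
    """
    # -- stage: data ------------------------------------------------------
    with _Stage("data"):
        if config.simulation is not None:
            study = simulate_study(config.simulation)
            sequences = study.sequences
            events = study.events
            metadata = study.metadata
        else:
            sequences = read_sequences(config.sequences_path)
            events = parse_rfid_log(config.rfid_path)
            metadata = pd.read_csv(config.metadata_path)
            study = None

    # -- stage: song measures --------------------------------------------
    with _Stage("song_measures"):
        summaries_by_male: dict[str, dict] = {}
        networks = {}
        for seq in sequences:
            rep = compute_repertoire(seq, window=config.window)
            met = network_metrics(seq, drop_self_loops=config.drop_self_loops)
            networks[seq.male_id] = build_network(
                seq, drop_self_loops=config.drop_self_loops
            )
            summaries_by_male[seq.male_id] = {
                "repertoire_size": rep.repertoire_size,
                "whistle_repertoire": rep.whistle_repertoire,
                "whistle_occurrence": rep.whistle_occurrence,
                "trill_repertoire": rep.trill_repertoire,
                "trill_occurrence": rep.trill_occurrence,
                "buzz_repertoire": rep.buzz_repertoire,
                "buzz_occurrence": rep.buzz_occurrence,
                "average_shortest_path": met.average_shortest_path,
                "transitivity": met.transitivity,
            }

    # -- stage: feeding ---------------------------------------------------
    with _Stage("feeding"):
        visits = events_to_visits(events, min_gap=config.min_gap)
        rates = session_rates(
            visits,
            morning_end=config.morning_end,
            evening_start=config.evening_start,
        )
        grouped = group_rates(rates)
        feeding_by_male = {}
        n_sessions = {}
        for male_id, vals in grouped.items():
            summary = summarize_male(vals, male_id=male_id)
            feeding_by_male[male_id] = summary.median_rate
            n_sessions[male_id] = summary.n_sessions
        anova = feeding_anova(grouped)

    # -- stage: features --------------------------------------------------
    with _Stage("features"):
        table = build_feature_table(sequences, summaries_by_male, feeding_by_male, metadata)
        measure_cols = list(SONG_MEASURES)
        stats = describe_measures(table[measure_cols])

    # -- stage: selection -------------------------------------------------
    with _Stage("selection"):
        model_table = standardize(
            table[measure_cols + ["n_hatchlings", "year"]],
        )[0]
        predictor_cols = [c for c in model_table.columns]
        model_table = model_table.assign(**{RESPONSE: table[RESPONSE]})
        sel_rng = np.random.default_rng(stage_seed(config.seed, "selection"))
        selection = select_features(
            model_table[predictor_cols].to_numpy(dtype=float),
            model_table[RESPONSE].to_numpy(dtype=float),
            feature_names=predictor_cols,
            rule=config.cv_rule,
            n_folds=config.cv_folds,
            seed=sel_rng,
            n_lambdas=config.n_lambdas,
            min_ratio=config.lambda_min_ratio,
        )

    # -- stage: loo -------------------------------------------------------
    with _Stage("loo"):
        # the raw (unstandardized) table feeds LOO: each round re-standardizes
        raw_table = table[measure_cols + ["n_hatchlings"]].copy()
        from .feature_model import expand_year

        year_expanded = expand_year(table[["year"]])
        for col in year_expanded.columns:
            raw_table[col] = year_expanded[col]
        raw_table[RESPONSE] = table[RESPONSE]

        loo_seed = int(stage_seed(config.seed, "loo").generate_state(1)[0])

        def _selector(train: pd.DataFrame) -> list[str]:
            cols = [c for c in train.columns if c != RESPONSE]
            std, _ = standardize(train[cols], columns=cols)
            sel = select_features(
                std[cols].to_numpy(dtype=float),
                train[RESPONSE].to_numpy(dtype=float),
                feature_names=cols,
                rule=config.cv_rule,
                n_folds=config.cv_folds,
                seed=np.random.default_rng(loo_seed),
                n_lambdas=config.n_lambdas,
                min_ratio=config.lambda_min_ratio,
            )
            chosen = list(sel.selected)
            if "n_hatchlings" not in chosen:
                chosen.append("n_hatchlings")
            return chosen

        if config.loo_mode == "refit":
            loo = loo_predict(
                raw_table, predictors=[], params=config.svm, selector=_selector
            )
        else:
            fixed = [c for c in selection.selected if c in raw_table.columns]
            if "n_hatchlings" not in fixed:
                fixed.append("n_hatchlings")
            loo = loo_predict(raw_table, predictors=fixed, params=config.svm)

        evaluation = spearman(loo.predicted, loo.observed)

    # -- report -----------------------------------------------------------
    report: dict[str, Any] = {
        "provenance": {
            "config_hash": config.hash(),
            "seed": config.seed,
            "version": __version__,
        },
        "measure_stats": [
            {"measure": s.measure, "mean": s.mean, "sd": s.sd, "cv": s.cv}
            for s in stats
        ],
        "measure_stats_rounded": [s.rounded(2) for s in stats],
        "per_male": (
            table.reset_index()
            .assign(n_sessions=lambda d: d["male_id"].map(n_sessions))
            .to_dict(orient="records")
        ),
        "session_rates": rates_to_frame(rates).to_dict(orient="records"),
        "anova": {
            "f_statistic": anova.f_statistic,
            "df_between": anova.df_between,
            "df_within": anova.df_within,
            "p_value": anova.p_value,
        },
        "lasso": {
            "lambda": selection.lam,
            "rule": selection.rule,
            "coefficients": selection.coef,
            "selected": list(selection.selected),
        },
        "loo": {
            "mode": config.loo_mode,
            "predictions": loo.table.reset_index().to_dict(orient="records"),
        },
        "evaluation": {
            "spearman_rho": evaluation.spearman_rho,
            "p_value": evaluation.p_value,
            "n": evaluation.n,
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_report(report, outdir / "report.json")
        table.to_csv(outdir / "feature_table.csv")
        rates_to_frame(rates).to_csv(outdir / "session_rates.csv", index=False)
        net_dir = outdir / "networks"
        net_dir.mkdir(exist_ok=True)
        for male_id, net in networks.items():
            write_graphml(net, net_dir / f"{male_id}.graphml")
        if study is not None:
            from .synthetic_data import write_study

            write_study(study, outdir / "synthetic_inputs")
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )


def make_figures(report: dict, outdir: str | Path, fmt: str = "png") -> list[Path]:
    """Render the two report figures (works headless via the Agg backend).

    * per-male session feeding rates with the per-male median marked,
    * predicted vs observed feeding rate scatter.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    rates = pd.DataFrame(report["session_rates"])
    per_male = pd.DataFrame(report["per_male"])
    fig, ax = plt.subplots(figsize=(8, 4))
    males = sorted(rates["male_id"].unique())
    for i, male in enumerate(males):
        vals = rates.loc[rates["male_id"] == male, "rate"]
        ax.plot([i] * len(vals), vals, "o", color="grey", alpha=0.6, ms=4)
    med = per_male.set_index("male_id")[RESPONSE]
    ax.plot(range(len(males)), [med[m] for m in males], "_", color="black",
            ms=14, mew=2, label="median")
    ax.set_xticks(range(len(males)))
    ax.set_xticklabels(males, rotation=90, fontsize=7)
    ax.set_ylabel("feeding rate (visits/h)")
    ax.set_xlabel("male")
    ax.legend(frameon=False)
    fig.tight_layout()
    p1 = outdir / f"feeding_rates.{fmt}"
    fig.savefig(p1, dpi=150)
    plt.close(fig)
    paths.append(p1)

    loo = pd.DataFrame(report["loo"]["predictions"])
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(loo["observed"], loo["predicted"], color="tab:blue")
    lim = [
        min(loo["observed"].min(), loo["predicted"].min()),
        max(loo["observed"].max(), loo["predicted"].max()),
    ]
    ax.plot(lim, lim, "--", color="grey", lw=1)
    rho = report["evaluation"]["spearman_rho"]
    ax.set_title(f"Spearman rho = {rho:.2f} (n = {report['evaluation']['n']})")
    ax.set_xlabel("observed feeding rate (visits/h)")
    ax.set_ylabel("predicted feeding rate (visits/h)")
    fig.tight_layout()
    p2 = outdir / f"predicted_vs_observed.{fmt}"
    fig.savefig(p2, dpi=150)
    plt.close(fig)
    paths.append(p2)
    return paths
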