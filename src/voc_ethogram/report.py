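"""Group summaries, parameter correlations, figures, and the pipeline runner.

Summaries are descriptive (mean, SD, n per strain x treatment x session);
hypothesis testing is deliberately left to external tools.  Correlations are
Pearson r computed on per-individual mean parameters pooled across groups
(n = 15 per group implies individual-level statistics); segment-level
correlation is available via ``level="segment"``.
"""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import ethogram as eth
from . import fractal as frc
from . import kinematics as kin
from . import synthetic as syn
from .tracks import Arena, FoodRegion, TrackSet, read_tracks, write_tracks

GROUP_COLS = ["strain", "treatment", "session"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _summarize_block(df: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    rows = []
    for key, g in df.groupby(GROUP_COLS, sort=True):
        for col in value_cols:
            vals = g[col].to_numpy(dtype=float)
            ok = vals[~np.isnan(vals)]
            n = len(ok)
            rows.append(
                {
                    "strain": key[0],
                    "treatment": key[1],
                    "session": key[2],
                    "parameter": col,
                    "mean": float(ok.mean()) if n else float("nan"),
                    # SD convention: 0 for a single observation, NaN for none
                    "sd": float(ok.std(ddof=1)) if n > 1 else (0.0 if n == 1 else float("nan")),
                    "n": n,
                    "n_excluded": int(len(vals) - n),
                }
            )
    return pd.DataFrame(rows)


def summarize_groups(
    features: pd.DataFrame,
    dimensions: pd.DataFrame | None = None,
    occupancy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-group mean +/- SD of the six movement parameters, and optionally the
    fractal dimension and zone stay durations.

    Undefined entries (NaN meander / locomotory rate) are excluded and counted
    in ``n_excluded`` rather than imputed.
    """
    parts = [_summarize_block(features, list(kin.FEATURE_COLUMNS))]
    if dimensions is not None and len(dimensions):
        dims = dimensions.rename(columns={"dimension": "fractal_dimension"})
        parts.append(_summarize_block(dims, ["fractal_dimension"]))
    if occupancy is not None and len(occupancy):
        occ = occupancy.rename(columns={z: f"stay_{z}" for z in ("top", "bottom", "food", "middle")})
        parts.append(
            _summarize_block(occ, [f"stay_{z}" for z in ("top", "bottom", "food", "middle")])
        )
    return pd.concat(parts, ignore_index=True)


def individual_means(
    features: pd.DataFrame, dimensions: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-individual (and per-session) mean parameters, NaN-skipping."""
    keys = [c for c in ("strain", "treatment", "session", "individual_id") if c in features.columns]
    means = features.groupby(keys, sort=True)[list(kin.FEATURE_COLUMNS)].mean().reset_index()
    if dimensions is not None and len(dimensions):
        dmeans = (
            dimensions.groupby(keys, sort=True)["dimension"]
            .mean()
            .reset_index()
            .rename(columns={"dimension": "fractal_dimension"})
        )
        means = means.merge(dmeans, on=keys, how="left")
    return means


def correlation_matrix(
    features: pd.DataFrame,
    dimensions: pd.DataFrame | None = None,
    level: str = "individual",
) -> pd.DataFrame:
    """Pearson correlations among the movement parameters (and the fractal
    dimension when supplied), pooled across groups.

    ``level="individual"`` (default) correlates per-individual means;
    ``level="segment"`` correlates raw segments.  A zero-variance parameter
    yields NaN entries and a warning.
    """
    if level == "individual":
        data = individual_means(features, dimensions)
    elif level == "segment":
        data = features.copy()
    else:
        raise ValueError("level must be 'individual' or 'segment'")
    value_cols = [c for c in list(kin.FEATURE_COLUMNS) + ["fractal_dimension"] if c in data.columns]
    if len(data) < 3:
        raise ValueError("need at least 3 observations for correlations")
    sub = data[value_cols]
    zero_var = [c for c in value_cols if sub[c].std(skipna=True) == 0]
    if zero_var:
        warnings.warn(f"zero-variance parameter(s): {zero_var}", stacklevel=2)
    return sub.corr(method="pearson")


def arena_from_config(cfg: dict | None) -> Arena:
    cfg = cfg or {}
    food = cfg.get("food_region", "default")
    if food == "default":
        kwargs = {}
    elif food is None:
        kwargs = {"food_region": None}
    else:
        kwargs = {"food_region": FoodRegion(**food)}
    return Arena(
        width=cfg.get("width", 50.0),
        height=cfg.get("height", 150.0),
        top_zone_fraction=cfg.get("top_zone_fraction", 0.2),
        bottom_zone_fraction=cfg.get("bottom_zone_fraction", 0.2),
        **kwargs,
    )


def _plot_figures(out_dir: Path, model, clusters, fractions) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    paths = []
    # component planes
    fig, axes = plt.subplots(2, 3, figsize=(10, 7))
    for ax, name in zip(axes.ravel(), model.feature_names):
        i = list(model.feature_names).index(name)
        plane = model.weights[:, i].reshape(model.rows, model.cols)
        im = ax.imshow(plane, origin="lower", cmap="viridis", vmin=0, vmax=1)
        ax.set_title(name, fontsize=9)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.suptitle("SOM component planes (normalized weights)")
    p = out_dir / "component_planes.png"
    fig.tight_layout()
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)
    # dendrogram with heights rescaled to 0-100%
    Z = clusters.linkage.copy()
    Z[:, 2] = 100.0 * Z[:, 2] / Z[:, 2].max()
    fig, ax = plt.subplots(figsize=(10, 4))
    dendrogram(Z, ax=ax, no_labels=True, color_threshold=0)
    ax.set_ylabel("linkage distance (%)")
    ax.set_title("Ward clustering of SOM codebook")
    p = out_dir / "dendrogram.png"
    fig.tight_layout()
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)
    # pattern time budgets
    if fractions is not None and len(fractions):
        df = fractions.copy()
        df["group"] = df[GROUP_COLS].agg("/".join, axis=1)
        fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(df)), 4))
        bottom = np.zeros(len(df))
        for pattern in eth.PATTERNS:
            ax.bar(df["group"], df[pattern], bottom=bottom, label=pattern)
            bottom += df[pattern].to_numpy()
        ax.set_ylabel("% of observation time")
        ax.legend(fontsize=8)
        ax.tick_params(axis="x", rotation=90, labelsize=7)
        p = out_dir / "pattern_fractions.png"
        fig.tight_layout()
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths.append(p)
    return paths


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Run simulate/ingest -> extract -> fractal -> som -> classify -> summarize.

    ``config`` is a plain mapping (typically loaded from a YAML file).  Keys:
    ``seed``, ``out_dir``, ``arena``, and either ``input`` (trajectory table
    path) or ``simulate`` ({n_individuals, duration, groups}); optional
    ``fractal.window``, ``som`` ({enabled, k, max_rows}), ``figures``.
    Everything is reproducible from config + seed; outputs and a run log are
    written to ``out_dir``.
    """
    t0 = time.time()
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out_dir", "voc_ethogram_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    arena = arena_from_config(config.get("arena"))
    outputs: dict[str, Any] = {"out_dir": out_dir}
    log: dict[str, Any] = {"seed": seed, "config": _jsonable(config), "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                t = time.time()
                result = fn()
                log["stages"][name] = {"seconds": round(time.time() - t, 3)}
                return result
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineStageError(name, exc) from exc

        return deco

    @stage("ingest")
    def trackset() -> TrackSet:
        if config.get("input"):
            return read_tracks(config["input"], arena)
        sim = config.get("simulate", {}) or {}
        groups = sim.get("groups")
        if groups is not None:
            groups = [tuple(g) for g in groups]
        sc = syn.SimulationConfig(
            arena=arena,
            duration=float(sim.get("duration", 1800.0)),
            n_individuals=int(sim.get("n_individuals", 15)),
            seed=seed,
        )
        return syn.generate_study(sc, groups=groups)

    outputs["tracks"] = write_tracks(trackset, out_dir / "tracks.csv")

    @stage("extract")
    def features() -> pd.DataFrame:
        df = kin.extract_features(trackset)
        df.to_csv(out_dir / "features.csv", index=False)
        return df

    outputs["features"] = out_dir / "features.csv"

    @stage("fractal")
    def dimensions() -> pd.DataFrame:
        window = float(config.get("fractal", {}).get("window", 1800.0))
        df = frc.track_dimensions(trackset, window=window)
        df.to_csv(out_dir / "fractal.csv", index=False)
        return df

    outputs["fractal"] = out_dir / "fractal.csv"

    @stage("occupancy")
    def occupancy() -> pd.DataFrame:
        df = kin.occupancy_table(trackset)
        df.to_csv(out_dir / "occupancy.csv", index=False)
        return df

    outputs["occupancy"] = out_dir / "occupancy.csv"

    @stage("summarize")
    def summary() -> pd.DataFrame:
        df = summarize_groups(features, dimensions, occupancy)
        df.to_csv(out_dir / "summary.csv", index=False)
        return df

    outputs["summary"] = out_dir / "summary.csv"

    @stage("correlations")
    def correlations() -> pd.DataFrame:
        df = correlation_matrix(features, dimensions)
        df.to_csv(out_dir / "correlations.csv")
        return df

    outputs["correlations"] = out_dir / "correlations.csv"

    som_cfg = config.get("som", {}) or {}
    fractions = None
    if som_cfg.get("enabled", True) and len(features):
        @stage("som-train")
        def som_parts():
            norm, bounds, _ = eth.normalize_features(features)
            max_rows = int(som_cfg.get("max_rows", 30_000))
            if len(norm) > max_rows:
                sel = np.random.default_rng(seed).choice(len(norm), max_rows, replace=False)
                train_tbl = norm.iloc[np.sort(sel)]
            else:
                train_tbl = norm
            model = eth.train_som(train_tbl, seed=seed, bounds=bounds)
            clusters = eth.label_patterns(
                model, eth.cluster_codebook(model, int(som_cfg.get("k", eth.N_CLUSTERS)))
            )
            model.to_json(out_dir / "som_model.json")
            return model, clusters

        model, clusters = som_parts

        @stage("classify")
        def ethores():
            res = eth.classify_segments(features, model, clusters)
            res.assignments.to_csv(out_dir / "ethogram.csv", index=False)
            res.pattern_fractions.to_csv(out_dir / "pattern_fractions.csv", index=False)
            return res

        fractions = ethores.pattern_fractions
        outputs["som_model"] = out_dir / "som_model.json"
        outputs["ethogram"] = out_dir / "ethogram.csv"
        outputs["pattern_fractions"] = out_dir / "pattern_fractions.csv"

        if config.get("figures", True):
            @stage("figures")
            def figs():
                return _plot_figures(out_dir, model, clusters, fractions)

            outputs["figures"] = figs

    log["total_seconds"] = round(time.time() - t0, 3)
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    outputs["run_log"] = out_dir / "run_log.json"
    return outputs


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
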