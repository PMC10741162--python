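"""End-to-end pipeline: simulate -> normalize -> stats -> trajectories ->
annotate -> enrich, with a reproducible run directory.

Each wound type is analyzed separately; QC filtering, drift correction
and multiplicity families are handled per ionization mode, and the modes
are merged again for trajectory clustering and reporting.  A manifest
records the config hash, seed and package version; rerunning with the
same config reproduces every numeric output exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import FeatureTable, ValidationError, WOUND_TYPES
from .io import (
    read_compound_db,
    read_feature_table,
    read_pathways,
    write_feature_table,
)
from .simulate import SimConfig, generate_study
from .qcnorm import loess_drift_correct, qc_presence_filter, qc_rsd_filter, qc_stats
from .stats import (
    day_ttest,
    features_of_interest,
    two_way_anova_scan,
    volcano_classify,
)
from .trajectory import infer_trajectories
from .annotate import match_features_level3
from .enrich import enrich, enrichment_frame, map_compounds

#: Day-7 treatment contrast per wound type (comparator of the graft arm)
DAY7_CONTRASTS = {"DPT": ("AFSG", "FBD"), "FT": ("AFSG", "CS")}


def packaged_data(name: str) -> Path:
    return Path(resources.files("woundmetab").joinpath("data", name))


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    # inputs: either simulate (default) or read a table from disk
    input_table: str | None = None
    input_samples: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    compound_db: str | None = None      # default: packaged demo DB
    pathways: str | None = None         # default: packaged demo pathways
    wound_types: tuple[str, ...] = WOUND_TYPES
    # thresholds
    qc_presence: float = 0.80
    qc_rsd: float = 25.0
    qc_rsd_keep: str = "below"
    loess_span: float = 0.75
    anova_q: float = 0.05
    anova_p: float = 0.05
    volcano_p: float = 0.1
    volcano_fc: float = 1.5
    k_min: int = 2
    k_max: int = 10
    ppm_tol: float = 10.0
    min_shared_fragments: int = 5
    make_plots: bool = True

    def validate(self) -> None:
        for name, lo, hi in (
            ("qc_presence", 0.0, 1.0),
            ("anova_q", 0.0, 1.0),
            ("anova_p", 0.0, 1.0),
            ("volcano_p", 0.0, 1.0),
            ("loess_span", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValidationError(f"{name} must be in [{lo}, {hi}], got {v}")
        if self.volcano_fc <= 1.0:
            raise ValidationError("volcano_fc must be > 1")
        if self.qc_rsd <= 0 or self.ppm_tol <= 0:
            raise ValidationError("qc_rsd and ppm_tol must be positive")
        if not (2 <= self.k_min <= self.k_max):
            raise ValidationError("need 2 <= k_min <= k_max")
        unknown = set(self.wound_types) - set(WOUND_TYPES)
        if unknown:
            raise ValidationError(f"unknown wound types {sorted(unknown)}")
        for path_attr in ("input_table", "input_samples", "compound_db", "pathways"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{path_attr}: file not found: {p}")
        self.sim.seed = self.seed
        self.sim.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim = data.pop("sim", {})
        cfg = cls(**data)
        if sim:
            cfg.sim = SimConfig(**{**cfg.sim.to_dict(), **sim})
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(
            {**asdict(self), "sim": self.sim.to_dict()}, sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def _normalize_mode(table: FeatureTable, cfg: RunConfig) -> tuple[FeatureTable, dict]:
    n0 = table.shape[0]
    t1 = qc_presence_filter(table, cfg.qc_presence)
    t2 = qc_rsd_filter(t1, cfg.qc_rsd, keep=cfg.qc_rsd_keep)
    t3, report = loess_drift_correct(t2, span=cfg.loess_span)
    log = {
        "features_in": n0,
        "removed_qc_presence": n0 - t1.shape[0],
        "removed_qc_rsd": t1.shape[0] - t2.shape[0],
        "removed_nonpositive_fit": report.n_dropped_nonpositive_fit,
        "features_out": t3.shape[0],
        "median_qc_rsd_before": float(np.nanmedian(qc_stats(t2)["qc_rsd"])),
        "median_qc_rsd_after": float(np.nanmedian(qc_stats(t3)["qc_rsd"])),
    }
    return t3, log


def _merge_tables(tables: list[FeatureTable]) -> FeatureTable:
    merged = tables[0]
    for t in tables[1:]:
        merged = FeatureTable(
            np.vstack([merged.intensities, t.intensities]),
            merged.features + t.features,
            merged.samples,
        )
    return merged


def _heatmap(z: pd.DataFrame, labels, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(labels, kind="stable")
    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(z.to_numpy()[order], aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_xlabel("study sample")
    ax.set_ylabel("feature (ordered by cluster)")
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}, "wound_types": {}}

    # ---- stage 1: obtain the feature table -----------------------------
    if config.input_table:
        table = read_feature_table(config.input_table, config.input_samples)
        truth = None
    else:
        table, truth = generate_study(config.sim)
        truth.to_csv(out / "ground_truth.tsv", sep="\t")
    write_feature_table(table, out / "raw_table.tsv")
    summary["stages"]["input"] = {"n_features": table.shape[0], "n_samples": table.shape[1]}

    # ---- stage 2: QC filtering + drift correction (per mode) -----------
    normalized_parts = []
    norm_log = {}
    for mode, sub in table.split_modes().items():
        norm, log = _normalize_mode(sub, config)
        norm_log[mode] = log
        normalized_parts.append(norm)
    normalized = _merge_tables(normalized_parts)
    write_feature_table(normalized, out / "normalized_table.tsv")
    (out / "normalization_log.json").write_text(json.dumps(norm_log, indent=2))
    summary["stages"]["normalize"] = norm_log

    db = read_compound_db(config.compound_db or packaged_data("compounds_demo.tsv"))
    pathways = read_pathways(config.pathways or packaged_data("pathways_demo.tsv"))
    name_to_kegg = {r.name: r.kegg_id for r in db if r.kegg_id}

    mode_of = {f.feature_id: f.mode for f in normalized.features}
    for wound in config.wound_types:
        wdir = out / wound
        wdir.mkdir(exist_ok=True)
        wsum: dict = {}

        # ---- stage 3: differential statistics (ANOVA per mode family) --
        anova_parts = []
        for mode, sub in normalized.split_modes().items():
            anova_parts.append(two_way_anova_scan(sub, wound))
        anova = pd.concat(anova_parts)
        anova = anova.loc[[f.feature_id for f in normalized.features]]
        _write_tsv(anova, wdir / "anova.tsv")
        foi = features_of_interest(anova, config.anova_q, config.anova_p)
        wsum["n_time_significant"] = len(foi)

        group_a, group_b = DAY7_CONTRASTS[wound]
        volcano_parts = []
        for mode, sub in normalized.split_modes().items():
            tt = day_ttest(sub, wound, day=config.sim.days[0],
                           group_a=group_a, group_b=group_b)
            vc = volcano_classify(tt, config.volcano_p, config.volcano_fc)
            volcano_parts.append(tt.join(vc))
        volcano = pd.concat(volcano_parts)
        _write_tsv(volcano, wdir / "day7_volcano.tsv")
        wsum["n_day7_responders"] = int(volcano["responder"].sum())

        # ---- stage 4: trajectory clustering ----------------------------
        if len(foi) >= 4:
            traj = infer_trajectories(
                normalized, wound, feature_ids=foi,
                k_range=range(config.k_min, config.k_max + 1),
            )
            _write_tsv(traj.assignments(), wdir / "trajectory_labels.tsv")
            _write_tsv(traj.centroids, wdir / "trajectory_centroids.tsv")
            _write_tsv(traj.metric_table, wdir / "trajectory_metrics.tsv")
            wsum["k"] = traj.k
            wsum["patterns"] = {str(c): p for c, p in sorted(traj.pattern_labels.items())}
            if config.make_plots:
                from .trajectory import zscore_features

                z = zscore_features(normalized.subset_features(foi), wound)
                _heatmap(z, traj.labels, wdir / "trajectory_heatmap.png")
        else:
            wsum["k"] = None
            wsum["patterns"] = {}

        # ---- stage 5: annotation ---------------------------------------
        foi_features = [f for f in normalized.features if f.feature_id in set(foi)]
        hits = match_features_level3(foi_features, db, tol_ppm=config.ppm_tol)
        hits_df = pd.DataFrame([
            {
                "feature_id": h.feature_id,
                "compound": h.compound,
                "kegg_id": h.kegg_id,
                "mode": mode_of[h.feature_id],
                "adduct": h.adduct,
                "theoretical_mz": h.theoretical_mz,
                "ppm_error": h.ppm_error,
                "level": h.level,
            }
            for h in hits
        ])
        hits_df.to_csv(wdir / "annotations.tsv", sep="\t", index=False,
                       float_format="%.6f")
        wsum["n_annotated_features"] = int(hits_df["feature_id"].nunique()) if len(hits_df) else 0

        # ---- stage 6: pathway enrichment -------------------------------
        universe, _ = map_compounds(sorted(name_to_kegg.values()), name_to_kegg)
        hit_names = sorted({h.compound for h in hits})
        mapped_hits, unmapped = map_compounds(hit_names, name_to_kegg)
        if mapped_hits:
            results = enrich(sorted(set(mapped_hits)), universe, pathways)
            _write_tsv(enrichment_frame(results).set_index("pathway_id"),
                       wdir / "enrichment.tsv")
            wsum["n_enriched_p05"] = sum(r.p_value < 0.05 for r in results)
        else:
            (wdir / "enrichment.tsv").write_text(
                "pathway_id\tname\tn_pathway\tn_overlap\tp_value\tq_value\tneg_log10_p\timpact\thits\n"
            )
            wsum["n_enriched_p05"] = 0
        wsum["unmapped_compounds"] = unmapped
        summary["wound_types"][wound] = wsum

    manifest = {
        "package": "woundmetab",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return out
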