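"""End-to-end orchestration: simulate -> connect -> graph -> analyze.

Every stage reads and writes plain TSV under a single run directory so each
intermediate is independently inspectable and the pipeline can be resumed
stage by stage.  A run manifest records every produced file with a content
hash plus a provenance block (config, seed, package versions), and the whole
run is a pure function of the configuration's master seed.

Run layout::

    <out>/
      parcellation.tsv          manifest.tsv          timeseries/<sid>.tsv
      connectivity/<sid>.tsv    connectivity/_meta.tsv
      graphs/<sid>__<scope>.tsv graphs/adjacency/<sid>__<scope>.tsv
      analysis/*.tsv            run_manifest.json
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    CohortData,
    compare_connection_counts,
    confound_screen,
    connectogram,
    direction_matrix,
    hemispheric_analysis,
    lobar_analysis,
)
from .connectivity import ConnectivityMatrix, FilterSpec, connectivity_pipeline
from .exceptions import InvalidArgumentError, MissingStageInputError
from .graph import METRICS, SCOPES, ThresholdSpec, subject_graph_metrics
from .parcellation import ParcellationTable, make_parcellation
from .synthetic import (
    DEFAULT_EFFECTS,
    CohortSpec,
    EffectSpec,
    generate_cohort,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration covering every stage of one run."""

    # cohort
    n_roi: int = 136
    n_hc: int = 20
    n_lgg: int = 30
    n_hgg: int = 30
    T: int = 160
    TR: float = 2.5
    base_r_within_lobe: float = 0.35
    base_r_within_hemi: float = 0.02
    base_r_homotopic: float = 0.50
    base_r_background: float = 0.02
    ar_coeff: float = 0.3
    master_seed: int = 0
    # planted effects
    lgg_delta_left_global: float = 0.06
    lgg_delta_local: float = -0.10
    lgg_delta_right: float = 0.0
    lgg_tumor_location: str = ""
    hgg_delta_left_global: float = 0.0
    hgg_delta_local: float = 0.0
    hgg_delta_right: float = -0.04
    hgg_tumor_location: str = ""
    # filtering
    low_hz: float = 0.01
    high_hz: float = 0.1
    # thresholding
    z_stat_threshold: float = 2.0
    p_threshold: float = 0.05
    two_sided: bool = False
    # analysis
    alpha_normality: float = 0.05
    paired_lr: bool = True
    max_connectogram_seeds: int = 8
    write_adjacency: bool = True

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_hc=self.n_hc, n_lgg=self.n_lgg, n_hgg=self.n_hgg,
            T=self.T, TR=self.TR,
            base_r_within_lobe=self.base_r_within_lobe,
            base_r_within_hemi=self.base_r_within_hemi,
            base_r_homotopic=self.base_r_homotopic,
            base_r_background=self.base_r_background,
            ar_coeff=self.ar_coeff, master_seed=self.master_seed,
        )

    def effects(self) -> dict[str, EffectSpec]:
        return {
            "HC": DEFAULT_EFFECTS["HC"],
            "LGG": EffectSpec(
                group="LGG",
                tumor_location=self.lgg_tumor_location or None,
                delta_left_global=self.lgg_delta_left_global,
                delta_local=self.lgg_delta_local,
                delta_right=self.lgg_delta_right,
            ),
            "HGG": EffectSpec(
                group="HGG",
                tumor_location=self.hgg_tumor_location or None,
                delta_left_global=self.hgg_delta_left_global,
                delta_local=self.hgg_delta_local,
                delta_right=self.hgg_delta_right,
            ),
        }

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(low_hz=self.low_hz, high_hz=self.high_hz)

    def threshold_spec(self) -> ThresholdSpec:
        return ThresholdSpec(
            z_stat_threshold=self.z_stat_threshold,
            p_threshold=self.p_threshold,
            two_sided=self.two_sided,
        )


def _coerce(value: str):
    low = value.strip()
    if low.lower() in ("true", "false"):
        return low.lower() == "true"
    for cast in (int, float):
        try:
            return cast(low)
        except ValueError:
            continue
    return low


def parse_config(path: str | Path) -> RunConfig:
    """Read a flat ``key = value`` config file ('#' starts a comment)."""
    values: dict = {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidArgumentError(f"malformed config line: {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in known:
            raise InvalidArgumentError(f"unknown config key: {key}")
        values[key] = _coerce(value)
    return RunConfig(**values)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingStageInputError(stage, str(path))
    return path


def _write_matrix_tsv(path: Path, matrix: np.ndarray, roi_ids: np.ndarray,
                      fmt: str = _FLOAT_FMT) -> None:
    header = "roi_id\t" + "\t".join(str(i) for i in roi_ids)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i, row in zip(roi_ids, matrix):
            fh.write(str(i) + "\t" + "\t".join(fmt % v for v in row) + "\n")


def _read_matrix_tsv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), df.index.to_numpy(dtype=int)


def stage_simulate(config: RunConfig, out: Path) -> None:
    """Generate parcellation, cohort timeseries and the cohort manifest."""
    out.mkdir(parents=True, exist_ok=True)
    (out / "timeseries").mkdir(exist_ok=True)
    parcellation = make_parcellation(config.n_roi)
    parcellation.to_tsv(out / "parcellation.tsv")
    subjects = generate_cohort(parcellation, config.cohort_spec(), config.effects())
    rows = []
    for s in subjects:
        rel = f"timeseries/{s.subject_id}.tsv"
        np.savetxt(out / rel, s.data, delimiter="\t", fmt=_FLOAT_FMT)
        rows.append(
            {
                "subject_id": s.subject_id, "group": s.group,
                "tumor_location": s.tumor_location if s.tumor_location else "",
                "age": s.age, "tumor_size": s.tumor_size,
                "file": rel, "seed": s.seed,
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    logger.info("simulate: %d subjects, %d ROIs, T=%d", len(rows),
                parcellation.n_roi, config.T)


def stage_connect(config: RunConfig, out: Path) -> None:
    """Denoise every subject and write Fisher-z connectivity matrices."""
    manifest = pd.read_csv(_require(out / "manifest.tsv", "connect"), sep="\t")
    conn_dir = out / "connectivity"
    conn_dir.mkdir(exist_ok=True)
    parcellation = ParcellationTable.from_tsv(_require(out / "parcellation.tsv", "connect"))
    meta = []
    for _, row in manifest.iterrows():
        ts = np.loadtxt(_require(out / row["file"], "connect"), delimiter="\t")
        conn = connectivity_pipeline(ts, config.TR, config.filter_spec(),
                                     subject_id=row["subject_id"])
        _write_matrix_tsv(conn_dir / f"{row['subject_id']}.tsv", conn.z,
                          np.arange(parcellation.n_roi))
        meta.append({"subject_id": row["subject_id"], "t_effective": conn.t_effective})
    pd.DataFrame(meta).to_csv(conn_dir / "_meta.tsv", sep="\t", index=False)
    logger.info("connect: wrote %d connectivity matrices", len(meta))


def stage_graph(config: RunConfig, out: Path) -> None:
    """Threshold graphs and write per-subject nodal metric tables."""
    manifest = pd.read_csv(_require(out / "manifest.tsv", "graph"), sep="\t")
    parcellation = ParcellationTable.from_tsv(_require(out / "parcellation.tsv", "graph"))
    meta = pd.read_csv(_require(out / "connectivity" / "_meta.tsv", "graph"), sep="\t")
    t_eff = dict(zip(meta["subject_id"], meta["t_effective"]))
    graph_dir = out / "graphs"
    graph_dir.mkdir(exist_ok=True)
    if config.write_adjacency:
        (graph_dir / "adjacency").mkdir(exist_ok=True)
    threshold = config.threshold_spec()
    for sid in manifest["subject_id"]:
        z, _ = _read_matrix_tsv(_require(out / "connectivity" / f"{sid}.tsv", "graph"))
        conn = ConnectivityMatrix(z=z, t_effective=int(t_eff[sid]), subject_id=sid)
        tables = subject_graph_metrics(conn, parcellation, threshold)
        for scope, table in tables.items():
            table.to_csv(graph_dir / f"{sid}__{scope}.tsv", sep="\t",
                         float_format=_FLOAT_FMT)
        if config.write_adjacency:
            from .graph import threshold_graph

            g = threshold_graph(conn, threshold)
            _write_matrix_tsv(graph_dir / "adjacency" / f"{sid}__whole_brain.tsv",
                              g.adjacency.astype(int), np.arange(z.shape[0]), fmt="%d")
    logger.info("graph: wrote metric tables for %d subjects", len(manifest))


def _load_cohort(config: RunConfig, out: Path, stage: str) -> CohortData:
    manifest = pd.read_csv(_require(out / "manifest.tsv", stage), sep="\t")
    manifest["tumor_location"] = manifest["tumor_location"].where(
        manifest["tumor_location"].notna() & (manifest["tumor_location"] != ""), None
    )
    parcellation = ParcellationTable.from_tsv(_require(out / "parcellation.tsv", stage))
    meta = pd.read_csv(_require(out / "connectivity" / "_meta.tsv", stage), sep="\t")
    t_eff = dict(zip(meta["subject_id"], meta["t_effective"]))
    conns, metrics, mean_rows = {}, {}, []
    for _, row in manifest.iterrows():
        sid = row["subject_id"]
        z, _ = _read_matrix_tsv(_require(out / "connectivity" / f"{sid}.tsv", stage))
        conns[sid] = ConnectivityMatrix(z=z, t_effective=int(t_eff[sid]), subject_id=sid)
        tables = {}
        for scope in SCOPES:
            path = _require(out / "graphs" / f"{sid}__{scope}.tsv", stage)
            tables[scope] = pd.read_csv(path, sep="\t", index_col="roi_id")
        metrics[sid] = tables
        for scope in SCOPES:
            means = tables[scope].mean()
            for metric in METRICS:
                mean_rows.append({"subject_id": sid, "group": row["group"],
                                  "scope": scope, "metric": metric,
                                  "value": float(means[metric])})
    return CohortData(parcellation=parcellation, manifest=manifest,
                      connectivity=conns, metrics=metrics,
                      network_means=pd.DataFrame(mean_rows))


def stage_analyze(config: RunConfig, out: Path) -> None:
    """Hemispheric + lobar statistics, connectograms and confound screen."""
    cohort = _load_cohort(config, out, "analyze")
    analysis_dir = out / "analysis"
    analysis_dir.mkdir(exist_ok=True)
    cohort.network_means.to_csv(analysis_dir / "network_means.tsv", sep="\t", index=False)

    hemi = hemispheric_analysis(cohort, config.alpha_normality, config.paired_lr)
    hemi.to_csv(analysis_dir / "hemispheric.tsv", sep="\t", index=False)

    lobar = lobar_analysis(cohort, config.alpha_normality)
    lobar.to_csv(analysis_dir / "lobar.tsv", sep="\t", index=False)
    direction_matrix(lobar).to_csv(analysis_dir / "direction_matrix.tsv",
                                   sep="\t", index=False)

    confound_screen(cohort).to_csv(analysis_dir / "confounds.tsv", sep="\t", index=False)

    # Connectograms seeded from FDR-significant lobar nodes.
    seeds = (
        lobar.loc[lobar["p_fdr"] < 0.05, "node"].astype(int).drop_duplicates().tolist()
    )[: config.max_connectogram_seeds]
    edge_rows, count_rows = [], []
    groups = [g for g in ("HC", "LGG", "HGG")
              if (cohort.manifest["group"] == g).sum() >= 3]
    for seed in seeds:
        for group in groups:
            result = connectogram(cohort, seed, group)
            count_rows.append({"seed": seed, "group": group, "count": result.count})
            for target, q in zip(result.target_ids, result.p_fdr):
                if q < 0.05:
                    edge_rows.append({"seed": seed, "target": int(target),
                                      "group": group, "p_fdr": q})
    pd.DataFrame(edge_rows, columns=["seed", "target", "group", "p_fdr"]).to_csv(
        analysis_dir / "connectograms.tsv", sep="\t", index=False)
    counts = pd.DataFrame(count_rows, columns=["seed", "group", "count"])
    counts.to_csv(analysis_dir / "connectogram_counts.tsv", sep="\t", index=False)

    count_tests = []
    if seeds:
        for ga, gb in (("LGG", "HC"), ("HGG", "HC"), ("LGG", "HGG")):
            if ga in groups and gb in groups:
                res = compare_connection_counts(
                    counts.loc[counts["group"] == ga, "count"],
                    counts.loc[counts["group"] == gb, "count"],
                )
                count_tests.append({"group_a": ga, "group_b": gb,
                                    "statistic": res.statistic, "p": res.p,
                                    "direction": res.direction})
    pd.DataFrame(count_tests, columns=["group_a", "group_b", "statistic",
                                       "p", "direction"]).to_csv(
        analysis_dir / "connectogram_count_tests.tsv", sep="\t", index=False)
    logger.info("analyze: %d hemispheric rows, %d lobar rows, %d connectogram seeds",
                len(hemi), len(lobar), len(seeds))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_run_manifest(config: RunConfig, out: Path) -> dict:
    files = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*.tsv")
        if p.is_file()
    )
    manifest = {
        "provenance": {
            "package": "gliograph",
            "version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "master_seed": config.master_seed,
            "config": dataclasses.asdict(config),
        },
        "files": {rel: _sha256(out / rel) for rel in files},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


STAGES = {
    "simulate": stage_simulate,
    "connect": stage_connect,
    "graph": stage_graph,
    "analyze": stage_analyze,
}


def run_all(config: RunConfig, out: str | Path) -> dict:
    """Run every stage and return the manifest with file hashes."""
    out = Path(out)
    for name, stage in STAGES.items():
        logger.info("running stage: %s", name)
        stage(config, out)
    return write_run_manifest(config, out)


def summary_report(out: str | Path, alpha: float = 0.05) -> str:
    """Human-readable digest of a completed run."""
    out = Path(out)
    hemi = pd.read_csv(_require(out / "analysis" / "hemispheric.tsv", "report"), sep="\t")
    lobar = pd.read_csv(_require(out / "analysis" / "lobar.tsv", "report"), sep="\t")
    lines = ["gliograph run summary", "=" * 23]
    sig = hemi[hemi["p_fdr"] < alpha]
    lines.append(f"hemispheric/whole-brain comparisons: {len(hemi)} "
                 f"({len(sig)} significant at FDR {alpha})")
    for _, r in sig.iterrows():
        arrow = "increased" if r["direction"] > 0 else "decreased"
        lines.append(f"  {r['scope']:>14} {r['metric']:<18} "
                     f"{r['group_a']} vs {r['group_b']}: {arrow} "
                     f"(p_fdr={r['p_fdr']:.4g}, {r['test_used']})")
    sig_lobar = lobar[lobar["p_fdr"] < alpha]
    lines.append(f"lobar comparisons: {len(lobar)} rows "
                 f"({len(sig_lobar)} significant at FDR {alpha})")
    for scope, chunk in sig_lobar.groupby("scope"):
        lines.append(f"  {scope}: {len(chunk)} significant node/metric rows")
    return "\n".join(lines)
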