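"""End-to-end orchestration: simulate/load -> filter -> PLI -> graphs -> stats.

For every subject and band the continuous recording is band-passed,
cut into epochs, Hilbert-transformed, and reduced to a PLI matrix per
epoch.  Connectivity summaries (global mean, frontal/posterior cluster
means) use the epoch-averaged matrix; graph metrics are computed per
epoch, normalized against edge-shuffled surrogates, and averaged over
epochs (a config switch selects the epoch-mean-matrix alternative).
Group differences are two-tailed pooled t-tests on log-transformed
measures.
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
import yaml

from . import io as pio
from .connectivity import (ClusterDefinition, DEFAULT_FRONTAL, DEFAULT_POSTERIOR,
                           cluster_means, connectivity_matrix, global_mean_pli)
from .graph import DEFAULT_N_SURROGATES, WeightedGraph, normalize_metrics
from .montage import DEFAULT_MONTAGE, Montage, MultichannelRecording
from .preprocess import (BAND_BY_NAME, BandDefinition, DEFAULT_BANDS,
                         DEFAULT_EPOCH_LENGTH, DEFAULT_N_EPOCHS, bandpass,
                         instantaneous_phase, make_epochs)
from .simulate import (Subject, control_like_template, fxs_like_template,
                       generate_cohort)
from .stats import independent_t, log_transform

logger = logging.getLogger(__name__)

#: Measures entering the group-stats table by default: the connectivity
#: and network quantities the group contrast is usually reported on.
DEFAULT_STAT_MEASURES = (
    "global_pli", "long_range", "clustering_norm", "path_length_norm",
    "small_world",
)


@dataclass
class PipelineConfig:
    montage: Montage = DEFAULT_MONTAGE
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    n_epochs: int = DEFAULT_N_EPOCHS
    epoch_length: int = DEFAULT_EPOCH_LENGTH
    frontal: ClusterDefinition = DEFAULT_FRONTAL
    posterior: ClusterDefinition = DEFAULT_POSTERIOR
    n_surrogates: int = DEFAULT_N_SURROGATES
    alpha: float = 0.05
    seed: int | None = None
    mode: str = "simulate"  # simulate | ascii | edf
    n_per_group: int = 8  # simulate mode
    n_per_group_b: int | None = 12  # unbalanced cohorts; None = same as group a
    manifest: str | None = None  # ascii/edf modes
    out_dir: str = "plinet_out"
    stat_measures: tuple[str, ...] = DEFAULT_STAT_MEASURES
    graph_level: str = "per_epoch"  # per_epoch | subject_mean
    dump_matrices: bool = False

    def __post_init__(self) -> None:
        for cluster in (self.frontal, self.posterior):
            for lab in cluster.labels:
                self.montage.index(lab)  # raises on unknown labels
        if self.mode == "simulate" and self.seed is None:
            raise ValueError("simulate mode requires a master seed")
        if self.graph_level not in ("per_epoch", "subject_mean"):
            raise ValueError(f"unknown graph_level {self.graph_level!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        kwargs: dict = {}
        if "montage" in raw:
            m = raw.pop("montage")
            kwargs["montage"] = Montage(tuple(m["channels"]),
                                        float(m.get("sampling_rate", 500.0)))
        if "bands" in raw:
            bands = []
            for b in raw.pop("bands"):
                if isinstance(b, str):
                    bands.append(BAND_BY_NAME[b])
                else:
                    bands.append(BandDefinition(b["name"], b["low"], b["high"]))
            kwargs["bands"] = tuple(bands)
        if "clusters" in raw:
            c = raw.pop("clusters")
            kwargs["frontal"] = ClusterDefinition("frontal", tuple(c["frontal"]))
            kwargs["posterior"] = ClusterDefinition("posterior", tuple(c["posterior"]))
        for key in ("n_epochs", "epoch_length", "n_surrogates", "alpha", "seed",
                    "mode", "n_per_group", "n_per_group_b", "manifest", "out_dir",
                    "graph_level", "dump_matrices"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if "stat_measures" in raw:
            kwargs["stat_measures"] = tuple(raw.pop("stat_measures"))
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        payload = json.dumps(dataclasses.asdict(self), default=default,
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    subject_table: pd.DataFrame
    stats_table: pd.DataFrame
    out_dir: Path | None = None


def analyze_subject(recording: MultichannelRecording,
                    config: PipelineConfig,
                    surrogate_rng: np.random.Generator,
                    subject_id: str = "", group: str = "",
                    compute_graph: bool = True) -> list[dict]:
    """Per-band connectivity and graph measures for one subject."""
    rows = []
    for band in config.bands:
        filtered = bandpass(recording, band)
        epoched = make_epochs(filtered, config.n_epochs, config.epoch_length, band)
        phases = [instantaneous_phase(e, epoched.channels) for e in epoched.epochs]
        subj_mat = connectivity_matrix(phases, "pli", band)
        clusters = cluster_means(subj_mat, config.frontal, config.posterior)
        row = {
            "subject_id": subject_id, "group": group, "band": band.name,
            "global_pli": global_mean_pli(subj_mat),
            "frontal_short": clusters.frontal_short,
            "posterior_short": clusters.posterior_short,
            "long_range": clusters.long_range,
        }
        if compute_graph:
            if config.graph_level == "per_epoch":
                mats = [connectivity_matrix(p, "pli", band) for p in phases]
            else:
                mats = [subj_mat]
            metrics = [
                normalize_metrics(WeightedGraph(m.values, m.channels),
                                  config.n_surrogates, surrogate_rng)
                for m in mats
            ]
            row.update({
                "clustering": float(np.mean([m.mean_clustering for m in metrics])),
                "path_length": float(np.mean([m.mean_path_length for m in metrics])),
                "clustering_norm": float(np.mean([m.clustering_norm for m in metrics])),
                "path_length_norm": float(np.mean([m.path_length_norm for m in metrics])),
                "small_world": float(np.mean([m.small_world for m in metrics])),
            })
        rows.append(row)
    return rows


def group_statistics(subject_table: pd.DataFrame,
                     measures: tuple[str, ...] = DEFAULT_STAT_MEASURES,
                     ) -> pd.DataFrame:
    """Pooled t-tests on log-transformed measures, per band and measure.

    The sign convention is first group minus second group, groups taken
    in order of first appearance in the table.
    """
    groups = list(dict.fromkeys(subject_table["group"]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    rows = []
    for band in dict.fromkeys(subject_table["band"]):
        sub = subject_table[subject_table["band"] == band]
        for measure in measures:
            if measure not in sub.columns or sub[measure].isna().all():
                continue
            a = sub.loc[sub["group"] == groups[0], measure].to_numpy(float)
            b = sub.loc[sub["group"] == groups[1], measure].to_numpy(float)
            res = independent_t(log_transform(a), log_transform(b))
            rows.append({"band": band, "measure": measure, "t": res.t,
                         "df": res.df, "p": res.p, "eta_p2": res.eta_p2})
    return pd.DataFrame(rows, columns=pio.STATS_COLUMNS)


def _load_cohort(config: PipelineConfig) -> list[Subject]:
    if config.mode == "simulate":
        nb = config.n_per_group_b
        fxs = fxs_like_template()
        ctl = control_like_template()
        if nb is None or nb == config.n_per_group:
            return generate_cohort(fxs, ctl, config.n_per_group, config.seed)
        big = generate_cohort(fxs, ctl, max(config.n_per_group, nb), config.seed)
        by_group: dict[str, list[Subject]] = {}
        for s in big:
            by_group.setdefault(s.group, []).append(s)
        return (by_group[fxs.label][: config.n_per_group]
                + by_group[ctl.label][:nb])
    if config.manifest is None:
        raise ValueError(f"mode {config.mode!r} requires a cohort manifest")
    manifest = pio.read_manifest(config.manifest)
    root = Path(config.manifest).parent
    cohort = []
    for _, entry in manifest.iterrows():
        if config.mode == "edf":
            rec = pio.read_edf(root / str(entry["path"]), config.montage)
        elif config.mode == "ascii":
            mats = [pio.read_ascii_epoch(root / p.strip(), config.montage,
                                         config.epoch_length)
                    for p in str(entry["path"]).split(";")]
            # epochs re-joined into one continuous matrix so filtering and
            # re-epoching follow the same path as raw recordings
            rec = MultichannelRecording(np.concatenate(mats, axis=1),
                                        config.montage.sfreq,
                                        config.montage.channels)
        else:
            raise ValueError(f"unknown input mode {config.mode!r}")
        cohort.append(Subject(str(entry["subject_id"]), str(entry["group"]),
                              int(entry.get("seed", -1)), rec))
    return cohort


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run the full analysis and (optionally) write the results bundle."""
    logger.info("loading cohort (mode=%s)", config.mode)
    cohort = _load_cohort(config)
    logger.info("cohort of %d subjects", len(cohort))
    # the surrogate stream is separate from the simulation stream, so
    # connectivity results do not depend on normalization settings
    surrogate_ss = np.random.SeedSequence([int(config.seed or 0), 7_654_321])
    subject_rows: list[dict] = []
    out_dir = Path(config.out_dir)
    for subject, child in zip(cohort, surrogate_ss.spawn(len(cohort))):
        logger.info("analyzing subject %s (%s)", subject.subject_id, subject.group)
        rng = np.random.default_rng(child)
        rows = analyze_subject(subject.recording, config, rng,
                               subject.subject_id, subject.group)
        subject_rows.extend(rows)
        if config.dump_matrices and write:
            mat_dir = out_dir / "matrices"
            mat_dir.mkdir(parents=True, exist_ok=True)
            for band in config.bands:
                filtered = bandpass(subject.recording, band)
                ep = make_epochs(filtered, config.n_epochs, config.epoch_length)
                phases = [instantaneous_phase(e, ep.channels) for e in ep.epochs]
                mat = connectivity_matrix(phases, "pli", band)
                pio.write_connectivity_matrix(
                    mat_dir / f"{subject.subject_id}_{band.name}.tsv",
                    mat.values, mat.channels)
    subject_table = pd.DataFrame(subject_rows, columns=pio.SUBJECT_COLUMNS)
    stats_table = (group_statistics(subject_table, config.stat_measures)
                   if len(set(subject_table["group"])) == 2
                   else pd.DataFrame(columns=pio.STATS_COLUMNS))
    result = PipelineResult(subject_table, stats_table,
                            out_dir if write else None)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        pio.write_results(subject_rows, stats_table.to_dict("records"), out_dir)
        from . import __version__
        run_manifest = {
            "version": __version__,
            "seed": config.seed,
            "mode": config.mode,
            "config_hash": config.config_hash(),
            "n_subjects": len(cohort),
            "n_tests": int(len(stats_table)),
            "bands": [b.name for b in config.bands],
        }
        (out_dir / "run_manifest.json").write_text(
            json.dumps(run_manifest, indent=2) + "\n")
        logger.info("results written to %s", out_dir)
    return result
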