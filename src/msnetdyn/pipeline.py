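"""End-to-end cohort analysis with a Model/Results interface.

:class:`MicrostateNetworkModel` is constructed from a cohort of recordings
(or generates a synthetic one) and `fit()` runs the full chain —
preprocessing, microstate template fitting on pooled GFP peaks, per-subject
backfitting, per-microstate phase-locking networks, graph topology,
synchronizability, controllability, and pinning-gain ranking on the
group-average networks.  The returned :class:`CohortResults` holds tidy
DataFrames, exposes `compare_groups()` / `correlations()` for the group
statistics, and prints a `summary()` table.

Randomness policy: every stochastic stage consumes a child of one master
`numpy.random.SeedSequence` keyed on the synthetic config's seed, in a
fixed order (subjects, then template clustering, then surrogate nulls), so
a config plus master seed reproduces the analysis bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import run_length_encode
from .montage import scalp_montage, region_channels
from .synthetic import SyntheticConfig, make_cohort, make_templates
from .preprocessing import average_reference, bandpass
from .microstates import (
    CLASS_NAMES,
    backfit,
    cluster_microstates,
    compute_gfp,
    extract_peak_maps,
    microstate_parameters,
)
from .plv import instantaneous_phase, microstate_network, group_average
from .graphmetrics import topology, sync_index
from .control import PinningSpec, control_profile, pinning_gains, select_pinned
from .stats import two_sample_test, correlation, bh_fdr

logger = logging.getLogger("msnetdyn")

PARAM_METRICS = ("coverage", "occurrence", "duration", "contribution")


@dataclass
class PipelineConfig:
    """All knobs of the analysis, defaulted to the study conditions."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # filtering
    filter_low: float = 0.5
    filter_high: float = 60.0
    notch: Optional[tuple] = (49.0, 51.0)
    theta_low: float = 4.0
    theta_high: float = 7.0
    filter_order: Optional[int] = None
    # microstates
    peak_min_distance: int = 5            # samples (10 ms at 500 Hz)
    max_peak_maps_per_subject: int = 400
    kmeans_restarts: int = 50
    min_duration_ms: float = 0.0          # backfit smoothing; 0 = off
    # networks
    plv_display_threshold: float = 0.55
    min_class_samples: int = 100
    n_surrogates: int = 20
    compute_sw: bool = True
    # pinning
    pinning: PinningSpec = field(default_factory=PinningSpec)
    pinning_threshold: float = 1.24
    pinning_upper: float = 1.4
    # statistics
    alpha: float = 0.05
    bh_correction: bool = False

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as f:
            raw = tomllib.load(f)
        cfg = cls()
        if "synthetic" in raw:
            cfg.synthetic = SyntheticConfig(**raw["synthetic"])
        if "pinning" in raw:
            cfg.pinning = PinningSpec(**raw["pinning"])
        for section in ("filter", "microstates", "networks", "stats"):
            for key, val in raw.get(section, {}).items():
                if key == "notch":
                    val = tuple(val) if val else None
                if not hasattr(cfg, key):
                    raise KeyError(f"unknown config key [{section}] {key}")
                setattr(cfg, key, val)
        return cfg


class MicrostateNetworkModel:
    """Cohort-level model of microstate-resolved network dynamics.

    Parameters
    ----------
    recordings : list of EEGRecording
    config : PipelineConfig
    ground_truths : list of GroundTruth, optional
        Generating truths for synthetic cohorts; their planted templates
        anchor the canonical A-D labeling and enable recovery diagnostics.
    """

    def __init__(self, recordings, config: Optional[PipelineConfig] = None, ground_truths=None):
        if not recordings:
            raise ValueError("no recordings")
        self.recordings = list(recordings)
        self.config = config if config is not None else PipelineConfig()
        self.ground_truths = list(ground_truths) if ground_truths else None
        n_ch = {r.n_channels for r in self.recordings}
        if len(n_ch) > 1:
            raise ValueError("all recordings must share the channel count")

    @classmethod
    def from_cohort(cls, config: Optional[PipelineConfig] = None) -> "MicrostateNetworkModel":
        """Generate a synthetic two-group cohort and wrap it as a model."""
        config = config if config is not None else PipelineConfig()
        pairs = make_cohort(config.synthetic)
        recs = [r for r, _ in pairs]
        gts = [g for _, g in pairs]
        return cls(recs, config=config, ground_truths=gts)

    @classmethod
    def from_recordings(cls, recordings, config: Optional[PipelineConfig] = None):
        return cls(recordings, config=config)

    # ------------------------------------------------------------------ fit
    def fit(self) -> "CohortResults":
        cfg = self.config
        master = np.random.SeedSequence(cfg.synthetic.seed)
        seeds = master.spawn(3)  # clustering, surrogates, reserve
        kmeans_seed = int(seeds[0].generate_state(1)[0] % (2**31))
        surro_seed = int(seeds[1].generate_state(1)[0] % (2**31))

        # segmentation runs on the broad band (short impulse response keeps
        # microstate timing sharp); the narrow theta band is used only for
        # the phase networks
        logger.info("preprocessing %d recordings", len(self.recordings))
        broad_recs, theta_recs, gfps, peak_maps, peak_gfps = [], [], [], [], []
        sub_rng = np.random.default_rng(seeds[2])
        for rec in self.recordings:
            r = average_reference(rec)
            bb = bandpass(r, cfg.filter_low, cfg.filter_high, notch=cfg.notch,
                          order=cfg.filter_order)
            broad_recs.append(bb)
            theta_recs.append(
                bandpass(bb, cfg.theta_low, cfg.theta_high, order=cfg.filter_order)
            )
            gfp = compute_gfp(bb)
            gfps.append(gfp)
            maps, g_at_peaks, _ = extract_peak_maps(bb, min_distance=cfg.peak_min_distance)
            if len(maps) > cfg.max_peak_maps_per_subject:
                keep = np.sort(
                    sub_rng.choice(len(maps), cfg.max_peak_maps_per_subject, replace=False)
                )
                maps, g_at_peaks = maps[keep], g_at_peaks[keep]
            peak_maps.append(maps)
            peak_gfps.append(g_at_peaks)

        canonical = (
            self.ground_truths[0].templates
            if self.ground_truths
            else make_templates(self.recordings[0].n_channels, seed=cfg.synthetic.seed)
        )
        logger.info("clustering pooled GFP-peak maps")
        templates = cluster_microstates(
            np.vstack(peak_maps),
            gfp=np.concatenate(peak_gfps),
            restarts=cfg.kmeans_restarts,
            seed=kmeans_seed,
            canonical=canonical,
        ).ordered()

        montage = scalp_montage(self.recordings[0].n_channels)
        frontal = region_channels(montage, "frontal")

        param_rows, net_rows, node_rows = [], [], []
        segmentations, networks = {}, {}
        srng = np.random.default_rng(surro_seed)
        for rec, broad, theta, gfp in zip(self.recordings, broad_recs, theta_recs, gfps):
            seg = backfit(broad, templates, min_duration_ms=cfg.min_duration_ms)
            segmentations[rec.subject_id] = seg
            params = microstate_parameters(seg, rec.fs, gfp=gfp.values)
            for cls_name, row in params.iterrows():
                for metric in PARAM_METRICS:
                    param_rows.append(
                        dict(subject=rec.subject_id, group=rec.group,
                             state=cls_name, metric=metric, value=row[metric])
                    )
            phases = instantaneous_phase(theta)
            for c, cls_name in enumerate(CLASS_NAMES):
                try:
                    net = microstate_network(
                        phases, seg, c, subject_id=rec.subject_id, group=rec.group,
                        channels=rec.channels, min_samples=cfg.min_class_samples,
                    )
                except ValueError:
                    continue
                networks[(rec.subject_id, cls_name)] = net
                if not net.reliable:
                    continue
                topo = topology(
                    net, n_surrogates=cfg.n_surrogates,
                    seed=int(srng.integers(2**31)), compute_sw=cfg.compute_sw,
                )
                sync = sync_index(net)
                prof = control_profile(net.matrix)
                for metric, value in (
                    ("cp", topo.cp), ("lp", topo.lp), ("eg", topo.eg),
                    ("eloc", topo.eloc), ("sw", topo.sw),
                    ("sync_M", sync.M), ("lambda2", sync.lambda2),
                    ("lambda_max", sync.lambda_max),
                    ("mean_ac", prof.ac.mean()), ("mean_mc", prof.mc.mean()),
                    ("frontal_ac", prof.ac[frontal].mean()),
                    ("frontal_mc", prof.mc[frontal].mean()),
                ):
                    net_rows.append(
                        dict(subject=rec.subject_id, group=rec.group,
                             state=cls_name, metric=metric, value=float(value))
                    )
                for metric, vec in (
                    ("ac", prof.ac), ("mc", prof.mc),
                    ("clustering", topo.node_clustering),
                    ("nodal_efficiency", topo.node_efficiency),
                    ("nodal_path_length", topo.node_path_length),
                    ("local_efficiency", topo.node_local_efficiency),
                ):
                    for ch, value in zip(rec.channels, vec):
                        node_rows.append(
                            dict(subject=rec.subject_id, group=rec.group,
                                 state=cls_name, channel=ch, metric=metric,
                                 value=float(value))
                        )

        logger.info("group-average networks and pinning gains")
        group_networks, pinning_rows, pinning_results = {}, [], {}
        for grp in sorted({r.group for r in self.recordings}):
            for cls_name in CLASS_NAMES:
                nets = [
                    networks[(r.subject_id, cls_name)]
                    for r in self.recordings
                    if r.group == grp and (r.subject_id, cls_name) in networks
                    and networks[(r.subject_id, cls_name)].reliable
                ]
                if not nets:
                    continue
                avg = group_average(nets)
                group_networks[(grp, cls_name)] = avg
                try:
                    pr = pinning_gains(avg.matrix, self.config.pinning)
                except ValueError as exc:
                    logger.warning("pinning infeasible for %s/%s: %s", grp, cls_name, exc)
                    continue
                tiers = select_pinned(pr, cfg.pinning_threshold, cfg.pinning_upper)
                tier_of = {}
                for tier_name, idx in tiers.items():
                    for i in idx:
                        tier_of[i] = tier_name
                rank_of = {node: r for r, node in enumerate(pr.ranking, start=1)}
                pinning_results[(grp, cls_name)] = pr
                for i, ch in enumerate(avg.channels or range(avg.n_nodes)):
                    pinning_rows.append(
                        dict(group=grp, state=cls_name, channel=ch,
                             gain=float(pr.gains[i]), rank=rank_of[i],
                             pinned=bool(i in set(pr.pinned_set)), tier=tier_of[i])
                    )

        return CohortResults(
            config=cfg,
            templates=templates,
            montage=montage,
            segmentations=segmentations,
            networks=networks,
            group_networks=group_networks,
            pinning_results=pinning_results,
            params=pd.DataFrame(param_rows),
            network_metrics=pd.DataFrame(net_rows),
            node_metrics=pd.DataFrame(node_rows),
            pinning=pd.DataFrame(pinning_rows),
            ground_truths=self.ground_truths,
        )


@dataclass
class CohortResults:
    """Fitted microstate network dynamics of one cohort."""

    config: PipelineConfig
    templates: object
    montage: pd.DataFrame
    segmentations: dict
    networks: dict
    group_networks: dict
    pinning_results: dict
    params: pd.DataFrame
    network_metrics: pd.DataFrame
    node_metrics: pd.DataFrame
    pinning: pd.DataFrame
    ground_truths: Optional[list] = None

    # ----------------------------------------------------------- statistics
    def compare_groups(
        self,
        which: str = "all",
        groups: tuple = ("HC", "SZ"),
        alpha: Optional[float] = None,
        bh: Optional[bool] = None,
    ) -> pd.DataFrame:
        """Independent-samples tests (group A minus group B) for every
        (state, metric) cell.

        ``which`` selects the family: "params", "network", "nodes" or "all"
        (excluding nodes).  BH-FDR adjustment is applied per family when
        enabled; the report records whether it was.
        """
        alpha = self.config.alpha if alpha is None else alpha
        bh = self.config.bh_correction if bh is None else bh
        frames = {
            "params": [self.params],
            "network": [self.network_metrics],
            "nodes": [self.node_metrics],
            "all": [self.params, self.network_metrics],
        }[which]
        rows = []
        for frame in frames:
            if frame.empty:
                continue
            keys = ["state", "metric"] + (["channel"] if "channel" in frame else [])
            for key_vals, sub in frame.groupby(keys):
                x = sub.loc[sub.group == groups[0], "value"].dropna().to_numpy()
                y = sub.loc[sub.group == groups[1], "value"].dropna().to_numpy()
                if len(x) < 2 or len(y) < 2:
                    continue
                res = two_sample_test(x, y, alpha=alpha)
                row = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
                row.update(
                    t=res.t, df=res.df, p=res.p, effect=res.effect,
                    mean_a=float(x.mean()), mean_b=float(y.mean()),
                    significant=res.significant,
                )
                rows.append(row)
        out = pd.DataFrame(rows)
        if bh and not out.empty:
            reject, p_adj = bh_fdr(out["p"].to_numpy(), alpha=alpha)
            out["p_adj"] = p_adj
            out["significant"] = reject
        out.attrs["alpha"] = alpha
        out.attrs["bh_correction"] = bh
        if not bh:
            logger.warning("no multiple-comparison correction applied (per-test alpha=%.3g)", alpha)
        return out

    def correlations(
        self,
        state: str = "D",
        param_metrics: tuple = ("occurrence", "coverage"),
        network_metric: str = "sync_M",
    ) -> pd.DataFrame:
        """Pearson correlations between microstate parameters and a network
        metric, across subjects (both groups pooled)."""
        net = self.network_metrics.query("state == @state and metric == @network_metric")
        net = net.set_index("subject")["value"]
        rows = []
        for pm in param_metrics:
            par = self.params.query("state == @state and metric == @pm").set_index("subject")["value"]
            common = par.index.intersection(net.index)
            if len(common) < 3:
                continue
            res = correlation(par[common].to_numpy(), net[common].to_numpy())
            rows.append(dict(state=state, param=pm, network_metric=network_metric,
                             r=res.r, p=res.p, n=res.n))
        return pd.DataFrame(rows)

    # -------------------------------------------------------------- summary
    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        lines = ["Microstate network dynamics - cohort fit", ""]
        tpl = self.templates
        if tpl.canonical_corr is not None:
            rows = [[c, f"{r:.3f}"] for c, r in zip(tpl.class_labels, tpl.canonical_corr)]
            lines.append(str(SimpleTable(rows, headers=["class", "|r| vs canonical"],
                                         title="Template identification")))
            lines.append("")
        lines.append(f"Clustering GEV: {tpl.gev:.4f}")
        lines.append("")
        if not self.params.empty and self.params.group.nunique() > 1:
            piv = (
                self.params.pivot_table(index=["state", "metric"], columns="group",
                                        values="value", aggfunc="mean")
                .round(4)
            )
            rows = [[f"{s}/{m}"] + [f"{v:.4g}" for v in vals]
                    for (s, m), vals in piv.iterrows()]
            lines.append(str(SimpleTable(rows, headers=["state/metric"] + list(piv.columns),
                                         title="Microstate parameters (group means)")))
            lines.append("")
            tests = self.compare_groups("all")
            sig = tests[tests.significant].sort_values("p")
            if not sig.empty:
                rows = [
                    [f"{r.state}/{r.metric}", f"{r.t:.3f}", f"{r.p:.2e}", f"{r.effect:.2f}"]
                    for r in sig.itertuples()
                ]
                lines.append(str(SimpleTable(
                    rows, headers=["state/metric", "t", "p", "d"],
                    title=f"Significant group contrasts (alpha={tests.attrs['alpha']})",
                )))
        return "\n".join(lines)

    # ----------------------------------------------------------------- save
    def save(self, out_dir) -> dict:
        """Write tidy CSVs, networks, segmentations and a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.params.to_csv(out / "microstate_parameters.csv", index=False)
        self.network_metrics.to_csv(out / "network_metrics.csv", index=False)
        self.node_metrics.to_csv(out / "node_metrics.csv", index=False)
        self.pinning.to_csv(out / "pinning.csv", index=False)
        np.savetxt(out / "templates.csv", self.templates.maps, delimiter=",")
        seg_payload = {
            sid: run_length_encode(seg.labels) for sid, seg in self.segmentations.items()
        }
        (out / "segmentations.json").write_text(json.dumps(seg_payload))
        for (grp, cls_name), net in self.group_networks.items():
            df = pd.DataFrame(net.matrix, index=net.channels, columns=net.channels)
            df.to_csv(out / f"group_network_{grp}_{cls_name}.csv")
        tests = self.compare_groups("all") if self.params.group.nunique() > 1 else pd.DataFrame()
        if not tests.empty:
            tests.to_csv(out / "group_tests.csv", index=False)
        manifest = {
            "config": _config_dict(self.config),
            "n_recordings": int(len(self.segmentations)),
            "gev": float(self.templates.gev),
            "bh_correction": bool(self.config.bh_correction),
            "alpha": self.config.alpha,
            "files": sorted({p.name for p in out.iterdir()} | {"manifest.json"}),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    syn = d["synthetic"]
    if syn.get("transition_matrix") is not None:
        syn["transition_matrix"] = np.asarray(syn["transition_matrix"]).tolist()
    for k, v in list(d["pinning"].items()):
        if isinstance(v, np.ndarray):
            d["pinning"][k] = v.tolist()
    return d


def run_pipeline(config, out_dir, seed: Optional[int] = None) -> CohortResults:
    """Full synthetic-cohort analysis from a config (path or object).

    ``seed`` overrides the synthetic master seed.  Every output is a pure
    function of (config, seed); the log carries timestamps, the data files
    do not.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_toml(config)
    if seed is not None:
        config.synthetic.seed = int(seed)
    logging.basicConfig(level=logging.INFO)
    model = MicrostateNetworkModel.from_cohort(config)
    results = model.fit()
    results.save(out_dir)
    return results
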