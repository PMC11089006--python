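"""End-to-end orchestration: simulate -> censor -> connectivity -> map ->
atlas -> reliability, from a single config, with a hashed output manifest.

The pipeline is deliberately a thin composition of the library modules; it
adds only artifact routing, per-stage logging counters and the manifest.
Re-running an unchanged config rewrites byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import atlas as atlas_mod
from . import connectivity as conn_mod
from . import infomap_consensus as im_mod
from . import motion_prep, omni, reliability, template_matching, templates
from .gray_model import (LabelMap, ScalarMap, write_dense, write_labels,
                         write_overlap, write_scalar)
from .motion_prep import CensorConfig
from .synthetic import Cohort, CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

METHODS = ("tm", "omni", "im_consensus")


@dataclass
class RunConfig:
    """Single-document run configuration (JSON-serializable)."""

    out_dir: str
    method: str = "tm"
    simulation: CohortSpec = field(default_factory=CohortSpec)
    censor: CensorConfig = field(default_factory=CensorConfig)
    minutes: float | None = None          # exact-duration sampling target
    z_cut: float = 1.0
    roi_threshold: float = 0.8
    izone_threshold: float = 2.2
    min_cluster: int = 30
    densities: tuple[float, ...] = (0.3, 0.4, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    backend: str = "reference"
    distance_exclusion_mm: float = 30.0
    split_half_n: int = 10
    seed: int = 0
    write_timeseries: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if isinstance(self.simulation, dict):
            self.simulation = CohortSpec(**self.simulation)
        if isinstance(self.censor, dict):
            self.censor = CensorConfig(**self.censor)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))

    def to_json(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True),
                              encoding="utf-8")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured pipeline; return (and write) the output manifest.

    The manifest maps artifact names to paths and content hashes, plus the
    per-stage counters (censored frames, winner-take-all ties, fallback
    thresholds) the QC culture of precision mapping expects.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "artifacts": {}, "counters": {}}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path),
                                       "sha256": _sha256(path)}

    try:
        # -- simulate ------------------------------------------------------
        cohort = generate_cohort(config.simulation)
        manifest["stages"].append("simulate")
        space = cohort.space
        palette = cohort.spec.palette

        # -- censor --------------------------------------------------------
        masks = []
        n_censored = []
        rng = np.random.default_rng(config.seed)
        for p in cohort.participants:
            fd = motion_prep.compute_fd(p.motion,
                                        config.censor.sphere_radius_mm)
            bold_sd = p.timeseries.values.std(axis=1)
            mask = motion_prep.censor_frames(fd, bold_sd, config.censor,
                                             tr_seconds=cohort.spec.tr_seconds)
            if config.minutes is not None:
                mask = motion_prep.sample_exact_duration(
                    mask, cohort.spec.tr_seconds, config.minutes,
                    seed=int(rng.integers(2 ** 31)))
            masks.append(mask)
            n_censored.append(int((~mask.retained).sum()))
        manifest["stages"].append("censor")
        manifest["counters"]["censored_frames"] = n_censored

        # -- connectivity --------------------------------------------------
        conns = []
        for p, mask in zip(cohort.participants, masks):
            C = conn_mod.dense_correlation(p.timeseries, mask)
            conns.append(conn_mod.blockwise_zscore(C))
        manifest["stages"].append("connectivity")

        # -- templates (truth group partition initializes the seeds) -------
        stack = np.stack([
            templates.participant_seed_maps(p.timeseries,
                                            cohort.truth.group_labels, mask)
            for p, mask in zip(cohort.participants, masks)])
        tset = templates.build_templates(stack, palette)
        tset.save(out / "templates.tsv")
        record("templates", out / "templates.tsv")
        manifest["stages"].append("templates")

        # -- mapping -------------------------------------------------------
        label_maps: list[LabelMap] = []
        overlap_maps = []
        fallback_count = 0
        for i, C in enumerate(conns):
            profile = template_matching.eta_profiles(C, tset,
                                                     z_cut=config.z_cut)
            if config.method == "omni":
                ths = omni.omni_thresholds(profile)
                fallback_count += sum(t.fallback_used for t in ths)
                om = omni.omni_assign(profile, ths)
                overlap_maps.append(om)
                path = out / f"sub-{i:03d}_overlap.tsv"
                write_overlap(om, path)
                record(f"sub-{i:03d}_overlap", path)
            elif config.method == "tm":
                lm = template_matching.winner_take_all(profile)
                label_maps.append(lm)
                path = out / f"sub-{i:03d}_labels.tsv"
                write_labels(lm, path)
                record(f"sub-{i:03d}_labels", path)
            else:  # im_consensus
                Cx = conn_mod.distance_exclude(C,
                                               config.distance_exclusion_mm)
                solutions = []
                for d in config.densities:
                    edges = conn_mod.density_threshold(Cx, d)
                    sol = im_mod.detect_communities(
                        edges, space.n_gray, density_percent=d,
                        backend=config.backend, seed=config.seed)
                    solutions.append(
                        (d, im_mod.match_communities(
                            sol, cohort.truth.group_labels)))
                lm = im_mod.consensus_across_densities(solutions)
                lm = im_mod.clean_small_clusters(
                    lm, min_cluster=config.min_cluster)
                label_maps.append(lm)
                path = out / f"sub-{i:03d}_labels.tsv"
                write_labels(lm, path)
                record(f"sub-{i:03d}_labels", path)
        manifest["stages"].append(f"map:{config.method}")
        if config.method == "omni":
            manifest["counters"]["threshold_fallbacks"] = fallback_count

        # -- atlas ---------------------------------------------------------
        if config.method == "omni":
            counts = [omni.overlap_count(om) for om in overlap_maps]
            iz = atlas_mod.integration_zones(
                counts, threshold=config.izone_threshold,
                min_cluster=config.min_cluster)
            write_scalar(iz.mean_counts, out / "mean_overlap_count.tsv")
            record("mean_overlap_count", out / "mean_overlap_count.tsv")
            zone = ScalarMap(space=space, name="integration_zones",
                             values=iz.zone_mask().astype(float))
            write_scalar(zone, out / "integration_zones.tsv")
            record("integration_zones", out / "integration_zones.tsv")
            prob = atlas_mod.probability_maps(overlap_maps)
        else:
            prob = atlas_mod.probability_maps(label_maps)
            roi = atlas_mod.derive_roiset(prob, config.roi_threshold,
                                          min_cluster=config.min_cluster)
            write_labels(roi.to_labelmap(), out / "roiset.tsv")
            record("roiset", out / "roiset.tsv")
            manifest["counters"]["n_parcels"] = roi.n_parcels
        np.savetxt(out / "probability_maps.tsv", prob.values,
                   delimiter="\t", fmt="%.6g")
        record("probability_maps", out / "probability_maps.tsv")
        manifest["stages"].append("atlas")

        # -- reliability ---------------------------------------------------
        n_rel = min(config.split_half_n, len(cohort.participants))
        if n_rel >= 2:
            mapper = _tm_mapper(tset, config.z_cut)
            res = reliability.split_half(
                [p.timeseries for p in cohort.participants[:n_rel]], mapper)
            report = {
                "intra_nmi": res.intra_nmi.tolist(),
                "inter_nmi_mean": float(res.inter_nmi.mean()),
                "t_statistic": res.t_statistic,
                "dof": res.dof,
                "p_value": res.p_value,
                "tail": res.tail,
                "variance_assumption": res.variance_assumption,
            }
            (out / "reliability.json").write_text(
                json.dumps(report, indent=2, sort_keys=True), encoding="utf-8")
            record("reliability", out / "reliability.json")
            manifest["stages"].append("reliability")

        if config.write_timeseries:
            for p in cohort.participants:
                path = out / f"sub-{p.index:03d}_bold.tsv"
                write_dense(p.timeseries, path)
                record(f"sub-{p.index:03d}_bold", path)

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
        logger.error("pipeline failed at stage %s: %s",
                     manifest["stages"][-1] if manifest["stages"] else "init",
                     exc)
        raise

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return manifest


def _tm_mapper(tset, z_cut: float):
    """Template-matching mapper usable by the split-half harness."""
    def mapper(ts):
        C = conn_mod.blockwise_zscore(conn_mod.dense_correlation(ts))
        profile = template_matching.eta_profiles(C, tset, z_cut=z_cut)
        return template_matching.winner_take_all(profile)
    return mapper
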