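"""End-to-end pipeline: phantoms -> preprocessing -> radiomics + dual-channel
latents -> cross-cohort selection -> fused classification -> interpretation.

Deterministic given the config seed: all stage seeds derive from it.  Each
stage logs its feature counts; stage errors propagate with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from contextlib import contextmanager
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import fusion, interpret, phantom, preprocess, selection
from .config import PipelineConfig, config_hash
from .globalnet import GlobalEncoder, extract_global_latents, global_latent_names, rollout_map, train_global_network
from .localnet import LocalEncoder, extract_local_latents, layer_cam, local_latent_names, prepare_input, train_network
from .radiomics import extract_table, normalize_table
from .volume import AttributionVolume, Volume3D, write_volume, write_labels

logger = logging.getLogger("petfusion")

__all__ = ["PipelineReport", "run_pipeline"]


@dataclass
class PipelineReport:
    seed: int
    config_hash: str
    classes: list[str]
    n_subjects: dict
    n_radiomics_candidates: int
    stage_counts: dict
    selected: dict
    metrics: dict
    concordance: dict
    attribution: dict
    artifacts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @staticmethod
    def from_json(text: str) -> "PipelineReport":
        return PipelineReport(**json.loads(text))


@contextmanager
def _stage(name: str):
    import time

    logger.info("stage %s: start", name)
    t0 = time.perf_counter()
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: done (%.1f s)", name, time.perf_counter() - t0)


class _PreparedCohort:
    """SUVR volumes plus network inputs for one simulated cohort."""

    def __init__(self, cohort: phantom.Cohort, local_shape, global_shape):
        self.ids = [s.subject_id for s in cohort.subjects]
        self.labels = np.asarray(cohort.labels)
        self.atlas = cohort.atlas
        self.cohort_id = cohort.cohort_id
        self.suvr_subjects = []
        self.local_inputs = []
        self.zvols = []
        for s in cohort.subjects:
            suvr = preprocess.to_suvr(s.volume)
            z = preprocess.zscore_image(suvr)
            suvr32 = Volume3D(suvr.data.astype(np.float32), suvr.spacing, suvr.mask)
            self.suvr_subjects.append(phantom.Subject(s.subject_id, suvr32, s.diagnosis))
            self.local_inputs.append(prepare_input(z, local_shape))
            self.zvols.append(z.data.astype(np.float32))

    @property
    def spacing(self):
        return self.suvr_subjects[0].volume.spacing

    def as_cohort(self) -> phantom.Cohort:
        return phantom.Cohort(self.suvr_subjects, self.cohort_id, 0, self.atlas)


def _latent_frames(local_net: LocalEncoder, global_net: GlobalEncoder,
                   prepared: _PreparedCohort):
    loc = np.stack([extract_local_latents(local_net, x) for x in prepared.local_inputs])
    glo = np.stack([extract_global_latents(global_net, z) for z in prepared.zvols])
    ldf = pd.DataFrame(loc, index=prepared.ids, columns=local_latent_names(loc.shape[1]))
    gdf = pd.DataFrame(glo, index=prepared.ids, columns=global_latent_names(glo.shape[1]))
    return ldf, gdf


def _planted_regions(effects: dict[str, phantom.DiseaseEffect]) -> dict[str, list[str]]:
    return {diag: [r for r, f in eff.factors.items() if f != 1.0]
            for diag, eff in effects.items() if diag != "HC"}


def _region_contrast(amap: AttributionVolume, atlas, planted: list[str]) -> dict:
    name_to_label = {v: k for k, v in atlas.registry.items()}
    labels = atlas.labels
    planted_mask = np.zeros(labels.shape, bool)
    for r in planted:
        planted_mask |= labels == name_to_label[r]
    unaffected_mask = (labels > 0) & ~planted_mask
    pm = float(amap.data[planted_mask].mean())
    um = float(amap.data[unaffected_mask].mean())
    return {"planted_mean": pm, "unaffected_mean": um,
            "ratio": pm / um if um > 0 else float("inf")}


def _subsample_per_class(ids, labels, k, classes):
    picked = []
    for c in classes:
        picked.extend([i for i, l in zip(ids, labels) if l == c][:k])
    return picked


_STAGE_ORDER = ("phantom", "preprocess", "radiomics", "networks", "selection",
                "classification", "interpretation", "attribution")


def run_pipeline(config: PipelineConfig, out_dir: str | None = None,
                 until: str = "attribution") -> PipelineReport:
    if until not in _STAGE_ORDER:
        raise ValueError(f"unknown stage {until!r}; expected one of {_STAGE_ORDER}")
    stop_at = _STAGE_ORDER.index(until)

    def _partial(**kwargs) -> PipelineReport:
        base = dict(seed=config.seed, config_hash=config_hash(config), classes=classes,
                    n_subjects={}, n_radiomics_candidates=0, stage_counts={},
                    selected={}, metrics={}, concordance={}, attribution={})
        base.update(kwargs)
        return PipelineReport(**base)

    ph = config.phantom
    classes = list(ph.classes)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(8) % (2 ** 31 - 1)]

    with _stage("phantom"):
        base_spec = phantom.CohortSpec(
            counts={c: ph.n_train_per_class for c in classes}, cohort_id="A_train",
            grid_shape=ph.grid_shape, spacing=ph.spacing, fwhm_mm=ph.fwhm_mm,
            noise_sd=ph.noise_sd, atlas_seed=ph.atlas_seed)
        test_spec = replace(base_spec, counts={c: ph.n_test_per_class for c in classes},
                            cohort_id="A_test")
        b_spec = replace(base_spec, counts={c: ph.n_cohort_b_per_class for c in classes},
                         cohort_id="B_train", gain=ph.cohort_b_gain,
                         noise_sd=ph.cohort_b_noise_sd,
                         effect_scale=ph.cohort_b_effect_scale)
        cohort_tr = phantom.simulate_cohort(base_spec, seed=seeds[0])
        cohort_te = phantom.simulate_cohort(test_spec, seed=seeds[1])
        cohort_b = phantom.simulate_cohort(b_spec, seed=seeds[2])
        atlas = cohort_tr.atlas
        logger.info("cohorts: A_train=%d A_test=%d B_train=%d",
                    len(cohort_tr.subjects), len(cohort_te.subjects), len(cohort_b.subjects))

    if stop_at < 1:
        n_sub = {"A_train": len(cohort_tr.subjects), "A_test": len(cohort_te.subjects),
                 "B_train": len(cohort_b.subjects)}
        artifacts = {}
        if out_dir:
            os.makedirs(out_dir, exist_ok=True)
            write_labels(atlas, ph.spacing, os.path.join(out_dir, "atlas.nii"))
            manifests = []
            for cohort in (cohort_tr, cohort_te, cohort_b):
                for s in cohort.subjects:
                    write_volume(s.volume, os.path.join(out_dir, f"{s.subject_id}.nii"))
                man = cohort.manifest()
                man["seed"] = cohort.seed
                manifests.append(man)
            pd.concat(manifests).to_csv(os.path.join(out_dir, "manifest.tsv"),
                                        sep="\t", index=False)
            artifacts = {"atlas": os.path.join(out_dir, "atlas.nii"),
                         "manifest": os.path.join(out_dir, "manifest.tsv")}
        return _partial(n_subjects=n_sub, artifacts=artifacts)

    with _stage("preprocess"):
        prep_tr = _PreparedCohort(cohort_tr, config.localnet.input_shape, config.globalnet.input_shape)
        prep_te = _PreparedCohort(cohort_te, config.localnet.input_shape, config.globalnet.input_shape)
        prep_b = _PreparedCohort(cohort_b, config.localnet.input_shape, config.globalnet.input_shape)
        del cohort_tr, cohort_te, cohort_b

    with _stage("radiomics"):
        rc = config.radiomics
        t_tr = extract_table(prep_tr.as_cohort(), atlas, rc.families, rc.bin_width)
        t_te = extract_table(prep_te.as_cohort(), atlas, rc.families, rc.bin_width)
        t_b = extract_table(prep_b.as_cohort(), atlas, rc.families, rc.bin_width)
        n_candidates = t_tr.data.shape[1]
        norm_tr = normalize_table(t_tr, t_tr, "A_train")
        norm_te = normalize_table(t_te, t_tr, "A_train")
        norm_b = normalize_table(t_b, t_b, "B_train")
        logger.info("radiomics: %d candidate columns", n_candidates)

    if stop_at < 3:
        artifacts = {}
        if out_dir:
            os.makedirs(out_dir, exist_ok=True)
            for name, tab in (("A_train", norm_tr), ("A_test", norm_te), ("B_train", norm_b)):
                p = os.path.join(out_dir, f"radiomics_{name}.tsv")
                tab.to_tsv(p)
                artifacts[f"radiomics_{name}"] = p
        return _partial(n_subjects={"A_train": len(prep_tr.ids), "A_test": len(prep_te.ids),
                                    "B_train": len(prep_b.ids)},
                        n_radiomics_candidates=int(n_candidates), artifacts=artifacts)

    with _stage("networks"):
        local_net = LocalEncoder(config.localnet, seed=seeds[3])
        train_network(local_net, prep_tr.local_inputs, list(prep_tr.labels),
                      replace(config.local_train, seed=seeds[3]))
        global_net = GlobalEncoder(config.globalnet, seed=seeds[4])
        train_global_network(global_net, prep_tr.zvols, list(prep_tr.labels),
                             replace(config.global_train, seed=seeds[4]))
        loc_tr, glo_tr = _latent_frames(local_net, global_net, prep_tr)
        loc_te, glo_te = _latent_frames(local_net, global_net, prep_te)
        loc_b, glo_b = _latent_frames(local_net, global_net, prep_b)

    with _stage("selection"):
        common = [c for c in norm_tr.data.columns if c in set(norm_b.data.columns)]
        sel_cfg = replace(config.selection, seed=seeds[5])
        spec = selection.select_features(
            {"A": norm_tr.data[common], "B": norm_b.data[common]},
            {"A": prep_tr.labels, "B": prep_b.labels},
            local_latents=loc_tr, global_latents=glo_tr, latent_labels=prep_tr.labels,
            config=sel_cfg)
        logger.info("selection: %d radiomics + %d local + %d global",
                    len(spec.radiomics), len(spec.local), len(spec.global_))

    if stop_at < 5:
        return _partial(
            n_subjects={"A_train": len(prep_tr.ids), "A_test": len(prep_te.ids),
                        "B_train": len(prep_b.ids)},
            n_radiomics_candidates=int(n_candidates),
            stage_counts={k: int(v) for k, v in spec.audit.get("counts", {}).items()},
            selected={"radiomics": list(spec.radiomics), "local": list(spec.local),
                      "global": list(spec.global_)})

    with _stage("classification"):
        clf_spec = replace(config.classifier, seed=seeds[6])
        variants = {
            "radiomics": replace(spec, local=[], global_=[]),
            "radiomics_local": replace(spec, global_=[]),
            "radiomics_global": replace(spec, local=[]),
            "fused": spec,
        }
        metrics = {}
        models = {}
        fused_train = fused_test = None
        for name, vspec in variants.items():
            m_tr = fusion.fuse_features(norm_tr.data, loc_tr, glo_tr, vspec, prep_tr.labels)
            m_te = fusion.fuse_features(norm_te.data, loc_te, glo_te, vspec, prep_te.labels,
                                        latent_stats=m_tr.latent_stats)
            model = fusion.train_classifier(m_tr, spec=clf_spec)
            metrics[name] = fusion.evaluate(model, m_te).to_dict()
            models[name] = model
            if name == "fused":
                fused_train, fused_test = m_tr, m_te
        logger.info("fused macro AUC %.3f accuracy %.3f",
                    metrics["fused"]["macro_auc"], metrics["fused"]["accuracy"])

    if stop_at < 6:
        return _partial(
            n_subjects={"A_train": len(prep_tr.ids), "A_test": len(prep_te.ids),
                        "B_train": len(prep_b.ids)},
            n_radiomics_candidates=int(n_candidates),
            stage_counts={k: int(v) for k, v in spec.audit.get("counts", {}).items()},
            selected={"radiomics": list(spec.radiomics), "local": list(spec.local),
                      "global": list(spec.global_)},
            metrics=metrics)

    with _stage("interpretation"):
        ic = config.interpret
        rng = np.random.default_rng(seeds[7])
        bg_idx = rng.permutation(len(fused_train.data))[:ic.background_cap]
        background = fused_train.data.to_numpy()[bg_idx]
        pick_a = _subsample_per_class(prep_te.ids, prep_te.labels, ic.instances_per_class, classes)
        inst_a = fused_test.data.loc[pick_a].to_numpy()
        shap_a = interpret.explain_instances(models["fused"], background, inst_a,
                                             n_permutations=ic.n_permutations,
                                             seed=seeds[7], feature_names=spec.columns,
                                             class_names=classes)
        prof_a = interpret.importance_profile(shap_a)

        m_b = fusion.fuse_features(norm_b.data, loc_b, glo_b, spec, prep_b.labels)
        model_b = fusion.train_classifier(m_b, spec=clf_spec)
        bg_b = m_b.data.to_numpy()[rng.permutation(len(m_b.data))[:ic.background_cap]]
        pick_b = _subsample_per_class(prep_b.ids, prep_b.labels, ic.instances_per_class, classes)
        shap_b = interpret.explain_instances(model_b, bg_b, m_b.data.loc[pick_b].to_numpy(),
                                             n_permutations=ic.n_permutations,
                                             seed=seeds[7] + 1, feature_names=spec.columns,
                                             class_names=classes)
        prof_b = interpret.importance_profile(shap_b)
        conc = interpret.cohort_concordance(prof_a, prof_b)
        concordance = {c: {"pearson_r": float(conc.loc[c, "pearson_r"]),
                           "p_value": float(conc.loc[c, "p_value"])}
                       for c in conc.index}

    with _stage("attribution"):
        planted = _planted_regions(base_spec.resolved_effects())
        class_idx = {c: i for i, c in enumerate(sorted(classes))}
        attribution: dict = {"layer_cam": {}, "rollout": {}}
        group_maps: dict = {}
        for c in classes:
            subj = [i for i, l in enumerate(prep_te.labels) if l == c][:ic.maps_per_class]
            cams = [layer_cam(local_net, prep_te.local_inputs[i], class_idx[c],
                              layer=ic.cam_layer, target_shape=ph.grid_shape,
                              spacing=ph.spacing) for i in subj]
            rolls = [rollout_map(global_net, prep_te.zvols[i], target_shape=ph.grid_shape,
                                 spacing=ph.spacing) for i in subj]
            gcam = interpret.group_average_map(cams)
            groll = interpret.group_average_map(rolls)
            group_maps[c] = {"layer_cam": gcam, "rollout": groll}
            attribution["layer_cam"][c] = _region_contrast(gcam, atlas, planted[c])
            attribution["rollout"][c] = _region_contrast(groll, atlas, planted[c])

    artifacts: dict = {}
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        write_labels(atlas, ph.spacing, os.path.join(out_dir, "atlas.nii"))
        artifacts["atlas"] = os.path.join(out_dir, "atlas.nii")
        for c, maps in group_maps.items():
            for src, amap in maps.items():
                p = os.path.join(out_dir, f"group_{src}_{c}.nii")
                write_volume(amap.as_volume(), p)
                artifacts[f"group_{src}_{c}"] = p
        sel_path = os.path.join(out_dir, "selected_features.tsv")
        pd.Series(spec.columns, name="feature").to_csv(sel_path, sep="\t", index=False)
        artifacts["selected_features"] = sel_path

    report = PipelineReport(
        seed=config.seed,
        config_hash=config_hash(config),
        classes=classes,
        n_subjects={"A_train": len(prep_tr.ids), "A_test": len(prep_te.ids),
                    "B_train": len(prep_b.ids)},
        n_radiomics_candidates=int(n_candidates),
        stage_counts={k: int(v) for k, v in spec.audit.get("counts", {}).items()},
        selected={"radiomics": list(spec.radiomics), "local": list(spec.local),
                  "global": list(spec.global_)},
        metrics=metrics,
        concordance=concordance,
        attribution=attribution,
        artifacts=artifacts,
    )
    if out_dir:
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            fh.write(report.to_json())
    return report
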