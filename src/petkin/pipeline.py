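"""End-to-end orchestration: simulate -> fit input -> quantify -> extract ->
regional stats -> association mapping, reproducible from a config + seed."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, input_function, kinetics, mapping, regional, synthetic
from .errors import ConfigurationError, DataError

log = logging.getLogger("petkin")


@dataclass
class RunConfig:
    """Serializable description of one full synthetic-cohort run."""

    out_dir: str = "petkin_run"
    seed: int = 0
    n_female: int = 10
    n_male: int = 11
    n_arterial: int = 4
    noise_fraction: float = 0.02
    blood_noise_fraction: float = 0.03
    t_star: float = kinetics.DEFAULT_T_STAR
    k2_prime: object = "estimate"         # "estimate" or a float (1/min)
    alpha: float = 0.05
    p_uncorrected: float = 0.001
    min_extent_mm3: float = 80.0
    n_perm: int = 1000
    atlas_shape: tuple = (24, 28, 24)
    trait_links: tuple = synthetic.CohortSpec().trait_links

    def validate(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ConfigurationError("alpha must lie in (0, 1]")
        if not (0 < self.p_uncorrected < 1):
            raise ConfigurationError("p_uncorrected must lie in (0, 1)")
        if self.noise_fraction < 0 or self.blood_noise_fraction < 0:
            raise ConfigurationError("noise fractions must be >= 0")
        if self.n_female < 0 or self.n_male < 0 or self.n_arterial < 0:
            raise ConfigurationError("cohort counts must be >= 0")
        if not isinstance(self.k2_prime, str) and float(self.k2_prime) <= 0:
            raise ConfigurationError("k2_prime must be positive or 'estimate'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _simulate_arterial_cohort(cfg: RunConfig, sched, aif, hill, rng):
    """Arterially sampled subjects with fitted input models."""
    studies = []
    regional_params = {r: synthetic.tcm_for_bpnd(m[1])
                       for r, m in synthetic.default_region_means().items()}
    for i in range(cfg.n_arterial):
        subj = synthetic.simulate_arterial_subject(
            regional_params, aif, hill, sched,
            sample_times=core.ARTERIAL_SAMPLE_TIMES,
            parent_times=core.VENOUS_SAMPLE_TIMES,
            noise_fraction=cfg.blood_noise_fraction,
            seed=int(rng.integers(0, 2 ** 31)), subject_id=f"art-{i + 1:03d}")
        model = input_function.fit_input_model(
            subj.plasma_samples, *subj.parent_fraction_samples,
            seed=int(rng.integers(0, 2 ** 31)), route="arterial")
        studies.append(kinetics.ArterialStudy(subj.id, subj.regional_tacs,
                                              model, sched))
    return studies


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the output manifest."""
    config.validate()
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(config).items()
                           if k != "trait_links"},
                "files": {}, "resolved": {}}

    # --- stage: simulate -------------------------------------------------
    sched = core.make_study_schedule()
    aif = synthetic.AifParams()
    hill = synthetic.HillParams()
    atlas = synthetic.make_synthetic_atlas(tuple(config.atlas_shape))
    spec = synthetic.CohortSpec(
        n_female=config.n_female, n_male=config.n_male,
        noise_fraction=config.noise_fraction, trait_links=config.trait_links,
        seed=int(rng.integers(0, 2 ** 31)))
    cohort = synthetic.generate_cohort(spec, atlas, image_mode="dynamic",
                                       aif=aif, schedule=sched)
    core.write_atlas(atlas, out / "atlas.nii")
    core.write_cohort_table(cohort.records, out / "cohort.csv")
    cohort.truth.to_csv(out / "truth_bpnd.csv", index=False)
    manifest["files"]["atlas"] = "atlas.nii"
    manifest["files"]["cohort"] = "cohort.csv"
    manifest["files"]["truth"] = "truth_bpnd.csv"
    log.info("simulated %d subjects in %.1fs", len(cohort.records), time.time() - t0)

    # --- stage: input function + k2' -------------------------------------
    arterial = _simulate_arterial_cohort(config, sched, aif, hill, rng)
    if config.k2_prime == "estimate":
        if arterial:
            k2p = kinetics.estimate_k2_prime(arterial)
        else:
            k2p = kinetics.DEFAULT_K2_PRIME
            log.warning("no arterial subjects: falling back to k2' = %.3f", k2p)
    else:
        k2p = float(config.k2_prime)
    manifest["resolved"]["k2_prime"] = k2p
    manifest["resolved"]["t_star"] = config.t_star

    if arterial:
        regions = [r for r in atlas.name_map.values() if r != "cerebellum"]
        xval_df, xval = kinetics.crossvalidate_vt_normalization(
            arterial, regions, t_star=config.t_star, k2_prime=k2p)
        xval_df.to_csv(out / "vt_normalization.csv", index=False)
        manifest["files"]["vt_normalization"] = "vt_normalization.csv"
        manifest["resolved"]["vt_vs_bpnd_mean_pct"] = xval["cohort_mean_pct"]
        manifest["resolved"]["vt_vs_bpnd_sd_pct"] = xval["cohort_sd_pct"]

    # --- stage: quantify --------------------------------------------------
    bpnd_images = {}
    for sid, dyn in cohort.dynamic_images.items():
        pim = kinetics.parametric_bpnd_image(dyn, atlas, k2p, config.t_star)
        bpnd_images[sid] = pim
        core.write_dynamic_image(dyn, out / f"{sid}_dynamic.nii")
        import nibabel as nib
        nib.save(nib.Nifti1Image(pim.bpnd_voxels, pim.affine),
                 str(out / f"{sid}_bpnd.nii"))
        manifest["files"][f"bpnd_{sid}"] = f"{sid}_bpnd.nii"

    # --- stage: extract + regional stats ---------------------------------
    table = regional.build_regional_table(bpnd_images, atlas, cohort.records)
    table.to_csv(out / "regional_bpnd.csv", index=False)
    manifest["files"]["regional_table"] = "regional_bpnd.csv"
    sex_tests = regional.sex_difference_tests(table)
    sex_tests.to_csv(out / "sex_differences.csv", index=False)
    manifest["files"]["sex_differences"] = "sex_differences.csv"

    regressions = []
    for link in config.trait_links:
        reg_name = link.region if link.region in set(table["region"]) else "thalamus"
        res = regional.voi_trait_regression(table, cohort.records, link.trait,
                                            reg_name, sex_filter=link.sex)
        regressions.append({"trait": res.trait, "region": res.region,
                            "sex": link.sex, "r2": res.r2, "p": res.p,
                            "direction": res.direction,
                            "target_r2": link.target_r2})
    pd.DataFrame(regressions).to_csv(out / "trait_regressions.csv", index=False)
    manifest["files"]["trait_regressions"] = "trait_regressions.csv"

    # --- stage: association mapping --------------------------------------
    sex_of = {r.id: r.sex for r in cohort.records}
    f_ids = [r.id for r in cohort.records if r.sex == "F"]
    baq = [r.baq_total for r in cohort.records if r.sex == "F"]
    fwe = mapping.fwe_smallvolume(
        [bpnd_images[s] for s in f_ids], baq,
        atlas.mask("amygdala_L") | atlas.mask("amygdala_R"),
        n_perm=config.n_perm, alpha=config.alpha,
        seed=int(rng.integers(0, 2 ** 31)), affine=atlas.affine,
        trait="baq_total")
    manifest["resolved"]["amygdala_fwe_significant_voxels"] = fwe["n_significant"]

    coop = [r.tci["cooperativeness"] for r in cohort.records]
    amap = mapping.voxelwise_glm([bpnd_images[r.id] for r in cohort.records],
                                 coop, atlas.labels > 0, affine=atlas.affine,
                                 trait="cooperativeness")
    clusters = mapping.cluster_threshold(amap, config.p_uncorrected,
                                         config.min_extent_mm3)
    pd.DataFrame([{"trait": c.trait, "direction": c.direction,
                   "x": c.peak_xyz_mm[0], "y": c.peak_xyz_mm[1],
                   "z": c.peak_xyz_mm[2], "peak_z": c.peak_z,
                   "size_mm3": c.size_mm3} for c in clusters]
                 ).to_csv(out / "clusters_cooperativeness.csv", index=False)
    manifest["files"]["clusters"] = "clusters_cooperativeness.csv"

    manifest["n_subjects"] = len(cohort.records)
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    manifest["files"]["manifest"] = "manifest.json"
    return manifest


def recovery_report(manifest: dict) -> dict:
    """Truth-versus-estimate scorecard for a simulated run."""
    out = Path(manifest["config"]["out_dir"])
    truth_path = out / manifest["files"].get("truth", "")
    if not truth_path.exists():
        raise ConfigurationError("manifest has no ground-truth table")
    truth = pd.read_csv(truth_path)
    est = pd.read_csv(out / manifest["files"]["regional_table"])
    merged = est.merge(truth, on=["subject", "region"], how="inner")
    if merged.empty:
        raise DataError("estimate/truth tables do not align")
    nonzero = merged[merged["bpnd_truth"] > 0.05]
    rel_err = ((nonzero["bpnd"] - nonzero["bpnd_truth"]).abs()
               / nonzero["bpnd_truth"])
    report = {
        "n_rows": int(len(merged)),
        "median_rel_err_pct": float(100 * rel_err.median()),
        "max_rel_err_pct": float(100 * rel_err.max()),
        "k2_prime": manifest["resolved"]["k2_prime"],
    }
    if "vt_vs_bpnd_mean_pct" in manifest["resolved"]:
        report["vt_vs_bpnd_mean_pct"] = manifest["resolved"]["vt_vs_bpnd_mean_pct"]
    report["amygdala_fwe_significant_voxels"] = manifest["resolved"].get(
        "amygdala_fwe_significant_voxels")
    return report
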