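"""End-to-end orchestration with config, seeds and standard-format outputs.

``run_full`` chains the stages on synthetic inputs: image generation ->
segmentation -> CAM decomposition -> subregion feature extraction for a
small imaging cohort, then a linked cohort analysis (univariate and
multivariate Cox with BH correction, optimal-cutoff stratification) and an
optional radiogenomic branch (module detection, module-feature correlation,
elastic-net signature, enrichment, signature transfer).  Every stage seed
is derived deterministically from the master seed and all parameters are
recorded in a provenance JSON.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, radiomics, segmentation, survival
from .cam import CamDecomposition
from .radiogenomics import (
    CoexpressionModules,
    ElasticNetSignature,
    filter_genes,
    hypergeometric_enrichment,
    module_feature_correlation,
)
from .synthetic import generate_cohort, generate_kinetic_curves, generate_mixture_image

logger = logging.getLogger("camrad")

__all__ = ["PipelineConfig", "run_full", "decompose_tumour", "stage_seed"]


@dataclass
class PipelineConfig:
    """All stage parameters with the pipeline defaults.

    Unknown keys in a YAML config are rejected; a round-trip through
    ``to_yaml``/``from_yaml`` is identity.
    """

    seed: int = 0
    # synthetic image stage
    n_imaging_subjects: int = 3
    image_shape: tuple = (14, 14, 8)
    timepoints: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.5)
    n_compartments: int = 3
    select_j: bool = False
    dirichlet_alpha: tuple = (1.0, 1.0, 1.0)
    corner_fraction: float = 0.05
    noise_sigma: float = 0.02
    nontrivial_threshold: float = 1e-2
    # survival stage
    endpoint: str = "rfs"
    n_cohort_subjects: int = 150
    survival_beta: float = 0.7
    censor_rate: float = 0.3
    fdr_level: float = 0.1
    prune_r: float = 0.7
    # radiogenomic stage
    run_radiogenomics: bool = True
    n_genes: int = 1000
    module_sizes: tuple = (80, 70, 60)
    target_r: float = 0.59
    module_power: int = 5
    module_min_size: int = 60
    module_merge_height: float = 0.25
    top_corr_genes: int = 100
    elastic_net_folds: int = 10

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                v = data[f.name]
                kwargs[f.name] = tuple(v) if isinstance(f.default, tuple) else v
        return cls(**kwargs)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    import zlib

    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode()) % 2**31])
    return int(ss.generate_state(1)[0] % 2**31)


def decompose_tumour(tumour, config: PipelineConfig):
    """Segment (from the true mask's centre), decompose and extract features."""
    pre = tumour.image[0]
    early = tumour.image[1]
    late = tumour.image[-1]
    enhancement = early - pre
    centre = tuple(int(round(c)) for c in np.argwhere(tumour.mask).mean(axis=0))
    try:
        mask = segmentation.extract_tumour_mask(
            enhancement, centre, min_size=4, seed=stage_seed(config.seed, "fcm")
        )
    except segmentation.SeedOutsideLesionError:
        logger.warning("segmentation failed; falling back to the generator mask")
        mask = tumour.mask
    X = tumour.image[:, mask].T
    cam = CamDecomposition(
        n_compartments=config.n_compartments,
        select_j=config.select_j,
        random_state=stage_seed(config.seed, "cam"),
    ).fit(X, timepoints=np.asarray(config.timepoints))
    sub = cam.subregions(config.nontrivial_threshold)
    series = radiomics.build_series(pre, early, late)
    regions = {"whole_tumour": mask}
    for role, member in sub.masks.items():
        vol_mask = np.zeros_like(mask)
        vol_mask[mask] = member
        regions[role] = vol_mask
    features = radiomics.feature_table(series, regions)
    return mask, cam, features


def _imaging_stage(config: PipelineConfig, out_dir: Path) -> pd.DataFrame:
    curves = generate_kinetic_curves(
        config.n_compartments, config.timepoints, seed=stage_seed(config.seed, "curves")
    )
    tables = []
    for i in range(config.n_imaging_subjects):
        tumour = generate_mixture_image(
            curves,
            shape=tuple(config.image_shape),
            dirichlet_alpha=tuple(config.dirichlet_alpha),
            corner_fraction=config.corner_fraction,
            noise_sigma=config.noise_sigma,
            seed=stage_seed(config.seed, f"tumour{i}"),
        )
        mask, cam, features = decompose_tumour(tumour, config)
        features.insert(0, "subject", f"subj{i:03d}")
        tables.append(features)
        if i == 0:
            io.write_series(out_dir / "example_series.nii.gz", tumour.image,
                            timepoints=config.timepoints)
            io.write_nifti(out_dir / "example_mask.nii.gz", mask)
            io.write_table(out_dir / "example_curves.tsv",
                           pd.DataFrame(cam.curves_, index=list(cam.roles_),
                                        columns=[f"t{j}" for j in range(cam.curves_.shape[1])]))
            io.write_table(out_dir / "example_proportions.tsv",
                           pd.DataFrame(cam.proportions_, columns=list(cam.roles_)))
    feature_table = pd.concat(tables).rename_axis("region").reset_index()
    io.write_table(out_dir / "imaging_features.tsv", feature_table, index=False)
    return feature_table


def _cohort_stage(config: PipelineConfig, out_dir: Path) -> dict:
    cohort = generate_cohort(
        n_subjects=config.n_cohort_subjects,
        n_genes=config.n_genes,
        module_sizes=tuple(config.module_sizes),
        target_r=config.target_r,
        survival_beta=config.survival_beta,
        censor_rate=config.censor_rate,
        seed=stage_seed(config.seed, "cohort"),
    )
    feature = cohort.features.iloc[:, 0]
    fit = survival.cox_univariate(feature, cohort.survival)
    cut = survival.optimal_cutoff(feature.to_numpy(), cohort.survival)
    io.write_table(out_dir / "survival.tsv", pd.concat([cohort.features, cohort.survival], axis=1))
    results = {
        "cox": {"beta": fit.beta, "hr": fit.hr, "ci95": list(fit.ci95), "p": fit.p,
                "c_index": fit.c_index},
        "optimal_cutoff": {"threshold": cut.threshold, "logrank_chi2": cut.logrank_chi2,
                           "logrank_p": cut.logrank_p, "group_sizes": list(cut.group_sizes)},
    }

    if config.run_radiogenomics:
        expr = filter_genes(cohort.expression, top_k=config.n_genes)
        modules = CoexpressionModules(
            power=config.module_power,
            min_size=config.module_min_size,
            merge_height=config.module_merge_height,
        ).fit(expr)
        io.write_table(out_dir / "module_assignments.tsv",
                       modules.assignments_.rename("module").to_frame())
        if len(modules.eigengenes_):
            io.write_table(out_dir / "eigengenes.tsv", modules.eigengenes_)
            corr = module_feature_correlation(modules.eigengenes_, cohort.features)
            io.write_table(out_dir / "module_feature_correlation.tsv", corr, index=False)
            best = corr.loc[corr["r"].abs().idxmax()]
            results["modules"] = {"n_modules": int(len(modules.eigengenes_)),
                                  "best_module": str(best["module"]),
                                  "best_r": float(best["r"])}
        sig = ElasticNetSignature(
            top_corr_genes=config.top_corr_genes,
            folds=config.elastic_net_folds,
            random_state=stage_seed(config.seed, "enet"),
        ).fit(expr, feature)
        io.write_json(out_dir / "signature.json", {
            "genes": sig.signature_, "coefficients": list(sig.coef_),
            "intercept": sig.intercept_, "alpha": sig.l1_ratio_, "lambda": sig.lambda_,
            "r2": sig.r2_,
        })
        results["signature"] = {"n_genes": len(sig.signature_), "r2": sig.r2_,
                                "alpha": sig.l1_ratio_, "lambda": sig.lambda_}
        module_sets = {m: list(modules.assignments_.index[modules.assignments_ == m])
                       for m in modules.eigengenes_.index}
        if module_sets:
            enrich = hypergeometric_enrichment(sig.signature_, module_sets, list(expr.index))
            io.write_table(out_dir / "signature_module_enrichment.tsv", enrich)
    return results


def run_full(config: PipelineConfig, out_dir) -> dict:
    """Run every stage; partial outputs are retained on stage failure."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {"config": config.to_dict(), "stages": []}
    results: dict = {}
    stages = [("imaging", lambda: _imaging_stage(config, out_dir)),
              ("cohort", lambda: _cohort_stage(config, out_dir))]
    for name, fn in stages:
        logger.info("running stage %s", name)
        try:
            out = fn()
        except Exception as exc:  # pragma: no cover - error path
            io.write_json(out_dir / "provenance.json", provenance)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        provenance["stages"].append(name)
        if isinstance(out, dict):
            results.update(out)
    io.write_json(out_dir / "provenance.json", provenance)
    io.write_json(out_dir / "results.json", results)
    return results
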