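"""End-to-end orchestration: simulate → segment → map → test → cohort stats.

A run is driven by a single config (YAML on disk or a RunConfig in
memory), writes every artifact under one output directory, and records a
manifest with the config, the seed, software versions, and a deterministic
checksum per artifact (computed over array/CSV bytes, not file metadata),
so a rerun with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import BinaryMask, InvalidSpecError
from .mapping import (
    MatchSpec,
    build_probability_map,
    match_samples,
    percent_voxels_different,
    standardized_mean_difference,
    threshold_difference_map,
    voxel_test_with_fdr,
)
from .segmentation import SegmentationParams, compute_brain_mask, segment_wmh
from .stats import build_model_designs, logistic_fit, univariable_table
from .synthetic import CohortSpec, PhantomSpec, generate_brain_phantom, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """One reproducible run. Inputs are simulated from the specs below;
    alternatively `cohort_csv` points at an existing table (exactly one
    source per input)."""

    out_dir: str = "wmhkit_run"
    seed: int = 0
    n_subjects_per_group: int = 12
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    cohort_csv: str | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    match: MatchSpec = field(default_factory=MatchSpec)
    q: float = 0.05
    diff_thr_a: float = 0.75
    diff_thr_b: float = 0.60
    write_nifti: bool = True

    def validate(self) -> None:
        if self.n_subjects_per_group < 2:
            raise InvalidSpecError("need at least 2 subjects per group")
        self.phantom.validate()
        self.cohort.validate()
        self.segmentation.validate()
        self.match.validate()


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file of (nested) overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    for key, cls in (
        ("phantom", PhantomSpec),
        ("cohort", CohortSpec),
        ("segmentation", SegmentationParams),
        ("match", MatchSpec),
    ):
        if key in kwargs and isinstance(kwargs[key], dict):
            sub = kwargs[key]
            for tup in ("grid_shape", "voxel_size_mm", "lesion_radius_range_mm",
                        "exact_vars"):
                if tup in sub and isinstance(sub[tup], list):
                    sub[tup] = tuple(sub[tup])
            kwargs[key] = cls(**sub)
    return RunConfig(**kwargs)


def _sha(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    Stage failures abort with the stage name prepended to the cause.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "software": {"wmhkit": __version__, "numpy": np.__version__},
        "seed": config.seed,
        "stages": {},
        "checksums": {},
    }

    current_stage = "setup"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        t0 = time.perf_counter()

        def done(**info):
            manifest["stages"][name] = {
                "elapsed_s": round(time.perf_counter() - t0, 3), **info
            }

        return done

    try:
        # -- cohort ----------------------------------------------------------
        done = stage("cohort")
        if config.cohort_csv is not None:
            cohort = pd.read_csv(config.cohort_csv)
        else:
            cohort = generate_cohort(config.cohort)
        cohort_path = out / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        manifest["checksums"]["cohort.csv"] = _sha(
            cohort.to_csv(index=False).encode()
        )
        done(n_rows=len(cohort))

        # -- phantoms + segmentation -----------------------------------------
        done = stage("segmentation")
        group_masks: dict[str, list[BinaryMask]] = {"A": [], "B": []}
        pct_icv: dict[str, list[float]] = {"A": [], "B": []}
        for gname in ("A", "B"):
            for _ in range(config.n_subjects_per_group):
                subject_seed = int(rng.integers(2**31 - 1))
                spec = replace(config.phantom, seed=subject_seed)
                flair, truth, icv, excl = generate_brain_phantom(spec)
                brain = compute_brain_mask(flair)
                res = segment_wmh(
                    flair, brain, exclusions=[excl], params=config.segmentation
                )
                group_masks[gname].append(res.wmh_mask)
                pct_icv[gname].append(res.wmh_pct_icv)
        done(
            n_per_group=config.n_subjects_per_group,
            median_pct_icv={
                g: float(np.median(v)) for g, v in pct_icv.items()
            },
        )
        manifest["wmh_pct_icv"] = {
            g: float(np.median(v)) for g, v in pct_icv.items()
        }

        # -- probability maps ------------------------------------------------
        done = stage("probability_maps")
        maps = {g: build_probability_map(m) for g, m in group_masks.items()}
        for g, pm in maps.items():
            if config.write_nifti:
                pm.save(out / f"probmap_{g}.nii.gz")
            manifest["checksums"][f"probmap_{g}.nii.gz"] = _sha(
                pm.values.tobytes()
            )
        done()

        # -- matching --------------------------------------------------------
        done = stage("matching")
        match = match_samples(cohort, "phenotype", config.match)
        match.pairs.to_csv(out / "matched_pairs.csv", index=False)
        manifest["checksums"]["matched_pairs.csv"] = _sha(
            match.pairs.to_csv(index=False).encode()
        )
        smd = {
            var: standardized_mean_difference(cohort, match, var)
            for var, _ in config.match.continuous_vars
        } if match.n_pairs else {}
        done(n_pairs=match.n_pairs, smd=smd)

        # -- voxel-wise comparison -------------------------------------------
        done = stage("voxel_tests")
        vt = voxel_test_with_fdr(
            group_masks["A"], group_masks["B"], q=config.q
        )
        diff = threshold_difference_map(
            maps["A"], maps["B"], config.diff_thr_a, config.diff_thr_b
        )
        if config.write_nifti:
            import nibabel as nib

            affine = maps["A"].affine
            nib.save(nib.Nifti1Image(vt.p_map.astype(np.float32), affine),
                     str(out / "p_map.nii.gz"))
            nib.save(nib.Nifti1Image(vt.q_map.astype(np.float32), affine),
                     str(out / "q_map.nii.gz"))
            vt.significant.save(out / "significant.nii.gz")
            nib.save(nib.Nifti1Image(diff, affine),
                     str(out / "difference_map.nii.gz"))
        for name, arr in (
            ("p_map.nii.gz", vt.p_map),
            ("q_map.nii.gz", vt.q_map),
            ("difference_map.nii.gz", diff),
        ):
            manifest["checksums"][name] = _sha(np.ascontiguousarray(arr).tobytes())
        pct_diff = (
            percent_voxels_different(vt.significant, vt.analysis_mask)
            if vt.analysis_mask.n_voxels else 0.0
        )
        manifest["percent_voxels_different"] = pct_diff
        done(percent_voxels_different=pct_diff)

        # -- cohort statistics -----------------------------------------------
        done = stage("cohort_stats")
        uni = univariable_table(cohort)
        uni.to_csv(out / "univariable.csv", index=False)
        manifest["checksums"]["univariable.csv"] = _sha(
            uni.to_csv(index=False).encode()
        )
        X1, X2, y1, y2, selected = build_model_designs(cohort)
        frames = []
        for label, X, y in (("model1", X1, y1), ("model2", X2, y2)):
            fit = logistic_fit(y, X)
            fr = fit.to_frame()
            fr.insert(0, "model", label)
            frames.append(fr)
        models = pd.concat(frames, ignore_index=True)
        models.to_csv(out / "models.csv", index=False)
        manifest["checksums"]["models.csv"] = _sha(
            models.to_csv(index=False).encode()
        )
        done(model2_selected=selected)
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed in stage {current_stage!r}: {err}"
        ) from err

    if "A" in manifest["wmh_pct_icv"]:
        manifest["wmh_pct_icv_median"] = manifest["wmh_pct_icv"]["A"]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
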