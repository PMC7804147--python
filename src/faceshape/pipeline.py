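"""End-to-end orchestration of the shape-scoring and preference analyses.

A run takes either synthetic data (generated with full ground truth) or
user-supplied files, and produces per face sex: the score table, interrater
agreement per rater group, group-mean ratings, the Pearson correlation
screen, the mixed-effects preference model with rater-group contrasts, and
one path-model fit per rater group (six in total).  A machine-readable
manifest records versions, seed, config hash and stage timings.

One global seed fans out to per-stage substreams (data generation,
permutation tests) so that disabling one stage never shifts another's
randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import faceshape
from faceshape import landmark_io
from faceshape.landmark_io import ValidationError
from faceshape.path_model import PathSpec, permutation_pvalues, to_dot
from faceshape.preference_models import (
    PreferenceModelSpec,
    fit_preference_model,
    group_contrasts,
)
from faceshape.rating_analysis import (
    cronbach_alpha,
    correlation_screen,
    group_mean_ratings,
    rater_by_face_matrix,
)
from faceshape.shape_scores import score_table
from faceshape.synthetic_data import SyntheticConfig, simulate_faces, simulate_ratings

__all__ = ["RunConfig", "run", "PipelineError"]

CONTRAST_FAMILIES = ("intercept", "age", "bmi", "avrg", "sshd")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    landmarks_path: str | None = None
    sliders_path: str | None = None
    covariates_path: str | None = None
    ratings_path: str | None = None
    gpa_max_iter: int = 20
    gpa_tol: float = 1e-8
    sliding: bool = True
    run_alpha: bool = True
    run_correlations: bool = True
    run_mixed_model: bool = True
    run_contrasts: bool = True
    run_path: bool = True
    n_perm: int = 10_000
    seed: int = 0
    out_dir: str = "faceshape_results"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValidationError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if self.mode == "files":
            for name in ("landmarks_path", "covariates_path", "ratings_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValidationError(f"files mode requires {name}")
                if not Path(p).exists():
                    raise ValidationError(f"{name} does not exist: {p}")
            if self.sliding and self.sliders_path is None:
                raise ValidationError("sliding enabled but no sliders_path given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", {})
        cfg = cls(**raw)
        if synth:
            for key in ("group_weights", "n_raters_per_group"):
                if key in synth:
                    synth[key] = dict(synth[key])
            for key in ("cutpoints", "age_range"):
                if key in synth:
                    synth[key] = tuple(synth[key])
            if "group_weights" in synth:
                synth["group_weights"] = {
                    g: tuple(w) for g, w in synth["group_weights"].items()
                }
            cfg.synthetic = SyntheticConfig(**synth)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _perm_seed(seed: int, index: int) -> int:
    state = np.random.SeedSequence(entropy=seed, spawn_key=(7, index)).generate_state(1)
    return int(state[0]) % (2**31)


def _load_inputs(config: RunConfig, out: Path, log: list[dict]):
    if config.mode == "synthetic":
        synth = dataclasses.replace(config.synthetic, seed=config.seed)
        configs, covariates, truth = simulate_faces(synth)
        from faceshape.synthetic_data import generate_template

        _, sliders = generate_template(synth.n_landmarks, synth.n_semilandmarks)
        landmark_io.write_tps(configs, out / "landmarks.tps")
        landmark_io.write_landmarks_csv(configs, out / "landmarks.csv")
        landmark_io.write_sliders_csv(sliders, out / "sliders.csv")
        covariates.to_csv(
            out / "covariates.csv", index=False, float_format=landmark_io.repr_float
        )
        truth.to_csv(out / "truth.csv", index=False, float_format=landmark_io.repr_float)
        (out / "synthetic_config.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(synth), sort_keys=True)
        )
        ratings = None  # generated after scoring (needs score table)
        return configs, sliders, covariates, ratings, synth
    configs = landmark_io.read_tps(config.landmarks_path) if str(
        config.landmarks_path
    ).endswith(".tps") else landmark_io.read_landmarks_csv(config.landmarks_path)
    sliders = (
        landmark_io.read_sliders_csv(config.sliders_path, n_landmarks=configs[0].k)
        if config.sliders_path
        else None
    )
    covariates = landmark_io.read_covariates_csv(config.covariates_path)
    ratings = landmark_io.read_ratings_csv(config.ratings_path)
    return configs, sliders, covariates, ratings, None


def run(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns the result bundle.

    All result tables are also written as CSV under ``config.out_dir``.
    Outputs are byte-identical across runs with the same config and seed
    (the manifest's timings excepted).  A failing stage raises
    :class:`PipelineError` naming the stage; partial outputs are kept and a
    ``FAILED`` marker names the stage in the output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    log: list[dict] = []
    t_start = time.time()
    stage = "setup"

    def _mark(stage_name: str, **info) -> None:
        log.append({"stage": stage_name, "elapsed_s": round(time.time() - t_start, 3), **info})

    try:
        stage = "load_inputs"
        configs, sliders, covariates, ratings, synth = _load_inputs(config, out, log)
        if not config.sliding:
            sliders = None
        _mark(stage, n_specimens=len(configs))

        stage = "shape_scores"
        scores = score_table(
            configs, covariates, sliders=sliders,
            max_iter=config.gpa_max_iter, tol=config.gpa_tol,
        )
        scores.to_csv(out / "scores.csv", index=False)
        results["scores"] = scores
        _mark(stage, n_rows=len(scores))

        if config.mode == "synthetic":
            stage = "simulate_ratings"
            ratings = simulate_ratings(scores, synth)
            ratings.to_csv(out / "ratings.csv", index=False)
            _mark(stage, n_rows=len(ratings))
        results["ratings"] = ratings

        for face_sex in ("F", "M"):
            tag = {"F": "female_faces", "M": "male_faces"}[face_sex]
            face_ids = set(scores.loc[scores["sex"] == face_sex, "specimen_id"])
            sub = ratings[ratings["face_id"].isin(face_ids)]
            if sub.empty:
                continue

            if config.run_alpha:
                stage = f"alpha_{tag}"
                rows = []
                for group in sorted(sub["rater_group"].unique()):
                    mat = rater_by_face_matrix(sub, rater_group=group)
                    complete = mat.dropna(axis=0)
                    rows.append(
                        {
                            "rater_group": group,
                            "n_raters_complete": len(complete),
                            "n_faces": mat.shape[1],
                            "alpha": cronbach_alpha(mat),
                        }
                    )
                alpha_df = pd.DataFrame(rows)
                alpha_df.to_csv(out / f"alpha_{tag}.csv", index=False)
                results[f"alpha_{tag}"] = alpha_df
                _mark(stage, n_groups=len(rows))

            stage = f"group_means_{tag}"
            gm = group_mean_ratings(sub)
            gm.to_csv(out / f"group_means_{tag}.csv", index=False)
            results[f"group_means_{tag}"] = gm
            _mark(stage, n_rows=len(gm))

            if config.run_correlations:
                stage = f"correlations_{tag}"
                corr = correlation_screen(
                    scores[scores["sex"] == face_sex], gm
                )
                corr.to_csv(out / f"correlations_{tag}.csv", index=False)
                results[f"correlations_{tag}"] = corr
                _mark(stage, n_pairs=len(corr))

            if config.run_mixed_model:
                stage = f"mixed_model_{tag}"
                mspec = PreferenceModelSpec(face_sex=face_sex)
                fit = fit_preference_model(sub, scores, mspec)
                fit.fixed_effects.to_csv(out / f"mixed_fixed_{tag}.csv", index=False)
                fit.random_effects.to_csv(out / f"mixed_random_{tag}.csv", index=False)
                results[f"mixed_model_{tag}"] = fit
                _mark(stage, n_obs=fit.n_obs, converged=fit.converged)
                if config.run_contrasts and fit.converged:
                    stage = f"contrasts_{tag}"
                    tables = [
                        group_contrasts(fit, fam).table for fam in CONTRAST_FAMILIES
                    ]
                    contrasts = pd.concat(tables, ignore_index=True)
                    contrasts.to_csv(out / f"contrasts_{tag}.csv", index=False)
                    results[f"contrasts_{tag}"] = contrasts
                    _mark(stage, n_rows=len(contrasts))

            if config.run_path:
                face_scores = scores[scores["sex"] == face_sex]
                for gi, group in enumerate(sorted(sub["rater_group"].unique())):
                    stage = f"path_{tag}_{group}"
                    attr = gm[gm["rater_group"] == group].set_index("face_id")[
                        "mean_rating"
                    ]
                    data = face_scores.set_index("specimen_id")[
                        ["age", "bmi", "sshd", "avrg"]
                    ].join(attr.rename("attractiveness"), how="inner")
                    pseed = _perm_seed(
                        config.seed, gi + {"F": 0, "M": 3}[face_sex]
                    )
                    pfit = permutation_pvalues(
                        data, PathSpec(), n_perm=config.n_perm, seed=pseed
                    )
                    pfit.edges.to_csv(out / f"path_{tag}_{group}.csv", index=False)
                    (out / f"path_{tag}_{group}.dot").write_text(to_dot(pfit))
                    results[f"path_{tag}_{group}"] = pfit
                    _mark(stage, n=pfit.n_observations, n_perm=config.n_perm)

        stage = "manifest"
        manifest = {
            "package": "faceshape",
            "version": faceshape.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "stages": log,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        results["manifest"] = manifest
        return results
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
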