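"""End-to-end orchestration: config, seeding, and the four pipeline runs.

A run is driven by a small YAML config (paths or generator specs per data
type, scoring flags, regression and VBM settings, one master seed).  Every
stochastic stage consumes a sub-seed derived from the master seed and the
stage name, so a full run is reproducible from the config alone; every
output file gets a sidecar ``<name>.meta.json`` recording the config hash
and the seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from semfluency import cohort_stats, synthetic, vbm_glm, vft_scoring
from semfluency.semantic_space import SemanticSpace, load_space
from semfluency.synthetic import (
    ClusterSpaceSpec,
    RetrievalPolicy,
    lambda_calibration,
    simulate_sequence,
)
from semfluency.vft_scoring import (
    FluencyScores,
    UndefinedScoreError,
    load_disallowed,
    read_transcripts_csv,
    score_transcript,
    write_scores_csv,
)

__all__ = [
    "load_config",
    "derive_seed",
    "resolve_space",
    "run_scoring",
    "run_cohort",
    "run_vbm",
    "calibrate_lambda",
    "run_calibration",
]

logger = logging.getLogger("semfluency")

COSINE_MODEL = ("samq", "n_correct", "age", "gender")


def load_config(path: str | Path) -> dict[str, Any]:
    with Path(path).open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ValueError("config must be a mapping")
    return dict(cfg)


def config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed: hash of stage name mixed with the master."""
    digest = hashlib.sha256(f"{stage}:{master_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def write_sidecar(
    out_path: str | Path, config: Mapping[str, Any], seed: int
) -> None:
    meta = {"config_hash": config_hash(config), "seed": seed}
    Path(str(out_path) + ".meta.json").write_text(
        json.dumps(meta, indent=2), encoding="utf-8"
    )


def resolve_space(config: Mapping[str, Any], master_seed: int) -> SemanticSpace:
    """Load a space from ``space.path`` or generate one from ``space.generate``."""
    section = config.get("space", {})
    has_path = "path" in section
    has_gen = "generate" in section
    if has_path == has_gen:
        raise ValueError("config must give exactly one of space.path / space.generate")
    if has_path:
        return load_space(section["path"])
    gen = dict(section["generate"])
    gen.setdefault("seed", derive_seed(master_seed, "space"))
    return synthetic.make_clustered_space(ClusterSpaceSpec(**gen))


def score_all(
    transcripts: Sequence[vft_scoring.Transcript],
    space: SemanticSpace,
    disallowed: Sequence[str] = (),
    duplicates: str = "later",
) -> tuple[list[FluencyScores], list[tuple[str, str]]]:
    """Score every transcript; undefined scores are collected, not raised."""
    scores: list[FluencyScores] = []
    failures: list[tuple[str, str]] = []
    for t in transcripts:
        try:
            scores.append(score_transcript(t, space, disallowed, duplicates))
        except UndefinedScoreError as exc:
            failures.append((t.participant_id, str(exc)))
            logger.warning("excluded %s: %s", t.participant_id, exc)
    return scores, failures


def run_scoring(config: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Score transcripts against the configured space; write the scores CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    space = resolve_space(config, seed)
    sc = config.get("scoring", {})
    transcripts = read_transcripts_csv(sc["transcripts"])
    disallowed = (
        load_disallowed(sc["disallowed"]) if sc.get("disallowed") else set()
    )
    scores, failures = score_all(
        transcripts, space, disallowed, sc.get("duplicates", "later")
    )
    if not transcripts:
        logger.warning("no transcripts found in %s", sc["transcripts"])
    out = out_dir / "scores.csv"
    write_scores_csv(scores, out)
    write_sidecar(out, config, seed)
    logger.info(
        "scoring: %d scored, %d excluded (undefined scores)",
        len(scores),
        len(failures),
    )
    return out


def run_cohort(
    config: Mapping[str, Any], out_dir: str | Path, scores_csv: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join scores with the cohort table and fit the two regressions.

    Model 1: mean cosine similarity ~ SAMQ + items + age + gender.
    Model 2: mean vector length  ~ SAMQ + items + age + gender.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    co = config.get("cohort", {})
    cohort = pd.read_csv(co["table"])
    if "samq" not in cohort.columns:
        raise ValueError("cohort table is missing the 'samq' column")
    if scores_csv is None:
        scores_csv = co.get("scores", out_dir / "scores.csv")
    scores = pd.read_csv(scores_csv)
    orphans = sorted(
        set(cohort["participant_id"]) ^ set(scores["participant_id"])
    )
    if orphans:
        raise ValueError(f"cohort/scores participant mismatch: {orphans}")
    merged = cohort.merge(
        scores[
            ["participant_id", "n_correct", "mean_vector_length", "mean_cosine_similarity"]
        ],
        on="participant_id",
    )
    tables = []
    for dv, fname in (
        ("mean_cosine_similarity", "regression_cosine.csv"),
        ("mean_vector_length", "regression_vector_length.csv"),
    ):
        result = cohort_stats.fit_model(merged, dv, COSINE_MODEL)
        frame = result.to_frame()
        out = out_dir / fname
        frame.to_csv(out, index=False)
        write_sidecar(out, config, seed)
        tables.append(frame)
    return tables[0], tables[1]


def run_vbm(
    config: Mapping[str, Any], out_dir: str | Path, cohort_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Voxelwise GLM with permutation FWE; writes maps and the cluster table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    vb = config.get("vbm", {})
    if cohort_table is None:
        cohort_table = pd.read_csv(vb["covariates"])
    paths = sorted(Path(vb["volumes_dir"]).glob("*.nii*"))
    stack = vbm_glm.load_volumes(paths)
    if stack.n != len(cohort_table):
        raise ValueError(
            f"{stack.n} volumes but {len(cohort_table)} cohort rows"
        )
    voxel_vol = float(abs(np.linalg.det(stack.affine[:3, :3])))
    table = cohort_table.copy()
    table["icv"] = vbm_glm.compute_icv(stack.data, voxel_vol)
    design = vbm_glm.GLMDesign.from_table(
        table,
        ["mean_cosine_similarity", "samq", "n_correct", "age", "gender", "icv"],
        interest="mean_cosine_similarity",
    )
    mask = vbm_glm.make_mask(stack, float(vb.get("mask_threshold", 0.1)))
    statmap = vbm_glm.permutation_fwe(
        stack,
        design,
        n_perm=int(vb.get("n_perm", 1000)),
        seed=derive_seed(seed, "vbm-perm"),
        mask=mask,
    )
    alpha = float(vb.get("alpha", 0.05))
    sig = vbm_glm.StatMap(
        t=np.where(statmap.p_fwe <= alpha, statmap.t, 0.0),
        mask=mask,
        affine=stack.affine,
        df_resid=statmap.df_resid,
    )
    clusters = vbm_glm.extract_clusters(sig, t_threshold=0.0)
    for name, img in (
        ("tmap.nii", statmap.t),
        ("p_fwe.nii", statmap.p_fwe),
        ("mask.nii", mask.astype(np.float64)),
    ):
        out = out_dir / name
        vbm_glm.save_map(img, stack.affine, out)
        write_sidecar(out, config, seed)
    out = out_dir / "clusters.csv"
    clusters.to_csv(out, index=False)
    write_sidecar(out, config, seed)
    logger.info(
        "vbm: %d in-mask voxels, %d significant clusters at alpha=%g",
        int(mask.sum()),
        len(clusters),
        alpha,
    )
    return clusters


def calibrate_lambda(
    space: SemanticSpace,
    target: float,
    policy: RetrievalPolicy | None = None,
    tol: float = 0.005,
    n_rep: int = 60,
    seed: int = 0,
    max_iter: int = 25,
) -> dict[str, float]:
    """Bisection on the organization parameter lambda to hit a target
    cohort-mean adjacent cosine.

    The Monte-Carlo objective uses common random numbers (the same
    per-replicate seeds at every lambda), so it is deterministic and
    monotone up to discretisation and bisection converges.  A target outside
    the achievable range [f(0), f(1)] raises an error reporting that
    interval.
    """
    if policy is None:
        policy = RetrievalPolicy(organization=0.5)
    rep_seeds = np.random.default_rng(seed).integers(2**31, size=n_rep)

    def objective(lam: float) -> float:
        pol = replace(policy, organization=lam)
        vals = []
        for s in rep_seeds:
            t = simulate_sequence(space, pol, int(s))
            coded = vft_scoring.code_sequence(t, space, synthetic.DEFAULT_DISALLOWED)
            m, _ = vft_scoring.mean_adjacent_cosine(coded, space)
            vals.append(m)
        return float(np.mean(vals))

    lo, hi = 0.0, 1.0
    f_lo, f_hi = objective(lo), objective(hi)
    if not (min(f_lo, f_hi) <= target <= max(f_lo, f_hi)):
        raise ValueError(
            f"target {target:.4f} outside achievable mean-cosine interval "
            f"[{min(f_lo, f_hi):.4f}, {max(f_lo, f_hi):.4f}]"
        )
    lam, achieved = lo, f_lo
    for _ in range(max_iter):
        lam = 0.5 * (lo + hi)
        achieved = objective(lam)
        if abs(achieved - target) < tol:
            break
        if (achieved < target) == (f_lo < f_hi):
            lo = lam
        else:
            hi = lam
    return {"lambda": lam, "achieved": achieved, "target": target, "tol": tol}


def fwer_null_experiment(
    n_datasets: int = 500,
    n_subjects: int = 40,
    shape: tuple[int, int, int] = (12, 12, 12),
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical any-voxel FWER of the permutation max-T procedure under a
    global null.

    Each dataset is pure Gaussian noise; the design holds an intercept plus
    six covariates (coherence score, SAMQ, item count, age, gender, ICV
    stand-ins) drawn independently of the data, with the contrast on the
    coherence score.  Returns the fraction of datasets in which any in-mask
    voxel reaches FWE-adjusted p < ``alpha``; with valid FWE control this
    fraction stays at or below ``alpha`` up to Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    names = ("intercept", "score", "samq", "items", "age", "gender", "icv")
    contrast = np.zeros(len(names))
    contrast[1] = 1.0
    hits = 0
    for _ in range(n_datasets):
        data = rng.normal(size=(n_subjects, *shape))
        X = np.column_stack(
            [np.ones(n_subjects), rng.normal(size=(n_subjects, len(names) - 1))]
        )
        design = vbm_glm.GLMDesign(X, names, contrast)
        mask = np.ones(shape, dtype=bool)
        statmap = vbm_glm.permutation_fwe(
            vbm_glm.VolumeStack(data),
            design,
            n_perm=n_perm,
            seed=rng,
            mask=mask,
        )
        if (statmap.p_fwe[mask] < alpha).any():
            hits += 1
    return hits / n_datasets


def run_calibration(config: Mapping[str, Any], out_dir: str | Path) -> dict[str, float]:
    """Calibrate lambda to the configured target mean cosine; write summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    cal = config.get("calibrate", {})
    space = resolve_space(config, seed)
    policy = RetrievalPolicy(
        organization=0.5,
        sequence_length=int(cal.get("sequence_length", 26)),
    )
    result = calibrate_lambda(
        space,
        target=float(cal.get("target", 0.364)),
        policy=policy,
        tol=float(cal.get("tol", 0.005)),
        n_rep=int(cal.get("n_rep", 60)),
        seed=derive_seed(seed, "calibrate"),
    )
    out = out_dir / "calibration.json"
    out.write_text(json.dumps(result, indent=2), encoding="utf-8")
    write_sidecar(out, config, seed)
    return result
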