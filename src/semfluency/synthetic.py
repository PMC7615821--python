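"""Synthetic study data: spaces, retrieval sequences, cohorts, volumes.

The study data behind the fluency-coherence analysis (transcripts, SAMQ
ratings, MRI volumes) cannot be shared, so every stage of the pipeline is
exercised on synthetic inputs that emulate its statistical structure:

* :func:`make_clustered_space` — word vectors organized into semantic
  clusters (the category structure the animal fluency task taps), with a
  shared positive component so random word pairs have the moderately
  positive cosines typical of distributional spaces.
* :func:`simulate_sequence` — a retrieval model with one organization
  parameter lambda in [0, 1]: at each step the next answer is the
  nearest-by-cosine unvisited word with probability lambda (organized,
  semantically sequential retrieval) and a uniform unvisited word otherwise
  (random retrieval).  Out-of-vocabulary, repeated and disallowed answers
  are injected at configurable rates to exercise the NA-coding rules.
* :func:`simulate_cohort` — participants with SAMQ / age / gender / item
  counts drawn from the study's marginal distributions and fluency scores
  generated from a linear model with planted coefficients, either injected
  directly or realized through transcripts by inverting the lambda-to-cosine
  calibration curve.
* :func:`make_roster` — a pre-exclusion roster with missing-data and
  over-age flags.
* :func:`simulate_volumes` — smooth 3-D gray-matter-like maps with a
  compact region whose intensity scales with a participant score.

All generators are deterministic given their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from semfluency.semantic_space import SemanticSpace
from semfluency.vbm_glm import VolumeStack, gaussian_smooth
from semfluency.vft_scoring import (
    FluencyScores,
    Transcript,
    code_sequence,
    mean_adjacent_cosine,
    score_transcript,
)

__all__ = [
    "ClusterSpaceSpec",
    "RetrievalPolicy",
    "CohortSpec",
    "VolumeSpec",
    "DEFAULT_DISALLOWED",
    "make_clustered_space",
    "simulate_sequence",
    "lambda_calibration",
    "simulate_cohort",
    "make_roster",
    "simulate_volumes",
]

# category-word injections; ship as the default disallowed lexicon
DEFAULT_DISALLOWED = ("säugetiere", "vögel", "fische", "insekten", "reptilien")


@dataclass(frozen=True)
class ClusterSpaceSpec:
    """Geometry of a clustered synthetic semantic space.

    ``separation`` is the expected between-centroid distance in units of the
    within-cluster spread.  ``common_strength`` adds a shared positive
    component to every vector, lifting the baseline random-pair cosine to
    the moderately positive level real distributional spaces show (0 gives a
    centred isotropic space).  Vector norms are drawn independently of
    direction around ``norm_mean``.
    """

    n_clusters: int = 8
    words_per_cluster: int = 16
    dimensionality: int = 40
    separation: float = 4.0
    seed: int = 0
    common_strength: float = 0.65
    norm_mean: float = 2.811
    norm_sd: float = 0.48

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.words_per_cluster < 1:
            raise ValueError("cluster counts must be >= 1")
        if self.dimensionality < 1:
            raise ValueError("dimensionality must be >= 1")
        if self.dimensionality < 2 and self.n_clusters > 1:
            raise ValueError("need dimensionality >= 2 for multiple clusters")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")


@dataclass(frozen=True)
class RetrievalPolicy:
    """Retrieval behaviour for one simulated transcript.

    ``organization`` (lambda) interpolates between uniform-random retrieval
    (0) and strict nearest-semantic-neighbour retrieval (1).  The injection
    probabilities give, per emitted position, the chance the answer is an
    out-of-vocabulary word, a repetition of an earlier answer, or a
    disallowed category word instead of a fresh retrieval.
    """

    organization: float
    sequence_length: int = 26
    p_oov: float = 0.0
    p_duplicate: float = 0.0
    p_disallowed: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.organization <= 1.0:
            raise ValueError("organization must be in [0, 1]")
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")
        probs = (self.p_oov, self.p_duplicate, self.p_disallowed)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("injection probabilities must be in [0, 1]")
        if sum(probs) >= 1.0:
            raise ValueError("injection probabilities must sum to < 1")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and planted regression structure.

    Defaults follow the study cohort after exclusions (n = 101): SAMQ
    language-item histogram over -2..+3 of 5/9/19/18/32/18; age truncated
    normal 24.34 (SD 5.34) on [16, 40]; 23/101 male; item counts truncated
    normal 25.62 (SD 5.479) on [14, 41].  ``effects_cosine`` /
    ``effects_length`` plant linear coefficients of the two fluency scores
    on (intercept, samq, n_correct, age, gender); defaults are the study's
    point estimates, with residual SDs chosen so the implied t-ratios match
    the printed scale.
    """

    n_participants: int = 101
    samq_weights: Mapping[int, float] = field(
        default_factory=lambda: {-2: 5, -1: 9, 0: 19, 1: 18, 2: 32, 3: 18}
    )
    age_mean: float = 24.34
    age_sd: float = 5.34
    age_bounds: tuple[float, float] = (16.0, 40.0)
    p_male: float = 23 / 101
    items_mean: float = 25.62
    items_sd: float = 5.479
    items_bounds: tuple[float, float] = (14.0, 41.0)
    effects_cosine: Mapping[str, float] = field(
        default_factory=lambda: {
            "intercept": 0.374,
            "samq": 0.004,
            "n_correct": 0.000,
            "age": -0.001,
            "gender": -0.005,
        }
    )
    effects_length: Mapping[str, float] = field(
        default_factory=lambda: {
            "intercept": 3.047,
            "samq": -0.007,
            "n_correct": -0.007,
            "age": -0.001,
            "gender": -0.012,
        }
    )
    noise_sd_cosine: float = 0.023
    noise_sd_length: float = 0.09
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 7:  # 5 parameters + 2
            raise ValueError("n_participants must exceed #parameters + 2")
        total = sum(self.samq_weights.values())
        if total <= 0:
            raise ValueError("SAMQ weights must have positive total")
        if any(not -3 <= k <= 3 for k in self.samq_weights):
            raise ValueError("SAMQ levels must lie in [-3, 3]")


@dataclass(frozen=True)
class VolumeSpec:
    """Geometry and effect structure of a synthetic volume stack."""

    shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 1.5
    region_center: tuple[int, int, int] = (8, 8, 8)
    region_radius: float = 2.5
    effect_size: float = 1.0  # intensity change per unit (centred) score
    baseline: float = 0.5
    noise_sd: float = 0.1
    fwhm_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if any(s < 1 for s in self.shape):
            raise ValueError("grid shape entries must be >= 1")
        if not all(0 <= c < s for c, s in zip(self.region_center, self.shape)):
            raise ValueError("effect region centre outside grid")
        if self.region_radius < 0:
            raise ValueError("region radius must be nonnegative")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff

    def region_mask(self) -> np.ndarray:
        grid = np.indices(self.shape, dtype=float)
        d2 = sum(
            (grid[a] - self.region_center[a]) ** 2 for a in range(3)
        )
        return d2 <= self.region_radius**2


def make_clustered_space(spec: ClusterSpaceSpec) -> SemanticSpace:
    """Generate a clustered space; tokens are ``c<cluster>_w<word>``.

    Cluster members are an isotropic cloud around their centroid; centroids
    are scattered so the expected pairwise centroid distance is
    ``separation`` times the within-cluster spread; all directions get a
    shared positive component of magnitude ``common_strength``.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.dimensionality
    s = 1.0 / np.sqrt(d)  # within-cluster per-coordinate SD; noise norm ~ 1
    sigma_c = spec.separation * s / np.sqrt(2.0)
    centroids = rng.normal(0.0, sigma_c, size=(spec.n_clusters, d))
    common = np.zeros(d)
    common[0] = spec.common_strength  # fixed shared direction
    tokens: list[str] = []
    directions = []
    for ci in range(spec.n_clusters):
        noise = rng.normal(0.0, s, size=(spec.words_per_cluster, d))
        directions.append(common + centroids[ci] + noise)
        tokens.extend(
            f"c{ci:02d}_w{wi:02d}" for wi in range(spec.words_per_cluster)
        )
    dirs = np.vstack(directions)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    norms = np.abs(rng.normal(spec.norm_mean, spec.norm_sd, size=len(tokens)))
    norms = np.maximum(norms, 1e-3)
    return SemanticSpace(tuple(tokens), dirs * norms[:, None])


def simulate_sequence(
    space: SemanticSpace,
    policy: RetrievalPolicy,
    seed: int | np.random.Generator,
    disallowed: Sequence[str] = DEFAULT_DISALLOWED,
    participant_id: str = "sim",
) -> Transcript:
    """Simulate one transcript from the lambda-mixture retrieval model.

    Each emitted position is, with the policy's injection probabilities, an
    out-of-vocabulary token, a repetition of an earlier real answer, or a
    disallowed category word; otherwise a fresh retrieval: the
    nearest-by-cosine unvisited word to the previous real answer with
    probability lambda, else a uniform unvisited word.
    """
    if policy.sequence_length > len(space):
        raise ValueError(
            f"sequence_length {policy.sequence_length} exceeds vocabulary "
            f"size {len(space)}"
        )
    rng = np.random.default_rng(seed)
    # unit directions once; nearest-by-cosine = max dot of unit vectors
    unit = space.vectors / np.linalg.norm(space.vectors, axis=1, keepdims=True)
    unvisited = list(range(len(space)))
    emitted: list[str] = []
    real_indices: list[int] = []
    prev: int | None = None
    p_edges = np.cumsum([policy.p_oov, policy.p_duplicate, policy.p_disallowed])
    for pos in range(policy.sequence_length):
        u = rng.random()
        if u < p_edges[0]:
            emitted.append(f"zzoov{pos:03d}")  # never in a generated vocabulary
            continue
        if u < p_edges[1]:
            if real_indices:  # nothing to repeat yet -> fresh retrieval
                emitted.append(space.vocabulary[int(rng.choice(real_indices))])
                continue
        elif u < p_edges[2]:
            emitted.append(disallowed[int(rng.integers(len(disallowed)))])
            continue
        if not unvisited:
            break
        if prev is None or rng.random() >= policy.organization:
            idx = unvisited[int(rng.integers(len(unvisited)))]
        else:
            sims = unit[unvisited] @ unit[prev]
            idx = unvisited[int(np.argmax(sims))]
        unvisited.remove(idx)
        real_indices.append(idx)
        emitted.append(space.vocabulary[idx])
        prev = idx
    return Transcript(participant_id, tuple(emitted))


def lambda_calibration(
    space: SemanticSpace,
    policy: RetrievalPolicy,
    lambdas: Sequence[float] = tuple(np.linspace(0.0, 1.0, 11)),
    n_rep: int = 40,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo map lambda -> expected mean adjacent cosine.

    Returns (lambda grid, mean cosine per grid point), the basis for
    inverting target coherence scores into retrieval-organization values.
    The curve is made non-decreasing (isotonic running maximum) before
    inversion, since expected coherence is monotone in lambda up to MC
    noise.
    """
    rng = np.random.default_rng(seed)
    means = []
    for lam in lambdas:
        pol = replace(policy, organization=float(lam))
        vals = []
        for _ in range(n_rep):
            t = simulate_sequence(space, pol, rng)
            coded = code_sequence(t, space, DEFAULT_DISALLOWED)
            m, _ = mean_adjacent_cosine(coded, space)
            vals.append(m)
        means.append(float(np.mean(vals)))
    curve = np.maximum.accumulate(np.asarray(means))
    return np.asarray(list(lambdas), dtype=float), curve


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float], size: int
) -> np.ndarray:
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(
    spec: CohortSpec,
    space: SemanticSpace | None = None,
    mode: str = "inject",
    policy: RetrievalPolicy | None = None,
) -> tuple[pd.DataFrame, list[Transcript] | None]:
    """Simulate a cohort with planted covariate effects on the fluency scores.

    ``mode="inject"`` writes the linear-model scores directly into the
    cohort table (no transcripts; isolates the regression stage from
    retrieval-model noise).  ``mode="lambda"`` realizes each participant's
    target coherence by inverting the lambda calibration curve of ``space``
    and simulating an actual transcript; a target outside the achievable
    coherence range of the space raises an error naming the participant.
    """
    if mode not in ("inject", "lambda"):
        raise ValueError("mode must be 'inject' or 'lambda'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    levels = sorted(spec.samq_weights)
    weights = np.array([spec.samq_weights[k] for k in levels], dtype=float)
    weights /= weights.sum()
    samq = rng.choice(levels, size=n, p=weights)
    age = _truncnorm(rng, spec.age_mean, spec.age_sd, spec.age_bounds, n)
    gender = (rng.random(n) < spec.p_male).astype(int)  # 1 = male
    items = np.rint(
        _truncnorm(rng, spec.items_mean, spec.items_sd, spec.items_bounds, n)
    ).astype(int)

    def linpred(effects: Mapping[str, float]) -> np.ndarray:
        return (
            effects["intercept"]
            + effects["samq"] * samq
            + effects["n_correct"] * items
            + effects["age"] * age
            + effects["gender"] * gender
        )

    target_cos = linpred(spec.effects_cosine) + rng.normal(0, spec.noise_sd_cosine, n)
    target_len = linpred(spec.effects_length) + rng.normal(0, spec.noise_sd_length, n)
    ids = [f"P{i + 1:03d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "participant_id": ids,
            "samq": samq,
            "age": age,
            "gender": gender,
            "handedness": rng.choice(
                ["right", "left", "mixed"], size=n, p=[84 / 101, 8 / 101, 9 / 101]
            ),
            "n_correct": items,
        }
    )
    if mode == "inject":
        table["mean_cosine_similarity"] = target_cos
        table["mean_vector_length"] = target_len
        return table, None

    if space is None:
        raise ValueError("mode='lambda' requires a semantic space")
    if policy is None:
        policy = RetrievalPolicy(organization=0.5)
    grid, curve = lambda_calibration(
        space, policy, seed=int(rng.integers(2**31))
    )
    lo, hi = float(curve[0]), float(curve[-1])
    transcripts = []
    realized_cos = []
    realized_len = []
    for i, pid in enumerate(ids):
        tc = float(target_cos[i])
        if tc < lo or tc > hi:
            raise ValueError(
                f"participant {pid}: target mean cosine {tc:.3f} outside "
                f"achievable range [{lo:.3f}, {hi:.3f}] of this space"
            )
        lam = float(np.interp(tc, curve, grid))
        pol = replace(
            policy, organization=lam, sequence_length=int(items[i])
        )
        t = simulate_sequence(
            space, pol, int(rng.integers(2**31)), participant_id=pid
        )
        transcripts.append(t)
        sc = score_transcript(t, space, DEFAULT_DISALLOWED)
        realized_cos.append(sc.mean_cosine_similarity)
        realized_len.append(sc.mean_vector_length)
        table.loc[i, "n_correct"] = sc.n_correct
    table["mean_cosine_similarity"] = realized_cos
    table["mean_vector_length"] = realized_len
    return table, transcripts


def make_roster(n_total: int, n_flagged: int, seed: int = 0) -> pd.DataFrame:
    """Pre-exclusion roster with missing-data and over-age exclusion triggers.

    Exactly ``n_flagged`` rows carry at least one trigger among missing
    fluency data, missing MRI data, and age above 40; the remaining rows are
    clean and aged 16-40.
    """
    if n_total < 0 or n_flagged < 0:
        raise ValueError("counts must be nonnegative")
    if n_flagged > n_total:
        raise ValueError("n_flagged cannot exceed n_total")
    rng = np.random.default_rng(seed)
    age = _truncnorm(rng, 24.34, 5.34, (16.0, 40.0), n_total)
    missing_vft = np.zeros(n_total, dtype=bool)
    missing_mri = np.zeros(n_total, dtype=bool)
    flagged = rng.choice(n_total, size=n_flagged, replace=False)
    for i in flagged:
        # each flagged participant draws >= 1 of the three triggers
        while True:
            draws = rng.random(3) < (1 / 3)
            if draws.any():
                break
        if draws[0]:
            missing_vft[i] = True
        if draws[1]:
            missing_mri[i] = True
        if draws[2]:
            age[i] = rng.uniform(41.0, 60.0)
    return pd.DataFrame(
        {
            "participant_id": [f"R{i + 1:03d}" for i in range(n_total)],
            "age": age,
            "missing_vft": missing_vft,
            "missing_mri": missing_mri,
        }
    )


def simulate_volumes(
    scores: Sequence[FluencyScores] | pd.DataFrame | np.ndarray,
    spec: VolumeSpec,
) -> VolumeStack:
    """Simulate gray-matter-like volumes with a score-coupled effect region.

    ``volume_i = baseline + effect_size * (score_i - mean) * region + noise``
    then Gaussian-smoothed at the spec's FWHM; one shared affine.
    """
    if isinstance(scores, pd.DataFrame):
        score_vals = scores["mean_cosine_similarity"].to_numpy(dtype=float)
    elif len(scores) and isinstance(scores[0], FluencyScores):
        score_vals = np.array([s.mean_cosine_similarity for s in scores])
    else:
        score_vals = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(spec.seed)
    region = spec.region_mask()
    centred = score_vals - score_vals.mean()
    data = np.empty((len(score_vals), *spec.shape))
    for i, sc in enumerate(centred):
        vol = (
            spec.baseline
            + spec.effect_size * sc * region
            + rng.normal(0.0, spec.noise_sd, spec.shape)
        )
        data[i] = gaussian_smooth(vol, spec.fwhm_mm, spec.voxel_size_mm)
    return VolumeStack(data, spec.affine)
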