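"""Synthetic cohort and ASRT behaviour generator with known ground truth.

Emulates the structure of a pooled three-study healthy-young-adult cohort
(N = 47/103/85): demographics and morningness per study, correlated
integer-valued PSQI/AIS totals produced by discretizing a correlated latent
Gaussian, Study-2-only GSQS and sleep-diary scores, and twelve cognitive
outcome columns generated from a random-intercept linear model

    z(outcome) = u_study + beta * f + (covariate effects) + noise,

where ``f`` is the latent sleep-disturbance factor that PSQI and AIS
noisily indicate. ``beta`` defaults to zero — the generating conditions of
the evidence-for-null analyses — and every generated dataset carries a
:class:`SyntheticTruth` sidecar with the realized parameters so that
recovery can be tested against ground truth.

The trial-level simulator produces ASRT sessions whose deterministic RT
structure embeds a high-frequency advantage, an extra pattern-trial
advantage and a linear skill drift, with mean-preserving multiplicative
lognormal noise (right-skewed RTs); accuracy is Bernoulli with logit
shifts parametrized on the probability scale, so the engine's
statistical-learning and higher-order cells recover the injected effects
directly. Defaults are calibrated so that a default cohort lands near the
published index means (RT triplet learning ≈ 26.5 ms, ACC triplet
learning ≈ 0.04, average RT ≈ 360 ms).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .asrt import PatternSequence, classify_triplets, generate_stream
from .models import OUTCOMES
from .questionnaires import SCALE_RANGES

__all__ = [
    "CohortConfig",
    "ASRTEffects",
    "SyntheticTruth",
    "generate_cohort",
    "generate_asrt_participant",
]

#: Published per-study demographics: (mean age, sd age), male fraction,
#: (mean MEQ, sd MEQ).
_STUDY_AGE = ((21.38, 1.79), (21.62, 2.00), (20.99, 1.59))
_STUDY_MALE = (10 / 47, 30 / 103, 23 / 85)
_STUDY_MEQ = ((34.96, 6.69), (33.99, 6.31), (33.61, 5.68))

#: Pooled-sample outcome means and SDs used as output scales.
OUTCOME_SCALES: dict[str, tuple[float, float]] = {
    "rt_triplet": (26.48, 26.37),
    "rt_higher_order": (16.63, 40.34),
    "rt_statistical": (16.74, 9.94),
    "rt_average": (359.88, 40.94),
    "rt_general_skill": (31.13, 30.15),
    "acc_triplet": (0.04, 0.03),
    "acc_higher_order": (0.02, 0.03),
    "acc_statistical": (0.03, 0.03),
    "acc_average": (0.90, 0.10),
    "acc_general_skill": (-0.02, 0.09),
    "counting_span": (3.59, 0.85),
    "wcst_persev_err": (14.76, 5.27),
}


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters of a synthetic cohort.

    ``true_beta`` is the standardized effect of the *latent* sleep
    disturbance on each outcome (scalar = same for all); zero by default.
    Score marginals target the published means/SDs; integer scores come
    from rounding/clipping a correlated latent Gaussian, which shifts the
    means slightly upward for strongly skewed scales (documented in the
    methods note).
    """

    study_sizes: tuple[int, int, int] = (47, 103, 85)
    age: tuple[tuple[float, float], ...] = _STUDY_AGE
    male_fraction: tuple[float, ...] = _STUDY_MALE
    meq: tuple[tuple[float, float], ...] = _STUDY_MEQ
    psqi: tuple[float, float] = (2.99, 1.57)
    ais: tuple[float, float] = (3.98, 2.66)
    gsqs: tuple[float, float] = (2.86, 2.87)
    diary: tuple[float, float] = (1.38, 1.22)
    latent_r: float = 0.55  # PSQI–AIS latent correlation
    gsqs_loading: float = 0.5  # correlation of GSQS/diary latents with f
    diary_loading: float = 0.5
    true_beta: float | Mapping[str, float] = 0.0
    study_intercept_sd: float = 0.2
    residual_sd: float | None = None  # None: chosen so var(z-outcome) ≈ 1
    covariate_betas: tuple[float, float, float] = (0.0, 0.0, 0.0)  # age, gender, meq
    n_missing_ef: int = 6  # executive-function scores missing (technical loss)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.study_sizes):
            raise ValueError("study sizes must be positive")
        if not -1.0 < self.latent_r < 1.0:
            raise ValueError("latent_r must lie in (-1, 1)")
        for name in ("psqi", "ais", "gsqs", "diary"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} SD must be >= 0")
        if self.study_intercept_sd < 0:
            raise ValueError("study_intercept_sd must be >= 0")
        betas = self.beta_map().values()
        if self.residual_sd is not None and self.residual_sd == 0 and any(
            b != 0 for b in betas
        ):
            raise ValueError("residual_sd = 0 with nonzero true beta is infeasible")

    def beta_map(self) -> dict[str, float]:
        if isinstance(self.true_beta, Mapping):
            return {o: float(self.true_beta.get(o, 0.0)) for o in OUTCOMES}
        return {o: float(self.true_beta) for o in OUTCOMES}


@dataclass
class SyntheticTruth:
    """Realized generating parameters of one synthetic cohort."""

    true_beta: dict[str, float]
    study_intercepts: dict[str, np.ndarray]  # per outcome, one value per study
    residual_sd: dict[str, float]
    latent_disturbance: np.ndarray  # f, one value per participant
    latent_r: float
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "true_beta": self.true_beta,
            "study_intercepts": {k: v.tolist() for k, v in self.study_intercepts.items()},
            "residual_sd": self.residual_sd,
            "latent_disturbance": self.latent_disturbance.tolist(),
            "latent_r": self.latent_r,
            "seed": self.seed,
            "config": self.config,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _discretize(latent_z: np.ndarray, mean: float, sd: float, scale: str) -> np.ndarray:
    lo, hi = SCALE_RANGES[scale]
    return np.clip(np.rint(mean + sd * latent_z), lo, hi).astype(int)


def generate_cohort(
    config: CohortConfig = CohortConfig(),
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a participant table and its ground truth.

    Deterministic for a fixed seed: the same seed reproduces the table
    bit-for-bit. Columns follow the pipeline's CSV schema: study,
    participant_id, age, gender, meq, psqi, ais, gsqs, diary, plus the
    twelve cognitive outcome columns.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = config.study_sizes
    n = sum(sizes)
    study = np.repeat(np.arange(1, len(sizes) + 1), sizes)

    age = np.concatenate(
        [rng.normal(m, s, size=k) for (m, s), k in zip(config.age, sizes)]
    ).round(2)
    gender = np.concatenate(
        [
            np.where(rng.random(k) < frac, "M", "F")
            for frac, k in zip(config.male_fraction, sizes)
        ]
    )
    meq = np.concatenate(
        [np.rint(rng.normal(m, s, size=k)) for (m, s), k in zip(config.meq, sizes)]
    ).astype(int)

    # correlated latent Gaussians: f is the disturbance factor; PSQI and AIS
    # load sqrt(r) on it, giving corr(psqi, ais) = r
    r = config.latent_r
    a = np.sqrt(abs(r))
    f = rng.standard_normal(n)
    z_psqi = a * f + np.sqrt(1 - a * a) * rng.standard_normal(n)
    z_ais = np.sign(r) * a * f + np.sqrt(1 - a * a) * rng.standard_normal(n)
    psqi = _discretize(z_psqi, *config.psqi, "psqi")
    ais = _discretize(z_ais, *config.ais, "ais")

    def study2_scale(loading: float, mean: float, sd: float, scale: str) -> np.ndarray:
        z = loading * f + np.sqrt(1 - loading**2) * rng.standard_normal(n)
        vals = _discretize(z, mean, sd, scale).astype(float)
        vals[study != 2] = np.nan
        return vals

    gsqs = study2_scale(config.gsqs_loading, *config.gsqs, "gsqs")
    diary = study2_scale(config.diary_loading, *config.diary, "diary")

    table = pd.DataFrame(
        {
            "study": study,
            "participant_id": np.arange(1, n + 1),
            "age": age,
            "gender": gender,
            "meq": meq,
            "psqi": psqi,
            "ais": ais,
            "gsqs": gsqs,
            "diary": diary,
        }
    )

    # cognitive outcomes from the random-intercept linear model on z-scale
    betas = config.beta_map()
    tau = config.study_intercept_sd
    b_age, b_gender, b_meq = config.covariate_betas
    z_age = (age - age.mean()) / age.std(ddof=1)
    z_meq = (meq - meq.mean()) / (meq.std(ddof=1) or 1.0)
    x_gender = np.where(gender == "M", 1.0, -1.0)
    intercepts: dict[str, np.ndarray] = {}
    resid_sds: dict[str, float] = {}
    for outcome in OUTCOMES:
        beta = betas[outcome]
        if config.residual_sd is not None:
            sd_e = config.residual_sd
        else:
            explained = beta**2 + tau**2 + b_age**2 + b_gender**2 + b_meq**2
            sd_e = float(np.sqrt(max(1.0 - explained, 0.05)))
        u = rng.normal(0.0, tau, size=len(sizes))
        y_z = (
            u[study - 1]
            + beta * f
            + b_age * z_age
            + b_gender * x_gender
            + b_meq * z_meq
            + rng.normal(0.0, sd_e, size=n)
        )
        mean_k, sd_k = OUTCOME_SCALES[outcome]
        table[outcome] = mean_k + sd_k * y_z
        intercepts[outcome] = u
        resid_sds[outcome] = sd_e
    table["counting_span"] = table["counting_span"].clip(1.0, 6.0).round(2)
    table["wcst_persev_err"] = table["wcst_persev_err"].clip(lower=0.0).round(0)
    table["acc_average"] = table["acc_average"].clip(0.0, 1.0)

    if config.n_missing_ef > 0:
        drop = rng.choice(n, size=config.n_missing_ef, replace=False)
        table.loc[table.index[drop], "wcst_persev_err"] = np.nan

    truth = SyntheticTruth(
        true_beta=betas,
        study_intercepts=intercepts,
        residual_sd=resid_sds,
        latent_disturbance=f,
        latent_r=r,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
        config=dataclasses.asdict(config),
    )
    return table, truth


# ---------------------------------------------------------------------------
# trial-level ASRT simulation


@dataclass(frozen=True)
class ASRTEffects:
    """Injected learning effects for the trial-level simulator.

    RT effects are in milliseconds: ``triplet_rt`` is the high-frequency
    advantage (recovered as statistical learning), ``pattern_rt`` the extra
    pattern-trial advantage (recovered as higher-order sequence learning),
    ``skill_rt`` the total linear RT drop across the session. ACC effects
    are on the probability scale at the low-frequency baseline ``acc_base``
    (converted to logit shifts internally), so the engine's cell contrasts
    recover them directly.
    """

    triplet_rt: float = 16.7
    pattern_rt: float = 12.2
    skill_rt: float = 39.4
    triplet_acc: float = 0.035
    pattern_acc: float = 0.01
    skill_acc: float = 0.02

    @classmethod
    def none(cls) -> "ASRTEffects":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def _logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p) - np.log1p(-p)


def generate_asrt_participant(
    effects: ASRTEffects = ASRTEffects(),
    base_rt: float = 359.9,
    rt_noise_sd: float = 0.11,
    acc_base: float = 0.87,
    n_blocks: int = 20,
    block_length: int = 85,
    n_warmup: int = 5,
    pattern: PatternSequence | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one participant's ASRT session (positions, RTs, accuracy).

    ``base_rt`` is approximately the session-average RT of correct trials;
    ``rt_noise_sd`` is the lognormal sigma of the mean-preserving
    multiplicative RT noise (0.11 ≈ 11% coefficient of variation, giving
    an RT SD near 40 ms at 360 ms); ``acc_base`` is the accuracy of
    low-frequency trials.
    """
    if not (0.0 < acc_base < 1.0):
        raise ValueError("acc_base must lie in (0, 1)")
    for delta in (effects.triplet_acc, effects.pattern_acc):
        if not (0.0 < acc_base + delta < 1.0):
            raise ValueError("accuracy effects push probabilities outside (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if pattern is None:
        order = rng.permutation([1, 2, 3, 4])
        pattern = PatternSequence(tuple(int(v) for v in order))

    stream = generate_stream(pattern, n_blocks, block_length, n_warmup, seed=rng)
    labels = classify_triplets(stream, pattern)
    is_high = (labels["frequency"] == "high").to_numpy()
    is_pattern = (stream["trial_type"] == "pattern").to_numpy()
    block = stream["block"].to_numpy()
    progress = (block - 1) / max(n_blocks - 1, 1)

    # shares of the included-trial pool (pattern 4/7, random-high 1/7);
    # recentering keeps the included-trial mean RT at ~base_rt
    share_high, share_pattern = 5.0 / 7.0, 4.0 / 7.0
    base0 = base_rt + effects.triplet_rt * share_high + effects.pattern_rt * share_pattern
    det = (
        base0
        + effects.skill_rt * (0.5 - progress)
        - effects.triplet_rt * is_high
        - effects.pattern_rt * is_pattern
    )
    noise = np.exp(rng.normal(-0.5 * rt_noise_sd**2, rt_noise_sd, size=len(det)))
    rt = det * noise

    eta = np.full(len(det), _logit(acc_base))
    eta += np.where(is_high, _logit(acc_base + effects.triplet_acc) - _logit(acc_base), 0.0)
    eta += np.where(
        is_pattern,
        _logit(acc_base + effects.triplet_acc + effects.pattern_acc)
        - _logit(acc_base + effects.triplet_acc),
        0.0,
    )
    p_base_drift = np.clip(acc_base + effects.skill_acc * (progress - 0.5), 1e-3, 1 - 1e-3)
    eta += _logit(p_base_drift) - _logit(acc_base)
    p_correct = 1.0 / (1.0 + np.exp(-eta))
    correct = (rng.random(len(det)) < p_correct).astype(int)

    out = stream.copy()
    out["rt_ms"] = rt
    out["correct"] = correct
    return out
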