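"""Synthetic samples and null families with known ground truth.

The generator emulates the score tables a protein-inference pipeline
would emit. True-positive proteins receive high probabilities drawn
from Beta(8, 1); false-positive targets and decoy identifications share
a common low-score distribution, Beta(1, 8) — encoding the target-decoy
assumption that decoy scores model false-positive scores. Each sample
comes with ``n_repeats`` independent decoy score sets (default 20,
matching the usual number of permutation repeats), so the pooled null
has M = n_repeats * (n_true + n_false) scores.

A second generator produces families of null distributions whose
cumulative probabilities follow a logit-linear model in a scalar
feature, the exact generating process assumed by the null-inference
model; it is the test bed for coefficient recovery and held-out
inference.

Labels make the true FDR computable: the realized fraction of accepted
proteins that are false positives, the quantity an FDR estimate is
judged against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .fdr import accept_at, bh_adjust
from .features import FeatureVector
from .null_model import (
    NullDistribution,
    ProteinScore,
    SampleScores,
    build_null,
    pool_decoy_scores,
    pvalues,
)

TRUE_POSITIVE = "true_positive"
FALSE_POSITIVE = "false_positive"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic sample."""

    n_true: int = 300
    n_false: int = 700
    true_params: tuple[float, float] = (8.0, 1.0)
    false_params: tuple[float, float] = (1.0, 8.0)
    n_repeats: int = 20
    seed: int = 0
    bin_width: float = 0.003

    def __post_init__(self) -> None:
        if self.n_true + self.n_false < 1:
            raise ValueError("need at least one target protein")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")
        for a, b in (self.true_params, self.false_params):
            if a <= 0 or b <= 0:
                raise ValueError("Beta parameters must be positive")


@dataclass
class SyntheticSample:
    scores: SampleScores
    labels: dict[str, str]
    decoy_repeats: list[SampleScores] = field(default_factory=list)
    config: SimulationConfig | None = None


def _beta_scores(rng: np.random.Generator, n: int, params: tuple[float, float]) -> np.ndarray:
    return np.clip(rng.beta(*params, size=n), 0.0, 1.0)


def simulate_sample(config: SimulationConfig) -> SyntheticSample:
    """Draw one labelled sample plus its permutation decoy repeats."""
    rng = np.random.default_rng(config.seed)
    n_targets = config.n_true + config.n_false
    true_scores = _beta_scores(rng, config.n_true, config.true_params)
    false_scores = _beta_scores(rng, config.n_false, config.false_params)
    entries: list[ProteinScore] = []
    labels: dict[str, str] = {}
    for i, s in enumerate(true_scores):
        acc = f"T{i + 1:05d}"
        entries.append(ProteinScore(accession=acc, score=float(s)))
        labels[acc] = TRUE_POSITIVE
    for i, s in enumerate(false_scores):
        acc = f"F{i + 1:05d}"
        entries.append(ProteinScore(accession=acc, score=float(s)))
        labels[acc] = FALSE_POSITIVE
    repeats = []
    for rep in range(config.n_repeats):
        decoy_scores = _beta_scores(rng, n_targets, config.false_params)
        repeats.append(
            SampleScores(
                sample_id=f"repeat_{rep + 1}",
                entries=[
                    ProteinScore(
                        accession=f"DECOY_{rep + 1}_{i + 1:05d}",
                        score=float(s),
                        decoy=True,
                    )
                    for i, s in enumerate(decoy_scores)
                ],
                provenance="simulated decoy repeat",
            )
        )
    sample = SampleScores(
        sample_id=f"sim_seed{config.seed}",
        entries=entries,
        provenance="simulated",
    )
    return SyntheticSample(scores=sample, labels=labels, decoy_repeats=repeats, config=config)


def simulate_null_family(
    I: int,
    feature_values,
    beta: np.ndarray,
    K: int,
    seed: int = 0,
    noise_sd: float = 0.0,
    lo: float = 0.0,
    hi: float = 1.0,
    nominal_m: float = 1e6,
) -> tuple[list[NullDistribution], list[FeatureVector]]:
    """Generate I nulls whose CDFs are logit-linear in a scalar feature.

    ``beta`` is a (K-1) x 2 array of per-bin (intercept, slope) pairs.
    For each sample i and bin k < K,
    Pr_{i,k} = logistic(beta_{k,0} + beta_{k,1} r_i + eps) with
    eps ~ Normal(0, noise_sd); the sequence is made monotone in k,
    capped by Pr_{i,K} = 1, and differenced into a density. Counts are
    stored as exact fractional mass at ``nominal_m``, so with
    noise_sd = 0 refitting recovers ``beta`` to machine precision.
    """
    feature_values = np.asarray(feature_values, dtype=float)
    if len(feature_values) != I:
        raise ValueError("feature_values must have length I")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (K - 1, 2):
        raise ValueError(f"beta must have shape ({K - 1}, 2), got {beta.shape}")
    rng = np.random.default_rng(seed)
    bin_width = (hi - lo) / K
    nulls: list[NullDistribution] = []
    features: list[FeatureVector] = []
    for i, r in enumerate(feature_values):
        lin = beta[:, 0] + beta[:, 1] * r
        if noise_sd > 0:
            lin = lin + rng.normal(0.0, noise_sd, size=K - 1)
        cum = np.append(expit(lin), 1.0)
        cum = np.minimum(np.maximum.accumulate(cum), 1.0)
        density = np.diff(cum, prepend=0.0)
        if np.any(density < 0):
            raise ValueError("degenerate parameters: could not monotonize CDF")
        nulls.append(
            NullDistribution(counts=density * nominal_m, bin_width=bin_width, lo=lo, hi=hi)
        )
        features.append(FeatureVector(sample_id=f"family_{i + 1}", r=np.array([r])))
    return nulls, features


def true_fdr(accepted, labels: dict[str, str]) -> float:
    """Realized FDR: fraction of accepted proteins labelled false positive.

    Returns 0 for an empty accepted set by convention.
    """
    accepted = list(accepted)
    if not accepted:
        return 0.0
    unknown = [a for a in accepted if a not in labels]
    if unknown:
        raise ValueError(f"unlabelled accessions in accepted set: {unknown[:3]}")
    n_false = sum(1 for a in accepted if labels[a] == FALSE_POSITIVE)
    return n_false / len(accepted)


def calibration_report(sample: SyntheticSample, alphas) -> pd.DataFrame:
    """Estimated vs true FDR at each BH level, on one synthetic sample.

    Builds the empirical null from the sample's pooled decoy repeats,
    computes p-values, runs BH acceptance per alpha, and reports the
    estimated FDR (the BH q-value of the last accepted protein), the
    realized true FDR among accepted proteins, and their absolute
    difference — the evaluation metric for FDR estimators on labelled
    data.
    """
    cfg = sample.config or SimulationConfig()
    decoys = pool_decoy_scores(sample.decoy_repeats)
    null = build_null(decoys, bin_width=cfg.bin_width)
    pset = pvalues(null, sample.scores)
    q = bh_adjust(pset.p)
    rows = []
    for alpha in alphas:
        count, idx = accept_at(pset.p, alpha)
        accepted = [pset.accessions[i] for i in idx]
        est = float(np.max(q[idx])) if count else 0.0
        truth = true_fdr(accepted, sample.labels)
        rows.append(
            {
                "alpha": alpha,
                "n_accepted": count,
                "estimated_fdr": est,
                "true_fdr": truth,
                "abs_difference": abs(est - truth),
            }
        )
    return pd.DataFrame(rows)
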